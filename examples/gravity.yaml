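# Synthetic negative-geotaxis experiment: sham vs exposed, trajectory level.
# Set `render: true` to rasterise videos and run the full tracking chain.
mode: gravity
seed: 1
out_dir: flymag_out
gravity:
  n_tubes_per_group: 5
  exposure_effect: 1.0       # 1.0 = null; 0.7 = 30% climb-speed reduction
  render: false
  subsample: 10
  kinematics:
    n_flies: 10
    n_trials: 5
    trial_duration_s: 30
    fps: 10
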