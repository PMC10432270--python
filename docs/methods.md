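# Methods

This note documents the models implemented in `flymag`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Synthetic data

### T-maze choice counts

A T-maze run releases a set of roughly 100 flies that distribute between a
magnetic and a non-magnetic arm. The generator draws, per set, a choice
probability from a Beta distribution with mean `p_magnetic` and variance
`icc · p(1−p)`, then a binomial count given that probability. The
intraclass correlation `icc` is therefore the exchangeable within-set
correlation of fly choices; `icc = 0` collapses exactly to independent
Bernoulli choices. The beta-binomial was chosen because it is the standard
generative model for overdispersed proportion data and because it makes the
pseudoreplication phenomenon quantitative: the variance of a set's count is
`n·p(1−p)·(1 + (n−1)·icc)`, so even tiny correlations inflate between-set
scatter far beyond what a per-fly analysis assumes. Defaults: sets of 100
flies, `p_magnetic = 0.5` (the empirical behaviour of flies with no
magnetic preference), `icc = 0` unless a study asks otherwise.

### Climbing trajectories

Each fly draws a persistent base climbing speed from
`Normal(speed_mean · exposure_effect, speed_sd)`, clipped at zero; in each
frame it pauses with probability `pause_prob` or advances by
`base_speed / fps`. Heights are confined to `[0, 20 cm]` (200 mm tubes) and
reset to zero at every trial start, emulating the knockdown or vacuum
pulse. Defaults — 10 flies/tube, 5 trials of 30 s at 10 frames/s,
`speed_mean = 1.5 cm/s`, `speed_sd = 0.5 cm/s`, `pause_prob = 0.25` — were
chosen once so that roughly 60 % of flies meet the 15 cm / 15 s climber
criterion with a smooth, unimodal spread of climbed distances (observed
climbing data are graded, not bimodal, which is why a persistent per-fly
speed rather than i.i.d. per-step speeds is the right minimal model: per-step
noise alone averages out and produces an all-or-nothing criterion).
The persistent speed also induces realistic tube-level heterogeneity and
across-trial correlation, which is what the mixed models' random intercepts
are for.

### Rendering

Ground-truth trajectories are rasterised as dark ellipses
(default semi-axes 5 × 3.5 px, grey 30) on a bright backlit field (grey 200)
with additive Gaussian sensor noise, in 8-bit grayscale. Each fly occupies
its own vertical lane inside the tube so that separated silhouettes never
merge; an optional faint mirrored ellipse emulates reflections off the tube
wall. The rendered world deliberately omits optics, fly–fly occlusion and
interaction, shadows, and illumination gradients — so a tracking test that
passes here demonstrates correctness of the segmentation chain, not
robustness to every artefact of real footage (the known failure mode of the
real assay, crowding just after knockdown, is exactly what lane placement
removes). All generators take one explicit seed; no global random state.

## Tracking

The chain follows the order: preprocessing → background → per-frame scaling
→ subtraction → opening → binarisation → region measurement → gates.

* **Preprocessing.** Gamma correction with exponent 0.45 on intensities
  normalised to [0, 1], then unsharp masking
  `out = in + 0.93·(in − G₁(in))`, clipped to range.
* **Background.** Pass 1: per-pixel arithmetic mean of all frames. Pass 2:
  per-pixel mean over frames whose intensity is not more than 20 % below
  the pass-1 mean (darker frames are presumed to contain a fly). A pixel is
  *unreliable* when any frame was excluded (`min_reliable_fraction = 1.0`;
  the strictest reading — only pixels flies actually crossed are affected,
  and those are precisely the ones that need filling). Unreliable pixels
  are filled by a 10 px square moving average over reliable neighbours,
  iterated outward until everything is filled (a 2-D window; with a 1-D
  ambiguity in the prose, 2-D is the symmetric choice). The result is
  smoothed with a σ = 1 px Gaussian.
* **Per-frame scaling.** `a·frame + b` fitted by least squares against the
  background over off-tube calibration strips. Over a flat backlit field
  the gain is not identifiable (the regression would chase sensor noise and
  collapse the image), so when the background varies by < 2 grey levels
  across the calibration pixels the gain is pinned at 1 and only the offset
  is fitted. Degenerate (constant, or single-pixel) calibration regions are
  an error.
* **Detection.** Difference is computed as background − frame so flies are
  bright. Grayscale opening with a disk (radius 2 px by default) precedes
  binarisation, which uses Otsu's threshold on the opened difference with a
  10-grey-level floor (the floor prevents Otsu from hallucinating structure
  in noise-only frames; a fixed threshold can be configured instead).
  Connected regions are measured by normalised second central moments
  (ellipse-equivalent axes, the regionprops convention); a region is kept
  only if major axis ∈ [4, 20] px, minor ∈ [3, 20] px and area
  ∈ [8, 200] px². The ranges gate the measured regions, not the structuring
  element; the removal of small connected regions is subsumed by the
  8 px² minimum. Note an interaction: the radius-2 disk suppresses blobs
  narrower than ~5 px, so silhouettes at the very bottom of the admissible
  minor-axis range are only detectable with a radius-1 disk (both are
  configurable).
* **Coordinates.** Pixel origin top-left, y down, frames 0-based,
  time = index / fps. Height in cm is measured from the bottom ROI row
  (tube base) with a cm-per-pixel calibration; 20 cm tubes throughout.
* **Validity.** Gravity mode: any (tube, frame) with more than 10
  detections is marked excluded (false positives); excluded frames
  contribute to no downstream statistic. FlyVac mode: a fly is dropped
  entirely if its height at any trial's first frame exceeds 1 cm (the
  vacuum pulse failed to bring it down; the threshold is configurable, as
  no quantitative criterion is standard) or if its height range is zero in
  every trial.
* **No identity.** In the group assay flies are not individually tracked —
  with ten interchangeable silhouettes, identity maintenance is both
  impossible and unnecessary. All downstream statistics are identity-free.

## Climbing statistics

* **Climber proportion.** Per tube × trial: the running maximum over frames
  at or before 15 s of (detections above 15 cm) / group size, capped at 1.
  The running maximum is the identity-free reading of "how many flies have
  reached the line by now"; the time bound is inclusive. The cumulative
  proportion timecourse is the same quantity per frame, averaged across
  tubes with a Wilson score interval from pooled counts (Wilson, because
  normal intervals misbehave at 0 and 1, exactly where these curves live).
  Evaluated at 15 s the curve equals the scalar criterion by construction.
* **Mean-height timecourse.** Per-frame tube-average height, then mean and
  s.d. across tubes. Frames with no valid detection in a tube are missing,
  never zero.
* **Exposure tests.**
  - *Repeated-measures ANOVA* on per-trial climber ratios (mixed ANOVA:
    Exposure between, trial within, tube as subject — the repeated-measure
    structure is trials within replicate, the natural reading for this
    design).
  - *Binomial GLMM* of per-frame above-line counts on Exposure with random
    intercepts `(1|id) + (1|trial/frame)`, fitted variationally
    (`BinomialBayesMixedGLM`). **Limitation:** the mean-field posterior
    understates fixed-effect uncertainty when biological replicates are few
    (5–15 tubes), so its p-values are anti-conservative; every result
    carries a `variational_approximation` warning and the calibrated routes
    below should be used for inference.
  - *Linear mixed model* `Ycm ~ Exposure × condition + (1|id) +
    (1|trial/frame)` on per-frame tube-mean heights (the interaction is
    dropped with a single condition level). The shared frame-in-trial
    random effects absorb the common climb curve; the replicate intercept
    absorbs tube-level heterogeneity. Fixed effects use sum-to-zero
    contrasts and type-III Wald F tests with between-replicate denominator
    degrees of freedom (`n_ids − p`), the appropriate reference for a
    between-tube factor — Wald tests with normal reference would be
    anti-conservative at these replicate counts. REML fitting uses Powell's
    method, which converges reliably on this variance-component structure
    where quasi-Newton optimisers often fail; non-convergence and singular
    fits are flagged, not hidden.
  - Fitting at 10 fps is wasteful — adjacent frames are nearly redundant —
    so frames are subsampled (default every 5th) before fitting; the
    subsampling factor is exposed and the tests check insensitivity.
    Null calibration of both the ANOVA and LME routes was verified by
    simulation (rejection rates within [0.03, 0.07] at α = 0.05, ≥ 500
    null replicates each; see `tests/test_acceptance.py`, which uses
    8 tubes/group, 5 × 20 s trials, every 20th frame — sizes chosen to
    exercise the exact model at realistic replicate counts).

## T-maze statistics

* **Preference index.** `PI = 2·P_M − 1` per set.
* **Group tests** model per-set (magnetic, non-magnetic) counts on the
  group factor. Three dispersion treatments: plain binomial (likelihood-
  ratio χ²), quasi-binomial (F test with Pearson-estimated scale — the
  default, since real sets are overdispersed and the F reference keeps the
  test calibrated at 10–50 sets), and beta-binomial maximum likelihood
  (likelihood-ratio χ², for likelihood-based intervals). Complete
  separation is flagged. All tests are two-sided.
* **Pseudoreplicated test.** The per-fly t-test (or pooled two-proportion
  z-test) that treats every fly as an independent replicate. It is
  implemented *deliberately* and labelled "for comparison only": its only
  legitimate use is demonstrating how within-set correlation inflates
  significance. It runs even with one set per group — that it produces a
  p-value at all in that design is the fallacy.
* **Effect size and power.** Cohen's `h = 2·arcsin√p₂ − 2·arcsin√p₁`;
  two-sided power of the two-sample arcsine test under the normal
  approximation, `Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2})` with
  `λ = |h|·√(n₁n₂/(n₁+n₂))`. At `h = 0` this is exactly α. The arcsine
  form was chosen because it is the standard companion of Cohen's h and it
  reproduces the ~10 % power of the largest published contrast
  (0.445 vs 0.585 at n = 10/12) from its printed inputs. The approximation
  is accurate to ±0.01 against Monte-Carlo for moderate group sizes
  (n ≳ 25); at n ≈ 10 binomial discreteness introduces deviations of about
  one percentage point. Sample-size inversion seeds with
  `(z_{1−α/2}+z_power)²/h²` and searches integers for the exact threshold.
* **Type-I-error study.** For each ICC on a grid, simulate paired null
  groups, apply both the set-level GLM and the per-fly test, and tabulate
  rejection rates. Deterministic given one seed (per-replicate seeds are
  spawned from a `SeedSequence`).

## Blinding and reproducibility

Treatment labels are replaced by opaque random codes; the code→label map
lives in a separate key file protected by a salted SHA-256 hash (software
stand-in for the hardware encryption used in blinded rigs — sufficient to
keep the analyst blind, not a cryptographic guarantee against a determined
adversary). Statistics never inspect label contents, so blinded and
unblinded analyses are identical. Pipeline runs write a JSON-lines log with
every parameter including defaults, and a summary embedding the config hash
and seed; identical config + seed reproduces the summary byte for byte.

## Known limitations

* The renderer's separated-lane placement means tracking benchmarks do not
  probe occlusion handling; the real algorithm simply loses merged blobs to
  the area gate, as the original did in the seconds after knockdown.
* A fly that never moves for an entire recording is absorbed into the
  estimated background and cannot be detected — an intrinsic property of
  self-calibrated background subtraction, shared with the original method.
* The variational binomial GLMM is descriptive, not inferential, at small
  replicate counts (see above).
* The arcsine power formula is an approximation; at very small n use the
  Monte-Carlo route the tests use for validation.
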