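"""Configuration, file formats, blinding and the end-to-end pipeline.

Formats are deliberately plain: frame stacks as directories of zero-padded
PNGs or multipage TIFF, tables as CSV, configuration as YAML or JSON, and a
JSON-lines run log that records every parameter (including defaults) so any
run can be reproduced from its log.  The blinding utility replaces true
exposure/condition labels with random codes and stores the mapping in a
separate, hash-protected key file, mirroring the experimental practice of
revealing the field conditions only after the analysis is frozen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import secrets
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import geotaxis, tmaze, tracking
from .synthetic import (
    ClimbKinematics,
    GroundTruth,
    TMazeSimParams,
    VideoSpec,
    render_video,
    simulate_climb_trajectories,
    simulate_tmaze_experiment,
    track_table_from_ground_truth,
    write_choice_sets_csv,
    write_frames,
)
from .tracking import FrameStack, SegmentationParams, TrackTable

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "read_frames",
    "write_background",
    "read_choice_sets_csv",
    "blind_labels",
    "unblind_labels",
    "write_blinding_key",
    "read_blinding_key",
    "run_pipeline",
]

MODES = ("tmaze", "gravity", "flyvac")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated run configuration for :func:`run_pipeline`."""

    mode: str
    seed: int = 0
    out_dir: str = "flymag_out"
    log_level: str = "INFO"
    options: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "mode" not in d:
            raise ValueError("config is missing required field 'mode'")
        known = {f.name for f in dataclasses.fields(cls)} - {"options"}
        return cls(**{k: d[k] for k in known if k in d},
                   options={k: v for k, v in d.items() if k not in known})


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def read_frames(path, fps: float = 10.0) -> FrameStack:
    """Read a frame stack from a PNG/TIFF directory or a multipage TIFF."""
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {p}")
        frames = np.stack([_to_gray(iio.imread(f)) for f in files])
    elif p.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
        frames = np.stack([_to_gray(f) for f in frames])
    else:
        raise ValueError(f"unsupported frame source: {p}")
    return FrameStack(frames.astype(np.uint8), fps=fps)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img


def write_background(model: tracking.BackgroundModel, tiff_path, json_path) -> None:
    """Persist a background model as TIFF (float) plus JSON metadata."""
    tifffile.imwrite(tiff_path, model.background.astype(np.float32))
    meta = {
        "reliable_fraction": float(model.reliability_mask.mean()),
        "n_contributing_min": int(model.n_contributing.min()),
        "n_contributing_max": int(model.n_contributing.max()),
    }
    Path(json_path).write_text(json.dumps(meta, sort_keys=True, indent=2))


def read_choice_sets_csv(path) -> list:
    """Read ChoiceSets from a CSV with columns set_id, group, n_magnetic, n_total."""
    df = pd.read_csv(path)
    return [
        tmaze.ChoiceSet(int(r.n_magnetic), int(r.n_total),
                        group=str(r.group), set_id=int(r.set_id))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# blinding
# ---------------------------------------------------------------------------

def blind_labels(design: pd.DataFrame, columns=("Exposure", "condition"),
                 seed: int = 0, id_column: str = "id"):
    """Replace true treatment labels with opaque random codes.

    Returns ``(coded_design, key)``.  The key maps each code back to the
    true label combination and carries a salted hash so tampering (or an
    accidental partial key) is detectable.  Analyses run identically on
    coded labels — the statistics never look inside them.
    """
    columns = [c for c in columns if c in design.columns]
    if not columns:
        raise ValueError("design has none of the label columns to blind")
    if id_column in design.columns and design[id_column].duplicated().any():
        raise ValueError("duplicate ids in design")
    rng = np.random.default_rng(seed)
    combos = design[columns].astype(str).agg("|".join, axis=1)
    uniq = list(dict.fromkeys(combos))
    codes = [f"T{c:03d}" for c in rng.permutation(10 ** 3)[:len(uniq)]]
    mapping = dict(zip(uniq, codes))
    coded = design.drop(columns=columns).copy()
    coded["coded_label"] = combos.map(mapping)
    salt = secrets.token_hex(8) if seed is None else f"{seed:016x}"
    inverse = {code: true for true, code in mapping.items()}
    key = {
        "columns": columns,
        "mapping": inverse,
        "salt": salt,
        "hash": _key_hash(inverse, salt),
    }
    return coded, key


def _key_hash(inverse: dict, salt: str) -> str:
    blob = (salt + json.dumps(inverse, sort_keys=True)).encode()
    return hashlib.sha256(blob).hexdigest()


def unblind_labels(coded: pd.DataFrame, key: dict) -> pd.DataFrame:
    """Restore true labels from a coded design using a verified key."""
    if key["hash"] != _key_hash(key["mapping"], key["salt"]):
        raise ValueError("blinding key failed integrity check")
    out = coded.copy()
    trues = out["coded_label"].map(key["mapping"])
    if trues.isna().any():
        raise ValueError("coded labels not present in key")
    parts = trues.str.split("|", expand=True)
    for i, col in enumerate(key["columns"]):
        out[col] = parts[i]
    return out.drop(columns=["coded_label"])


def write_blinding_key(key: dict, path) -> None:
    Path(path).write_text(json.dumps(key, sort_keys=True, indent=2))


def read_blinding_key(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class _RunLog:
    """Structured JSON-lines log of every pipeline stage and parameter."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def event(self, stage: str, **params) -> None:
        rec = {"stage": stage, **params}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def run_pipeline(config: dict | RunConfig):
    """Execute simulate -> track -> filter -> analyze for one mode.

    Writes a machine-readable ``summary.json`` (embedding the config hash
    and seed), per-stage CSV outputs and a JSON-lines log of all parameters
    to the configured output directory.  Reruns with the same config and
    seed are byte-identical.
    """
    if isinstance(config, dict):
        cfg = RunConfig.from_dict(config)
        raw = config
    else:
        cfg = config
        raw = {**dataclasses.asdict(cfg), **cfg.options}
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    chash = config_hash(raw)
    log.event("start", mode=cfg.mode, seed=cfg.seed, config_hash=chash, config=raw)
    try:
        if cfg.mode == "tmaze":
            results = _run_tmaze(cfg, out, log)
        else:
            results = _run_geotaxis(cfg, out, log)
    except Exception as exc:
        log.event("error", mode=cfg.mode, message=str(exc))
        (out / "summary.json").write_text(json.dumps(
            {"config_hash": chash, "seed": cfg.seed, "mode": cfg.mode,
             "status": "failed", "error": str(exc)}, sort_keys=True, indent=2))
        raise RuntimeError(f"pipeline stage failed in mode {cfg.mode!r}: {exc}") from exc
    summary = {"config_hash": chash, "seed": cfg.seed, "mode": cfg.mode,
               "status": "ok", "results": results}
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2))
    log.event("done")
    return summary


def _run_tmaze(cfg: RunConfig, out: Path, log: _RunLog) -> dict:
    opts = cfg.options.get("tmaze", {})
    groups = opts.get("groups", [
        {"name": "sham", "p_magnetic": 0.5, "icc": 0.02, "n_sets": 10,
         "flies_per_set": 100},
        {"name": "exposed", "p_magnetic": 0.5, "icc": 0.02, "n_sets": 10,
         "flies_per_set": 100},
    ])
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(groups)) % (2 ** 31)
    sets = []
    for g, s in zip(groups, seeds):
        params = TMazeSimParams(
            n_sets=int(g.get("n_sets", 10)),
            flies_per_set=int(g.get("flies_per_set", 100)),
            p_magnetic=float(g.get("p_magnetic", 0.5)),
            icc=float(g.get("icc", 0.0)), seed=int(s), group=g["name"])
        log.event("simulate_tmaze", **dataclasses.asdict(params))
        sets.extend(simulate_tmaze_experiment(params))
    write_choice_sets_csv(sets, out / "choice_sets.csv")
    pis = {g["name"]: float(np.mean([tmaze.preference_index(s)
                                     for s in sets if s.group == g["name"]]))
           for g in groups}
    glm = tmaze.glm_group_test(sets, dispersion=opts.get("dispersion", "quasi"))
    pseudo = tmaze.pseudoreplicated_test(sets)
    log.event("analyze_tmaze", glm_p=glm.pvalue, pseudo_p=pseudo.pvalue)
    return {"mean_preference_index": pis,
            "glm_group_test": glm.to_dict(),
            "pseudoreplicated_test": pseudo.to_dict()}


def _run_geotaxis(cfg: RunConfig, out: Path, log: _RunLog) -> dict:
    opts = cfg.options.get(cfg.mode, {})
    n_tubes = int(opts.get("n_tubes_per_group", 5))
    effect = float(opts.get("exposure_effect", 1.0))
    kin_kw = dict(opts.get("kinematics", {}))
    if cfg.mode == "flyvac":
        kin_kw.setdefault("n_flies", 1)
    render = bool(opts.get("render", False))
    crit = geotaxis.ClimberCriterion(
        height_cm=float(opts.get("climber_height_cm", 15.0)),
        time_s=float(opts.get("climber_time_s", 15.0)))
    subsample = int(opts.get("subsample", 5))

    ss = np.random.SeedSequence(cfg.seed)
    seeds = iter(ss.generate_state(4 * n_tubes + 16) % (2 ** 31))
    ratio_rows, height_frames, design_rows = [], [], []
    for exposure, eff in (("sham", 1.0), ("exposed", effect)):
        for t in range(n_tubes):
            kin = ClimbKinematics(**{**kin_kw,
                                     "exposure_effect": eff,
                                     "seed": int(next(seeds))})
            truth = simulate_climb_trajectories(kin, tube=t)
            rid = f"{exposure}_{t}"
            log.event("simulate_climb", id=rid, **dataclasses.asdict(kin))
            if render:
                table = _track_rendered(truth, kin, opts, int(next(seeds)), log)
            else:
                table = track_table_from_ground_truth(truth)
            table = tracking.apply_validity_filters(
                table, mode="gravity" if cfg.mode == "gravity" else "flyvac")
            props = geotaxis.climber_proportion(table, crit)
            for r in props.itertuples():
                ratio_rows.append((rid, exposure, int(r.trial), float(r.proportion)))
            ycm = geotaxis.per_frame_tube_means(table)
            ycm["id"] = rid
            ycm["Exposure"] = exposure
            height_frames.append(ycm)
            design_rows.append((rid, exposure))

    ratios = pd.DataFrame(ratio_rows, columns=["id", "Exposure", "trial", "proportion"])
    ratios.to_csv(out / "climber_ratios.csv", index=False)
    heights = pd.concat(height_frames, ignore_index=True)
    heights.to_csv(out / "per_frame_heights.csv", index=False)

    results = {}
    enough_reps = ratios.groupby("Exposure")["id"].nunique().min() >= 2
    if ratios["trial"].nunique() > 1 and enough_reps:
        rm = geotaxis.test_exposure_ratio(ratios, method="rm_anova")
        rm.extra.pop("anova_table", None)
        log.event("test_exposure_ratio", p=rm.pvalue)
        results["rm_anova_climber_ratio"] = rm.to_dict()
    lme = geotaxis.test_exposure_height(heights, subsample=subsample)
    log.event("test_exposure_height", p=lme.pvalue)
    results["lme_height"] = lme.to_dict()
    return results


def _track_rendered(truth: GroundTruth, kin: ClimbKinematics, opts: dict,
                    seed: int, log: _RunLog) -> TrackTable:
    video_kw = dict(opts.get("video", {}))
    video_kw.setdefault("n_tubes", 1)
    spec = VideoSpec(**video_kw)
    stack = render_video(truth, spec, seed=seed)
    seg = SegmentationParams(**opts.get("segmentation", {}))
    log.event("render_track", n_frames=len(stack), seg=dataclasses.asdict(seg))
    trial_len = int(round(kin.trial_duration_s * kin.fps))
    starts = list(range(0, len(stack), trial_len))
    return tracking.track_stack(
        FrameStack(stack, fps=kin.fps), seg, spec.tube_rois, spec.calibration,
        trial_starts=starts, tube_length_cm=truth.tube_length_cm,
        group_size=kin.n_flies)
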