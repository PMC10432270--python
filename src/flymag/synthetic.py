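"""Synthetic data with ground truth for the behavioural assays.

Two generators stand in for the raw experimental recordings:

* **T-maze choice counts.**  Groups of ~100 flies choose between a magnetic
  and a non-magnetic maze arm.  Choices made by flies sharing a maze run are
  not independent; the generator models this with a beta-binomial whose
  intraclass correlation (ICC) is a free parameter, so the pseudoreplication
  analyses have a known truth to calibrate against.  ICC = 0 reduces exactly
  to independent Bernoulli choices.

* **Negative-geotaxis climbing videos.**  Flies are knocked to the bottom of
  a vertical tube and climb; the camera sees dark silhouettes on a bright
  backlit background at 10 frames/s.  The generator draws per-fly climbing
  speeds, integrates noisy monotone trajectories with pauses, and rasterises
  them as elliptical blobs with Gaussian sensor noise, retaining the exact
  per-frame positions so tracking can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

# Tube length used throughout the climbing assays (200 mm tubes).
DEFAULT_TUBE_LENGTH_CM = 20.0

__all__ = [
    "TMazeSimParams",
    "ClimbKinematics",
    "VideoSpec",
    "GroundTruth",
    "ChoiceSet",
    "simulate_tmaze_experiment",
    "simulate_climb_trajectories",
    "render_video",
    "track_table_from_ground_truth",
    "write_ground_truth_csv",
    "write_choice_sets_csv",
    "write_frames",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TMazeSimParams:
    """Parameters of a simulated T-maze experiment.

    ``icc`` is the intraclass correlation of choices within a set: the
    per-set choice probability is drawn from a Beta distribution with mean
    ``p_magnetic`` and variance ``icc * p * (1 - p)``, then the set's
    magnetic-arm count is binomial given that probability.
    """

    n_sets: int = 10
    flies_per_set: int = 100
    p_magnetic: float = 0.5
    icc: float = 0.0
    seed: int = 0
    group: str = "group"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_magnetic <= 1.0:
            raise ValueError("p_magnetic must be in [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must be in [0, 1)")
        if self.flies_per_set < 1:
            raise ValueError("flies_per_set must be >= 1")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


@dataclass
class ClimbKinematics:
    """Kinematic model of flies climbing a vertical tube.

    Each fly draws a persistent base speed from
    ``Normal(speed_mean * exposure_effect, speed_sd)`` clipped at zero; at
    every frame it either pauses (probability ``pause_prob``) or advances by
    ``base_speed / fps``.  Heights are confined to ``[0, tube_length]`` and
    reset to zero at each trial start (the knockdown / vacuum pulse).  The
    per-fly speed draw makes tubes heterogeneous — graded "climbers versus
    non-climbers" without a bimodal split — and induces realistic
    within-tube correlation across trials.
    """

    n_flies: int = 10
    speed_mean: float = 1.5       # cm/s
    speed_sd: float = 0.5         # cm/s between flies
    pause_prob: float = 0.25      # per-frame probability of not moving
    exposure_effect: float = 1.0  # multiplicative factor on speed_mean
    n_trials: int = 5
    trial_duration_s: float = 30.0
    fps: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be in [0, 1]")
        if self.n_flies < 0 or self.n_trials < 1:
            raise ValueError("n_flies must be >= 0 and n_trials >= 1")


@dataclass
class VideoSpec:
    """Geometry and photometry of the rendered climbing video.

    Flies appear dark on a bright backlit background.  ``tube_rois`` are
    pixel rectangles ``(x0, y0, x1, y1)`` (half-open, origin top-left);
    ``calibration`` is cm per pixel along the vertical tube axis, with the
    tube base at the bottom row of each ROI.
    """

    width: int = 1280
    height: int = 1024
    n_tubes: int = 1
    tube_rois: list = field(default_factory=list)
    background_level: int = 200
    fly_level: int = 30
    noise_sd: float = 3.0
    blob_axes: tuple = (5.0, 3.5)   # semimajor (vertical), semiminor in px
    calibration: float = 0.02       # cm per pixel
    reflection_level: int | None = None  # optional faint mirrored blob
    reflection_offset_px: int = 6

    def __post_init__(self) -> None:
        if not self.tube_rois:
            self.tube_rois = [_default_roi(self, i) for i in range(self.n_tubes)]
        self.n_tubes = len(self.tube_rois)
        if self.fly_level >= self.background_level:
            raise ValueError("fly_level must be darker than background_level")
        for i, a in enumerate(self.tube_rois):
            for b in self.tube_rois[i + 1:]:
                if not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]):
                    raise ValueError("tube ROIs must be disjoint")

    @property
    def tube_length_px(self) -> float:
        x0, y0, x1, y1 = self.tube_rois[0]
        return float(y1 - 1 - y0)


def _default_roi(spec: VideoSpec, i: int) -> tuple:
    """Evenly spaced vertical tube ROIs with margins."""
    margin = max(8, spec.width // (8 * max(spec.n_tubes, 1)))
    slot = spec.width // max(spec.n_tubes, 1)
    x0 = i * slot + margin
    x1 = (i + 1) * slot - margin
    return (x0, 8, x1, spec.height - 8)


@dataclass
class ChoiceSet:
    """One T-maze run: flies choosing the magnetic arm out of the set total."""

    n_magnetic: int
    n_total: int
    group: str = "group"
    set_id: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_magnetic <= self.n_total:
            raise ValueError("n_magnetic must be in [0, n_total]")

    @property
    def p_magnetic(self) -> float:
        return self.n_magnetic / self.n_total


class GroundTruth:
    """Per-frame, per-fly true positions for a rendered recording.

    ``table`` has one row per (frame, fly) with columns ``frame, time_s,
    tube, trial, fly, x_px, y_px, height_cm``.
    """

    COLUMNS = ["frame", "time_s", "tube", "trial", "fly", "x_px", "y_px", "height_cm"]

    def __init__(self, table: pd.DataFrame, fps: float, tube_length_cm: float,
                 n_frames: int | None = None):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"ground truth table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.fps = float(fps)
        self.tube_length_cm = float(tube_length_cm)
        if n_frames is None:
            n_frames = int(self.table["frame"].max()) + 1 if len(self.table) else 0
        self.n_frames = int(n_frames)


# ---------------------------------------------------------------------------
# T-maze choice generator
# ---------------------------------------------------------------------------

def simulate_tmaze_experiment(params: TMazeSimParams) -> list:
    """Simulate one group of T-maze sets as beta-binomial counts.

    Marginally each fly chooses the magnetic arm with probability
    ``p_magnetic``; within a set, choices are exchangeable with correlation
    ``icc``.  With ``icc = 0`` the counts are plain binomial.

    Returns a list of :class:`ChoiceSet`, deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    p, rho, n = params.p_magnetic, params.icc, params.flies_per_set
    if rho == 0.0 or p in (0.0, 1.0):
        counts = rng.binomial(n, p, size=params.n_sets)
    else:
        # Beta(a, b) with mean p and variance rho * p * (1 - p).
        s = (1.0 - rho) / rho
        ps = rng.beta(p * s, (1.0 - p) * s, size=params.n_sets)
        counts = rng.binomial(n, ps)
    return [
        ChoiceSet(int(c), n, group=params.group, set_id=i)
        for i, c in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# climbing trajectories
# ---------------------------------------------------------------------------

def simulate_climb_trajectories(
    kin: ClimbKinematics,
    tube_length_cm: float = DEFAULT_TUBE_LENGTH_CM,
    tube: int = 0,
) -> GroundTruth:
    """Integrate noisy monotone climbing trajectories for one tube.

    Pixel columns (``x_px``) place each fly in its own vertical lane so the
    rendered silhouettes of separated flies do not merge; ``y_px`` is left
    NaN here and filled in by :func:`render_video` from the video geometry.
    """
    rng = np.random.default_rng(kin.seed)
    n_steps = int(round(kin.trial_duration_s * kin.fps))
    if n_steps < 1:
        raise ValueError("trial too short for one frame")
    dt = 1.0 / kin.fps

    base = np.clip(
        rng.normal(kin.speed_mean * kin.exposure_effect, kin.speed_sd, kin.n_flies),
        0.0, None,
    )
    frames_total = kin.n_trials * n_steps
    heights = np.zeros((frames_total, kin.n_flies))
    for trial in range(kin.n_trials):
        moving = rng.random((n_steps, kin.n_flies)) >= kin.pause_prob
        # frame 0 of each trial is the knockdown instant: height exactly 0
        moving[0, :] = False
        steps = moving * base[None, :] * dt
        h = np.minimum(np.cumsum(steps, axis=0), tube_length_cm)
        heights[trial * n_steps:(trial + 1) * n_steps, :] = h

    frames = np.repeat(np.arange(frames_total), kin.n_flies)
    flies = np.tile(np.arange(kin.n_flies), frames_total)
    table = pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames * dt,
            "tube": tube,
            "trial": frames // n_steps,
            "fly": flies,
            "x_px": np.nan,
            "y_px": np.nan,
            "height_cm": heights.ravel(),
        }
    )
    return GroundTruth(table, fps=kin.fps, tube_length_cm=tube_length_cm,
                       n_frames=frames_total)


def merge_ground_truths(truths: list) -> GroundTruth:
    """Concatenate per-tube ground truths sharing a timebase."""
    if not truths:
        raise ValueError("no ground truths to merge")
    fps = truths[0].fps
    tl = truths[0].tube_length_cm
    table = pd.concat([t.table for t in truths], ignore_index=True)
    return GroundTruth(table.sort_values(["frame", "tube", "fly"]), fps, tl)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_video(truth: GroundTruth, spec: VideoSpec, seed: int = 0) -> np.ndarray:
    """Rasterise ground-truth trajectories as an 8-bit grayscale frame stack.

    Each fly is an ellipse of ``fly_level`` grey at its true centroid;
    Gaussian noise of ``noise_sd`` grey levels is added per pixel.  The
    ground-truth table is updated in place with the pixel coordinates
    actually rendered (``x_px``, ``y_px``), keeping truth and frames
    index-aligned.

    Returns an array of shape ``(n_frames, height, width)``, dtype uint8.
    """
    rng = np.random.default_rng(seed)
    tab = truth.table
    n_frames = truth.n_frames
    a, b = spec.blob_axes  # semimajor (vertical), semiminor (horizontal)

    # assign pixel coordinates from tube geometry
    x_px = np.empty(len(tab))
    y_px = np.empty(len(tab))
    for tube_id, grp in tab.groupby("tube"):
        x0, y0, x1, y1 = spec.tube_rois[int(tube_id)]
        base_row = y1 - 1
        px_per_cm = 1.0 / spec.calibration
        y = base_row - grp["height_cm"].to_numpy() * px_per_cm
        n_flies = int(grp["fly"].max()) + 1
        # one vertical lane per fly; lanes are spaced so blobs cannot merge
        lane_w = (x1 - x0 - 2 * b - 2) / max(n_flies - 1, 1)
        if lane_w < 2 * b + 2 and n_flies > 1:
            lane_w = max(lane_w, 1.0)
        x = x0 + b + 1 + grp["fly"].to_numpy() * lane_w
        if (y < y0).any() or (x >= x1).any():
            raise ValueError("true centroid outside its tube ROI")
        x_px[grp.index] = x
        y_px[grp.index] = y
    tab["x_px"] = x_px
    tab["y_px"] = y_px

    hi, wi = spec.height, spec.width
    if (y_px - a < 0).any() or (y_px + a >= hi).any() or \
       (x_px - b < 0).any() or (x_px + b >= wi).any():
        raise ValueError("blob would exceed frame bounds")

    stack = np.empty((n_frames, hi, wi), dtype=np.uint8)
    # precompute per-frame fly positions
    by_frame = tab.groupby("frame")
    yy, xx = np.mgrid[-int(np.ceil(a)):int(np.ceil(a)) + 1,
                      -int(np.ceil(b)):int(np.ceil(b)) + 1]
    for f in range(n_frames):
        img = np.full((hi, wi), float(spec.background_level))
        try:
            rows = by_frame.get_group(f)
        except KeyError:
            rows = None
        if rows is not None:
            for x, y in zip(rows["x_px"].to_numpy(), rows["y_px"].to_numpy()):
                _draw_ellipse(img, y, x, a, b, float(spec.fly_level), yy, xx)
                if spec.reflection_level is not None:
                    _draw_ellipse(img, y, x + spec.reflection_offset_px,
                                  a, max(b * 0.6, 1.0),
                                  float(spec.reflection_level), yy, xx)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 255).astype(np.uint8)
    return stack


def _draw_ellipse(img, cy, cx, a, b, level, yy, xx):
    """Paint a filled ellipse (semi-axes a vertical, b horizontal) at (cy, cx)."""
    iy, ix = int(round(cy)), int(round(cx))
    dy, dx = cy - iy, cx - ix
    mask = ((yy - dy) / a) ** 2 + ((xx - dx) / b) ** 2 <= 1.0
    ys = yy[mask] + iy
    xs = xx[mask] + ix
    ok = (ys >= 0) & (ys < img.shape[0]) & (xs >= 0) & (xs < img.shape[1])
    img[ys[ok], xs[ok]] = np.minimum(img[ys[ok], xs[ok]], level)


# ---------------------------------------------------------------------------
# ground truth -> idealised track table
# ---------------------------------------------------------------------------

def track_table_from_ground_truth(truth: GroundTruth, blob_area: float = 39.0,
                                  blob_axes: tuple = (10.0, 5.0)):
    """Build the track table an ideal tracker would produce from ground truth.

    Every true fly position becomes one valid detection with nominal blob
    geometry.  This bypasses rendering and segmentation, giving the
    statistical layers a fast, noise-free input with known truth.
    """
    from .tracking import TrackTable

    t = truth.table
    df = pd.DataFrame({
        "frame": t["frame"].to_numpy(),
        "time_s": t["time_s"].to_numpy(),
        "tube": t["tube"].to_numpy(),
        "trial": t["trial"].to_numpy(),
        "x_px": t["x_px"].to_numpy(),
        "y_px": t["y_px"].to_numpy(),
        "area": blob_area,
        "major": blob_axes[0],
        "minor": blob_axes[1],
        "height_cm": t["height_cm"].to_numpy(),
        "valid": True,
        "excluded_reason": "",
    })
    group_size = int(t.groupby("tube")["fly"].nunique().max()) if len(t) else 0
    return TrackTable(df, fps=truth.fps, tube_length_cm=truth.tube_length_cm,
                      group_size=max(group_size, 1))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, index=False)


def write_choice_sets_csv(sets: list, path) -> None:
    pd.DataFrame(
        [
            {"set_id": s.set_id, "group": s.group,
             "n_magnetic": s.n_magnetic, "n_total": s.n_total}
            for s in sets
        ]
    ).to_csv(path, index=False)


def write_frames(stack: np.ndarray, out_dir, fmt: str = "png") -> list:
    """Write a frame stack as zero-padded PNG (or TIFF) files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(stack))))
    paths = []
    for i, frame in enumerate(stack):
        p = out / f"frame_{i:0{width}d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
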