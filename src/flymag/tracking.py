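"""Video tracking for the negative-geotaxis assays.

The assay films backlit vertical tubes at 10 frames/s; flies appear as dark
silhouettes on a bright background.  The pipeline is:

1. **Preprocessing** — gamma correction (default 0.45) and unsharp masking
   (sigma 1.0, weight 0.93) to boost silhouette contrast.
2. **Two-pass background estimation** — first the arithmetic mean of all
   frames; then a refined per-pixel mean over only those frames whose
   intensity does not fall short of the first-pass mean by more than 20%
   (frames where a fly covered the pixel).  Pixels with too few contributing
   frames are unreliable and are filled from neighbouring reliable pixels by
   a moving average (window 10 px), and the result is smoothed with a
   Gaussian (sigma 1 px): the scene without flies.
3. **Per-frame scaling** — each frame is linearly rescaled (least squares)
   to match the background in calibration regions the flies cannot reach,
   compensating global illumination flicker.
4. **Detection** — background minus frame gives flies as bright blobs;
   grayscale morphological opening with a disk suppresses noise; the opened
   image is binarised (Otsu by default) and connected regions are measured.
   Only regions whose ellipse-equivalent major axis lies in [4, 20] px,
   minor axis in [3, 20] px and area in [8, 200] px² are kept.
5. **Validity filtering** — group (gravity) recordings exclude frames with
   more than 10 detections per tube as false positives; single-fly (FlyVac)
   recordings drop flies that were not drawn to the tube base by every
   vacuum pulse or that never moved in any trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

__all__ = [
    "FrameStack",
    "BackgroundModel",
    "SegmentationParams",
    "Detection",
    "TrackTable",
    "preprocess_frames",
    "estimate_background",
    "scale_to_background",
    "detect_flies",
    "geometry_gate",
    "track_stack",
    "apply_validity_filters",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class FrameStack:
    """Ordered 8-bit grayscale frames with a timebase.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        8-bit grayscale pixel data.
    fps : float
        Frames per second; must be positive.
    """

    def __init__(self, frames: np.ndarray, fps: float = 10.0):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) grayscale stack")
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.frames = frames
        self.fps = float(fps)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape

    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.fps


@dataclass
class BackgroundModel:
    """Per-pixel background estimate: the scene without flies.

    ``background`` is the smoothed estimate used downstream;
    ``reliability_mask`` marks pixels whose second-pass mean met the
    contributing-frame criterion; ``n_contributing`` counts the frames that
    entered each pixel's second-pass mean.
    """

    background: np.ndarray
    reliability_mask: np.ndarray
    n_contributing: np.ndarray


@dataclass
class SegmentationParams:
    """All tunables of the preprocessing / segmentation chain (pixel units)."""

    gamma: float = 0.45
    unsharp_sigma: float = 1.0
    unsharp_weight: float = 0.93
    exclusion_fraction: float = 0.20
    fill_window: int = 10
    smooth_sigma: float = 1.0
    min_reliable_fraction: float = 1.0
    opening_disk_radius: int = 2
    threshold_method: str = "otsu"      # "otsu" | "fixed"
    threshold_value: float | None = None
    min_threshold: float = 10.0         # grey-level floor under Otsu
    major_axis_range: tuple = (4.0, 20.0)
    minor_axis_range: tuple = (3.0, 20.0)
    area_range: tuple = (8.0, 200.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_fraction < 1.0:
            raise ValueError("exclusion_fraction must be in (0, 1)")
        for name in ("major_axis_range", "minor_axis_range", "area_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-empty interval")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")


@dataclass
class Detection:
    """One segmented blob in one frame."""

    frame: int
    x_px: float
    y_px: float
    area: float
    semimajor: float
    semiminor: float
    tube: int = -1
    valid: bool = True


class TrackTable:
    """Tidy per-frame detection table with validity annotations.

    ``df`` columns: frame, time_s, tube, trial, x_px, y_px, area, major,
    minor, height_cm, valid, excluded_reason.  ``major``/``minor`` are full
    ellipse-equivalent axis lengths (twice the semi-axes).
    """

    COLUMNS = ["frame", "time_s", "tube", "trial", "x_px", "y_px", "area",
               "major", "minor", "height_cm", "valid", "excluded_reason"]

    def __init__(self, df: pd.DataFrame, fps: float = 10.0,
                 tube_length_cm: float = 20.0, group_size: int = 10):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        self.fps = float(fps)
        self.tube_length_cm = float(tube_length_cm)
        self.group_size = int(group_size)

    def valid_rows(self) -> pd.DataFrame:
        return self.df[self.df["valid"]]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float = 10.0, tube_length_cm: float = 20.0,
                 group_size: int = 10) -> "TrackTable":
        df = pd.read_csv(path)
        if "excluded_reason" in df.columns:
            df["excluded_reason"] = df["excluded_reason"].fillna("")
        return cls(df, fps=fps, tube_length_cm=tube_length_cm, group_size=group_size)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_frames(stack: FrameStack, params: SegmentationParams) -> FrameStack:
    """Gamma-correct then unsharp-mask every frame.

    Gamma acts on intensities normalised to [0, 1]: ``out = in ** gamma``.
    Unsharp masking adds back the high-pass residual:
    ``out = in + weight * (in - gaussian_sigma(in))``, clipped to range.
    """
    frames = stack.frames
    if frames.dtype != np.uint8:
        raise ValueError("preprocess_frames expects 8-bit grayscale input")
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        f = frame.astype(np.float64) / 255.0
        f = f ** params.gamma
        if params.unsharp_weight != 0.0:
            blurred = gaussian_filter(f, params.unsharp_sigma)
            f = f + params.unsharp_weight * (f - blurred)
        out[i] = np.clip(f * 255.0, 0, 255).astype(np.uint8)
    return FrameStack(out, fps=stack.fps)


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------

def estimate_background(stack: FrameStack, params: SegmentationParams) -> BackgroundModel:
    """Two-pass per-pixel background estimate with fill-in and smoothing.

    Pass 1 is the arithmetic mean of all frames.  Pass 2 averages, per
    pixel, only frames whose intensity is at least
    ``(1 - exclusion_fraction)`` times the pass-1 mean — darker frames are
    presumed to contain a fly.  Pixels whose contributing-frame fraction is
    below ``min_reliable_fraction`` are unreliable and filled by a moving
    average (side ``fill_window``) over reliable neighbours, iterated until
    every pixel has a value.  The filled image is smoothed with a Gaussian
    of ``smooth_sigma``.
    """
    frames = stack.frames
    if len(frames) < 2:
        raise ValueError("background estimation needs at least 2 frames")
    arr = frames.astype(np.float64)
    n = len(arr)
    mean1 = arr.mean(axis=0)
    cutoff = (1.0 - params.exclusion_fraction) * mean1
    keep = arr >= cutoff[None, :, :]
    n_contrib = keep.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean2 = np.where(n_contrib > 0,
                         (arr * keep).sum(axis=0) / np.maximum(n_contrib, 1),
                         np.nan)
    reliable = n_contrib >= int(np.ceil(params.min_reliable_fraction * n))
    if not reliable.any():
        raise ValueError("no reliable background pixels")

    bg = np.where(reliable, mean2, np.nan)
    bg = _fill_unreliable(bg, reliable, params.fill_window)
    bg = gaussian_filter(bg, params.smooth_sigma)
    return BackgroundModel(background=bg, reliability_mask=reliable,
                           n_contributing=n_contrib)


def _fill_unreliable(bg: np.ndarray, reliable: np.ndarray, window: int) -> np.ndarray:
    """Fill NaN pixels with the moving average of known neighbours, iterated."""
    filled = bg.copy()
    known = reliable.copy()
    while not known.all():
        vals = np.where(known, filled, 0.0)
        num = uniform_filter(vals, size=window, mode="constant")
        den = uniform_filter(known.astype(np.float64), size=window, mode="constant")
        newly = (~known) & (den > 0)
        if not newly.any():
            raise ValueError("unreliable region too large to fill")
        filled[newly] = num[newly] / den[newly]
        known |= newly
    return filled


# ---------------------------------------------------------------------------
# per-frame scaling
# ---------------------------------------------------------------------------

def scale_to_background(frame: np.ndarray, background: BackgroundModel,
                        calib_regions: list) -> np.ndarray:
    """Linearly rescale a frame so it matches the background off-tube.

    ``calib_regions`` are ``(x0, y0, x1, y1)`` rectangles between the tubes,
    inaccessible to the flies.  The gain/offset are the least-squares
    solution of ``a * frame + b = background`` over those pixels.  The gain
    is identifiable only when the background actually varies across the
    calibration pixels; over a flat backlit field the regression would chase
    sensor noise, so there the gain is pinned at 1 and only the offset
    (illumination drift) is fitted.
    """
    if not calib_regions:
        raise ValueError("calib_regions must be non-empty")
    f = frame.astype(np.float64)
    bg = background.background
    fs, bs = [], []
    for x0, y0, x1, y1 in calib_regions:
        fs.append(f[y0:y1, x0:x1].ravel())
        bs.append(bg[y0:y1, x0:x1].ravel())
    fv = np.concatenate(fs)
    bv = np.concatenate(bs)
    if fv.size < 2 or np.ptp(fv) == 0.0:
        raise ValueError("degenerate calibration region: constant or too small")
    if np.ptp(bv) < 2.0:  # grey levels: flat background, gain unidentifiable
        return f + (bv.mean() - fv.mean())
    A = np.column_stack([fv, np.ones_like(fv)])
    (a, b), *_ = np.linalg.lstsq(A, bv, rcond=None)
    return a * f + b


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def geometry_gate(major: float, minor: float, area: float,
                  params: SegmentationParams) -> bool:
    """True iff a region's measured geometry lies inside all three ranges."""
    return (params.major_axis_range[0] <= major <= params.major_axis_range[1]
            and params.minor_axis_range[0] <= minor <= params.minor_axis_range[1]
            and params.area_range[0] <= area <= params.area_range[1])


def detect_flies(frame: np.ndarray, background: BackgroundModel,
                 params: SegmentationParams, frame_index: int = 0) -> list:
    """Segment fly blobs in one (already rescaled) frame.

    Background minus frame makes flies bright; grayscale opening with a disk
    of ``opening_disk_radius`` removes sub-fly-sized bright specks; the
    opened difference is thresholded (Otsu with a grey-level floor, or a
    fixed value) and connected regions are measured with ellipse-equivalent
    second moments.  Regions failing any geometry range are disregarded.
    """
    bg = background.background
    if frame.shape != bg.shape:
        raise ValueError("frame and background dimensions differ")
    diff = np.clip(bg - frame.astype(np.float64), 0.0, None)
    opened = opening(diff, disk(params.opening_disk_radius))
    if params.threshold_method == "fixed":
        thr = float(params.threshold_value)
    else:
        thr = threshold_otsu(opened) if opened.max() > 0 else np.inf
        thr = max(thr, params.min_threshold)
    binary = opened > thr
    detections = []
    for region in regionprops(label(binary, connectivity=2)):
        area = float(region.area)
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        if not geometry_gate(major, minor, area, params):
            continue
        cy, cx = region.centroid
        detections.append(Detection(frame=frame_index, x_px=float(cx),
                                    y_px=float(cy), area=area,
                                    semimajor=major / 2.0,
                                    semiminor=minor / 2.0))
    return detections


# ---------------------------------------------------------------------------
# whole-recording tracking
# ---------------------------------------------------------------------------

def default_calib_regions(tube_rois: list, width: int, height: int,
                          margin: int = 2, min_width: int = 3) -> list:
    """Vertical strips between (and beside) the tube ROIs."""
    xs = sorted((r[0], r[2]) for r in tube_rois)
    edges = [0] + [x for pair in xs for x in pair] + [width]
    regions = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        x0, x1 = lo + margin, hi - margin
        if x1 - x0 >= min_width:
            regions.append((x0, 0, x1, height))
    if not regions:
        raise ValueError("no off-tube area available for calibration regions")
    return regions


def track_stack(stack: FrameStack, params: SegmentationParams, tube_rois: list,
                calibration: float, trial_starts: list | None = None,
                calib_regions: list | None = None, preprocess: bool = True,
                tube_length_cm: float = 20.0, group_size: int = 10) -> TrackTable:
    """Run the full tracking chain on one recording.

    Background is estimated once; every frame is then rescaled to it and
    segmented.  Detections are assigned to tubes by ROI (those outside every
    ROI are flagged, not fatal) and centroid rows are converted to height in
    cm with the tube base at the bottom ROI row.  ``trial_starts`` are frame
    indices beginning each trial (default: one trial spanning the recording).
    """
    if preprocess:
        stack = preprocess_frames(stack, params)
    n_frames, height, width = stack.shape
    if calib_regions is None:
        calib_regions = default_calib_regions(tube_rois, width, height)
    bg = estimate_background(stack, params)
    if trial_starts is None or len(trial_starts) == 0:
        trial_starts = [0]
    starts = np.asarray(sorted(trial_starts))

    rows = []
    for i, frame in enumerate(stack.frames):
        scaled = scale_to_background(frame, bg, calib_regions)
        trial = int(np.searchsorted(starts, i, side="right") - 1)
        for det in detect_flies(scaled, bg, params, frame_index=i):
            tube, height_cm, valid, reason = -1, np.nan, True, ""
            for t, (x0, y0, x1, y1) in enumerate(tube_rois):
                if x0 <= det.x_px < x1 and y0 <= det.y_px < y1:
                    tube = t
                    height_cm = max((y1 - 1 - det.y_px) * calibration, 0.0)
                    break
            else:
                valid, reason = False, "outside_roi"
            rows.append((i, i / stack.fps, tube, trial, det.x_px, det.y_px,
                         det.area, 2 * det.semimajor, 2 * det.semiminor,
                         height_cm, valid, reason))
    df = pd.DataFrame(rows, columns=TrackTable.COLUMNS)
    return TrackTable(df, fps=stack.fps, tube_length_cm=tube_length_cm,
                      group_size=group_size)


# ---------------------------------------------------------------------------
# validity filters
# ---------------------------------------------------------------------------

def apply_validity_filters(table: TrackTable, mode: str = "gravity",
                           max_flies: int = 10, bottom_threshold_cm: float = 1.0,
                           mobility_eps_cm: float = 1e-9) -> TrackTable:
    """Apply the per-assay exclusion rules.

    gravity
        Any (tube, frame) with more than ``max_flies`` detections is a false
        positive: all its rows are marked invalid.
    flyvac
        One fly per tube.  A fly is dropped entirely if at the start of any
        trial (the post-vacuum-pulse frame) its height exceeds
        ``bottom_threshold_cm`` (it was not sucked to the bottom), or if its
        height range is zero in every one of its trials (no mobility).
    """
    df = table.df.copy()
    if "trial" not in df.columns or df["trial"].isna().any():
        raise ValueError("track table must be annotated with trials")

    if mode == "gravity":
        counts = df[df["valid"]].groupby(["tube", "frame"])["frame"].transform("size")
        over = df["valid"] & (counts > max_flies)
        df.loc[over, "valid"] = False
        df.loc[over, "excluded_reason"] = "too_many_detections"
    elif mode == "flyvac":
        drop_tubes = []
        for tube, sub in df[df["valid"]].groupby("tube"):
            not_bottom = False
            moved = False
            for _, tr in sub.groupby("trial"):
                first = tr.loc[tr["frame"].idxmin()]
                if first["height_cm"] > bottom_threshold_cm:
                    not_bottom = True
                if tr["height_cm"].max() - tr["height_cm"].min() > mobility_eps_cm:
                    moved = True
            if not_bottom or not moved:
                drop_tubes.append(tube)
        df = df[~df["tube"].isin(drop_tubes)].reset_index(drop=True)
    else:
        raise ValueError("mode must be 'gravity' or 'flyvac'")
    return TrackTable(df, fps=table.fps, tube_length_cm=table.tube_length_cm,
                      group_size=table.group_size)
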