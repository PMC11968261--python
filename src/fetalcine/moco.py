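"""Mutual-information data rejection and translational motion correction.

Fetal acquisitions are corrupted by two motion classes: in-plane translation
(maternal respiration, gross fetal shifts), which is correctable in k-space by
phase ramps, and through-plane motion (anatomy leaving the slice), which is
not correctable and must be rejected.  Periods of through-plane motion are
detected as real-time frames whose mutual information against a fixed
reference set of frames drops below a threshold; retained frames are then
registered to the highest-MI frame by phase correlation inside the heart ROI,
and the per-frame shifts are interpolated to arm timestamps and applied as
k-space phase ramps.

Frames are temporally smoothed over roughly one cardiac cycle before MI and
registration, suppressing cardiac pulsation that would otherwise bias the
gross-motion estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.registration import phase_cross_correlation

from .containers import ImageSeries, MotionRecord, RawSpiralDataset, Roi
from .encoding import shift_phase_ramp
from .recon import BinnedData

__all__ = [
    "temporal_smooth",
    "mutual_information",
    "reject_frames",
    "estimate_translations",
    "shifts_to_arms",
    "rejected_fraction",
    "run_moco",
    "apply_moco",
]


def temporal_smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Moving-average magnitude smoothing along time with edge truncation.

    ``window`` must be odd; near the series ends the average simply uses the
    frames that exist (truncated window).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    mag = np.abs(np.asarray(series))
    if window == 1:
        return mag.copy()
    t = mag.shape[0]
    csum = np.cumsum(mag, axis=0)
    out = np.empty_like(mag)
    half = window // 2
    for i in range(t):
        lo = max(0, i - half)
        hi = min(t, i + half + 1)
        top = csum[hi - 1]
        bot = csum[lo - 1] if lo > 0 else 0.0
        out[i] = (top - bot) / (hi - lo)
    return out


def _normalize_roi(img: np.ndarray) -> np.ndarray | None:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return None
    return (img - lo) / (hi - lo)


def mutual_information(frame_a: np.ndarray, frame_b: np.ndarray, roi: Roi,
                       n_bins: int = 32) -> float:
    """Mutual information (nats) of the joint magnitude histogram inside roi.

    Each image is min-max normalized over the ROI before binning, which makes
    the metric invariant to joint linear intensity rescaling.  A constant
    image inside the ROI yields MI = 0 with a warning.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have the same shape")
    a = _normalize_roi(np.abs(roi.extract(np.asarray(frame_a))).ravel())
    b = _normalize_roi(np.abs(roi.extract(np.asarray(frame_b))).ravel())
    if a is None or b is None:
        warnings.warn("constant image inside ROI; MI defined as 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins, range=[[0, 1], [0, 1]])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _reference_indices(n_frames: int, n_refs: int) -> np.ndarray:
    n_refs = min(n_refs, n_frames)
    return np.unique(np.linspace(0, n_frames - 1, n_refs).round().astype(int))


def reject_frames(series: np.ndarray, roi: Roi, *, threshold_frac: float = 0.8,
                  n_refs: int = 50, n_bins: int = 32, bridge: int = 2,
                  summary_quantile: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Flag through-plane-corrupted frames by their MI against reference frames.

    Each frame's MI summary is an upper quantile (default 0.9) of its MI
    against ``n_refs`` frames spread evenly over the scan: a clean frame at
    an extreme in-plane position still matches the references acquired near
    that position, whereas a through-plane-corrupted frame matches *none*,
    so the upper quantile separates the two where a median is confounded by
    in-plane motion.  A frame is rejected when its summary falls below
    ``threshold_frac`` times the median summary over frames.  Runs of
    rejections separated by <= ``bridge`` kept frames are merged into one
    contiguous rejected run.

    Returns (keep_frame_mask, frame_mi).
    """
    mag = np.abs(np.asarray(series))
    t = mag.shape[0]
    if t < 3:
        raise ValueError("need at least 3 frames for rejection")
    refs = _reference_indices(t, n_refs)
    mi = np.empty((t, refs.size))
    for j, rix in enumerate(refs):
        for i in range(t):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mi[i, j] = mutual_information(mag[i], mag[rix], roi, n_bins)
    # exclude the trivial self-pair, which would inflate reference frames
    self_mask = refs[None, :] == np.arange(t)[:, None]
    mi_masked = np.where(self_mask, np.nan, mi)
    frame_mi = np.nanquantile(mi_masked, summary_quantile, axis=1)
    cutoff = threshold_frac * float(np.median(frame_mi))
    keep = frame_mi >= cutoff
    # merge: short kept gaps inside rejected runs are unreliable, drop them
    if bridge > 0 and not keep.all():
        rejected = ~keep
        runs = []
        start = None
        for i in range(t):
            if rejected[i] and start is None:
                start = i
            elif not rejected[i] and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, t))
        for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
            if s1 - e0 <= bridge:
                keep[e0:s1] = False
    if not keep.any():
        raise ValueError(
            "rejection policy removed every frame; lower threshold_frac")
    return keep, frame_mi


def estimate_translations(series: np.ndarray, roi: Roi, res_mm: float,
                          keep_mask: np.ndarray | None = None,
                          frame_mi: np.ndarray | None = None,
                          upsample: int = 10) -> tuple[np.ndarray, int]:
    """Per-frame in-plane shifts (mm) of retained frames vs the reference.

    The reference is the retained frame with the highest MI summary (or frame
    0 when no MI is supplied).  Shifts are estimated by windowed phase
    correlation with subpixel refinement and reported as the displacement of
    the frame content relative to the reference, in mm along (x, y) =
    (columns, rows).  Rejected frames get NaN shifts.

    Returns (frame_shifts_mm of shape (T, 2), reference_frame_index).
    """
    mag = np.abs(np.asarray(series))
    t = mag.shape[0]
    if keep_mask is None:
        keep_mask = np.ones(t, dtype=bool)
    kept = np.flatnonzero(keep_mask)
    if kept.size < 2:
        raise ValueError("need at least 2 retained frames")
    if frame_mi is not None:
        ref = int(kept[np.argmax(frame_mi[kept])])
    else:
        ref = int(kept[0])
    rs, cs = roi.slices()
    ref_img = mag[ref, rs, cs]
    shifts = np.full((t, 2), np.nan)
    for i in kept:
        if i == ref:
            shifts[i] = 0.0
            continue
        # plain cross-correlation peak: frames share content, and windowing
        # the ROI would bias the estimate toward zero shift
        sh, _, _ = phase_cross_correlation(ref_img, mag[i, rs, cs],
                                           upsample_factor=upsample,
                                           normalization=None)
        # sh = (row, col) displacement moving the frame onto the reference;
        # content displacement relative to the reference is the negation
        shifts[i, 0] = -sh[1] * res_mm   # x (columns)
        shifts[i, 1] = -sh[0] * res_mm   # y (rows)
    return shifts, ref


def shifts_to_arms(frame_shifts_mm: np.ndarray, frame_times_ms: np.ndarray,
                   arm_times_ms: np.ndarray) -> np.ndarray:
    """Linear interpolation of frame shifts to arm timestamps, held constant
    outside the frame-time range."""
    frame_times_ms = np.asarray(frame_times_ms, dtype=float)
    if np.any(np.diff(frame_times_ms) <= 0):
        raise ValueError("frame times must be strictly increasing")
    fs = np.asarray(frame_shifts_mm, dtype=float)
    out = np.empty((np.asarray(arm_times_ms).size, 2))
    for c in range(2):
        out[:, c] = np.interp(arm_times_ms, frame_times_ms, fs[:, c])
    return out


def rejected_fraction(keep_arm_mask: np.ndarray) -> int:
    """Percentage of rejected arms, rounded half up to an integer percent."""
    mask = np.asarray(keep_arm_mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask must be nonempty")
    frac = 100.0 * np.count_nonzero(~mask) / mask.size
    return int(np.floor(frac + 0.5))


def _arms_keep_mask(n_arms: int, bins: BinnedData,
                    keep_frame_mask: np.ndarray) -> np.ndarray:
    """An arm is rejected iff every frame containing it is rejected."""
    keep = np.zeros(n_arms, dtype=bool)
    covered = np.zeros(n_arms, dtype=bool)
    for j, b in enumerate(bins.bins):
        idx = np.asarray(b, dtype=np.int64)
        covered[idx] = True
        if keep_frame_mask[j]:
            keep[idx] = True
    keep[~covered] = False  # trailing arms never reconstructed: drop
    return keep


def run_moco(rt_series: ImageSeries, dataset: RawSpiralDataset,
             bins: BinnedData, roi: Roi, *, smooth_window: int = 15,
             reject_window: int = 5, threshold_frac: float = 0.8,
             n_refs: int = 50, n_bins: int | None = None) -> MotionRecord:
    """Full rejection + translational estimation stage on a real-time series.

    Registration uses frames smoothed over ``smooth_window`` (~one cardiac
    cycle at the default frame rate), which suppresses cardiac pulsation;
    rejection uses a short ``reject_window`` so corruption stays temporally
    localized.  When ``n_bins`` is None the MI histogram size adapts to the
    ROI pixel count (sqrt(n_px/3), clipped to [8, 32]) to keep the joint
    histogram well populated on small heart ROIs.
    """
    if n_bins is None:
        rs, cs = roi.slices()
        n_px = (rs.stop - rs.start) * (cs.stop - cs.start)
        n_bins = int(np.clip(round(np.sqrt(n_px / 3.0)), 8, 32))
    light = temporal_smooth(rt_series.frames, reject_window)
    keep_frames, frame_mi = reject_frames(light, roi,
                                          threshold_frac=threshold_frac,
                                          n_refs=n_refs, n_bins=n_bins)
    smooth = temporal_smooth(rt_series.frames, smooth_window)
    frame_shifts, ref = estimate_translations(smooth, roi, rt_series.res_mm,
                                              keep_mask=keep_frames,
                                              frame_mi=frame_mi)
    kept = np.flatnonzero(keep_frames)
    arm_shifts = shifts_to_arms(frame_shifts[kept],
                                rt_series.times_ms[kept],
                                dataset.timestamps_ms)
    keep_arms = _arms_keep_mask(dataset.n_arms, bins, keep_frames)
    return MotionRecord(roi=roi, frame_mi=frame_mi,
                        keep_frame_mask=keep_frames,
                        frame_shifts_mm=frame_shifts,
                        arm_shifts_mm=arm_shifts,
                        keep_arm_mask=keep_arms,
                        reference_frame=ref,
                        meta={"smooth_window": smooth_window,
                              "threshold_frac": threshold_frac,
                              "n_refs": n_refs, "n_bins": n_bins})


def apply_moco(dataset: RawSpiralDataset, record: MotionRecord) -> np.ndarray:
    """Return samples with per-arm phase ramps undoing the estimated shifts.

    Only retained arms are corrected; rejected arms are returned unchanged
    (they are excluded downstream by ``keep_arm_mask``).
    """
    out = dataset.samples.copy()
    coords = dataset.trajectory.coords
    for i in np.flatnonzero(record.keep_arm_mask):
        dx, dy = record.arm_shifts_mm[i]
        # ramp(+d) translates the sampled content by -d, undoing a +d shift
        out[i] = shift_phase_ramp(out[i], coords[i], (dx, dy))
    return out
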