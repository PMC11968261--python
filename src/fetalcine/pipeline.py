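"""End-to-end reconstruction pipeline and experiment drivers.

Workflow (mirroring a motion-corrected fetal cine exam):

1. simulate (or load) a raw spiral dataset;
2. real-time compressed sensing (15 arms/frame, 10 shared, lambda 0.08,
   20 iterations);
3. mutual-information data rejection + translational motion correction;
4. metric-optimized gating on the motion-corrected real-time frames;
5. gated cine compressed sensing (20 phases, lambda 0.02, 50 iterations);
6. quality evaluation (SNR/contrast/CNR/PIQE, NRMSD vs ground truth).

Every stage's output can be persisted into the HDF5 container; a manifest
records configuration, seeds and content hashes so a rerun with the same
config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import fourier_shift

from . import io_h5
from .cine import bin_arms_to_phases, reconstruct_cine, retrospective_subset
from .containers import (CineSeries, GatingRecord, ImageSeries, MotionRecord,
                         RawSpiralDataset, Roi)
from .metrics import QualityReport, nrmsd, pique_score, roi_quality
from .moco import apply_moco, run_moco
from .mog import mog_optimize
from .phantom import (PhantomConfig, SceneGeometry, ground_truth_masks,
                      simulate_acquisition)
from .recon import BinnedData, CSParams, cs_reconstruct, sliding_window_frames
from .trajectory import SpiralProtocol

logger = logging.getLogger("fetalcine")

__all__ = [
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "evaluate_quality",
    "align_cine_to_truth",
    "acceleration_sweep",
    "consistency_experiment",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    protocol: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    arms_per_frame: int = 15
    shared_arms: int = 10
    rt_lambda: float = 0.08
    rt_iters: int = 20
    cine_lambda: float = 0.02
    cine_iters: int = 50
    n_phases: int = 20
    smooth_window: int = 15
    mi_threshold_frac: float = 0.8
    mi_n_refs: int = 50
    mog_bounds_ms: tuple = (300.0, 600.0)
    mog_segment_len_ms: float = 2000.0
    seed: int = 1234
    out_dir: str | None = None

    def build_protocol(self) -> SpiralProtocol:
        return SpiralProtocol(**self.protocol)

    def build_phantom(self) -> PhantomConfig:
        kw = dict(self.phantom)
        geom = kw.pop("geometry", None)
        kw.setdefault("seed", self.seed)
        if geom is not None:
            kw["geometry"] = SceneGeometry(**geom) if isinstance(geom, dict) else geom
        return PhantomConfig(**kw)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["mog_bounds_ms"] = list(self.mog_bounds_ms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "mog_bounds_ms" in d:
            d["mog_bounds_ms"] = tuple(d["mog_bounds_ms"])
        return cls(**d)


def default_phantom_dict(n_arms: int = 2500, tr_ms: float = 5.7,
                         throughplane_frac: float = 0.10) -> dict:
    """Default study conditions: variable RR 433 +/- 10 ms, 2.5 mm
    respiration, one gross-motion step, one through-plane window covering
    ``throughplane_frac`` of the scan."""
    duration = n_arms * tr_ms
    d = {
        "n_arms": n_arms,
        "rr_mean_ms": 433.0,
        "rr_sd_ms": 10.0,
        "resp_amp_mm": 2.5,
        "resp_period_s": 4.0,
        "gross_events": ((0.65 * duration, (1.5, -1.0)),),
    }
    if throughplane_frac > 0:
        d["throughplane_windows"] = ((0.45 * duration,
                                      (0.45 + throughplane_frac) * duration),)
    return d


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: RawSpiralDataset
    rt_series: ImageSeries
    rt_bins: BinnedData
    motion: MotionRecord
    gating: GatingRecord
    cine: CineSeries
    samples_corrected: np.ndarray
    reports: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def correct_frames(series: ImageSeries, motion: MotionRecord) -> ImageSeries:
    """Undo the estimated per-frame translation in the image domain
    (Fourier-domain subpixel shift of each retained frame)."""
    frames = series.frames.copy()
    px = series.res_mm
    for i in np.flatnonzero(motion.keep_frame_mask):
        dx, dy = motion.frame_shifts_mm[i]
        if dx == 0 and dy == 0:
            continue
        f = np.fft.fft2(frames[i])
        frames[i] = np.fft.ifft2(fourier_shift(f, (-dy / px, -dx / px)))
    return dc_replace(series, frames=frames)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate -> recon-rt -> moco -> mog -> recon-cine -> evaluate.

    Raises :class:`PipelineError` naming the failing stage; artifacts
    produced before the failure are kept on the returned error object's
    ``partial`` attribute when an output directory is configured.
    """
    t_start = time.time()
    stage = "simulate"
    try:
        prot = config.build_protocol()
        ph = config.build_phantom()
        dataset, gt = simulate_acquisition(prot, ph, n_phases=config.n_phases)
        logger.info("simulated %d arms at %.1f mm (%.1f s scan)",
                    dataset.n_arms, prot.res_mm,
                    dataset.n_arms * prot.tr_ms / 1000)

        stage = "recon-rt"
        rt_bins = sliding_window_frames(dataset.n_arms, config.arms_per_frame,
                                        config.shared_arms,
                                        arm_times_ms=dataset.timestamps_ms)
        rt = cs_reconstruct(dataset, rt_bins,
                            CSParams(lambda_t=config.rt_lambda,
                                     n_iters=config.rt_iters),
                            seed=config.seed)
        logger.info("real-time: %d frames, spacing %.1f ms",
                    rt.n_frames, rt.frame_spacing_ms)

        stage = "moco"
        roi = gt.heart_roi if gt is not None else _central_roi(prot.grid_size)
        motion = run_moco(rt, dataset, rt_bins, roi,
                          smooth_window=config.smooth_window,
                          threshold_frac=config.mi_threshold_frac,
                          n_refs=config.mi_n_refs)
        logger.info("moco: %d%% of arms rejected, shift ranges [%.1f, %.1f] mm",
                    motion.rejected_fraction, *motion.shift_ranges_mm())

        stage = "mog"
        rt_corr = correct_frames(rt, motion)
        gating = mog_optimize(rt_corr, roi,
                              keep_frame_mask=motion.keep_frame_mask,
                              segment_len_ms=config.mog_segment_len_ms,
                              bounds_ms=config.mog_bounds_ms,
                              n_phases=config.n_phases)
        logger.info("mog: %s", gating.rr_summary())

        stage = "recon-cine"
        samples_corr = apply_moco(dataset, motion)
        cine = reconstruct_cine(dataset, motion, gating,
                                CSParams(lambda_t=config.cine_lambda,
                                         n_iters=config.cine_iters),
                                samples_override=samples_corr)

        stage = "evaluate"
        reports = {}
        if gt is not None:
            reports = evaluate_pipeline(dataset, rt, motion, gating, cine)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, exc) from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 1),
        "hashes": {
            "samples": _sha(dataset.samples),
            "rt_frames": _sha(rt.frames),
            "keep_arm_mask": _sha(motion.keep_arm_mask),
            "arm_shifts": _sha(motion.arm_shifts_mm),
            "triggers": _sha(gating.trigger_times_ms),
            "cine": _sha(cine.phases),
        },
    }
    result = PipelineResult(config=config, dataset=dataset, rt_series=rt,
                            rt_bins=rt_bins, motion=motion, gating=gating,
                            cine=cine, samples_corrected=samples_corr,
                            reports=reports, manifest=manifest)
    if config.out_dir:
        _persist(result, Path(config.out_dir))
    return result


def _central_roi(n: int) -> Roi:
    q = n // 4
    return Roi(q, n - q, q, n - q)


def _persist(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    container = out / "dataset.h5"
    io_h5.write_dataset(str(container), result.dataset)
    io_h5.write_motion(str(container), result.motion)
    io_h5.write_gating(str(container), result.gating)
    result.rt_series.to_nifti(str(out / "realtime.nii.gz"))
    result.cine.to_nifti(str(out / "cine.nii.gz"))
    (out / "reports.json").write_text(json.dumps(result.reports, indent=2,
                                                 default=float))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  default=float))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def phantom_quality_rois(config: PhantomConfig, protocol: SpiralProtocol,
                         offset_mm=(0.0, 0.0)) -> dict:
    """Noise/blood/myocardium ROI masks from the phantom geometry.

    ``offset_mm`` translates the blood and myocardium ROIs (e.g. by the
    fetal position at measurement time).  The noise ROI sits at the image
    corner, outside the maternal body.
    """
    g = config.geometry
    n = protocol.grid_size
    px = protocol.fov_mm / n
    coords = (np.arange(n) - n // 2) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    hx = g.heart_center[0] + offset_mm[0]
    hy = g.heart_center[1] + offset_mm[1]

    def ensure(mask, cx, cy):
        # coarse grids can leave a small ROI empty: fall back to the pixel
        # nearest its intended center
        if not mask.any():
            d = np.hypot(xx - cx, yy - cy)
            mask.flat[np.argmin(d)] = True
        return mask

    bx, by = hx + g.lv_offset[0], hy + g.lv_offset[1]
    blood = ensure(np.hypot(xx - bx, yy - by) <= 0.5 * g.lv_radius, bx, by)
    # septal box midway between the pools
    sx = hx + 0.5 * (g.lv_offset[0] + g.lv_radius + g.rv_offset[0] - g.rv_radius)
    sy = hy + 0.5 * (g.lv_offset[1] + g.rv_offset[1])
    myo = ensure((np.abs(xx - sx) <= 1.2) & (np.abs(yy - sy) <= 3.0), sx, sy)
    edge = int(round(4.0 / px))
    size = int(round(16.0 / px))
    noise = np.zeros((n, n), dtype=bool)
    noise[edge:edge + size, edge:edge + size] = True
    return {"noise": noise, "blood": blood, "myo": myo}


def evaluate_quality(image: np.ndarray, config: PhantomConfig,
                     protocol: SpiralProtocol,
                     offset_mm=(0.0, 0.0)) -> QualityReport:
    rois = phantom_quality_rois(config, protocol, offset_mm)
    snr, contrast, cnr = roi_quality(image, rois["noise"], rois["blood"],
                                     rois["myo"])
    return QualityReport(snr=snr, contrast=contrast, cnr=cnr,
                         pique=pique_score(np.abs(image)),
                         rois={k: int(v.sum()) for k, v in rois.items()})


def end_diastole_phase(cine_mag: np.ndarray, config: PhantomConfig,
                       protocol: SpiralProtocol,
                       offset_mm=(0.0, 0.0)) -> int:
    """Phase with the largest ventricular blood pool.

    Scored on an annulus just inside the diastolic pool boundary: it holds
    bright blood at end diastole and myocardium at end systole.
    """
    g = config.geometry
    n = protocol.grid_size
    px = protocol.fov_mm / n
    coords = (np.arange(n) - n // 2) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    cx = g.heart_center[0] + g.lv_offset[0] + offset_mm[0]
    cy = g.heart_center[1] + g.lv_offset[1] + offset_mm[1]
    r = np.hypot(xx - cx, yy - cy)
    ring = (r >= 0.7 * g.lv_radius) & (r <= 0.95 * g.lv_radius)
    means = [float(p[ring].mean()) for p in cine_mag]
    return int(np.argmax(means))


def align_cine_to_truth(cine: CineSeries, gt) -> tuple[np.ndarray, dict]:
    """Align a reconstructed cine to the ground-truth cine.

    The reconstruction is translated (the motion-correction reference frame
    sits at an arbitrary fetal position), cyclically rotated in phase (the
    recovered triggers have an arbitrary offset within the beat) and
    amplitude-matched by least squares.  Returns the aligned magnitude stack
    and the alignment parameters.
    """
    from skimage.registration import phase_cross_correlation

    mag = np.abs(cine.phases)
    truth = np.abs(gt.cine)
    sh, _, _ = phase_cross_correlation(truth.mean(axis=0), mag.mean(axis=0),
                                       upsample_factor=10, normalization=None)
    shifted = np.empty_like(mag)
    for p in range(mag.shape[0]):
        f = np.fft.fft2(mag[p])
        shifted[p] = np.abs(np.fft.ifft2(fourier_shift(f, sh)))
    mask = gt.anatomy_mask
    best = None
    for k in range(mag.shape[0]):
        rolled = np.roll(shifted, k, axis=0)
        num = float(np.sum(rolled[:, mask] * truth[:, mask]))
        den = float(np.sum(rolled[:, mask] ** 2))
        c = num / max(den, 1e-30)
        err = nrmsd(c * rolled, truth, mask)
        if best is None or err < best[0]:
            best = (err, k, c)
    err, k, c = best
    aligned = c * np.roll(shifted, k, axis=0)
    return aligned, {"nrmsd_pct": err, "phase_roll": k, "scale": c,
                     "shift_px": tuple(float(s) for s in sh)}


def evaluate_pipeline(dataset: RawSpiralDataset, rt: ImageSeries,
                      motion: MotionRecord, gating: GatingRecord,
                      cine: CineSeries) -> dict:
    """Ground-truth-based evaluation: parameter recovery and image quality."""
    gt = dataset.ground_truth
    prot = dataset.protocol
    ph_cfg = gt.config

    rr_true = gt.rr_series_ms.mean()
    rr_est = gating.rr_series_ms.mean()

    seg_mae = float("nan")
    if gating.segment_rr_ms is not None:
        edges = np.append(gating.segment_edges_ms,
                          dataset.timestamps_ms.max() + prot.tr_ms)
        truths = []
        trig, rr_s = gt.trigger_times_ms[:-1], gt.rr_series_ms
        for e0, e1 in zip(edges[:-1], edges[1:]):
            sel = (trig >= e0) & (trig < e1)
            truths.append(rr_s[sel].mean() if sel.any() else np.nan)
        seg_mae = float(np.nanmean(np.abs(np.asarray(truths)
                                          - gating.segment_rr_ms)))

    # translation recovery: compare estimated frame shifts (relative to the
    # reference frame) against the true trace sampled at frame times
    kept = np.flatnonzero(motion.keep_frame_mask)
    true_at_frames = np.stack([
        np.interp(rt.times_ms[kept], dataset.timestamps_ms,
                  gt.translation_trace[:, c]) for c in range(2)], axis=1)
    est = motion.frame_shifts_mm[kept]
    resid = est - true_at_frames
    resid -= resid.mean(axis=0)   # reference-frame offset is unobservable
    trans_rms_px = float(np.sqrt(np.mean(resid ** 2)) / prot.res_mm)

    corrupt = gt.corrupted_arm_mask
    rejected = ~motion.keep_arm_mask
    sens = float(np.mean(rejected[corrupt])) if corrupt.any() else float("nan")
    false_rej = float(np.mean(rejected[~corrupt]))

    aligned, align_info = align_cine_to_truth(cine, gt)

    # image quality at end diastole; the cine sits at the moco reference
    # position, real-time frames at their own instantaneous position
    sh = np.asarray(align_info["shift_px"])   # (row, col) moving cine -> truth
    offset = (-sh[1] * prot.res_mm, -sh[0] * prot.res_mm)
    cine_mag = np.abs(cine.phases)
    ed = end_diastole_phase(cine_mag, ph_cfg, prot, offset)
    cine_q = evaluate_quality(cine_mag[ed], ph_cfg, prot, offset)
    ref_frame = motion.reference_frame
    rt_offset = tuple(np.interp(rt.times_ms[ref_frame], dataset.timestamps_ms,
                                gt.translation_trace[:, c]) for c in range(2))
    # end-diastole real-time frame: the retained frame closest to a trigger
    trig = gt.trigger_times_ms
    kept_t = rt.times_ms[kept]
    dist = np.min(np.abs(kept_t[:, None] - trig[None, :]), axis=1)
    rt_ed = int(kept[np.argmin(dist)])
    rt_off = tuple(np.interp(rt.times_ms[rt_ed], dataset.timestamps_ms,
                             gt.translation_trace[:, c]) for c in range(2))
    rt_q = evaluate_quality(np.abs(rt.frames[rt_ed]), ph_cfg, prot, rt_off)

    return {
        "rr_true_mean_ms": float(rr_true),
        "rr_est_mean_ms": float(rr_est),
        "rr_mean_err_pct": float(100 * abs(rr_est - rr_true) / rr_true),
        "rr_segment_mae_ms": seg_mae,
        "rr_est_sd_ms": float(gating.rr_series_ms.std(ddof=1)),
        "translation_rms_err_px": trans_rms_px,
        "rejection_sensitivity": sens,
        "false_rejection_rate": false_rej,
        "rejected_fraction_pct": motion.rejected_fraction,
        "cine_nrmsd_vs_truth_pct": align_info["nrmsd_pct"],
        "cine_quality": cine_q.to_dict(),
        "rt_quality": rt_q.to_dict(),
        "rt_end_diastole_frame": rt_ed,
        "cine_end_diastole_phase": int(ed),
        "align": align_info,
    }


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _subset_cine(result: PipelineResult, start: int, n_arms: int,
                 params: CSParams | None = None) -> CineSeries:
    ds = retrospective_subset(result.dataset, n_arms, start)
    sl = slice(start, start + n_arms)
    motion_sub = dc_replace(result.motion,
                            keep_arm_mask=result.motion.keep_arm_mask[sl],
                            arm_shifts_mm=result.motion.arm_shifts_mm[sl])
    if params is None:
        params = CSParams(lambda_t=result.config.cine_lambda,
                          n_iters=result.config.cine_iters)
    return reconstruct_cine(ds, motion_sub, result.gating, params,
                            samples_override=result.samples_corrected[sl])


def acceleration_sweep(result: PipelineResult,
                       arm_counts=(250, 500, 750, 1000, 1250, 1500, 1750,
                                   2000, 2250, 2500)) -> list[dict]:
    """Cines from increasing arm counts, scored by NRMSD against the
    all-data reference (the pipeline's own cine)."""
    gt = result.dataset.ground_truth
    mask = gt.anatomy_mask if gt is not None \
        else np.ones(result.cine.phases.shape[-2:], bool)
    ref = np.abs(result.cine.phases)
    tr = result.dataset.protocol.tr_ms
    rows = []
    for n in arm_counts:
        cine_n = _subset_cine(result, 0, int(n))
        err = nrmsd(np.abs(cine_n.phases), ref, mask)
        rows.append({"n_arms": int(n), "scan_time_s": round(n * tr / 1000, 3),
                     "nrmsd_pct": err})
        logger.info("accel sweep: %d arms -> NRMSD %.1f%%", n, err)
    return rows


def consistency_experiment(result: PipelineResult,
                           window_arms: int = 1250) -> dict:
    """Two disjoint contiguous windows reconstructed independently and
    compared against the all-data reference."""
    gt = result.dataset.ground_truth
    mask = gt.anatomy_mask if gt is not None \
        else np.ones(result.cine.phases.shape[-2:], bool)
    ref = np.abs(result.cine.phases)
    s1 = _subset_cine(result, 0, window_arms)
    s2 = _subset_cine(result, window_arms, window_arms)
    e1 = nrmsd(np.abs(s1.phases), ref, mask)
    e2 = nrmsd(np.abs(s2.phases), ref, mask)
    return {"window_arms": window_arms,
            "scan_time_s": round(window_arms * result.dataset.protocol.tr_ms
                                 / 1000, 3),
            "nrmsd_s1_pct": e1, "nrmsd_s2_pct": e2,
            "nrmsd_diff_points": abs(e1 - e2)}
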