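"""Cardiac-gated cine reconstruction and the acceleration/consistency
experiments.

Motion-corrected arms are partitioned into cardiac phases with the recovered
triggers and reconstructed jointly by compressed sensing with a *cyclic*
temporal difference (cardiac phase is periodic: phase 19 is adjacent to
phase 0).  Retrospective windowing supports the acceleration sweep
(reconstructions from growing arm counts vs an all-data reference) and the
two-window consistency experiment.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np

from .containers import CineSeries, GatingRecord, MotionRecord, RawSpiralDataset
from .mog import phase_assignment
from .recon import BinnedData, CSParams, cs_reconstruct
from .trajectory import Trajectory

__all__ = [
    "bin_arms_to_phases",
    "reconstruct_cine",
    "retrospective_subset",
]


def bin_arms_to_phases(arm_times_ms: np.ndarray, keep_arm_mask: np.ndarray,
                       trigger_times_ms: np.ndarray,
                       n_phases: int = 20) -> BinnedData:
    """Partition retained arms by cardiac phase.

    Arms outside trigger coverage are dropped (their count is recorded in
    ``meta``).  Raises when any phase ends up empty — with few arms or
    unlucky heart rates the gated arms can cluster in k-space/phase; the
    caller then widens the data window or reduces n_phases.
    """
    arm_times_ms = np.asarray(arm_times_ms, dtype=float)
    keep = np.asarray(keep_arm_mask, dtype=bool)
    if keep.shape != arm_times_ms.shape:
        raise ValueError("mask and arm times must have equal length")
    if not keep.any():
        raise ValueError("all arms rejected; nothing to bin")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phases = phase_assignment(arm_times_ms, trigger_times_ms, n_phases)
    phases = np.where(keep, phases, -1)
    n_dropped = int(np.count_nonzero((phases < 0) & keep))
    bins = []
    empty = []
    counts = np.zeros(n_phases, dtype=int)
    for p in range(n_phases):
        idx = np.flatnonzero(phases == p)
        counts[p] = idx.size
        if idx.size == 0:
            empty.append(p)
        bins.append(idx)
    if empty:
        raise ValueError(f"empty cardiac phase bins {empty}: widen the data "
                         "window or reduce n_phases")
    return BinnedData(bins=bins, times_ms=None, cyclic=True,
                      meta={"per_phase_counts": counts,
                            "dropped_outside_triggers": n_dropped,
                            "n_phases": n_phases})


def max_angular_gap_deg(trajectory: Trajectory, arm_indices) -> float:
    """Largest azimuthal gap (degrees) of the selected arms' rotation angles;
    a k-space coverage summary for one phase bin."""
    ang = np.sort(np.asarray(trajectory.angles_deg)[np.asarray(arm_indices)] % 360.0)
    if ang.size == 1:
        return 360.0
    gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
    return float(gaps.max())


def reconstruct_cine(dataset: RawSpiralDataset, motion: MotionRecord,
                     gating: GatingRecord,
                     params: CSParams | None = None, *,
                     samples_override: np.ndarray | None = None) -> CineSeries:
    """Reconstruct the 20-phase cine from gated, motion-corrected arms.

    ``samples_override`` carries the phase-ramp-corrected samples (from
    :func:`fetalcine.moco.apply_moco`); without it the dataset's samples are
    used as-is.
    """
    if params is None:
        params = CSParams(lambda_t=0.02, n_iters=50)
    bins = bin_arms_to_phases(dataset.timestamps_ms, motion.keep_arm_mask,
                              gating.trigger_times_ms, gating.n_phases)
    ds = dataset
    if samples_override is not None:
        ds = dc_replace(dataset, samples=samples_override)
    series = cs_reconstruct(ds, bins, params)
    rr_mean = float(np.mean(gating.rr_series_ms))
    arms_used = np.concatenate(bins.bins)
    return CineSeries(phases=series.frames,
                      phase_duration_ms=rr_mean / gating.n_phases,
                      res_mm=dataset.protocol.res_mm,
                      arms_used=np.sort(arms_used),
                      lambda_t=params.lambda_t, n_iters=params.n_iters,
                      scale=series.scale, objective=series.objective,
                      meta={"per_phase_counts": bins.meta["per_phase_counts"],
                            "coverage_max_gap_deg": [
                                max_angular_gap_deg(dataset.trajectory, b)
                                for b in bins.bins],
                            "gating_entropy": gating.entropy_at_solution})


def retrospective_subset(dataset: RawSpiralDataset, n_arms: int,
                         start_arm: int = 0) -> RawSpiralDataset:
    """Contiguous arm window [start_arm, start_arm + n_arms) as a dataset view.

    Timestamps, trajectory and ground truth are preserved so the window can
    be reconstructed exactly as acquired (used by the acceleration sweep and
    the two-window consistency experiment).
    """
    if n_arms < 1 or start_arm < 0 or start_arm + n_arms > dataset.n_arms:
        raise ValueError("arm window out of range")
    sl = slice(start_arm, start_arm + n_arms)
    traj = Trajectory(coords=dataset.trajectory.coords[sl],
                      angles_deg=dataset.trajectory.angles_deg[sl],
                      k_max=dataset.trajectory.k_max,
                      dcf=None if dataset.trajectory.dcf is None
                      else dataset.trajectory.dcf[sl])
    return RawSpiralDataset(protocol=dataset.protocol, trajectory=traj,
                            samples=dataset.samples[sl],
                            timestamps_ms=dataset.timestamps_ms[sl],
                            ground_truth=dataset.ground_truth,
                            arm_offset=dataset.arm_offset + start_arm)
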