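"""HDF5 container for raw spiral datasets and derived pipeline records.

Layout (one file per acquisition):

* ``/protocol``      — protocol parameters as attributes
* ``/trajectory``    — ``coords`` (n_arms, n_samples, 2), ``angles_deg``,
                       optional ``dcf``; ``k_max`` attribute
* ``/data``          — ``samples`` (n_arms, n_samples) complex,
                       ``timestamps_ms``
* ``/ground_truth``  — simulator sidecar (optional)
* ``/motion``        — MotionRecord (optional)
* ``/gating``        — GatingRecord (optional)

All arrays round-trip bit-exactly.  External raw data can be imported by
filling ``/protocol``, ``/trajectory`` and ``/data`` only.
"""

from __future__ import annotations

import h5py
import numpy as np

from .containers import GatingRecord, MotionRecord, RawSpiralDataset, Roi
from .phantom import GroundTruth, PhantomConfig
from .trajectory import SpiralProtocol, Trajectory

__all__ = ["write_dataset", "read_dataset", "write_motion", "read_motion",
           "write_gating", "read_gating"]


class FormatError(ValueError):
    """Malformed raw-data container."""


def write_dataset(path: str, dataset: RawSpiralDataset) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("protocol")
        for k, v in dataset.protocol.to_dict().items():
            g.attrs[k] = v
        g = f.create_group("trajectory")
        g.create_dataset("coords", data=dataset.trajectory.coords)
        g.create_dataset("angles_deg", data=dataset.trajectory.angles_deg)
        if dataset.trajectory.dcf is not None:
            g.create_dataset("dcf", data=dataset.trajectory.dcf)
        g.attrs["k_max"] = dataset.trajectory.k_max
        g = f.create_group("data")
        g.create_dataset("samples", data=dataset.samples)
        g.create_dataset("timestamps_ms", data=dataset.timestamps_ms)
        g.attrs["arm_offset"] = dataset.arm_offset
        gt = dataset.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("rr_series_ms", data=gt.rr_series_ms)
            g.create_dataset("trigger_times_ms", data=gt.trigger_times_ms)
            g.create_dataset("translation_trace", data=gt.translation_trace)
            g.create_dataset("corrupted_arm_mask", data=gt.corrupted_arm_mask)
            g.create_dataset("cine", data=gt.cine)
            g.create_dataset("anatomy_mask", data=gt.anatomy_mask)
            g.create_dataset("heart_roi", data=gt.heart_roi.to_array())
            g.attrs["n_phases"] = gt.n_phases


def read_dataset(path: str) -> RawSpiralDataset:
    with h5py.File(path, "r") as f:
        for group in ("protocol", "trajectory", "data"):
            if group not in f:
                raise FormatError(f"missing mandatory group /{group}")
        prot = SpiralProtocol(**{k: (int(v) if isinstance(v, np.integer) else
                                     float(v) if isinstance(v, np.floating) else v)
                                 for k, v in f["protocol"].attrs.items()})
        tg = f["trajectory"]
        if "coords" not in tg:
            raise FormatError("missing /trajectory/coords")
        traj = Trajectory(coords=tg["coords"][()],
                          angles_deg=tg["angles_deg"][()],
                          k_max=float(tg.attrs["k_max"]),
                          dcf=tg["dcf"][()] if "dcf" in tg else None)
        dg = f["data"]
        if "samples" not in dg or "timestamps_ms" not in dg:
            raise FormatError("missing /data/samples or /data/timestamps_ms")
        gt = None
        if "ground_truth" in f:
            gg = f["ground_truth"]
            roi = Roi(*(int(v) for v in gg["heart_roi"][()]))
            gt = GroundTruth(rr_series_ms=gg["rr_series_ms"][()],
                             trigger_times_ms=gg["trigger_times_ms"][()],
                             translation_trace=gg["translation_trace"][()],
                             corrupted_arm_mask=gg["corrupted_arm_mask"][()].astype(bool),
                             cine=gg["cine"][()],
                             n_phases=int(gg.attrs["n_phases"]),
                             anatomy_mask=gg["anatomy_mask"][()].astype(bool),
                             heart_roi=roi)
        ds = RawSpiralDataset(protocol=prot, trajectory=traj,
                              samples=dg["samples"][()],
                              timestamps_ms=dg["timestamps_ms"][()],
                              ground_truth=gt,
                              arm_offset=int(dg.attrs.get("arm_offset", 0)))
        ds.validate()
        return ds


def write_motion(path: str, record: MotionRecord) -> None:
    with h5py.File(path, "a") as f:
        if "motion" in f:
            del f["motion"]
        g = f.create_group("motion")
        g.create_dataset("roi", data=record.roi.to_array())
        g.create_dataset("frame_mi", data=record.frame_mi)
        g.create_dataset("keep_frame_mask", data=record.keep_frame_mask)
        g.create_dataset("frame_shifts_mm", data=record.frame_shifts_mm)
        g.create_dataset("arm_shifts_mm", data=record.arm_shifts_mm)
        g.create_dataset("keep_arm_mask", data=record.keep_arm_mask)
        g.attrs["reference_frame"] = record.reference_frame


def read_motion(path: str) -> MotionRecord:
    with h5py.File(path, "r") as f:
        if "motion" not in f:
            raise FormatError("missing /motion group")
        g = f["motion"]
        return MotionRecord(roi=Roi(*(int(v) for v in g["roi"][()])),
                            frame_mi=g["frame_mi"][()],
                            keep_frame_mask=g["keep_frame_mask"][()].astype(bool),
                            frame_shifts_mm=g["frame_shifts_mm"][()],
                            arm_shifts_mm=g["arm_shifts_mm"][()],
                            keep_arm_mask=g["keep_arm_mask"][()].astype(bool),
                            reference_frame=int(g.attrs["reference_frame"]))


def write_gating(path: str, record: GatingRecord) -> None:
    with h5py.File(path, "a") as f:
        if "gating" in f:
            del f["gating"]
        g = f.create_group("gating")
        g.create_dataset("trigger_times_ms", data=record.trigger_times_ms)
        if record.segment_rr_ms is not None:
            g.create_dataset("segment_rr_ms", data=record.segment_rr_ms)
            g.create_dataset("segment_edges_ms", data=record.segment_edges_ms)
        g.attrs["n_phases"] = record.n_phases
        g.attrs["entropy_at_solution"] = record.entropy_at_solution


def read_gating(path: str) -> GatingRecord:
    with h5py.File(path, "r") as f:
        if "gating" not in f:
            raise FormatError("missing /gating group")
        g = f["gating"]
        return GatingRecord(
            trigger_times_ms=g["trigger_times_ms"][()],
            n_phases=int(g.attrs["n_phases"]),
            entropy_at_solution=float(g.attrs["entropy_at_solution"]),
            segment_rr_ms=g["segment_rr_ms"][()] if "segment_rr_ms" in g else None,
            segment_edges_ms=g["segment_edges_ms"][()] if "segment_edges_ms" in g else None)
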