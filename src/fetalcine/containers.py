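"""In-memory data containers shared across the reconstruction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import SpiralProtocol, Trajectory

__all__ = [
    "Roi",
    "RawSpiralDataset",
    "ImageSeries",
    "MotionRecord",
    "GatingRecord",
    "CineSeries",
]


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest in pixel coordinates [r0:r1, c0:c1]."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError("empty ROI")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r1), slice(self.c0, self.c1)

    def extract(self, image: np.ndarray) -> np.ndarray:
        rs, cs = self.slices()
        return image[..., rs, cs]

    def expand(self, margin_frac: float, grid_size: int) -> "Roi":
        dr = int(round((self.r1 - self.r0) * margin_frac / 2))
        dc = int(round((self.c1 - self.c0) * margin_frac / 2))
        return Roi(max(0, self.r0 - dr), min(grid_size, self.r1 + dr),
                   max(0, self.c0 - dc), min(grid_size, self.c1 + dc))

    def to_array(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.c0, self.c1], dtype=np.int64)


@dataclass
class RawSpiralDataset:
    """Raw spiral k-space data: the interchange object of the whole pipeline.

    samples has shape (n_arms, n_samples_per_arm) complex; timestamps_ms is the
    start time of each arm readout.  ``ground_truth`` is the simulator sidecar
    (absent for externally imported data).
    """

    protocol: SpiralProtocol
    trajectory: Trajectory
    samples: np.ndarray
    timestamps_ms: np.ndarray
    ground_truth: "object | None" = None
    arm_offset: int = 0   # index of arm 0 within the parent acquisition

    @property
    def n_arms(self) -> int:
        return self.samples.shape[0]

    def validate(self) -> None:
        if self.samples.shape != self.trajectory.coords.shape[:2]:
            raise ValueError("samples and trajectory shapes disagree")
        if self.timestamps_ms.shape != (self.n_arms,):
            raise ValueError("timestamps length must equal n_arms")


@dataclass
class ImageSeries:
    """Time series of complex 2-D frames (real-time reconstruction output)."""

    frames: np.ndarray                # (T, N, N) complex
    times_ms: np.ndarray              # frame timestamps (mean arm time)
    frame_spacing_ms: float           # nominal (interpolated) frame spacing
    res_mm: float
    scale: float = 1.0                # normalization factor applied to data
    objective: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames)

    def to_nifti(self, path: str) -> None:
        """Export the magnitude series (float32) with pixel size and frame
        duration in the header."""
        import nibabel as nib

        mag = np.abs(self.frames).astype(np.float32)
        data = np.transpose(mag, (2, 1, 0))[:, :, None, :]  # x, y, z, t
        affine = np.diag([self.res_mm, self.res_mm, 1.0, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((self.res_mm, self.res_mm, 1.0,
                              self.frame_spacing_ms / 1000.0))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path)


@dataclass
class MotionRecord:
    """Per-frame MI statistics, keep/reject masks, and translational shifts."""

    roi: Roi
    frame_mi: np.ndarray              # per-frame MI summary (nats)
    keep_frame_mask: np.ndarray       # bool, per frame
    frame_shifts_mm: np.ndarray       # (T, 2), NaN where rejected
    arm_shifts_mm: np.ndarray         # (n_arms, 2) interpolated to arm times
    keep_arm_mask: np.ndarray         # bool, per arm
    reference_frame: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def rejected_fraction(self) -> int:
        from .moco import rejected_fraction
        return rejected_fraction(self.keep_arm_mask)

    def shift_ranges_mm(self) -> tuple[float, float]:
        """Peak-to-peak [x, y] shift ranges over retained frames."""
        s = self.frame_shifts_mm[self.keep_frame_mask]
        return (float(np.ptp(s[:, 0])), float(np.ptp(s[:, 1])))


@dataclass
class GatingRecord:
    """Cardiac gating solution: trigger times and the variable RR series."""

    trigger_times_ms: np.ndarray      # strictly increasing
    n_phases: int = 20
    entropy_at_solution: float = float("nan")
    segment_rr_ms: np.ndarray | None = None
    segment_edges_ms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.trigger_times_ms, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("trigger times must be strictly increasing, >= 2 entries")
        self.trigger_times_ms = t

    @property
    def rr_series_ms(self) -> np.ndarray:
        return np.diff(self.trigger_times_ms)

    def rr_summary(self) -> str:
        rr = self.rr_series_ms
        return f"RR = {rr.mean():.0f} ± {rr.std(ddof=1):.0f} ms"


@dataclass
class CineSeries:
    """Cardiac-phase-resolved image stack (one representative heartbeat)."""

    phases: np.ndarray                # (n_phases, N, N) complex
    phase_duration_ms: float
    res_mm: float
    arms_used: np.ndarray | None = None
    lambda_t: float = 0.02
    n_iters: int = 50
    scale: float = 1.0
    objective: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.phases.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.phases)

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        mag = np.abs(self.phases).astype(np.float32)
        data = np.transpose(mag, (2, 1, 0))[:, :, None, :]
        img = nib.Nifti1Image(data, np.diag([self.res_mm, self.res_mm, 1.0, 1.0]))
        img.header.set_zooms((self.res_mm, self.res_mm, 1.0,
                              self.phase_duration_ms / 1000.0))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, path)
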