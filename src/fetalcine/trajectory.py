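"""Spiral readout geometry, pseudo golden-angle ordering and density compensation.

The acquisition tiles 2-D k-space with rotated copies of a single spiral-out
interleaf.  Arm rotations follow a *pseudo* golden-angle schedule: instead of the
irrational golden angle, the increment is a Fibonacci rational approximation
(360 * 55/144 = 137.5 deg) so that the arm set repeats exactly after
``golden_period`` arms.  Exact periodicity keeps the k-space point set finite,
which matters for caching density-compensation weights and for reproducible
retrospective binning.

Units: k-space coordinates are in cycles/mm throughout this module.  The
maximum trajectory radius is the Nyquist limit k_max = 1/(2 * res_mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

__all__ = [
    "SpiralProtocol",
    "Trajectory",
    "pseudo_golden_angle_sequence",
    "design_spiral_arm",
    "build_trajectory",
    "density_compensation",
    "default_trajectory",
]


@dataclass(frozen=True)
class SpiralProtocol:
    """Acquisition protocol for a 2-D spiral-out SSFP scan.

    Defaults follow a 0.55 T fetal cardiac protocol: 240 mm field of view,
    63 spiral interleaves, TR in 5.3-5.7 ms, 90 degree flip, pseudo
    golden-angle ordering with a 144-arm period.
    """

    fov_mm: float = 240.0
    res_mm: float = 1.5
    n_interleaves: int = 63
    tr_ms: float = 5.7
    te_ms: float = 0.8            # metadata only
    n_samples_per_arm: int = 512
    golden_period: int = 144
    flip_deg: float = 90.0        # metadata only

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if not (0 < self.res_mm < self.fov_mm):
            raise ValueError("res_mm must satisfy 0 < res_mm < fov_mm")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")
        if self.golden_period < 1:
            raise ValueError("golden_period must be >= 1")
        if self.n_samples_per_arm < 2:
            raise ValueError("n_samples_per_arm must be >= 2")
        if self.grid_size < 2:
            raise ValueError("resolution too coarse for this field of view")

    @property
    def k_max(self) -> float:
        """Nyquist radius in cycles/mm."""
        return 1.0 / (2.0 * self.res_mm)

    @property
    def grid_size(self) -> int:
        """Reconstruction matrix size N = round(fov/res)."""
        return int(round(self.fov_mm / self.res_mm))

    def to_dict(self) -> dict:
        return {
            "fov_mm": self.fov_mm,
            "res_mm": self.res_mm,
            "n_interleaves": self.n_interleaves,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "n_samples_per_arm": self.n_samples_per_arm,
            "golden_period": self.golden_period,
            "flip_deg": self.flip_deg,
        }


@dataclass
class Trajectory:
    """Rotated-arm k-space trajectory.

    coords has shape (n_arms, n_samples, 2) in cycles/mm; ``dcf`` holds
    per-sample density-compensation weights once computed.
    """

    coords: np.ndarray
    angles_deg: np.ndarray
    k_max: float
    dcf: np.ndarray | None = field(default=None)

    @property
    def n_arms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples_per_arm(self) -> int:
        return self.coords.shape[1]

    def radii(self) -> np.ndarray:
        return np.hypot(self.coords[..., 0], self.coords[..., 1])


def _fibonacci_numerator(period: int) -> int:
    """Integer m with m/period approximating 1 - 1/phi, coprime with period.

    For period 144 this is the Fibonacci number 55, giving the canonical
    pseudo golden-angle increment 360 * 55/144 = 137.5 degrees.
    """
    target = period * (1.0 - 1.0 / ((1.0 + math.sqrt(5.0)) / 2.0))
    m = max(1, int(round(target)))
    # nudge to the closest coprime so the full period is realized
    for delta in range(period):
        for cand in (m - delta, m + delta):
            if 1 <= cand < max(period, 2) and math.gcd(cand, period) == 1:
                return cand
    return 1


def pseudo_golden_angle_sequence(n_arms: int, period: int = 144) -> np.ndarray:
    """Arm rotation angles (degrees) with exact period ``period``.

    angle_i = mod(i * 360 * m / period, 360) with m the Fibonacci-ratio
    numerator (55 when period = 144, i.e. an increment of 137.5 degrees).
    """
    if not isinstance(n_arms, (int, np.integer)) or isinstance(n_arms, bool):
        raise TypeError("n_arms must be an integer")
    if not isinstance(period, (int, np.integer)) or isinstance(period, bool):
        raise TypeError("period must be an integer")
    if n_arms < 1 or period < 1:
        raise ValueError("n_arms and period must be >= 1")
    m = _fibonacci_numerator(int(period)) if period > 1 else 0
    i = np.arange(n_arms, dtype=np.int64)
    # exact rational arithmetic on degree numerators avoids float drift
    num = (i * 360 * m) % (360 * period)
    return num / float(period)


def design_spiral_arm(protocol: SpiralProtocol) -> np.ndarray:
    """Base spiral-out interleaf, shape (n_samples_per_arm, 2), cycles/mm.

    Archimedean design: radius r(tau) = k_max * tau, azimuth
    phi(tau) = 2*pi*n_turns*tau, with n_turns = k_max * fov / n_interleaves so
    that the full interleaf set satisfies the radial Nyquist criterion.
    """
    kmax = protocol.k_max
    n_turns = kmax * protocol.fov_mm / protocol.n_interleaves
    tau = np.linspace(0.0, 1.0, protocol.n_samples_per_arm)
    r = kmax * tau
    phi = 2.0 * np.pi * n_turns * tau
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)


def build_trajectory(base_arm: np.ndarray, angles_deg: np.ndarray,
                     k_max: float | None = None) -> Trajectory:
    """Rotate the base interleaf by each angle; arm i = R(angle_i) @ base arm."""
    base_arm = np.asarray(base_arm, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if base_arm.ndim != 2 or base_arm.shape[-1] != 2 or base_arm.shape[0] == 0:
        raise ValueError("base_arm must be a nonempty (n_samples, 2) array")
    if angles_deg.ndim != 1 or angles_deg.size == 0:
        raise ValueError("angles_deg must be a nonempty 1-D sequence")
    th = np.deg2rad(angles_deg)
    c, s = np.cos(th), np.sin(th)
    kx = base_arm[:, 0]
    ky = base_arm[:, 1]
    out = np.empty((angles_deg.size, base_arm.shape[0], 2))
    out[..., 0] = c[:, None] * kx[None, :] - s[:, None] * ky[None, :]
    out[..., 1] = s[:, None] * kx[None, :] + c[:, None] * ky[None, :]
    if k_max is None:
        k_max = float(np.hypot(kx, ky).max())
    return Trajectory(coords=out, angles_deg=angles_deg.copy(), k_max=float(k_max))


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex polygon given unordered vertices."""
    ctr = vertices.mean(axis=0)
    d = vertices - ctr
    order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _cell_areas(vor: Voronoi, ids: np.ndarray, points: np.ndarray,
                k_max: float) -> np.ndarray:
    """Clipped Voronoi cell areas for the selected point indices.

    Vertices outside the Nyquist circle are pulled back onto it; unbounded or
    wildly stretched boundary cells are assigned the median area of the
    outermost bounded band (the spiral's outer ring is nearly uniform).
    """
    areas = np.full(len(ids), np.nan)
    for j, ip in enumerate(ids):
        region = vor.regions[vor.point_region[ip]]
        if len(region) == 0 or -1 in region:
            continue
        verts = vor.vertices[np.asarray(region)]
        radii = np.hypot(verts[:, 0], verts[:, 1])
        if np.any(radii > k_max * 1.5):
            continue  # wildly stretched boundary cell; fill below
        outside = radii > k_max
        if np.any(outside):
            verts = verts.copy()
            verts[outside] *= (k_max / radii[outside])[:, None]
        areas[j] = _polygon_area(verts)
    bad = np.isnan(areas)
    if np.all(bad):
        raise ValueError("degenerate trajectory: no bounded Voronoi cells")
    if np.any(bad):
        r = np.hypot(points[ids, 0], points[ids, 1])
        band = (~bad) & (r >= np.quantile(r[~bad], 0.9))
        fill = float(np.median(areas[band])) if np.any(band) \
            else float(np.median(areas[~bad]))
        areas[bad] = fill
    return areas


def _voronoi_weights(points: np.ndarray, k_max: float) -> np.ndarray:
    vor = Voronoi(points)
    return _cell_areas(vor, np.arange(points.shape[0]), points, k_max)


def density_compensation(trajectory: Trajectory, method: str = "voronoi") -> np.ndarray:
    """Per-sample density-compensation weights, shape (n_arms, n_samples).

    ``"radial"``: |k| with a finite center value (fast analytic fallback for a
    constant-density spiral).  ``"voronoi"``: per-sample Voronoi cell area over
    the set of unique k-space locations, divided by location multiplicity;
    this is exact for arbitrary arm subsets of a periodic schedule.
    """
    coords = trajectory.coords
    flat = coords.reshape(-1, 2)
    if flat.shape[0] < 4 or np.allclose(flat, flat[0], atol=1e-12):
        raise ValueError("degenerate trajectory for density compensation")
    if method == "radial":
        r = np.hypot(coords[..., 0], coords[..., 1])
        pos = r[r > 0]
        if pos.size == 0:
            raise ValueError("degenerate trajectory: all samples at k = 0")
        w = r.copy()
        w[w == 0] = 0.5 * pos.min()
        return w
    if method != "voronoi":
        raise ValueError(f"unknown density compensation method: {method!r}")
    # collapse exactly repeated arms (periodic schedule) before Voronoi
    scale = 1e9
    keys = np.round(flat * scale).astype(np.int64)
    uniq, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                      return_counts=True)
    if uniq.shape[0] < 4:
        raise ValueError("degenerate trajectory for Voronoi density compensation")
    mult = counts[inverse].reshape(coords.shape[:2])

    # fast path: a complete uniformly spaced rotation set is invariant under
    # its own angular step, so the cell area depends only on the sample index
    # along the arm; compute areas for one representative arm only
    ang = np.unique(np.round(np.asarray(trajectory.angles_deg) % 360.0, 6))
    uniform = (ang.size >= 8
               and np.allclose(np.diff(ang), 360.0 / ang.size, atol=1e-6)
               and np.isclose(ang[0], 0.0, atol=1e-6))
    if uniform:
        vor = Voronoi(uniq / scale)
        rep = np.flatnonzero(np.isclose(
            np.asarray(trajectory.angles_deg) % 360.0, ang[0], atol=1e-6))[0]
        ns = coords.shape[1]
        rep_uniq = inverse[rep * ns:(rep + 1) * ns]
        area_by_sample = _cell_areas(vor, rep_uniq, uniq / scale,
                                     trajectory.k_max)
        return area_by_sample[None, :] / mult
    areas = _voronoi_weights(uniq / scale, trajectory.k_max)
    w = areas[inverse] / counts[inverse]
    return w.reshape(coords.shape[:2])


def default_trajectory(protocol: SpiralProtocol, n_arms: int,
                       dcf_method: str = "voronoi") -> Trajectory:
    """Convenience builder: base arm + pseudo golden-angle schedule + DCF."""
    angles = pseudo_golden_angle_sequence(n_arms, protocol.golden_period)
    traj = build_trajectory(design_spiral_arm(protocol), angles,
                            k_max=protocol.k_max)
    traj.dcf = density_compensation(traj, dcf_method)
    return traj
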