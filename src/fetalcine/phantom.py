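"""Dynamic fetal-heart phantom and spiral acquisition simulator.

The phantom is a 2-D analytic scene emulating a fetal four-chamber view inside
the maternal abdomen at SSFP-like contrast: bright ventricular blood pools
(relative intensity 3) inside a darker myocardial disc (1.2) embedded in a
fetal thorax and maternal background (~0.8-0.95), plus a descending-aorta dot.
Dynamics layered on top of the static scene:

* a variable fetal heartbeat (truncated-normal RR series, mean 433 ms by
  default) driving a smooth ventricular contraction with end-diastole at
  cardiac phase 0 and end-systole near phase 0.35 (systolic blood-pool radius
  = 0.65 x diastolic);
* quasiperiodic translation of the whole fetal block (maternal respiration,
  sinusoid of a few mm) plus sporadic gross-motion steps;
* through-plane corruption windows during which the heart content is replaced
  by a displaced, attenuated variant (anatomy leaving the slice);
* complex Gaussian noise added to the k-space samples.

Every spiral arm is rendered at its own timestamp, so view-sharing, gating and
motion artifacts arise in the simulated raw data exactly as they would during
a real acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .containers import RawSpiralDataset, Roi
from .encoding import NonuniformFourier
from .trajectory import SpiralProtocol, default_trajectory

__all__ = [
    "SceneGeometry",
    "PhantomConfig",
    "GroundTruth",
    "generate_rr_series",
    "generate_motion_traces",
    "TranslationTrace",
    "render_scene",
    "simulate_acquisition",
]

RR_FLOOR_MS = 200.0


@dataclass(frozen=True)
class SceneGeometry:
    """Analytic scene layout in mm (origin at the image center).

    Intensity ratios blood:myocardium:background = 3:1.2:0.8 approximate
    bright-blood SSFP contrast without any signal-equation simulation.
    """

    maternal_center: tuple = (0.0, 0.0)
    maternal_semiaxes: tuple = (110.0, 90.0)
    maternal_intensity: float = 0.8
    thorax_center: tuple = (15.0, -10.0)
    thorax_radius: float = 40.0
    thorax_intensity: float = 0.95
    heart_center: tuple = (8.0, -8.0)
    heart_radius: float = 18.5
    myo_intensity: float = 1.2
    lv_offset: tuple = (-8.5, -1.0)
    lv_radius: float = 6.0
    rv_offset: tuple = (7.5, 2.5)
    rv_radius: float = 5.0
    blood_intensity: float = 3.0
    dao_offset: tuple = (10.0, -22.0)
    dao_radius: float = 3.0
    edge_mm: float = 1.0              # soft-edge width (anti-aliasing)
    systolic_radius_frac: float = 0.65
    systole_phase: float = 0.35


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the simulated acquisition."""

    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    n_arms: int = 2500
    rr_mean_ms: float = 433.0
    rr_sd_ms: float = 10.0
    resp_amp_mm: float = 2.5
    resp_period_s: float = 4.0
    resp_axis_deg: float = 30.0
    gross_events: tuple = ()          # ((time_ms, (dx_mm, dy_mm)), ...)
    throughplane_windows: tuple = ()  # ((t_start_ms, t_end_ms), ...)
    noise_sd: float = 0.03            # complex-noise sd per k-space sample
    noise_mode: str = "relative"      # "relative": sd x RMS noiseless |sample|
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.rr_mean_ms <= 0 or self.rr_sd_ms < 0:
            raise ValueError("rr_mean_ms must be > 0 and rr_sd_ms >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError("noise_mode must be 'relative' or 'absolute'")


@dataclass
class GroundTruth:
    """Simulator sidecar: everything downstream stages try to recover."""

    rr_series_ms: np.ndarray
    trigger_times_ms: np.ndarray
    translation_trace: np.ndarray      # (n_arms, 2) mm at arm timestamps
    corrupted_arm_mask: np.ndarray     # bool per arm
    cine: np.ndarray                   # (n_phases, N, N) noiseless, untranslated
    n_phases: int
    anatomy_mask: np.ndarray           # fetal thorax mask at zero translation
    heart_roi: Roi                     # heart bounding box + 25 % margin
    config: PhantomConfig | None = None


def generate_rr_series(n_beats: int, mean_ms: float, sd_ms: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Truncated-normal beat-to-beat intervals (ms).

    Truncation at mean +/- 3 sd and at a 200 ms physiological floor.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if mean_ms < RR_FLOOR_MS:
        raise ValueError(f"mean_ms must be >= {RR_FLOOR_MS} ms")
    if sd_ms < 0:
        raise ValueError("sd_ms must be >= 0")
    if sd_ms == 0:
        return np.full(n_beats, float(mean_ms))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo = max(RR_FLOOR_MS, mean_ms - 3.0 * sd_ms)
    hi = mean_ms + 3.0 * sd_ms
    a, b = (lo - mean_ms) / sd_ms, (hi - mean_ms) / sd_ms
    return truncnorm.rvs(a, b, loc=mean_ms, scale=sd_ms, size=n_beats,
                         random_state=rng)


@dataclass(frozen=True)
class TranslationTrace:
    """Deterministic fetal-block translation: respiration + gross steps."""

    resp_amp_mm: float
    resp_period_ms: float
    axis: tuple
    events: tuple                      # ((time_ms, (dx, dy)), ...)

    def __call__(self, t_ms) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.zeros((t.size, 2))
        if self.resp_amp_mm != 0:
            s = self.resp_amp_mm * np.sin(2.0 * np.pi * t / self.resp_period_ms)
            out[:, 0] += s * self.axis[0]
            out[:, 1] += s * self.axis[1]
        for t_e, (dx, dy) in self.events:
            on = t >= t_e
            out[on, 0] += dx
            out[on, 1] += dy
        return out if np.ndim(t_ms) else out[0]


def generate_motion_traces(config: PhantomConfig, duration_ms: float,
                           seed: int = 0) -> tuple[TranslationTrace, np.ndarray]:
    """Translation trace plus the through-plane corruption schedule.

    Returns the trace callable and the corruption windows as an (n, 2) array
    of [t_start, t_end) in ms.  The trace itself is deterministic given the
    config; ``seed`` is reserved for randomized event layouts.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    th = np.deg2rad(config.resp_axis_deg)
    trace = TranslationTrace(resp_amp_mm=config.resp_amp_mm,
                             resp_period_ms=config.resp_period_s * 1000.0,
                             axis=(float(np.cos(th)), float(np.sin(th))),
                             events=tuple(config.gross_events))
    windows = np.array(config.throughplane_windows, dtype=float).reshape(-1, 2)
    if windows.size and (windows.min() < 0 or windows.max() > duration_ms):
        raise ValueError("through-plane windows must lie within the scan")
    return trace, windows


def _contraction(phase: float, geom: SceneGeometry) -> float:
    """Blood-pool radius scale: 1 at end-diastole, systolic_radius_frac at
    end-systole (phase ~0.35); raised-cosine in both limbs."""
    p = float(phase) % 1.0
    ps = geom.systole_phase
    if p <= ps:
        w = 0.5 * (1.0 - np.cos(np.pi * p / ps))
    else:
        w = 0.5 * (1.0 + np.cos(np.pi * (p - ps) / (1.0 - ps)))
    return 1.0 - (1.0 - geom.systolic_radius_frac) * w


def _soft_disc(xx, yy, cx, cy, r, edge):
    d = np.hypot(xx - cx, yy - cy)
    return np.clip((r - d) / edge + 0.5, 0.0, 1.0)


def _soft_ellipse(xx, yy, cx, cy, ax, ay, edge):
    d = np.hypot((xx - cx) / ax, (yy - cy) / ay)
    return np.clip((1.0 - d) * min(ax, ay) / edge + 0.5, 0.0, 1.0)


def render_scene(config: PhantomConfig, grid_size: int, fov_mm: float,
                 cardiac_phase: float, translation_mm=(0.0, 0.0),
                 throughplane: bool = False,
                 fetal_extra_mm=(0.0, 0.0)) -> np.ndarray:
    """Render the analytic scene at one cardiac phase and position.

    ``translation_mm`` displaces the whole scene (maternal respiration moves
    mother and fetus together); ``fetal_extra_mm`` adds a displacement of the
    fetal block only (sporadic fetal movement).  Returns a real (N, N) image;
    axis order is (row = y, col = x) with x to the right and y downward,
    matching pixel-index conventions elsewhere.
    """
    if not (0.0 <= cardiac_phase < 1.0 + 1e-12):
        raise ValueError("cardiac_phase must be in [0, 1)")
    g = config.geometry
    n = grid_size
    px = fov_mm / n
    coords = (np.arange(n) - n // 2) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    # soft edges never narrower than ~1.2 px: a partial-volume-like blur that
    # keeps the scene quasi-bandlimited to the sampled k-space disc
    e = max(g.edge_mm, 1.2 * px)
    img = np.zeros((n, n))

    def paint(mask, intensity):
        img[:] = img * (1.0 - mask) + intensity * mask

    gx, gy = float(translation_mm[0]), float(translation_mm[1])
    paint(_soft_ellipse(xx, yy, g.maternal_center[0] + gx,
                        g.maternal_center[1] + gy,
                        g.maternal_semiaxes[0], g.maternal_semiaxes[1], e),
          g.maternal_intensity)

    dx = gx + float(fetal_extra_mm[0])
    dy = gy + float(fetal_extra_mm[1])
    paint(_soft_disc(xx, yy, g.thorax_center[0] + dx, g.thorax_center[1] + dy,
                     g.thorax_radius, e), g.thorax_intensity)

    hx, hy = g.heart_center[0] + dx, g.heart_center[1] + dy
    scale = _contraction(cardiac_phase, g)
    pool_att = 1.0
    if throughplane:
        # anatomy leaving the slice: the section largely misses the
        # ventricular cavities, so the pools nearly vanish, dim, and the
        # residual heart cross-section appears displaced
        hx += 6.0
        hy -= 4.0
        scale *= 0.35
        pool_att = 0.55
    paint(_soft_disc(xx, yy, hx, hy, g.heart_radius, e), g.myo_intensity)
    paint(_soft_disc(xx, yy, hx + g.lv_offset[0], hy + g.lv_offset[1],
                     g.lv_radius * scale, e), g.blood_intensity * pool_att)
    paint(_soft_disc(xx, yy, hx + g.rv_offset[0], hy + g.rv_offset[1],
                     g.rv_radius * scale, e), g.blood_intensity * pool_att)
    paint(_soft_disc(xx, yy, hx + g.dao_offset[0], hy + g.dao_offset[1],
                     g.dao_radius, e), g.blood_intensity)
    return img


def _triggers_covering(rr: np.ndarray, t0: float, duration: float) -> np.ndarray:
    t = t0 + np.concatenate([[0.0], np.cumsum(rr)])
    if t[-1] < duration:
        raise ValueError("RR series does not cover the scan duration")
    return t


def _phase_at(t: np.ndarray, triggers: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(triggers, t, side="right") - 1
    idx = np.clip(idx, 0, triggers.size - 2)
    rr = np.diff(triggers)
    return (t - triggers[idx]) / rr[idx]


def ground_truth_masks(config: PhantomConfig, grid_size: int,
                       fov_mm: float) -> tuple[np.ndarray, Roi]:
    """Fetal-anatomy mask and heart ROI (bounding box + 25 % margin) at zero
    translation."""
    g = config.geometry
    px = fov_mm / grid_size
    coords = (np.arange(grid_size) - grid_size // 2) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    anatomy = np.hypot(xx - g.thorax_center[0], yy - g.thorax_center[1]) \
        <= g.thorax_radius
    cx = g.heart_center[0]
    cy = g.heart_center[1]
    r = g.heart_radius
    c0 = int(np.floor((cx - r) / px)) + grid_size // 2
    c1 = int(np.ceil((cx + r) / px)) + grid_size // 2
    r0 = int(np.floor((cy - r) / px)) + grid_size // 2
    r1 = int(np.ceil((cy + r) / px)) + grid_size // 2
    roi = Roi(max(0, r0), min(grid_size, r1), max(0, c0), min(grid_size, c1))
    return anatomy, roi.expand(0.25, grid_size)


def simulate_acquisition(protocol: SpiralProtocol, config: PhantomConfig,
                         n_phases: int = 20, dcf_method: str = "voronoi",
                         kernel_width: int = 6) -> tuple[RawSpiralDataset, GroundTruth]:
    """Simulate a pseudo golden-angle spiral acquisition of the dynamic scene.

    Arm i starts at timestamp i * TR; its samples are the non-uniform Fourier
    transform of the scene rendered at that instant's cardiac phase and fetal
    position, plus complex Gaussian noise.  The returned ground truth carries
    the RR series, trigger times, translation trace at arm times, the
    corrupted-arm mask, and the noiseless 20-phase reference cine rendered at
    phase-bin centers with zero translation.
    """
    rng = np.random.default_rng(config.seed)
    n_arms = config.n_arms
    duration = n_arms * protocol.tr_ms
    if duration < config.rr_mean_ms:
        warnings.warn("scan shorter than one heartbeat", stacklevel=2)

    n_beats = int(np.ceil(duration / max(RR_FLOOR_MS, config.rr_mean_ms
                                         - 3 * config.rr_sd_ms))) + 2
    rr = generate_rr_series(n_beats, config.rr_mean_ms, config.rr_sd_ms, rng)
    triggers = _triggers_covering(rr, 0.0, duration)
    trace, windows = generate_motion_traces(config, duration)

    t_arm = np.arange(n_arms) * protocol.tr_ms
    phases = _phase_at(t_arm, triggers)
    translations = trace(t_arm)
    # respiration displaces the whole scene; sporadic fetal events only the
    # fetal block (their difference is the globally uncorrectable part)
    resp_only = TranslationTrace(resp_amp_mm=trace.resp_amp_mm,
                                 resp_period_ms=trace.resp_period_ms,
                                 axis=trace.axis, events=())
    global_tr = resp_only(t_arm)
    fetal_extra = translations - global_tr
    corrupted = np.zeros(n_arms, dtype=bool)
    for t0, t1 in windows:
        corrupted |= (t_arm >= t0) & (t_arm < t1)

    traj = default_trajectory(protocol, n_arms, dcf_method)
    n = protocol.grid_size
    op = NonuniformFourier(n, traj.coords * protocol.res_mm,
                           width=kernel_width)
    samples = np.empty((n_arms, protocol.n_samples_per_arm), dtype=complex)
    chunk = 64
    ns = protocol.n_samples_per_arm
    for lo in range(0, n_arms, chunk):
        hi = min(n_arms, lo + chunk)
        imgs = np.stack([
            render_scene(config, n, protocol.fov_mm, phases[i] % 1.0,
                         global_tr[i], bool(corrupted[i]),
                         fetal_extra_mm=fetal_extra[i])
            for i in range(lo, hi)]).astype(complex)
        ghat = op._spectrum(imgs).reshape(hi - lo, -1)
        for i in range(lo, hi):
            samples[i] = op._forward_from_spectrum(ghat[i - lo],
                                                   slice(i * ns, (i + 1) * ns))
    if config.noise_sd > 0:
        sd = config.noise_sd
        if config.noise_mode == "relative":
            # scale-free noise specification: grid size and scene intensity
            # change the absolute sample magnitudes, not the SNR regime
            sd = sd * float(np.sqrt(np.mean(np.abs(samples) ** 2)))
        noise = rng.standard_normal(samples.shape) \
            + 1j * rng.standard_normal(samples.shape)
        samples += sd * noise

    # noiseless phase-resolved reference, rendered at bin centers
    cine = np.stack([
        render_scene(config, n, protocol.fov_mm, (p + 0.5) / n_phases)
        for p in range(n_phases)])
    anatomy, heart_roi = ground_truth_masks(config, n, protocol.fov_mm)

    gt = GroundTruth(rr_series_ms=np.diff(triggers),
                     trigger_times_ms=triggers,
                     translation_trace=translations,
                     corrupted_arm_mask=corrupted,
                     cine=cine, n_phases=n_phases,
                     anatomy_mask=anatomy, heart_roi=heart_roi,
                     config=config)
    ds = RawSpiralDataset(protocol=protocol, trajectory=traj, samples=samples,
                          timestamps_ms=t_arm, ground_truth=gt)
    ds.validate()
    return ds, gt
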