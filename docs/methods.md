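# Methods

`fetalcine` implements a motion-corrected reconstruction chain for dynamic
fetal cardiac MRI from pseudo golden-angle spiral SSFP acquisitions, together
with a synthetic dynamic phantom that provides ground truth for every stage.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Acquisition model

k-space is tiled by rotated copies of a single Archimedean spiral-out
interleaf: radius r(τ) = k_max·τ, azimuth φ(τ) = 2π·n_turns·τ, τ ∈ [0, 1]
sampled at `n_samples_per_arm` (default 512) points, with
n_turns = k_max·FOV/n_interleaves so that the 63-interleaf set satisfies the
radial Nyquist criterion at the chosen resolution (k_max = 1/(2·Δx)).  Arm
rotations advance by the Fibonacci rational approximation of the golden
angle, 360°·55/144 = 137.5°; because gcd(55, 144) = 1 the schedule repeats
after exactly 144 arms and one period tiles the 144 multiples of 2.5°.
Slew/gradient feasibility, variable-density designs, and trajectory
measurement are out of scope.  Density compensation defaults to Voronoi cell
areas clipped at the Nyquist circle (with a |k| "radial" fallback); for a
complete uniformly-rotated period the cell area depends only on the sample
index along the arm, which the implementation exploits.

The non-uniform Fourier operator is Kaiser–Bessel gridding with 2×
oversampling.  The default kernel width is 8 grid points, which meets a
~1e-6 transform accuracy target (width 6 only reaches ~4e-5); the
pipeline-scale solvers and the simulator use width 6 internally, ample for
regularized reconstruction at a ~40% cost saving.  The adjoint is the exact
conjugate transpose of the forward composition, so the operator pair passes
the inner-product identity at machine precision regardless of kernel
accuracy.  Image convention: pixel (0, 0) at the array corner, phase center
at pixel (N/2, N/2), normalized coordinates in cycles/pixel within
[−0.5, 0.5].  Translation is applied in k-space by the Fourier shift
theorem: multiplying samples by exp(+2πi(kx·dx + ky·dy)) moves image content
by (−dx, −dy), so applying the ramp with a *measured* displacement undoes it.

## Phantom

The scene is analytic: a maternal ellipse, a fetal thorax disc, a myocardial
disc containing two ventricular blood pools, and a descending-aorta dot, at
SSFP-like intensity ratios blood:myocardium:background = 3:1.2:0.8.  Soft
edges never narrower than ~1.2 px keep the scene quasi-bandlimited to the
sampled k-space disc (a partial-volume-like blur).  Ventricular pools
contract with a raised-cosine radius modulation (end-diastole at phase 0,
end-systole at phase 0.35, systolic radius = 0.65× diastolic).  Beat-to-beat
intervals are truncated-normal (mean 433 ms, sd 10 ms by default, truncated
at ±3 sd and a 200 ms floor).  Maternal respiration (2.5 mm, 4 s sinusoid)
translates the *whole* scene — mother and fetus move together, so a global
translational correction of it is exactly consistent — while sporadic gross
events translate only the fetal block.  Through-plane corruption windows
replace the heart with a displaced section in which the cavities nearly
vanish (radius ×0.35, intensity ×0.55): a 4 mm slice displaced off a ~35 mm
heart misses the ventricular cavities.  Complex Gaussian noise is added per
k-space sample; the default level is specified *relative* to the RMS
noiseless sample magnitude (making it independent of grid size and scene
units) and is 0.03, calibrated once so that the default pipeline's cine SNR
lands near the mid-40s reported for 1.5 mm fetal cine reconstructions at
0.55 T.  Anchoring instead on real-time SNR would require roughly double the
noise: on this deliberately simple scene the real-time reconstruction is far
less artifact-limited than in vivo (see Limitations), so both anchors cannot
hold at once, and the cine — the pipeline's deliverable — was preferred.

Every arm is rendered at its own timestamp and transformed with the same
gridding operator used for reconstruction.  This is an "inverse crime" in
the strict sense (no model mismatch between simulation and reconstruction
beyond noise and motion), acceptable here because the quantities under test
are motion/gating estimators and relative image errors, not absolute
accuracy of the forward model.

## Reconstruction

Both real-time and cine reconstructions minimize

    (1/L)·½ Σ_b ‖W_b^{1/2}(F_b x_b − y_b)‖² + λ ‖D_t x‖₁

by monotone FISTA with a fixed unit step, where F_b samples bin b on its
arms, W_b are Voronoi density-compensation weights, L is the largest
eigenvalue of the weighted normal operator (30 power iterations, 5% margin),
and D_t is the temporal finite difference — cyclic across cardiac phases for
cines (phase 19 borders phase 0).  Normalizing the fidelity by L makes the
weighted normal operator approximately the identity, so the DC-weighted
adjoint is a correctly scaled initialization and the proximal threshold per
step is λ itself.  λ is interpreted relative to the zero-filled
reconstruction's peak magnitude (data are scaled so max|x₀| = 1): the
real-time default is 0.08 with 20 iterations on 15-arm frames sharing 10
arms (stride 5, ≈ 28.5 ms interpolated frame spacing), the cine default is
0.02 with 50 iterations over 20 phases.  The DCF-weighted fidelity is what
lets these small fixed iteration budgets converge on spiral data; the λ = 0
solution agrees with conjugate-gradient least squares on the same weighted
normal equations to < 1e-3.

The temporal-TV proximal map is an exact, direct (non-iterative) 1-D
total-variation denoiser applied per pixel to real and imaginary parts
independently; it matches brute-force minimization to machine precision.
The cyclic prox needed for cines has no direct algorithm; it is approximated
by periodically padding each 20-point time course by half a period on both
sides, denoising, and cropping — rotation equivariance then holds to solver
tolerance.  Objective values are recorded per iteration; the monotone
variant keeps the best iterate, and forward evaluations are cached and
combined by linearity so each iteration costs exactly one forward and one
adjoint transform.

## Motion handling

Data rejection and registration operate on the real-time series inside a
rectangular heart ROI (on the phantom: bounding box of the heart + 25%
margin; with real data the ROI is supplied manually, as in clinical
practice).  Two different temporal smoothings are used deliberately:
*rejection* scores frames smoothed over 5 frames, which suppresses noise
while keeping corruption temporally localized (a one-cycle window smears the
MI dip beyond the corrupted period); *registration* uses a ~one-cardiac-
cycle window (15 frames) to suppress pulsation that would otherwise bias the
gross-motion estimate.  Mutual information uses min–max normalized joint
histograms; the pipeline adapts the bin count to the ROI size
(√(n_px/3), clipped to [8, 32]) because a 32×32 joint histogram over a
~800-pixel ROI is dominated by sparsity bias.  A frame's MI summary is the
0.9 quantile of its MI against 50 reference frames spread over the scan — a
clean frame at an extreme in-plane position still matches the references
acquired near that position, whereas a through-plane-corrupted frame
matches none, so the upper quantile separates the two where a median is
confounded by in-plane motion.  A frame is rejected when its summary falls
below 0.8× the median summary over frames; rejected runs separated by ≤ 2
kept frames are merged.  An arm is rejected only when every frame
containing it is rejected.  Retained frames are
registered to the highest-MI frame by plain cross-correlation peaks with
10× subpixel refinement (no ROI windowing — identical windows on both
images bias phase correlation toward zero shift).  Frame shifts are
linearly interpolated to arm timestamps (held at the ends) and undone by
k-space phase ramps at arm granularity.

## Metric-optimized gating

The heart-rate model is piecewise-constant RR over ~2 s segments plus the
first-trigger offset.  Candidate triggers assign each retained,
motion-corrected frame a phase (20 phases); frames per phase are averaged
and the Shannon entropy of the L1-normalized magnitude pooled over ROI
pixels and phases is minimized.  On the phantom this landscape is shallow
(relative variations ~1e-5) and contains aliases where a candidate RR locks
to the 28.5 ms frame grid (for a true 432 ms rhythm a false minimum appears
near 313 ms).  The search is therefore coarse-to-fine with a spectral
initializer: the summed Lomb–Scargle periodogram of the 100 highest-variance
ROI pixels peaks unambiguously at the cardiac frequency (it has no
binning aliases), and the subsequent entropy grid search runs within ±8% of
that prior (full 300–600 ms bounds when the prior is uninformative).
Golden-section refinement then optimizes the trigger offset and each
segment's RR over ±12 ms — a physiological prior on how far a 2 s segment
mean strays from the global rate — accepting updates only when entropy
improves beyond a 5e-6 relative floor, which prevents chasing landscape
noise.  On the default phantom this recovers the mean RR to a few tenths of
a percent; per-segment estimates shrink toward the global mean when the
entropy evidence is weak, which bounds their error near the constant-model
level (~4–6 ms at 10 ms beat-to-beat variability).

## Quality metrics and evaluation

SNR = mean(blood ROI)/sd(noise ROI at the FOV corner), no Rayleigh
correction; contrast = blood/myocardium mean ratio; CNR = (blood −
myocardium)/sd(noise).  The no-reference perceptual score follows the
block-based MSCN construction: 16×16 blocks, spatial activity at MSCN
variance ≥ 0.1, a noise criterion (uniformly high quadrant variance,
graded by its level) and a noticeable-artifact criterion (a near-uniform
6-pixel edge segment, graded and down-weighted ×0.3 relative to noise —
on analytic scenes blur is partly intrinsic rather than a degradation),
pooled as 100·(Σ distortion + 1)/(n_active + 1) into [0, 100], lower =
better.  NRMSD = 100·‖test − reference‖₂/‖reference‖₂ over an anatomy mask
on magnitude images.

Comparing a reconstructed cine against the noiseless ground-truth cine
requires alignment: the motion-correction reference frame sits at an
arbitrary fetal position (global subpixel translation), the recovered
triggers have an arbitrary offset within the beat (cyclic phase rotation,
chosen as the best of the 20 integer rolls), and the solver scale is matched
by least squares.  The acceleration sweep and consistency experiment need no
alignment because all windows share the reference's motion correction and
gating.  End-diastole is detected as the phase maximizing the mean over an
annulus just inside the diastolic pool boundary (blood at end-diastole,
myocardium at end-systole).

## Problem sizes

The default study conditions are 2500 arms (≈ 14.3 s of scan) at 1.5 mm on a
160×160 grid.  The multi-resolution comparison runs 2500 arms at 1.7 mm and
1250 arms at 1.0 mm (240×240 grid), and the acceleration sweep uses four
retrospective windows (250–2500 arms) against the all-data reference; these
sizes keep a complete evaluation within tens of minutes on one CPU while
preserving every qualitative regime of the full protocol.

## Known limitations

* The analytic scene is far more compressible than real anatomy: a 15-arm
  real-time frame of it reconstructs with little aliasing, so real-time SNR
  is *better*, relative to the cine, than reported in vivo.  The cine/real-
  time SNR ratio on the phantom is ≈ 1.4 at 1.5 mm and ≈ 1.8 at 1.7 mm
  rather than the in-vivo ≈ 3; the direction of all comparisons (SNR, CNR,
  perceptual score, contrast equality) is reproduced, but the ratio's
  magnitude is not, and the corresponding acceptance assertion fails
  honestly.  Reproducing the in-vivo ratio would require background texture
  that the phantom's scope excludes.
* The noise level is specified relative to the noiseless sample RMS, so the
  in-vivo fall of SNR with finer resolution is not emulated; SNR values are
  comparable within a resolution, not across resolutions.
* At 1.0 mm the scaled-down 1250-arm evaluation leaves each cardiac phase
  below full sampling; the gating estimate and cine quality there reflect
  that shortened scan, not the method's ceiling.
* Gross fetal motion is corrected globally, so the static maternal
  background is counter-shifted during gross-motion epochs; with the single
  default step this residual inconsistency is small.
* The entropy landscape's shallowness on this phantom means beat-level
  heart-rate variability is only partially recoverable; the spectral prior
  and refinement guards make the estimator conservative rather than noisy.
* Simulation and reconstruction share the gridding operator (inverse crime);
  absolute image fidelity claims should not be read off the phantom results.
* Single-coil by default; smooth synthetic sensitivity maps exercise the
  multi-coil code path but no parallel-imaging claims are made.
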