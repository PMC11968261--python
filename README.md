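# fetalcine

Motion-corrected real-time and cine reconstruction for **fetal cardiac MRI**
from pseudo golden-angle **spiral SSFP** acquisitions, as used on low-field
(0.55 T) systems — together with a dynamic numerical fetal phantom that makes
every stage of the chain testable against ground truth.

Fetal cardiac imaging has no ECG: the heart must be imaged through maternal
breathing, sporadic fetal movement, and a fast (~140 bpm) variable heartbeat,
and then retrospectively gated from the data themselves.  `fetalcine`
implements the complete pipeline:

1. **Real-time reconstruction** — sliding-window compressed sensing over
   15-arm frames (10 arms shared, ≈29 ms frame spacing), minimizing
   `½‖W^{1/2}(Fx − y)‖² + λ‖D_t x‖₁` with λ = 0.08, 20 monotone-FISTA
   iterations, where `F` is a Kaiser–Bessel gridding NUFFT, `W` Voronoi
   density-compensation weights, and `D_t` the temporal finite difference
   (the prox is an exact direct 1-D total-variation denoiser).
2. **Data rejection + MOCO** — through-plane-corrupted periods are found by
   the mutual information of each real-time frame against a reference set
   and rejected; retained frames are registered by subpixel phase
   correlation in a heart ROI and the in-plane shifts are undone as k-space
   phase ramps per arm.
3. **Metric-optimized gating (MOG)** — the variable fetal RR series
   (piecewise-constant over ~2 s segments) is recovered by minimizing the
   Shannon entropy of the re-binned 20-phase cine, initialized by a spectral
   (Lomb–Scargle) heart-rate estimate.
4. **Cine reconstruction** — the gated, motion-corrected arms are
   reconstructed into a 20-phase cine (λ = 0.02, 50 iterations, cyclic
   temporal difference).
5. **Evaluation** — SNR, blood/myocardium contrast, CNR, a block-based
   no-reference perceptual score (lower = better), and NRMSD against a
   reference, plus retrospective acceleration and two-window consistency
   experiments.

The synthetic phantom provides bright-blood SSFP-like contrast, a beating
heart (RR ≈ 433 ± 10 ms), maternal respiration, gross fetal motion, scheduled
through-plane corruption and calibrated complex noise; the simulator renders
every spiral arm at its own timestamp, so view-sharing, gating and motion
artifacts arise exactly as during a real acquisition.  Raw data travel in a
simple HDF5 container (`/protocol`, `/trajectory`, `/data`, optional
`/ground_truth`, `/motion`, `/gating`), and external spiral raw data mapped
into this container can be processed identically.

## Worked example

Run the full pipeline on the default phantom (1.5 mm, 2500 arms ≈ 14.3 s of
scan) and print the stage summaries:

```bash
fetalcine run --seed 11 --out runs/demo
```

```
rejected: 10%  shift ranges [x, y] = [5.7, 3.2] mm
RR = 434 ± 0 ms
cine NRMSD vs truth: 8.4%
```

Reading the numbers: 10% of the spiral arms fell in the through-plane
corruption window (or in frames contaminated by it) and were rejected; the
tracked in-plane fetal translation spans 5.7 mm in x and 3.2 mm in y
(respiration plus one gross movement); metric-optimized gating recovered a
mean RR of 434 ms against a generating mean of 432 ms (the ± value is the
spread of the piecewise heart-rate model, which stays at the global rate
when the entropy evidence for beat-level variability is weak); and the
final 20-phase cine differs from the noiseless ground-truth cine by 8.4%
NRMSD over the fetal anatomy after alignment.  `runs/demo/` holds the HDF5 container (with motion and
gating records), NIfTI exports of the real-time series and cine, a JSON
quality report and a manifest with content hashes.

The same stages are available as library calls (`simulate_acquisition`,
`cs_reconstruct`, `run_moco`, `mog_optimize`, `reconstruct_cine`) and as
individual CLI commands (`simulate`, `recon-rt`, `moco`, `mog`,
`recon-cine`, `evaluate`, `accel-sweep`, `consistency`).

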