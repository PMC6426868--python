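# infantdot

Simulation and analysis pipeline for infant high-density diffuse optical
tomography (HD-DOT) block-design speech experiments.

HD-DOT measures near-infrared light attenuation between many overlapping
source-detector pairs on the scalp and reconstructs 3D images of cortical
hemoglobin changes. In infant emotional-speech studies the experimental
structure is: 11 s blocks of four short spoken phrases (neutral / happy /
angry / sad prosody) separated by 20–30 s rests, a ~15-source / 15-detector
probe over the left temporal cortex sampling every ~1.2 s, and total
hemoglobin (ΔHbT, µM) as the contrast of interest. Raw infant recordings
from such studies are not publicly shareable, so this package pairs the
full analysis chain with a physics-based synthetic-data generator, allowing
every stage to be validated by parameter recovery against known ground
truth.

The pipeline:

1. **Phantom & sensitivity** (`infantdot.phantom`) — layered slab head model
   (scalp / skull / CSF / gray / white matter; brain starting ≈5 mm under
   the scalp), checkerboard probe, and a channel × voxel sensitivity matrix
   `J` from diffusion-approximation Green's functions for a semi-infinite
   medium (Rytov convention: −Δlog A = J Δµₐ). The field of view is the set
   of brain voxels with relative sensitivity > 0.001.
2. **Hemodynamics** (`infantdot.hemodynamics`) — boxcar phrase trains with
   within-block habituation (amplitudes 1, 0.6, 0.3, 0.2) convolved with the
   adult canonical double-gamma HRF; HbO₂ is the kernel shifted −1 s, HbR is
   the kernel × (−1/6), HbT = HbO₂ + HbR.
3. **Synthetic recordings** (`infantdot.datagen`) — forward-projected
   activations plus superficial physiology (coupling growing as separation
   shrinks), drift, an aliased cardiac line, photon noise, and annotated
   movement artifacts; TSV and SNIRF-style HDF5 dialects.
4. **Preprocessing** (`infantdot.preprocess`) — resampling to a common 1 Hz
   base, zero-phase bandpass with −3 dB points at 0.007 and 0.2 Hz,
   superficial signal regression against the mean of the < 12 mm channels,
   amplitude-threshold artifact rejection (k ∈ [3.5, 7] × a robust SD, with
   an automatic L-curve knee), and exclusion of triggers whose epochs touch
   flagged samples; a recording passes inclusion only with ≥ 5 clean
   repetitions per condition.
5. **Response estimation** (`infantdot.responses`) — FIR least-squares
   deconvolution of per-condition responses on lags −5…30 s, baseline
   correction over [−1, 0] s, and the mean over [2, 18] s post-onset as the
   response magnitude.
6. **Image reconstruction** (`infantdot.reconstruct`) — Δµₐ from
   `min ‖Jx − y‖² + λ‖Lx‖²` with a 6-neighbor Laplacian `L` (solved exactly
   via a sparse factorization plus a low-rank Woodbury correction), the
   Beer-Lambert conversion ΔHbT = Δµₐ/ε, and mask-normalized Gaussian
   smoothing (σ = 1.5 voxels) applied before clustering only.
7. **Group statistics** (`infantdot.stats`) — global FOV analysis (t vs 0,
   Bartlett, one-way ANOVA, Tukey-Kramer post hoc), adaptive voxel-based
   clustering (seeds at voxelwise p < 0.001 grown through p < 0.0033 and
   p < 0.01 superlevel sets, merged when they join, cluster-mean re-tested
   per level, ≥ 200 voxels required, Bonferroni-corrected with N = 120), and
   six left-hemisphere ROI tables (aSTS, STG, IFG, AI, MI, pSTS).

## Worked example

```python
from infantdot.config import PipelineConfig
from infantdot import pipeline

cfg = PipelineConfig(seed=7)
ctx = pipeline.build_study(cfg)                      # phantom, probe, J, FOV
calib = pipeline.calibrate_planted_amplitude(ctx, seed=cfg.seed)
print(f"planted HbT peak: {calib['planted_peak_hbt_um']:.2f} uM "
      f"(map noise SD {calib['map_noise_sd_um']:.2f} uM)")

rec = pipeline.simulate_subject(ctx, 1234, peak_hbt_um=calib["planted_peak_hbt_um"])
maps, log = pipeline.analyze_subject(rec, ctx)       # preprocess -> deconvolve -> reconstruct
print(f"inclusion: {log['inclusion'].passed}, clean reps "
      f"{log['inclusion'].reps_per_condition}, artifact k = {log['artifact_k']}")
vox = calib["center_voxel"]
print(f"HbT magnitude at the planted site: happy {maps['happy'][vox]:+.2f} uM, "
      f"neutral {maps['neutral'][vox]:+.2f} uM")
```

prints

```
planted HbT peak: 2.39 uM (map noise SD 0.31 uM)
inclusion: True, clean reps {'neutral': 7, 'happy': 6, 'angry': 7, 'sad': 6}, artifact k = 4.5
HbT magnitude at the planted site: happy +0.78 uM, neutral -0.54 uM
```

The calibration plants a happy-condition activation in anterior/posterior
temporal gray matter whose reconstructed effect is three times the
between-subject noise SD at that site (here a physiological ≈2.4 µM HbT
peak). For one noisy subject the recovered happy magnitude at the site
(+0.78 µM) already stands out against neutral; across a 21-subject cohort
the group ANOVA cluster and the Tukey-Kramer happy > neutral contrast are
recovered with corrected p ≪ 0.05 (see the reproduction script below).

A full cohort from the shell:

```bash
infantdot fixtures --config cfg.yaml --n 21 --seed 7 --out data/
infantdot run --config cfg.yaml --data data/ --out results/
```

which writes per-subject recordings with a hashed manifest, then the
global / cluster / ROI TSV tables, cluster masks as NIfTI, and a JSON run
report.

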