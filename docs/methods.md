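# Methods

This note documents the models, numerical choices and known limitations of
the `infantdot` pipeline in enough detail to audit or re-derive every
default. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Optical phantom and forward model

The head is a slab of tissue layers along the depth axis z: scalp (2 mm),
skull (2 mm), CSF (1 mm), gray matter (10 mm), white matter filling the
rest. Layer boundaries are rounded to the voxel grid, so at the default
desk scale (40³ voxels, 2 mm) gray matter starts 4 mm under the surface,
matching the ≈5 mm superficial-tissue thickness of a two-month-old head to
within half a voxel; at 1 mm voxels the boundary is exactly 5 mm. Per-tissue
absorption µₐ and reduced scattering µₛ′ (1/mm, ~798 nm) are configuration
placeholders, not measured values, and live in the phantom config.

Photon transport uses the diffusion approximation for a homogeneous
semi-infinite medium with an extrapolated boundary (effective reflection
from the Groenhuis polynomial at relative index 1.4; isotropic point source
at depth 1/(µₐ+µₛ′); negative image source). The channel sensitivity is the
Rytov kernel

    J(v) = φ_src(v) · φ_det(v) · V_vox / φ_src(det),

the first-order sensitivity of −Δlog(amplitude) to a local absorption
increase, in mm. The homogeneous background defaults to the volume-weighted
mean of the tissue properties. A small vectorized photon random-walk Monte
Carlo in the test suite independently confirms the depth profile of the
sensitivity on a coarse 8 mm grid. Distances are clipped below 0.5 mm to
regularize the source singularity. The probe is an interleaved checkerboard,
default 5×6 at 10 mm pitch (15 sources, 15 detectors, 198 channels at
separations 10–41 mm, 49 of them below the 12 mm short-channel limit so the
superficial regressor always exists); channels are restricted to ≤ 45 mm.

## Stimuli and hemodynamics

Block schedules are balanced and shuffled, with rests drawn uniformly from
[20, 30] s and an 11 s block of four phrases (2.2 s each, 0.7 s gaps —
phrase timing is a convention, the source protocol does not state it).
Habituation scales the four phrase boxcars by (1, 0.6, 0.3, 0.2); a
no-habituation variant and a single-boxcar block mode are provided. The
canonical double-gamma HRF uses the standard defaults (response delay 6 s,
undershoot delay 16 s, unit dispersions, response:undershoot ratio 6),
normalized to unit peak so that stimulus amplitudes carry physical units.
HbO₂ uses the kernel shifted −1 s, HbR the unshifted kernel scaled by −1/6,
HbT their pointwise sum; with the shift disabled the HbO₂:(−HbR) extrema
ratio is exactly 6.

## Synthetic recordings

Log-amplitude per channel is assembled as

    log A = −J Δµₐ(t) + c(SDS)·g(t) + drift + cardiac + shot noise
            [+ movement transients],

with Δµₐ(t) from GM-masked Gaussian activation blobs (peak in µM HbT at the
response peak, Beer-Lambert ε = 0.1 mm⁻¹mM⁻¹ by default) modulated by the
simulated HbT course. The superficial/global signal g is band-limited
(0.01–0.1 Hz) unit-SD noise coupled as exp(−SDS/20 mm), so short channels
carry ≈3× the global signal of 30+ mm channels; a 1.2 Hz cardiac sinusoid
aliases naturally on the ~1.2 s frame grid. Shot noise is white in the log
domain with SD growing linearly in separation (0.002 at 30 mm by default) —
per-channel baseline intensity is 1 because the emulated instrument
gain-adjusts every detector, so absolute intensity is uninformative and
photon noise appears as separation-dependent relative noise. Drift is an
integrated random walk (SD 0.005 over the recording). Movement artifacts
are Poisson events (0.3/min) of 1–3 s, amplitude 8× each channel's clean SD
with random per-channel sign, always emitted with ground-truth annotations.
Frames carry ±0.04 s timing jitter so resampling does real work.

What the generator does **not** emulate: head-geometry variability across
subjects (one shared phantom and probe), wavelength pairs and HbO₂/HbR
unmixing (single ~798 nm HbT channel, as in the target instrument),
nonstationary sleep/wake physiology, spatially structured scalp blood flow,
and optode-coupling changes that are not transient. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to every artifact class of real infant data.

## Preprocessing

Artifact detection runs on the native frames *before* interpolation
(resampling redistributes sample variance and would make thresholds
nonuniform), and on the *stimulus-regressed residual*: each channel's
trigger-locked epoch average is subtracted first, so a strong evoked
response cannot trip the amplitude threshold and reject its own epochs,
while movement transients — asynchronous to the stimuli and diluted by the
across-repetition averaging — survive essentially intact (the analyzed
data are not modified; the residual is used for detection only). The
high-pass is removal of a centered 25 s moving average —
unlike a recursive filter it has no boundary transients that masquerade as
artifacts, while second-scale transients pass unattenuated — and the
threshold is k times a per-channel MAD-consistent robust SD, so the
artifacts being hunted do not inflate their own threshold. k may be fixed
in [3.5, 7] or chosen automatically as the knee (maximum distance below the
chord, Kneedle-style) of the flagged-count vs k curve. The flagged-sample
mask is projected onto the common time base, unioned with annotated
intervals, and a trigger is kept only if its [−1, 18] s epoch touches no
flagged sample; inclusion requires ≥ 5 clean repetitions of every
condition.

Resampling is linear interpolation onto a shared 1 Hz grid (exact on affine
signals; sinusoid error bounded by h²·max|f″|/8). The bandpass is two
zero-phase (forward-backward) second-order Butterworth stages; because
filtfilt squares the magnitude response, each design cutoff is placed by
bisection on the digital response so the measured −3 dB points land on
0.007 and 0.2 Hz (the analog-prototype correction is inaccurate near
Nyquist). Mid-band gain is within 0.5% of unity. Superficial signal
regression subtracts each channel's least-squares projection onto
(intercept, mean of < 12 mm channels); residuals are exactly uncorrelated
with the regressor, and re-running SSR is a no-op.

## Response estimation

Deconvolution is FIR ordinary least squares: one lagged onset indicator per
condition and lag (−5…30 s at 1 Hz, one event per block — the four-phrase
train is treated as a single epoch) plus an intercept that absorbs the
signal mean (without it, centering biases every lag by a constant). Flagged
samples are dropped as rows rather than interpolated, so artifacts cannot
leak into the estimates; a rank check reports the offending conditions when
triggers coincide. With non-overlapping noise-free epochs the estimator
reproduces the trigger-locked epoch average exactly. Baseline correction
subtracts the [−1, 0] s mean; the magnitude is the arithmetic mean over
lags in [2, 18] inclusive.

## Image reconstruction

Δµₐ minimizes ‖Jx − y‖² + λ‖Lx‖² with L the 6-neighbor graph Laplacian
(reflecting/Neumann boundary: constants are annihilated). The solve is
exact and direct: K = λL᳠L is factorized once per study (sparse LU) after
pinning one voxel per connected component to remove the constant nullspace;
J᳠J (rank = number of channels) and the pin removal enter through the
Woodbury identity; one iterative-refinement step is applied and the
normal-equation relative residual is checked against `solver_rtol` (1e-4).
Repeated right-hand sides (conditions, lags, subjects sharing a probe) then
cost milliseconds.

The reconstruction domain is the brain voxels with relative sensitivity
above 1e-4 — an order of magnitude below the 0.001 field-of-view threshold,
so the whole FOV is strictly interior. Outside that domain the probe
carries no information and the regularized solution is indistinguishable
from zero; restricting the domain keeps the factorization tractable.
Setting the floor to 0 restores the full GM+WM domain.

λ is expressed relative to the mean diagonal of J᳠J so it transfers across
grid sizes and channel counts; the default λ = 10 was verified on noise-free
planted-blob fixtures: it recovers a 10 mm-deep blob's peak within one
voxel while suppressing the deep, high-amplitude artifacts that small λ
produces when small non-physical channel patterns (e.g. the superficial
component injected by SSR, or structured noise) are inverted into
low-sensitivity voxels. An explicit λ sweep test asserts that ‖Lx‖
decreases monotonically in λ.

"Gaussian filter of radius 1.5 voxels" is read as σ = 1.5 voxels (an FWHM
switch is provided). Smoothing is mask-normalized — the volume and the mask
are filtered separately and divided — so constants are preserved exactly
inside the brain and zeros do not bleed in from outside; it is applied only
before voxel-based clustering, never before global or ROI magnitude
extraction.

The group pipeline reconstructs the baseline-corrected window magnitude in
channel space (one solve per condition per subject) instead of per lag:
every stage between channel data and magnitude maps — filtering, SSR,
deconvolution, baseline, window mean, reconstruction, Beer-Lambert — is
linear, so the two orders give identical maps, at 1/36th the cost. Per-lag
image time courses remain available through `ResponseSet.map` with a
`Reconstructor`.

## Group statistics

Three group tests over subjects: two-tailed one-sample t of the
across-condition average against zero, one-way ANOVA across conditions
(subjects as replicates; a repeated-measures decomposition is a config
switch), and per-condition two-tailed t against (already subtracted)
baseline. Global analysis masks to GM∩FOV voxels whose *unsmoothed*
group-mean magnitude is positive for at least one condition, checks
equal-variance with Bartlett's test, and reports Tukey-Kramer ordered pairs
when the ANOVA rejects at 0.05.

Adaptive clustering: connected components (6-connectivity by default, 26
available) of voxelwise p < 0.001 seed candidate clusters; each seed grows
to its connected component of the p < 0.0033 and p < 0.01 superlevel sets;
because the superlevel sets are nested, seeds merge exactly when they share
a component at the loosest level. The cluster-mean magnitude is re-tested
with the same group test at each level, the smallest level p is the cluster
p with the level's extent as the cluster extent, clusters under 200 voxels
at the chosen level are discarded (genuine diffuse-optics activations
reconstruct into large volumes; small clusters are edge artifacts), and the
Bonferroni factor N = 120 approximates the number of separably imageable
~1 cm³ regions in the field of view. A 200-replicate null simulation
(21 subjects × 4 conditions of smoothed unit-variance noise maps) measures
the familywise error of the full chain; the acceptance suite requires it
≤ 0.075.

ROIs are 8 mm spheres (always containing their center voxel, so a
degenerate radius gives a single-voxel ROI) about six left-hemisphere
template coordinates (aSTS, STG, IFG, AI, MI, pSTS), mapped onto the
phantom by a config-declared affine (template RAS mm → grid mm; default
permutes axes so lateral depth becomes grid depth, placing all six centers
in GM at 6–12 mm). Each ROI row reports per-condition means, t vs baseline
with a Bonferroni factor equal to the number of ROIs, the ROI ANOVA p,
Tukey-Kramer flags, and the FOV coverage fraction.

## Effect-size calibration

The synthetic study's planted contrast (happy > neutral, Gaussian blobs of
σ = 6 mm at the aSTS and pSTS template sites) is calibrated at generation
time so that the *reconstructed map-level* effect is 3× the between-subject
noise SD at the anterior site:

1. noise SD: 12 noise-only pilot subjects are pushed through the full
   pipeline and the SD of the map value at the site is taken;
2. effective gain: pairs of pilot runs with identical noise seeds, with and
   without the planted activation, are differenced — the noise cancels and
   the response path, *including its interaction with SSR*, remains;
3. the planted peak is (3 × SD)/gain, with one fixed-point refinement since
   the SSR leakage grows mildly with amplitude.

Step 2 matters because on noise-free data the short-channel regressor *is*
the response (every channel is proportional to it), so SSR removes 100% of
a noise-free signal and a naive gain estimate would be meaningless; with
realistic physiology the regressor is dominated by the global signal and
the leakage is a second-order correction. With the default noise levels the
calibrated peak lands at a physiological ≈2.5–3.5 µM HbT.

## Problem sizes and determinism

Defaults: 40³ grid at 2 mm, 198 channels, 21 subjects with 7 blocks per
condition (~17 min recordings at 1.2 s frames), 200 null replicates for the
familywise-error calibration. One study context (phantom + sensitivity +
factorized inverse) builds in ~15 s and is shared; a subject simulates and
analyzes in under a second, and a full cohort with group statistics
completes in about a minute on one CPU. Every random draw flows from a
single integer seed through `numpy.random.default_rng`; identical
configurations and seeds produce byte-identical fixtures (hashed in the
dataset manifest) and identical statistical tables.

## Known limitations

- The slab geometry has no curvature or hemispheric asymmetry; template
  coordinates are meaningful only through the declared affine.
- The homogeneous-background diffusion kernel ignores the layered optical
  contrast it itself defines (standard first-order practice, but a known
  bias for CSF-adjacent sensitivity); the Monte Carlo cross-check is at
  coarse resolution and for the depth profile only.
- Inference treats subjects as exchangeable replicates on a shared grid; no
  spatial autocorrelation model beyond the fixed Bonferroni factor is
  attempted, so the clustering's error control is calibrated empirically,
  not analytically.
- The SSR stage can inject a small negative superficial copy of a focal
  response into all channels (visible as a shallow negative counterpart
  around strong activations); the default regularization suppresses its
  deep amplification but does not remove the phenomenon, which is inherent
  to short-channel regression when short channels see the brain.
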