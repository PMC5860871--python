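# Methods

## The model

Each constant-TOA block of an auditory run is modeled as an event
train (one impulse per trial) convolved with a two-gamma hemodynamic
response function (HRF) and scaled by a single per-block amplitude.
Ordinary least squares on a voxel's time course yields one amplitude
β per TOA condition. Across the four TOAs the amplitudes follow

    β(TOA) = a + b · exp(−TOA / τ)

with asymptotic level *a* (signal units), adaptation magnitude *b*
(signal units, unconstrained in sign), and decay time constant τ
(seconds). τ is the scientific quantity: how quickly the effect of a
trial on the response to the next trial fades. Group comparisons are
performed on per-subject τ estimates with rank statistics, because τ
estimates from four points are noisy and right-skewed.

Sign convention: the generator uses b > 0, i.e. block amplitude
declines as TOA grows. Flipping the sign of b (amplitude recovering
with TOA) leaves every stage of the analysis unchanged — the fit is
equivariant under β → −β and the group inference uses only τ.

## Forward model (synthetic cohorts)

Per subject, per run:

    signal(v, t) = Σ_blocks [a_v + b_v e^(−TOA/τ_v)] · (train ⋆ HRF)(t)
                   + drift(v, t) + noise(v, t)

* **Design defaults** (the study layout): TOAs {3, 6, 9, 15} s, 16
  trials/block, one block per TOA per run, 3 runs, TR = 1 s, 12³ grid
  of 3 mm voxels. Trials are unit impulses at onset (duration 0;
  boxcar durations supported). Blocks are separated by a 20 s rest
  gap — long enough that block responses do not overlap after HRF
  convolution — with a 10 s lead-in and 25 s tail. The scan protocol
  being emulated does not state inter-block gaps or in-scanner block
  order, so both are parameters (`gap_s`, `block_order`; order default
  "fixed", i.e. ascending TOA — run length is order-invariant).
* **Subject parameters**: τ is lognormal around the group center,
  τ_i = center · exp(N(0, between_subject_sd)), keeping τ positive
  with the right skew typical of time constants (default SD 0.2 on
  the log scale). a ~ N(0.5, 0.05), b ~ N(1.0, 0.1): order-one
  amplitudes with mild heterogeneity.
* **Noise**: additive white Gaussian noise per voxel and time point
  (optionally smoothed to a spatial FWHM and rescaled to the target
  SD), plus a one-cycle cosine drift with random phase and per-voxel
  amplitude uniform in [0, drift_amp] (default 0.3). The drift is a
  stand-in for exactly the slow structure the high-pass stage removes.
* **Noise level**: sigma defaults to 0.3, calibrated once so that the
  voxelwise scatter of fitted τ is "moderate" — SD ≈ 30% of the
  generating value under the default two-group cohort (measured 41%
  at τ = 10 s, 18% at τ = 5 s on a 6³ calibration grid).
* **Seeding**: one master seed expands through `SeedSequence.spawn`
  into per-subject parameter and per-run noise streams; equal seeds
  reproduce runs bit-for-bit, and subjects are mutually independent.

What the generator does **not** emulate: physiological (cardiac/
respiratory) noise, motion, scanner drift nonstationarity, spatial
heterogeneity of the HRF, anatomy, or any spatial structure in
(a, b, τ) beyond an optional active mask. Passing recovery tests on
these cohorts therefore demonstrates correctness of the estimation
chain under its own assumptions, not robustness to real-scanner
artifacts.

## Preprocessing

High-pass filtering is realized as regression, not FFT masking: the
basis {1, t, sin/cos at 1..3 cycles/run} is projected out of each
voxel (QR-based), which is deterministic, exactly idempotent, and
matches "up to three cycles per scan". One consequence worth knowing:
because the linear-trend column has broadband spectral content, a
pure 10-cycle sinusoid retains correlation ≈ 0.983 (not 1.0) with its
filtered version, independent of run length.

Z-scoring is per run, per voxel (whether normalization was per run or
per session in the original stream is unstated; per run is the
default). Constant voxels are zeroed and QC-flagged rather than
dividing by zero. Spatial smoothing uses σ = FWHM/(2√(2 ln 2)) per
axis with kernel renormalization at the volume border, so constants
pass unchanged and small synthetic grids are not darkened at edges.
Order: detrend → z-score → smooth; each stage has an off switch.

Because the data are filtered but the task regressors are built from
raw event trains, the pipeline projects the same low-frequency basis
out of the design columns before OLS. By the Frisch–Waugh theorem
this is equivalent to adding the basis as confound regressors and
keeps the per-TOA β unbiased; without it, long blocks (TOA 15 s spans
225 s) would lose task variance to the filter.

## GLM

The HRF is the difference of two gamma densities — peak shape 6,
undershoot shape 16, unit rates, undershoot ratio 1/6, 32 s support —
the conventional "standard two-gamma" (peak at 5.0 s); all parameters
are exposed since no specific values are mandated by the protocol
being emulated. The kernel is max-normalized to 1 so that β carries
signal units and is comparable across HRF parameter choices (scaling
the kernel by c scales β by 1/c; this trade-off is unit-tested).

For impulse events the regressor is computed as the exact analytic
superposition of HRF copies at each onset, evaluated at the volume
times — the same routine the simulator uses, so the noiseless
round trip (simulate → GLM) is exact to machine precision. Boxcar
events use oversampled convolution at the HRF's dt (0.1 s).

Task-responsive voxels: per subject, an omnibus F statistic of the
four TOA predictors against the confound-only model; subjects are
pooled fixed-effects style (numerator and denominator sums of squares
and degrees of freedom summed) and the pooled p-map is thresholded by
Benjamini–Hochberg FDR at q = 0.001. The omnibus statistic and the
pooling rule are the standard reading of "responded to the task when
all participants were considered"; both are open choices and are
confined to `select_task_responsive`.

## Decay fitting

For fixed τ the model is linear in (a, b), so the fit uses variable
projection: a 50-point log-spaced τ grid on (0.1 s, 60 s] locates the
SSE basin, then golden-section refinement on log τ (80 iterations)
within the bracketing grid cell polishes it. SSE is evaluated in
residual form rather than via the normal-equation identity; the
latter suffers catastrophic cancellation near perfect fits and would
flatten the 1-D landscape before the refinement converges. The scalar
`fit_decay` and the voxelwise `fit_decay_map` share this one
vectorized path, so they agree exactly.

Validity flags: all-equal βs → non-identifiable (a = mean, b = 0,
τ = NaN, invalid); τ within 10⁻⁶ (relative) of a bound → invalid
("tau_at_bound"); b < 0 → flagged ("negative_b") but kept, since the
model does not constrain the sign. Voxelwise maps keep invalid fits
(rank tests downweight extremes); the ROI group comparison excludes
invalid fits per subject and requires ≥ 2 valid subjects per group.
τ bounds are a package choice — no bounds are stated for the original
fits — and every boundary hit is visible in the reason volume.

Per-subject βs are averaged across the three runs per TOA before
fitting (one β per TOA per subject); fitting on concatenated runs is
available by constructing designs accordingly. Two τ-map paths exist
on purpose: per-subject fits feed the group inference, while fits to
group-mean βs produce the descriptive group maps.

## Group inference

Mann-Whitney U is computed from rank sums (U counts pairs where the
first sample exceeds the second; ties as midranks), z from the normal
approximation with tie-corrected variance and a 0.5 continuity
correction shrunk toward zero, two-sided p from z. For n1+n2 ≤ 12 the
p-value switches to exhaustive enumeration of all C(n, n1) labelings
(configurable limit). Effect size r = z/√(n1+n2).

Cluster-extent correction: null maps are white Gaussian fields drawn
on the mask grid (padded by 3 kernel σ per side when smoothed, so the
field is stationary after cropping), smoothed to the target FWHM,
standardized to unit variance within the mask, and thresholded
two-sidedly at the voxel α. The extent threshold k is the smallest
cluster size whose exceedance by the null maximum cluster is at most
the family-wise α (empirically: sorted descending extents indexed at
⌈α·n_iter⌉, plus one; as α → 1, k → 1). The default null-map
smoothness equals the preprocessing FWHM; a residual-based smoothness
estimator is out of scope. Connectivity defaults to 26 ("contiguous"
is ambiguous in 3-D); 6 and 18 are available, and the validation
suite exercises both 6 and 26.

The 44-voxel threshold reported for the original whole-brain analysis
depends on the real task-responsive mask and map smoothness, neither
of which is available; it is not a reproduction target here — the
package instead validates that its own thresholds control the
family-wise error on null cohorts.

## ROI analysis

βs are averaged over ROI voxels per TOA (missing voxels excluded and
logged), then fitted once per subject. Averaging βs across voxels is
identical, for OLS under a design shared across voxels, to averaging
the time series and re-fitting — the linearity is unit-tested rather
than assumed, since "the BOLD signal was averaged for each ROI" could
be read either way. ROIs are consumed as voxel masks on the analysis
grid (atlas assembly and template-space conversion are upstream of
this package); synthetic tests use geometric masks, e.g. an 11×3×3
box of 99 voxels mirroring the reported primary-auditory ROI size.

## Problem sizes in the validation suite

The test suite and the acceptance script run entirely on synthetic
data at desk scale, chosen as follows:

* exact-recovery checks: 4³ grids, full 16-trial blocks;
* study-scale recovery: one 19+20-subject cohort on the default 12³
  grid with default noise;
* power and null-calibration replicates: the 99-voxel ROI grid
  (11×3×3), 8 trials/block, 10 s gaps, smoothing off — the ROI
  statistic's sampling distribution depends on the per-subject ROI βs,
  which this preserves at the study's group sizes (19/20);
* family-wise-error replicates: 8³ grids, 8+8 subjects, 8 trials per
  block, with the Monte-Carlo threshold calibrated at 1000 iterations
  and both 6- and 26-connectivity;
* oracle equivalence of the Monte-Carlo threshold: 6³ mask at 10,000
  iterations against a brute-force reference.

Monte-Carlo acceptance bands use exact binomial 95% intervals at the
nominal rates.

## Known limitations

* Four TOA points fit three parameters; single-voxel τ estimates are
  intrinsically noisy, which is why group inference is rank-based and
  the ROI path averages before fitting.
* No prewhitening / AR noise model in the GLM; with TR = 1 s and
  white synthetic noise this is exact, on real data βs would have
  mildly underestimated standard errors (only βs, not their SEs, are
  used downstream).
* The Monte-Carlo correction simulates smoothed Gaussian statistic
  fields, not the rank-statistic field itself; with discrete
  Mann-Whitney p-values at small n the voxel threshold is effectively
  conservative, so family-wise error lands at or below the nominal α.
* Fixed-effects pooling of the task F across subjects ignores
  between-subject variance; it selects voxels, it does not provide
  population inference (the Mann-Whitney stage does that).
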