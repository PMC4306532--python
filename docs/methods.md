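# Methods

This note documents the models, estimators and numerical choices behind
`prestim`, what the synthetic-data generator does and does not emulate, and
the problem sizes used by the test suite and the acceptance script.

## Synthetic data model

**Trial schedule.** Conditions (left / right single target, two-target
choice) are i.i.d. from configurable probabilities (default equal thirds);
blocks are contiguous and equal sized. The foreperiod (= inter-trial
interval for the analysis) is drawn from an exponential distribution
(rate 1/0.35 s⁻¹ by default) truncated to [3, 4] s: truncated-exponential
sampling is the defining construction of a *non-aging* foreperiod, whose
hazard — the probability of target onset given it has not yet occurred — is
constant over the interval. The previous condition of the first trial of
each block is a dedicated `start` level that never enters the 3×3
renormalization cells.

**Reaction times.** RT (ms) is composed additively:

    rt = rt_mean + iti_slope·(iti − mean iti)
       + condition_offsets[current, previous]
       + block_slope[block]·(trial index − mean)
       + choice_penalty·1{choice}
       + Σ_k c_k·z_k + ε,     ε ~ N(0, rt_sd_spontaneous²)

where `z_k` is the standardized realized baseline amplitude of ground-truth
source k and `c_k` is chosen in closed form so that the *population*
correlation between `z_k` and rt equals the requested `rt_coupling_r`
(given the realized deterministic variance and the residual SD; the
configuration is rejected if Σ r² ≥ 1). Non-positive draws are redrawn.
Defaults (262 ms mean, 48 ms spontaneous SD, 18 ms choice penalty) follow
the emulated behavioural regime. `config_with_variance_shares` inverts the
composition: given target variance shares for ITI, condition history and
block trends, it computes the corresponding effect sizes analytically
(truncated-exponential ITI variance, probability-weighted 3×3 offset
pattern, uniform trial-index variance).

**MEG epochs.** Each source emits per-trial band-limited Gaussian noise
(4th-order zero-phase Butterworth in `center_freq ± bandwidth/2`),
normalized to unit RMS, scaled by `base_amplitude`, and modulated within its
coupling window (default [−1, 0] s, raised-cosine ramps of 100 ms) by a
per-trial log-normal gain (σ = 0.5, mean 1). The *realized* RMS over the
coupling window is the ground-truth amplitude that downstream estimates are
scored against, and the quantity coupled to RT. Fields reach the sensors
through the analytic spherical-conductor (Sarvas) lead field; i.i.d.
Gaussian sensor noise is added (default SD 1e-4 in the arbitrary field
units, ≈ unity single-channel amplitude SNR for the default occipital
source — a realistic regime for posterior alpha). Sensors are a Fibonacci
cap of radially oriented gradiometer-like channels (default 30 for desk
scale; any count up to a full 272-channel array is supported).

Because the amplitude modulation is a scalar per trial, the *phase* of every
source is uninformative about RT by construction: the ITC analysis sees an
exact null, which is what makes its calibration testable.

**EOG.** The horizontal channel is a logistic step of full stimulus
eccentricity (rise constant 8 ms) whose maximal slope falls exactly at
target onset + RT, signed by saccade direction; the vertical channel is
noise. `inject_artifacts` corrupts a chosen fraction of trials with labelled
violations (baseline blink, undersized saccade, flipped direction, latency
outside 75–500 ms) so exclusion rules can be validated against ground truth.

**What the generator does not emulate** (hence what green tests do and do
not show about real data): realistic head geometry and cortical orientation
maps, 1/f background spectra and physiological artifacts beyond the step +
blink templates, microsaccades, non-Gaussian RT distribution shape
(empirical RTs are right-skewed; the generator's are Gaussian around the
composition above), head movement, and between-subject anatomical
variability. Passing tests demonstrate the *estimators* are correct and
calibrated, not that real MEG meets their assumptions.

## Forward model and beamformer

The forward model is a homogeneous conducting sphere with the full Sarvas
closed-form solution (arbitrary sensor orientations supported; the constant
μ0/4π is dropped — all downstream statistics are scale invariant). Radial
dipoles are exactly silent, so source orientations live in the tangential
plane; the lead-field interface accepts any externally supplied matrix for
users with realistic forward models.

For each band × window, one *global* covariance pools all trials (zero-phase
4th-order Butterworth, mirror padding; window cropped after filtering).
Diagonal loading defaults to 5% of the mean eigenvalue (configurable); a
rank warning makes loading mandatory when pooled samples are scarce. The
scalar orientation at each voxel maximizes the unit-noise-gain output power
(pseudo-Z): the leading generalized eigenvector of (LᵀC⁻¹L, LᵀC⁻²L) in the
2-D tangential basis. This is the standard SAM orientation choice; plain
unit-gain output power has no generalized-eigenproblem form, so the
unit-noise-gain variant is used and noted here. Weights are
`C⁻¹l / (lᵀC⁻¹l)`, unit gain by construction. Per-trial source amplitude is
the RMS of the projected band-passed epoch over the window — for narrowband
signals this agrees with the mean Hilbert envelope up to a constant (√2),
which cancels in correlations.

The source grid is a cubic lattice on integer multiples of the spacing
(default 8 mm, sphere centre excluded since sources there are silent),
clipped 12 mm inside the scalp sphere. Six geometric ROI labels
(occipital/parietal/frontal × hemisphere) stand in for the anatomical
regions of interest; users with atlases can supply their own masks. Peak
statistics are reported two ways: the peak of the group-average map within
an ROI (a lower bound, sensitive to voxel-level spatial consistency) and
the group average of per-subject peaks (an upper bound).

## Time–frequency, ITC and regressors

The Hilbert filter bank band-passes each virtual-electrode projection at
centre ± 4 Hz (Butterworth order 4, forward–backward; 1 s reflective
padding), takes the analytic signal, and subsamples by 2 — the narrow bands
make further anti-aliasing unnecessary. Electrode weights come from a
0–100 Hz global covariance and the unfiltered signal is projected through
them. Correlation maps use 50 ms time bins; electrode-averaged maps average
*r values*, not amplitudes. MNI electrode coordinates are mapped into the
sphere by a single isotropic scale factor placing the outermost electrode at
85% of the head radius.

The quintile ITC test sorts trials by RT into contiguous fifths (stable
sort; remainder trials go one each to the first quintiles), computes the
mean over quintiles of within-quintile ITC per (frequency, time), and
standardizes it against the mean/SD of 100 random-requintiling shuffles;
p values come from the upper normal tail (the alternative is greater
within-quintile coherence). The quintile-mean is standardized (rather than
standardizing per quintile and averaging); both options are exposed via
`label_itc_contrast`'s group machinery. Phase analyses default to 5–35 Hz.
A reported cluster must span ≥ 2 adjacent frequencies *and* ≥ 2 adjacent
time bins below threshold. With a 100-shuffle Gaussian null the realized
false-positive rate is slightly anticonservative (~6% at nominal 5%), a
property of the shuffle-count/normal-tail design that the calibration tests
quantify.

RT corrections are applied sequentially (ITI → condition cells → block
trends), per dataset, never pooled; every step preserves the grand mean, and
the ledger defines each share sequentially against the *raw* variance, so
the three shares plus the residual tile the total reduction exactly.
Under-filled cells (< 5 trials) and session-start trials fall back to a
marginal current-condition grouping and are renormalized by that fallback
group's own mean — this keeps both invariants (exact mean preservation,
variance never increasing) that a naive marginal-mean subtraction would
break. Sequential least-squares/cell-mean corrections absorb, in
expectation, df/n of the remaining noise variance in addition to the true
effect (expected mean squares: df = 1 for the ITI slope, ≈ 8 for the 9-cell
renormalization, ≈ 7 for 4 blocks × offset+trend); at n = 800 this is a
~2% overhead that the recovery tests account for analytically. The V1
correction residualizes *raw* RT on the mean band amplitude across all 20
V1 electrodes (an alternative regressor, not a cascade stage).

Two amplitude estimators appear in the pipeline — the SAM band RMS and the
Hilbert band/window-mean envelope — and their RT correlations agree at the
same location to well within sampling error. Averaging per-(1 Hz × 50 ms)
cell r values instead is systematically attenuated (each cell is a much
noisier amplitude estimate), so cross-estimator comparisons always use the
band/window-averaged amplitude.

## Group inference

Per-subject r values enter one-sample t-tests untransformed (a Fisher-z
option exists, off by default). The omnibus correction is the max-|t|
sign-flip permutation across subjects: exhaustive for ≤ 12 subjects (4096
patterns, exact and seed free), Monte Carlo above that with the identity
pattern always included. Note that the two-sided max-|t| statistic is
invariant under flipping *all* signs, so the smallest attainable corrected
p in exhaustive mode is 2/2ⁿ. FDR control is Benjamini–Hochberg over the
declared family (frequencies × time bins × ROIs × regressor types). Tests
are two-sided throughout.

## Pipeline and determinism

Stages (`simulate … report`) communicate through files in the study
directory and a JSON manifest with SHA-256 checksums; per-subject seeds
derive from the master seed via `SeedSequence([master_seed, subject])`.
HDF5 datasets are written with `track_times=False` so identical
configurations give byte-identical artifacts (PNG figures may embed
renderer metadata and are excluded from determinism checks). A completed
stage is skipped on re-run unless forced; a missing upstream artifact is a
hard dependency error naming the stage.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
30-channel sensor caps, 15–30 mm validation grids (the study default is
8 mm), epochs trimmed to the windows a check actually uses, 10–20 replicates
for recovery analyses and 200–400 for calibration rates, and a compact
12-subject end-to-end study (160 trials, 20 channels, one band). Tolerances
follow the relevant sampling distributions (3 SE bands for Monte-Carlo
quantities; printed precision for analytic ones). All sizes are plain
function arguments, so any analysis scales up unchanged.

## Known limitations

Single-sphere forward model (no realistic conductor geometry); geometric
ROI stand-ins rather than atlas parcels; the vertical-EOG "clarification"
step of manual saccade scoring is not emulated; eye-ball source checks are
out of scope; sensor-space replication of the TF analysis is available
trivially (treat channels as electrodes) but not separately validated; the
generator's RT distribution is Gaussian rather than skewed.
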