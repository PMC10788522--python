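# Methods

This note documents the models, numerical choices and limitations of
each stage, in the order the pipeline runs them.

## HRV metrics

An `RRISeries` holds beat times (s) and intervals (ms) with the
invariant `intervals[i] = 1000 * (beat_times[i+1] - beat_times[i])`.
Ectopic-beat cleanup flags intervals deviating by more than 30 %
(configurable) from the 5-point running median and replaces them by
linear interpolation between accepted neighbours; beat times are
rebuilt from the cleaned intervals.  If more than 20 % of intervals are
flagged the series is returned with a cleared quality flag and a
warning — downstream metrics are then suspect.

VC uses the sample (n−1) standard deviation so that it matches the
cohort z-scoring convention.  The spectral pathway interpolates the
tachogram with a cubic spline onto a uniform 4 Hz grid (the common HRV
convention; the recording is a single ~5-min segment, so no Welch
averaging), removes a linear trend and applies a Hann window with power
correction before the one-sided FFT periodogram (ms²/Hz).  Band powers
integrate the density by rectangular bin-width summation over the
half-open band [lo, hi): this makes power exactly additive over
disjoint bands and assigns the boundary bins unambiguously — the LF
(0.04–0.14 Hz) and HF (0.15–0.50 Hz) bands leave the 0.14–0.15 Hz bins
to neither band.  For an interval modulation of amplitude *a* the band
power converges to a²/2, which the tests use as a closed-form oracle.

Z-scoring uses control-cohort means and (n−1) standard deviations per
metric.  Abnormality is *reduction only*: z < −1 strictly, because HRV
has no meaningful upper limit; z = −1 exactly is not abnormal.

## Synthetic generators

All generators are pure functions of their spec including the seed.

* **Tachograms** are generated by direct interval modulation
  (`rr(t) = mean_rr + lf_amp·sin(2π·lf_freq·t) + hf_amp·sin(2π·hf_freq·t) + ε`)
  rather than integral pulse frequency modulation: the band-power
  ground truth is then the analytic a²/2 and the total variance is
  lf_amp²/2 + hf_amp²/2 + noise_sd².  This deliberately omits
  ECG-level morphology and the tachometer nonlinearity of real
  recordings; passing tests therefore validate the *analysis*, not the
  physiological realism of the signal.
* **MVAR networks** simulate y_t = Σ_r A_r(t) y_{t−r} + ε_t with a
  per-segment stationarity check (companion spectral radius < 1) and a
  500-sample burn-in to remove the zero-state transient.  The exact
  coefficient schedule is returned per retained sample as ground truth.
  The series are band-limited AR processes, not hemodynamically
  convolved BOLD; balloon-model simulation is out of scope.
* **Lesion cohorts** embed one spatial component: each subject's map is
  `loading · component_map + N(0, noise_sd²)` voxelwise, and the scalar
  covariate is `ρ·z(loadings) + sqrt(1−ρ²)·e`, which has population
  correlation exactly ρ with the loadings.  The default pattern is a
  central block of amplitude 3 on a 12×12×8 grid with unit noise —
  a deliberately idealised stand-in for spatially normalised stroke
  masks.  Default cohort size is 42 subjects, the study-scale cohort.
* **Atlases** partition the grid into contiguous equal blocks; with 7
  ROIs the labels carry the seven network names.

## Component count and parallel ICA

The component count minimises a Wax–Kailath-style AIC on the eigenvalue
spectrum of the subject covariance.  Two robustness details matter:
feature-wise demeaning makes the smallest eigenvalue identically zero,
so it is excluded; and eigenvalues are floored at 1e−9 of the largest
so that machine-precision noise in a rank-deficient tail is not read as
structure.  The estimate is the median over five runs — the full
feature set plus four random 80 % feature subsets drawn *without*
replacement (bootstrap duplication would violate the independence the
criterion assumes and inflate k).

The lesion modality is whitened by truncated SVD (X = M·V, with M the
subjects×k loading basis).  Unmixing uses natural-gradient Infomax with
the logistic nonlinearity and symmetric re-orthogonalisation each
iteration, so the loading matrix stays A = M·Wᵀ (up to scaling).  The
scalar HRV covariate is a degenerate one-feature modality whose
"loading" is the covariate itself; the coupling term is therefore a
gradient-ascent step on the squared Pearson correlation between the
currently best-matched loading column and the covariate, applied to the
corresponding row of W.  Whenever that squared correlation decreases,
the coupling learning rate is halved (the adaptive adjustment).
Iteration stops when the elementwise change of W drops below 1e−6 or
after 1000 iterations; otherwise the best iterate is returned with
`converged=False`.  With a finite step size the strict 1e−6 fixed-point
tolerance is often not reached even though the decomposition has
stabilised — the recovery tests key on the recovered correlation, not
on the flag.

Per-component significance of the loading/covariate correlation uses a
subject-label permutation test (1000 permutations, two-sided on |r|);
the selected pair is the significant component with the largest |r|.
Sign indeterminacy is resolved when converting the selected source to a
map (flip so the loading correlation is positive), the source is scaled
by its standard deviation to pseudo-t units and thresholded strictly
above t = 3.

## Lesion mapping

Combination is voxelwise sum (or max) over co-registered maps in voxel
space; spatial normalisation is upstream.  Cluster filtering labels the
suprathreshold (> t) mask with 26-connectivity (configurable to 18/6)
and removes clusters with extent ≤ min_voxels — the rule is strict, so
a 10-voxel cluster dies under the default `min_voxels=10` and an
11-voxel cluster survives.  The overlay table reports, per ROI, the
lesioned volume (voxel count × voxel volume) and its percentage of the
total suprathreshold volume; ROIs with fewer than `min_voxels` lesioned
voxels are omitted, so percentages may sum to less than 100.

## Dual-EKF time-varying MVAR and PDC

Two coupled Kalman recursions run over the samples.  The *parameter*
filter treats the stacked MVAR coefficients as a random-walk state with
process covariance q_param·I (default 1e−4) observed through the linear
regression of the next sample on the lagged state; because the
observation is linear in the coefficients once the lags are fixed, the
filter decouples exactly into one scalar-observation Kalman filter per
target channel (cost O(c·(pc)²) per sample).  The *state* filter tracks
the stacked last p channel vectors with the companion-form transition
built from the freshest coefficient estimates and feeds its lag
estimates back as the regressors.  The innovation variance per channel
is initialised at the sample variance and tracks the squared one-step
prediction errors with rate 0.01; observation noise is 1e−4 of the
sample variance (the series is observed essentially noise-free).  The
first 10 % of the coefficient trajectory (filter transient) is
discarded before any averaging.  Non-finite states raise immediately
with the sample index.  The inner loop is numba-compiled with an
equivalent pure-NumPy fallback.

With a random-walk prior the instantaneous coefficient estimate wanders
(excursions of ~0.2 on pure noise are normal); time-averaged estimates
are the quantity with oracle-level accuracy — on stationary bivariate
VAR(2) data at n = 2000 they agree with the least-squares fit to RMSE
< 0.05 and with the truth to RMSE < 0.1.

Squared PDC from source j to target i at normalized frequency f and
time t is |Ā_ij(f,t)|² / Σ_k |Ā_kj(f,t)|² with
Ā(f,t) = I − Σ_r A_r(t)·e^(−i2πfr).  Column normalisation makes every
source column sum to 1 over targets, bounding all entries in [0, 1].  A
zero column norm (impossible for finite coefficients except in
contrived inputs) yields 0 with a warning.  The default frequency grid
is 64 bin-centred points in (0, 0.5) cycles/sample; Hz conversion uses
the sample rate (TR = 1 s ⇒ 1 Hz).  Band averaging takes the mean over
grid frequencies inside [0.009, 0.08] Hz and then over time (the two
means commute over fixed masks; band-then-time is implemented).
`time_stride` can subsample the coefficient trajectory before the PDC
transform — the band/time average is insensitive to moderate strides
and surrogate loops use stride 5 with a 16-point grid for speed.

Model order defaults to 5 and can be checked with
`select_order` (stationary least-squares VAR per candidate,
AIC = n_eff·log det Σ̂ + 2·p·c², argmin).

The seed channel is the unweighted mean over active lesion-pattern
voxels; networks are the per-label means of the seven-network
parcellation.  `connectivity_profile` reports seed→network (forward)
and network→seed (backward) values; entries below the 0.1 threshold are
reported but flagged pending the surrogate tests.  When connectivity
values are compared across medication groups, the medication class can
be regressed out of the band-averaged values before the comparison — a
plain linear covariate adjustment, chosen because no mechanism is
implied by the analysis itself.

## Surrogate significance

*Window shuffle*: the putative source channel is cut into
non-overlapping windows (default length 10·order samples; at least 4
windows required) whose order is permuted, destroying cross-channel lag
structure while preserving the channel's marginal distribution and
short-range autocorrelation.  Shuffling only the source — rather than
jointly permuting all channels, which would preserve the
cross-correlation being tested — makes this a genuine null for directed
coupling.  The full TPDC pipeline is re-evaluated per realization
(default 1000) and the 99th percentile of each connection's null is its
significance threshold.  Nulls are built separately per subject.

*Time reversal*: a second test on already-significant connections; a
connection passes only if its original value strictly exceeds its value
on the time-reversed series.  Genuinely lagged directed influence
passes almost always; for *symmetric instantaneous mixing* the original
and reversed values are statistically exchangeable, so single
connections pass at roughly chance rate rather than being reliably
rejected — the test removes the systematic part of mixing artefacts but
is not a per-connection guarantee, which is why it is applied only as a
second filter after the shuffle null.

*AAFT*: per channel, rank-remap onto sorted Gaussian draws, randomise
the Fourier phases of the gaussianised series, and rank-remap back onto
the original amplitudes.  The marginal distribution is preserved
exactly, the spectrum approximately.

Calibration: for an uncoupled pair the original value exceeds the
99th-percentile shuffle threshold in about 1 % of repetitions (the
acceptance suite checks ≤ 5 % over 200 repetitions at 200 realizations
per null, series length 600 — sizes chosen to keep the check tight but
cheap).

## SVR validation

`fit_svr` uses scikit-learn's polynomial-kernel SVR with γ fixed at
0.25.  The integer grid 1–10 is searched for both the polynomial degree
and the regularisation strength C (the literature this mirrors does not
say which parameters the grid covers; degree + C is the implemented
interpretation) on the 75 % training split with 10-fold inner CV; the
reported accuracy is the 10-fold cross-validation accuracy over all
subjects with the tuned setting, alongside the held-out 25 % accuracy.
For group targets a prediction is correct when it rounds to the true
label; for continuous targets, when it lies within 0.5 target standard
deviations of the truth (a configurable convention — no standard
accuracy definition exists for a regression output).  The report passes
when overall accuracy exceeds the fixed 0.75 threshold, and records the
95 % highest-density interval of the pooled connectivity values under a
normal model (symmetric mean ± z·sd interval; for mass 1 the data
range).

## Group comparison

`compare_groups` is a two-sample permutation test on the mean
difference, two-sided, with exact enumeration whenever the number of
group assignments is ≤ n_perm (default 10 000) and Monte Carlo with an
add-one correction otherwise; Welch's t is available.  Across the 14
network × direction comparisons, Bonferroni correction is applied by
default (configurable off).

## Pipeline and problem sizes

`run_pipeline` derives every stage seed from the config master seed, so
reruns are byte-identical.  Stage toggles respect dependency closure
(disabling TPDC disables surrogates, comparison and SVR).  Defaults
follow the study settings (order 5, band 0.009–0.08 Hz, 1000
realizations at the 99th percentile, t > 3, >10 voxels, z < −1,
γ = 0.25, 42 patients / 20 controls, 655 BOLD-like samples at TR 1 s);
the demo configs and tests use reduced sizes (a dozen subjects,
300-sample series, tens of realizations) chosen so a full run remains a
matter of seconds while exercising every code path.

## Known limitations

* The synthetic BOLD stand-in is an AR process: no hemodynamic
  convolution, measurement drift or motion artefacts, so robustness to
  those is untested.
* The DEKF tracks smooth coefficient drift; abrupt switches are crossed
  with a lag of a few percent of the series length, and the random-walk
  prior trades tracking speed against instantaneous variance via
  q_param.
* The time-reversal test is a population-level filter, not a
  per-connection guarantee under instantaneous mixing (see above).
* The ICA significance permutation ignores spatial autocorrelation of
  lesion maps; with heavily smoothed maps its p-values are optimistic.
* VC/LF are treated as given covariates for the fusion; no attempt is
  made to model their measurement error.
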