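# Methods

`emostroop` implements an analysis chain for event-related task-fMRI of an
emotional-Stroop paradigm in two small groups of adolescents — a positive
(FH+, n = 11) and a negative (FH−, n = 7) familial substance-use-disorder
history group — together with a synthetic-data generator that emulates the
statistical structure of such a study so every stage can be exercised and
validated without access to subject data.  This note records the models,
the defaults and the design decisions, and what the synthetic benchmarks
do and do not establish about real data.

## Task model and first-level GLM

Trials present a face whose overlaid emotion word is congruent (C) or
incongruent (I); each trial is classified jointly with its predecessor
into cC, iC, cI, iI.  Sequences are pseudorandom with pair-type counts
maximally balanced: 148 trials yield 147 classifiable pairs, which cannot
split into four equal counts, so "equal numbers" is implemented as
max − min ≤ 1 (the only realizable reading).  The first trial's pair type
is undefined; in the design matrix it joins the regressor of its own
condition with a congruent prior (C→cC, I→cI), since no preceding trial
exists.  Stimuli last 1 s with a uniform 3–5 s ISI (mean SOA 5 s) at
TR = 2 s.

The design matrix contains one regressor per pair type built from the
*correct* trials only, an error-trial regressor (same 1 s boxcar + HRF
model — error trials are simply modelled separately), six motion
parameters, an intercept, and a discrete-cosine drift basis with cutoff
1/128 Hz.  Boxcars are built at a microtime resolution of TR/16 and
sampled at slice-middle times to avoid onset aliasing; events can
optionally be modelled as delta sticks (`events_as_sticks`), boxcars being
the default.  The HRF is a double gamma parameterised so the response lobe
peaks exactly at `peak_delay_s` (default 6 s) and the undershoot at 16 s,
dispersions 1, peak:undershoot ratio 6, unit peak; all parameters are
configurable through `HrfSpec`.

Serial correlation is removed by iterated Cochrane–Orcutt AR(1)
prewhitening: the lag-1 autocorrelation of the OLS residuals estimates
rho; data and design are filtered (first row scaled by √(1−ρ²)) and
refit until |Δρ| < 1e-4 (max 20 iterations).  This replaces a full ReML
scheme with spatially pooled covariance: the statistical target — removal
of first-order serial correlation — is preserved at far lower complexity.
Degrees of freedom are n − rank(X) without a Satterthwaite correction, an
approximation that slightly overstates dof when whitening is imperfect.
All-zero design columns (e.g. an error regressor with no error trials)
are dropped from the fit and reported with β = 0.  Contrasts are
mean-difference scaled: cI−cC uses (+1, −1); I−C uses (+1, +1, −1, −1)/2.
For whole volumes a vectorised variant runs one OLS for all voxels and a
single spatially pooled rho (the median voxelwise residual lag-1
autocorrelation) with one whitened refit — a deliberate trade of per-voxel
precision for tractability at desk scale.

## Group inference

Voxelwise group differences use the pooled-variance (Student) two-sample
t (df = n₁+n₂−2), not Welch — the package also recomputes published
summary-statistic t values (−3.9261, −2.8369) from group means/SDs at
n = (11, 7), and those match the pooled formula to four decimals; Welch is
available as an option.

Cluster-extent correction estimates the minimum extent k by Monte-Carlo
simulation: unit Gaussian noise volumes are smoothed with the analysis
FWHM (8 mm on 3 mm voxels by default), re-standardised within the mask,
thresholded two-sided at voxelwise p = 0.01, and the maximum connected
cluster recorded per iteration (≥1000 iterations); k is the smallest
extent with exceedance frequency ≤ α = 0.05.  Connectivity defaults to
18 (6/26 configurable).  k depends strongly on the search volume, which
the original analysis context leaves open, so k is treated as a
property-tested output (deterministic per seed, monotone in FWHM and in
1−α), not a numeric target.  ROI summaries over a cluster are the voxel
mean by default; a first-eigenvariate summary (SVD of the rows × voxel
matrix, sign-aligned to the cluster mean, scaled so a spatially constant
cluster reproduces its value) is provided because region "eigenvectors"
are the other common reading.

## Granger causality

The GCI of a source for a target at order p (default 1, BIC selector
available) is ln(RSS_restricted/RSS_full), where the restricted model
regresses the target on its own lags 1..p (+intercept) and the full model
adds the source's lags.  Nesting guarantees GCI ≥ 0.  "Influence of A on B
through the thalamus" is implemented as *joint* mediated GC by default —
the full model adds the lags of both the thalamus and the source, matching
compound row labels like "Thalamus Putamen → IFG" — with *conditional*
(partial) GC as the alternative reading.  Within-group significance is a
two-sided one-sample t of subject GCIs against zero (undefined under zero
variance, which is flagged); between-group comparison is the pooled
two-sample t.  GCIs are computed on the raw task time courses; an option
to regress out the condition regressors first exists but defaults off,
since the original choice is unknown.

## Synthetic-data generator

The generator is the package's study stand-in, not a fixture.  Each
subject's ROI series is

    VAR(1) coupling process + Σ_condition β·(HRF ⊛ boxcar) + AR(1) noise

with ten ROIs (ACC, MFG, SFG, SMG, IFG, insula, hippocampus, putamen,
thalamus, VTA), self-lag 0.3, unit innovations, AR(1) measurement noise
(SD 0.3, ρ 0.3), and a 100-sample burn-in discarded for stationarity.
Condition effects default to an elevated conflict profile in FH+
(cC 0.30, iC 0.35, cI 0.90, iI 0.70) against a flat FH− profile
(cI 0.45, iI 0.40), so cI−cC and I−C contrasts are positive FH+ > FH−.
Motion covariates are smoothed random walks of small amplitude.  The
default run is 390 scans at TR 2 s (13 min): a 148-trial sequence at mean
SOA 5 s occupies ~740 s plus ISI variability, which a shorter run cannot
hold.

Directed coupling is specified as per-channel target GCI distributions
(group mean ± SD, defaults set to the published connectivity table).  A
subject's drawn GCIs are inverted to lag-1 coefficients via
GCI = ln(1 + c²·var(source)/σ²): for multi-source targets the system
X_i = (σ² + S)(1 − e^{−g_i}) is solved per source contribution, source
variances come from the VAR's stationary (discrete Lyapunov) solution by
damped fixed-point iteration, and measurement noise is compensated to
first order.  Because the analytic inversion ignores attenuation from the
target's own-lag absorption, the shared task signal and noise, the
generator additionally self-calibrates multiplicative per-channel,
per-group gains (capped at 4) by simulating small cohorts at the group
means; the calibration is deterministic and cached.  With defaults, the
simulated group means of the direct channels track their targets closely
(e.g. IFG→ACC ≈ 0.05 vs 0.24 against targets 0.0503 vs 0.2333), while the
joint mediated channels through the thalamus saturate below their targets
(≈0.19/0.37 and 0.21/0.50 against 0.38/0.44 and 0.59/0.62): the network's
feedback loops make the target's own past increasingly informative, which
bounds the measurable joint GCI.  The ordering of channels and the signs
of all group differences are preserved; magnitudes of the mediated rows
are a known limitation.

Volume data are background Gaussian noise plus spherical activation blobs
whose task amplitude differs by group (subject amplitude = group mean +
N(0, between-SD)), on a 3 mm isotropic grid exported as NIfTI-1.

Reaction times are generated per subject as one general-speed offset
shared by all four pair types — SD equal to the group's mean condition SE
× √n, so between-subject SEs of the condition means reproduce the
configured scale — plus condition-specific noise of SD
min(10 ms, smallest condition SD), truncated at zero.  Defaults are the
published condition means and SEs.  The small condition-specific noise
makes each group's conflict-adaptation sign (iI − cI: +20.79 ms FH+,
−12.47 ms FH−) a stable characteristic, while the large shared-speed
variance keeps the per-condition between-group t-tests non-significant.
The published per-condition SE differences *within* a group are not
reproduced exactly: modelling them as independent condition variances
would make the adaptation sign unstable, contradicting the reported group
patterns; the shared-speed model is the package's resolution of that
tension.

What passing the synthetic benchmarks shows — and does not.  They
establish that the estimators are correctly implemented (analytic GCI
limits, beta recovery, flood-fill equivalence, permutation calibration)
and that the chain recovers effects of the configured size at the study's
n.  They do not establish that real fMRI of this paradigm carries such
effects: physiological noise, spatial correlation beyond the planted
blobs, inter-regional hemodynamic variability and session structure are
not modelled.

## Classification

Feature vectors combine per-subject contrast summaries of the
suprathreshold regions with the GCIs of group-separating channels.
Selection keeps candidates whose whole-sample pooled t has p < 0.05 —
deliberately replicating the published, *circular* procedure, and flagged
as such in the selection manifest; a nested mode redoes selection inside
every training fold for an honest estimate.  Features are z-scored with
training-fold statistics only.

Two linear classifiers: a soft-margin linear SVM (C = 1 default;
scikit-learn behind the interface) and a maximum-uncertainty LDA in which
eigenvalues of the pooled within-class scatter below their mean are
raised to the mean before inversion; the MLDA boundary is the midpoint of
the projected class means, with ties going to the larger training class.
Hyperplane contributions are |w_i| of the unit-norm normal.

Cross-validation schemes: repeated random five-fold (stratified by
default), Monte-Carlo leave-one-out (one randomly chosen held-out subject
per repeat, the literal reading of the published procedure; exhaustive
LOO is available), and leave-M-blocks (train on M of 5 random blocks) for
learning curves.  The published repeat count is 1000; tests and the
acceptance script use reduced repeats chosen to keep full calibration
sweeps at desk scale (e.g. 4–20 repeats per CV, 100 permutations, 60–80
Monte-Carlo datasets).  Permutation p defaults to the smoothed
(1 + #{null ≥ observed})/(B + 1); the unsmoothed #/B variant is provided
since published p values of 0.002/0.003 at B = 1000 imply that form.

Null-calibration note: with 11/7 class sizes the SVM's hinge loss leans
toward the majority class, but an unbiased soft-margin SVM does not
collapse to it: on label-independent features its CV accuracy sits
between the balanced 50% and the 61.1% majority rate — about 55% at three
null features, rising toward 60% only in one dimension — and an
independent scikit-learn StratifiedKFold/SVC pipeline reproduces the same
value.  The MLDA midpoint boundary is class-balanced and sits nearer 50%.
A calibration expectation that null accuracy *equals* the majority
baseline therefore presumes a majority-defaulting classifier these
defaults do not produce; the leakage-relevant property — null accuracy
not rising *above* the baseline — holds with a wide margin.  The
permutation-uniformity check uses the cheaper MLDA with fold-averaged
accuracies (near-continuous, avoiding the tie-induced conservatism of
single-holdout accuracies).

## Behaviour

Conflict adaptation is summarised per group as mean RT(iI) − mean RT(cI)
with per-condition means and between-subject SEs.  Group comparisons are
pooled two-sample t-tests per pair type and for congruent/incongruent
aggregates; the 2 (group) × 2 (congruency) mixed ANOVA is computed from
per-subject condition means (matching how RT tables are stored), with the
exact sum-of-squares partition exposed and cross-checked against an
independent implementation in the tests.

## Orchestration and reproducibility

`run_pipeline` executes simulate → GLM → group inference → GCI →
classification → behaviour from a single validated config; one global
seed fans out to per-stage child seeds via `numpy.random.SeedSequence`,
so stages are independently reproducible and the bundle (cluster table,
GCI group table, accuracy table, learning curve, behavioural tables,
JSON manifest with config hash and library versions) is identical for
identical config + seed.  All tabular outputs are tidy CSV; figure
generation is intentionally out of scope.

## Known limitations

- Spatial preprocessing (slice timing, realignment, normalisation,
  smoothing of data) is out of scope; inputs are treated as preprocessed.
  The Gaussian kernel appears only inside the Monte-Carlo null.
- The mediated-GCI magnitudes of the generator saturate below large
  targets (above).
- dof and pooled-rho approximations in the GLM (above).
- Sensitivity/specificity are reported from exhaustive-LOO predictions at
  n = 18; published values with finer granularity imply aggregation over
  repeated folds, which is ambiguous and not replicated.
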