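# Methods

This note documents the models, defaults and numerical choices behind
`dyadmind`, a pipeline for assessing a dyadic (parent-child) breath-focused
mindfulness intervention with three outcome modalities: self-report
questionnaires, an adaptive emotion-bias reaction-time task, and an
EEG-recorded attention-to-breath task. Because no participant-level data
from such studies are distributed, the package pairs every analysis stage
with a synthetic-data generator whose ground truth the pipeline must
recover; all quantitative claims below are computed by the test suite or by
`scripts/acceptance.py`, not asserted.

## Survey scoring

Scales: child-report CDI (12 items, 0-2), parent-report CDI (17 items,
0-3), DASS-21 stress subscale (7 items, 0-3), GAD-7 (7 items, 0-3), PHQ-9
(9 items, 0-3), MAAS (14 items, 1-6, aggregated by mean), and a 16-item
feasibility survey on 1-7 anchors with 11 positive- and 5
negative-feedback items. Reverse coding maps `x -> lo + hi - x` before
aggregation. Symptom scales are summed; the MAAS is averaged (standard
practice; its anchors already run in the "higher = more mindful"
direction, so no per-item reversal is applied). CDI raw-to-T conversion
uses proprietary norms and is deliberately not implemented; the pipeline
operates on raw scores and accepts pre-computed T scores as ordinary
columns.

The feasibility composites follow the stated rule exactly: positive
average, negative average on raw anchors, and an overall average of
positive plus reverse-coded negative items. Note a documented quirk: with
the published item means, the positive (4.72) and negative (2.78)
composites recompute exactly, but the overall composite from the stated
rule is 4.88, not the published 4.97; the package implements the stated
rule.

Cronbach alpha uses the variance form `k/(k-1) * (1 - sum(item var) /
var(total))` with sample variances, refusing fewer than 2 items, fewer
than 3 respondents, or zero total variance.

## Emotion-bias task

144 trials in 3 blocks of 48; within each block every emotion (neutral,
happy, sad, angry) appears 12 times with face sex, visual field and arrow
direction each balanced 6/6 within the emotion cell. A full 2x2x2
crossing does not fit into 12 trials, so the factors are balanced
independently; all block-level counts are exact.

The response window starts at 1000 ms (the task's 1 s response window,
also the ceiling) with a 300 ms floor (the stimulus duration); neither
bound is dictated by the task description, both are package choices. Only
neutral trials adapt: -33 ms after a correct response, +100 ms after an
incorrect one; other emotions inherit the last neutral window (trials
before the first neutral trial inherit the initial window). This weighted
up-down rule equilibrates where `p * 33 = (1 - p) * 100`, i.e. accuracy
`100/133 ~ 0.752`, slightly below the ~80% such staircases are usually
described as holding; the package reports the theoretical value and the
test suite verifies convergence to it.

Processing speed is `log10(1 / mean RT in seconds)` over correct trials
with a recorded response (a flag admits all responses). Base 10 is an
inference from the magnitude of typical printed values (~0.25-0.30 for
sub-second RTs); natural log would give values near 0.6.

Simulated observers have a logistic window-accuracy curve rising from
chance 0.5 with a small lapse rate, and lognormal RTs truncated at the
window (slower draws become omissions, scored incorrect). Cohort defaults
place child mean RTs at 0.558 s pre and 0.499 s post and parent RTs at
0.540/0.525 s, with between-subject SDs of 0.09/0.06 log10 units and a
between-subject SD of the training benefit of 0.085/0.065 log10 units, so
that group processing speeds and the paired change effect sizes land in
the reported ranges (children improving with a medium effect, parents
marginally).

## Breath-monitoring EEG analysis

Trials are taps after every 2 breaths; the trial RT is the within-block
inter-tap interval. Each participant's trials are split at their own
median: high consistency when `|RT - median| <= 1 MAD`, low otherwise.
The rule is two-sided by default — a literal one-sided reading would call
extremely fast taps "consistent", contradicting the premise that
consistency indexes interoceptive attention — with a switch for the
literal rule. The differential statistic is mean low-consistency minus
mean high-consistency network alpha power within a session; only the
pre-to-post change of this differential is interpreted, so the sign
convention is recorded in output metadata rather than load-bearing.

Processing chain per session: optional minimal cleaning (zero-phase
order-2 Butterworth band-pass 1-40 Hz; epoch rejection at +/-150 uV peak
— deliberately minimal, not a full artifact pipeline), epoching to the
half-open window [t-4 s, t) before each tap with full-support taps only
(dropped taps are counted), Tikhonov-regularized minimum-norm inversion
`(L'L + lam I)^-1 L'` with `lam = 0.1 * mean diag(LL')` by default
(the channel-space form `L'(LL' + lam I)^-1` is identical for `lam > 0`;
the source-space form stays well posed at `lam = 0` for full column
rank), Welch alpha power (8-12 Hz, 1 s Hann segments, 50% overlap, mean
PSD over in-band bins) per source computed after projection
(project-then-power), and unweighted ROI means per network (FPN, CON,
DMN). The pre/post contrast is a one-sided paired Wilcoxon signed-rank on
per-participant differentials (hypothesis: DMN decreases), with
participants missing either session dropped and counted, never imputed.

Head modeling is out of scope: the lead field is a required input. The
bundled synthetic lead field has orthonormalized random source
topographies, which makes the minimum-norm inverse crosstalk-free by
construction so that network specificity tests exercise the analysis
chain rather than leakage of an arbitrary random mixing matrix; a
correlated-topography variant is available. Real lead fields do leak, so
specificity on real data will be worse than on this synthetic source
space — a stated limitation.

## Synthetic data

**Surveys.** Each scale has a latent standard-normal trait per person;
item responses discretize `m + s*(lambda*trait + sqrt(1-lambda^2)*noise)`
onto the item range, with loading `lambda` chosen so parallel-item alpha
matches the scale's reported reliability (`alpha = k*rho/(1+(k-1)*rho)`,
`rho = lambda^2`). Baseline moments use the published parent symptom
means/SDs; CDI raw and MAAS baselines are stated assumptions. Pre-to-post
and pre-to-follow-up changes shift the trait by a per-person normal draw
(SD 1.0 trait units — individual differences in training response); the
mean shift is calibrated deterministically (iterative secant on a 20k
internal sample, cached) so the *observed scale-score* paired Cohen d
equals the configured value despite discretization and floor/ceiling
clipping. Configured cross-measure change correlations (default:
stress change vs mindfulness change, Spearman -0.45) go through a
Gaussian copula whose latent correlation is de-attenuated by each
measure's empirically measured signal fraction; residual attenuation of
roughly 0.05 rank-correlation units remains at extreme targets.

**Training courses.** Each session holds a configurable number of level
attempts (default 3); each member passes an attempt with probability equal
to their skill, the pair advances one level only when both pass (the
"consistent for two-thirds of the level" rule abstracted to a pass
probability), levels cap at 10 and courses at 30 sessions.

**Breath runs.** Latent attention is a 2-state first-order Markov chain
per breath cycle (focused -> wandering 0.15, wandering -> focused 0.30 per
cycle), the simplest state model that produces consistency structure.
Breath period: 4 s mean. The 0.5 s spread is treated as between-individual
(applied by cohort-level callers); within-run cycle SD defaults to 0.1 s,
because a literal 0.5 s per-cycle SD would contribute a state-independent
interval noise of ~0.7 s and swamp the state-dependent tap jitter (0.15 s
focused, 0.60 s wandering), making the MAD split uninformative about the
latent state the generator exists to encode. Runs are 300 s in two 150 s
blocks; taps land after every 2 breaths at the cumulative breath time plus
state-dependent jitter.

**EEG.** Sources are 10 Hz sinusoids (the alpha band is specified only as
8-12 Hz; a fixed carrier with random phase per source and block is the
simplest spectrally correct choice) whose amplitude in each inter-tap
segment is the gain of that segment's network and latent state, mixed
through the lead field with white channel noise; tap markers are carried
through. Defaults: 24 channels (10-20 montage), 500 Hz. The ground-truth
intervention effect multiplies DMN amplitude by `1 + b` during wandering
at pre only; `b` varies across participants (mean 0.35, SD 0.2, truncated
at 0) and the channel noise SD is 4.5 relative to unit source amplitude.
These three numbers were calibrated once so that the cohort-level paired d
of the DMN differential matches the configured target of -0.62, then
frozen; FPN and CON gains are state-independent throughout, making them
pure specificity controls.

## Outcome battery

Per measure and comparison: listwise-complete pairs; MAD outlier screening
applied to the pre and post values per timepoint (union of flagged pairs
dropped) — screening the discrete change scores directly has a MAD of
about one scale point and removes up to a third of pairs, grossly
inflating standardized effects, so the per-value reading is used;
Anderson-Darling normality (case 3, scipy's small-sample correction,
alpha .05) routes to a one-sided paired t (normal) or one-sided Wilcoxon
signed-rank (otherwise); paired Cohen d is `mean(diff)/SD(diff)`; the 95%
CI on the mean difference is t-based; BH-FDR is applied within declared
families (default: the three parental self-reports form one family,
mirroring the study's correction scope; families are configurable and
logged in the table). Even per-value MAD screening mildly inflates |d| on
skewed floor-bounded scores (~0.1 at n=24 in simulation) — an inherent
property of the screening rule, reported here for transparency.

Signed-rank and rank-sum use hand-computed tie-corrected normal
approximations with a 0.5 continuity correction in the p value (zeros
dropped, standard Wilcoxon practice); exact enumeration bounds the
approximation error at about 0.03 for n=8 in the tests. Note that BH
adjustment is not idempotent (re-adjusting adjusted p values changes
them); the battery's invariants are monotonicity, permutation
equivariance, and adjusted >= raw.

## Study sizes and runtime choices

The end-to-end neural recovery study runs 200 replicate cohorts of 41
participants x 2 sessions x 300 s through the complete pipeline. These
simulations use a 100 Hz sampling rate rather than the 500 Hz recording
default: the alpha band sits far below either Nyquist limit, the welch
estimates are statistically equivalent for this signal family, and the
study cost scales linearly with the rate. Channel noise is generated in
single precision for the same reason. The acceptance script uses 60
replicates for the neural study and 200 for the survey-recovery studies;
test-battery calibration uses 2000 null simulations per test.

## Known limitations

- The synthetic EEG has no 1/f background, no artifacts, no volume-
  conduction leakage (orthonormal topographies) and a fixed 10 Hz carrier;
  passing recovery tests demonstrates the analysis chain is correct and
  specific under the generative model, not that it is robust to real-world
  EEG nuisance structure.
- The feasibility overall composite reproduces the stated rule, which
  disagrees with one published summary value (4.88 vs 4.97).
- The staircase equilibrium (75.2%) is the per-trial weighted up-down
  value; the "3-up-1-down" label is implemented as the stated -33/+100
  per-trial weights, not as a 3-consecutive-correct rule.
- Native .xdf ingestion and real head models are not provided; a converter
  stub documents the expected text-container layout, and the lead field is
  a user-supplied (or synthetic) input.
- One-sided tests follow the declared improvement directions; the z sign
  convention for printed signed-rank statistics is ambiguous in the
  literature, so reports carry |z| plus the direction label.
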