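# Methods

## Task geometry and schedules

Trials live on a 1536 × 2048 px canvas (origin top-left, continuous float
coordinates; orientation is irrelevant because every quantity is a
Euclidean distance — the maximum possible localisation error is the
2560 px screen diagonal). Displayed items are placed by rejection sampling
uniformly inside the screen minus a 100 px margin, with a 200 px minimum
pairwise separation; the margin and separation are design choices (the task
description fixes neither) that keep anchors distinguishable for the
classifier and resemble plausible touch-task layouts. Placement failures
after a bounded number of rejection rounds raise `PlacementError` rather
than looping forever.

A schedule interleaves the four conditions (set size {1, 3} × delay
{1, 4} s) in randomised order with exactly `n_per_condition` trials each —
30 by default (120-trial session), 20 in the short variant (80 scheduled
trials; the 7 introductory trials of the 87-trial administration are not
analysed and are left to the caller). Item identifiers (targets, displayed
non-targets, novel foils) are drawn without repetition across the whole
schedule.

## Generative response model

Each response is drawn from a three-component mixture
(`p_target + p_misbind + p_guess = 1`):

* **target**: target location + isotropic 2-D Gaussian noise with SD
  `sigma_px`, resampled until inside the screen (truncation by resampling
  keeps the model simple and the response on-canvas);
* **misbind**: same noise around a uniformly chosen displayed non-target;
* **guess**: uniform over the whole screen.

On set-size-1 trials no swap is expressible: misbinding mass is
reallocated proportionally to the remaining components (equally in the
degenerate all-misbind case), which keeps the weights a simplex without
inventing behaviour the task cannot display. Identification is Bernoulli
with `p_identify ∈ [0.5, 1]` (chance = 0.5 in the two-alternative test);
reaction times are log-normal (`rt_mu_log`, `rt_sigma_log`). Encoding
time and block structure are not modelled; set-size and delay affect
behaviour only through per-condition mixture parameters (no built-in
forgetting law is assumed).

## The nearest-distance classifier

For each analysed trial, two distances are fixed: response→target and
response→closest displayed non-target. Per repeat, one non-target location
is drawn uniformly **with replacement** from the pool of all non-target
locations of the *other* trials of the same session (never the trial's
own), and the smallest of the two or three distances decides the repeat's
category: target, misbind, or guess. Probabilities are category counts
over `n_resamples` (5000 by default), so they sum to 1 exactly. With a
single displayed item only target vs pool compete and misbinding is fixed
at 0. Exact distance ties — measure-zero for continuous data but possible
in constructed fixtures — resolve with the fixed priority
target > misbind > guess.

`classify_trial_exact` enumerates every eligible pool point once and
returns the exact expectation of the scheme (the guessing probability is
the fraction of pool points strictly nearer than both fixed distances;
the remaining mass goes to the nearer of target/closest non-target). It is
the deterministic limit of the Monte-Carlo estimator and doubles as a fast
exact mode for large simulation studies, which the cohort-level analyses
use.

**Interpretation.** The classified probabilities are a relative index of
response quality, *not* an unbiased estimate of the generative mixture
weights. For a pure guess, the drawn other-trial non-target is nearest
with probability ≈ 1/(set size + 1) (by exchangeability of uniform
points), so a session of pure guesses scores `p_guess_hat ≈ 0.25` at set
size 3, with the remainder split ≈ 1:2 between target and misbind. The
index is strictly monotone in the true guessing rate (verified as a
property test), and group or condition contrasts on it are meaningful;
absolute recovery of mixture weights would require a different estimator
(e.g. maximum-likelihood mixture fitting), which is deliberately out of
scope. Consequently validation compares the Monte-Carlo estimator against
the exact enumeration oracle (agreement within 3 binomial SEs per
component; session means within ±0.05), not against the generative
weights; the honest weight-recovery error (≈ 0.14 for guessing at mixture
(0.6, 0.2, 0.2), σ = 30 px) is reported by the acceptance script for
transparency.

Trials with an incorrect identification are excluded before
classification and before localisation averaging (the dragged item is not
the studied one); `include_incorrect` exists for sensitivity analyses. A
condition with no eligible trials is reported as missing (NaN), never as
zero. Set-size-1 trials are classified (target vs pool) with misbinding 0
and their non-existent non-targets simply contribute nothing to the pool;
the pool therefore consists of all set-size-3 trials' non-target
locations. Pool draws are with replacement, which allows more repeats
than pool points.

Per-participant randomness derives from a (master seed, CRC-32 of the
participant id) seed sequence, so classification results are independent
of the order in which participants are processed.

## Synthetic cohorts

`simulate_cohort` draws, per participant: mixture parameters from the
group's between-subject normal distributions (weights clipped to [0, 1]
and renormalised to the simplex; scales clipped non-negative;
`p_identify` clipped to [0.5, 1]); age, ACE and TIV from independent
normals; and VVIQ and regional volumes jointly from a multivariate normal
whose correlation matrix places `vviq_volume_rho` between VVIQ and every
region and `rho²` (a single common factor; overridable) between regions.
A non-positive-semi-definite specification raises. The latent VVIQ value
is rounded, clipped to [16, 80] and partitioned into 16 item ratings in
[1, 5] that sum to it exactly; discretisation attenuates the target
correlation negligibly at the SDs used.

Two presets define the study conditions. The **healthy** preset (N = 229
by default) uses age 57.7 ± 12.7, VVIQ 61.6 ± 13.3, ACE 97.2 ± 2.7,
elderly-control volume distributions for nine bilateral regions
(hippocampus, amygdala, V1, M1, fusiform, CA1, CA3, CA4, GC-ML-DG), a
VVIQ-volume correlation of 0.35, and mixture parameters
(0.78, 0.08, 0.14), σ = 100 px, `p_identify` = 0.92. Memory parameters
are independent of VVIQ by construction, so the preset carries no
imagery-memory association — the null the correlation analyses should
recover. The **clinical** preset has three groups of 19 (elderly
controls, an amnestic AD-like group, a PD-like disease-control group)
with group demographics, VVIQ and volume means/SDs following the
published clinical-table values; the amnestic group has mixture
(0.55, 0.20, 0.25), σ = 130 px, `p_identify` = 0.78 and slower RTs, while
the disease-control group tracks the healthy controls. `vviq_unchanged`
swaps the patient groups' VVIQ distributions for the control one — the
strict "memory impaired, imagery intact" configuration used in the
pattern checks. Condition effects (set size 3: −0.15 target mass,
−0.10 identification, +20 px noise, +0.25 log-RT; delay 4 s: smaller
decrements mostly into guessing) are additive offsets chosen once to
produce the expected within-subject effect directions at plausible
magnitudes; only their direction, not their size, is asserted anywhere.

What the generator does **not** emulate: encoding-order and block
effects, drag kinematics, spatial response biases (edge attraction,
systematic compression), item-level VVIQ psychometrics, and any
TIV-volume coupling. Passing tests therefore validate the pipeline's
statistical machinery and the classifier's internal consistency on
idealised data, not the behavioural realism of any particular parameter
value.

## Statistics

The 2 × 2 repeated-measures ANOVA tests each effect against its own
effect-by-subject interaction (df 1, N − 1); the mixed design adds a
between-subject group factor (group df k − 1, N − k; within effects keep
df 1, N − k). Both are sums-of-squares decompositions on cell means and
were verified against R's `aov` error-strata output and pingouin on
frozen fixtures. Partial η² = SS_effect/(SS_effect + SS_error). All
within effects have one numerator df, so sphericity corrections are moot.
Zero-variance edge cases are pinned: a zero effect SS gives F = 0 (even
when the error SS is also zero), a zero error SS with a positive effect
SS gives F = ∞.

t-tests are two-sided pooled-variance (Student) by default — consistent
with integer dfs in comparable reports — with Welch behind a flag. Holm
correction is applied per measure across the pairwise group contrasts
(the smallest defensible family); covariate (VVIQ, ACE, volume) contrasts
against the control group are reported uncorrected, as is conventional
for demographic tables, and no correction is applied across the many
volume correlations — a deliberate mirror of common practice, flagged
here. Correlations are Pearson with df = N − 2 and two-sided p. Regional
volumes are residualized on age and TIV by OLS (residual + grand mean)
before correlating; constant covariates are dropped, collinear ones
raise.

## Problem sizes and numerics

Cohort-level simulation studies use the exact classifier mode
(deterministic, equal in expectation to the 5000-repeat Monte-Carlo).
The package's own validation studies use: 100 random geometries for
Monte-Carlo/oracle agreement, a 200-trial session for session-mean
agreement, 500 cohort seeds (32 participants, 15 trials/condition) for
the null-correlation uniformity property, and 200 cohort seeds (3 × 19,
30 trials/condition) for the clinical-pattern rate — sizes chosen so the
whole battery runs in minutes on one CPU while keeping every check's
sampling error well inside its tolerance. Simplex sums are validated to
1e−12; serialisation round-trips are lossless to float precision (CSV
uses shortest round-trip representation).

## Known limitations

* The classifier index compresses the guessing scale (see above); levels
  are comparable within the procedure only.
* The OSF-deposit reader is a column-mapping adapter over the same
  validated schema; deposits that contain only precomputed error
  distances (no raw coordinates) cannot be reconstructed into trials and
  are out of scope.
* With unequal group sizes the mixed ANOVA uses the weighted (cell-size)
  decomposition; the designs it targets are balanced.
* Published clinical correlation reports quote df = 227 for analyses run
  on an N = 56 imaging subset, which is internally inconsistent; this
  implementation always reports df = N − 2 for the sample actually
  correlated.
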