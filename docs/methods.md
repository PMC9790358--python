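# Methods

## Task generative model

The environment is a circle of 360 degrees.  A latent mean `mu_t` is
redrawn uniformly over `n_positions` (default 360) discrete locations at
the start of every block and thereafter with i.i.d. per-trial probability
`hazard` (default 0.125).  Change points carry no minimum separation and no
constraint that the new mean differ from the old (an optional `min_jump`
config reinstates such a constraint, default off).  The outcome is
`X_t = mu_t + epsilon_t (mod 360)` with `epsilon_t ~ N(0, noise_sd^2)`;
wrapped-normal sampling is implemented as a Gaussian draw followed by
`mod 360`, which is indistinguishable from a true wrapped normal at
`noise_sd = 12 << 360`.  The outcome noise SD and the bucket half-width are
not dictated by the task description; the defaults (12 and 20 degrees)
follow the adult lineage of this paradigm and are exposed in `TaskConfig`.
A hit is inclusive at the half-width boundary and scores +10; a miss −10.

All angular arithmetic uses the signed circular difference mapped to
(−180, 180], with the antipodal tie resolved to +180.  A `linear_geometry`
flag throughout the pipeline switches to plain differences on the 0–360
scale for comparison with analyses that ignored the wrap.

## Reduced Bayesian observer

The observer approximates full change-point filtering with a single belief
`B_t` and belief variance `sigma_mu,t^2`.  Given the prediction error
`delta_t = X_t − B_t` (circular), the change-point probability is the
posterior odds of the uniform (change) versus Gaussian (no-change)
likelihood:

    Omega_t = H u / (H u + (1 − H) N(delta_t; 0, sigma_N^2 + sigma_mu,t^2)),

with `u = 1/n_positions`.  Relative uncertainty is
`tau_t = sigma_mu,t^2 / (sigma_mu,t^2 + sigma_N^2)` (the Kalman gain of the
no-change regime) and the learning rate is
`alpha_t = Omega_t + (1 − Omega_t) tau_t`.  The belief moves by
`alpha_t delta_t` (wrapped) and the variance update mixes the two regimes:

    sigma_mu,t+1^2 = Omega sigma_N^2 + (1 − Omega) tau sigma_N^2
                     + Omega (1 − Omega) (delta (1 − tau))^2 .

At `Omega = 1` the variance resets to `sigma_N^2`; at `Omega = 0` it follows
the exact known-mean Kalman recursion, giving `sigma_mu,t^2 = sigma_N^2/t`
under a zero hazard — the property the grid-based full-Bayes oracle in the
test suite checks.  The exact variance-update formula used by the original
analysis is not restated in the available task description; the form above
is the standard reduced-Bayesian one for this paradigm and is labelled as
our adopted variant, not a quotation.

Initialisation: `B_1 = X_1`, `sigma_mu,1^2 = sigma_N^2` at each block start
(uninformative).  The observer is purely normative: its parameters are fixed
at the true generative values and nothing is fitted to behaviour.  The
Gaussian density uses the circular distance directly rather than a von
Mises likelihood; at these concentrations the two are numerically
indistinguishable and the Gaussian keeps the variance recursion exact.

Model confidence defaults to `(1 − Omega)(1 − tau)`, strictly decreasing in
each of its arguments; `neg_total_uncertainty` (−sigma_mu^2) and
`one_minus_alpha` variants are selectable.  Only monotonicity matters for
the peri-change-point comparisons the confidence signal feeds.

## Synthetic cohorts

Agents place a bucket and update it by `alpha_eff * delta_t` where
`delta_t` is the agent's own circular prediction error and `alpha_eff`
comes from the policy: a fixed value, the observer's `alpha_t` scaled by
`base_gain`, or the scaled `alpha_t` plus `smallpe_boost` whenever
`|delta_t| < smallpe_threshold` (8 degrees by default).  Negative effective
rates are clipped to zero.  Group presets: controls are observer-coupled
with gain 0.8 (slightly conservative normative learners); the patient
preset adds a +0.6 boost at small errors; the medicated-patient preset a
+0.15 boost.  These presets target the qualitative case-control pattern —
higher overall learning rate driven by small-error trials, equivalent
confidence — not any participant's numbers, which depend on unavailable
data.

Motor noise is signal-dependent: the placement noise SD is
`motor_noise_sd * (1 + motor_noise_weber * |intended move|)` degrees
(defaults 0.3 and 0.3), following the amplitude-scaled noise characteristic
of human motor control.  This choice is load-bearing: with purely additive
noise `epsilon`, the empirical learning rate `alpha + epsilon/delta` has
Cauchy-like tails at small `|delta|`, and single trials can move a group's
small-error bin mean by whole units, destroying any systematic pattern.
With amplitude-scaled noise the ratio's tails are controlled.
`motor_noise_sd = 0` gives an exactly noiseless agent, which the round-trip
identity tests rely on.

Confidence reports are `round(100 * confidence_gain * model_confidence +
N(0, confidence_noise_sd))` clamped to [1, 100] (defaults gain 1, noise SD
8 report points).  Per-subject session and behaviour seeds derive
deterministically from the cohort's master seed by subject index.

What the generator does not emulate: response times, within-session
learning or fatigue, dependence of motor noise on speed–accuracy tradeoffs,
non-Gaussian confidence usage (end-of-scale anchoring), and any coupling of
confidence policy to group.  Consequently a passing pipeline shows that the
analysis chain detects the patterns the generator encodes — not that those
patterns exhaust real data.  One known artifact: because tertile edges are
computed on each subject's own |delta| distribution, groups with different
tracking precision can show genuine binned-confidence profile differences
even though their confidence policies are identical.

## Trialwise measures

`delta_t = X_t − b_t` and `alpha_t = (b_{t+1} − b_t)/delta_t`, both
circular.  Exclusions: block-final trials (no next placement), zero-error
trials, and trials whose `alpha` strictly exceeds the 95th percentile of
all pooled retained `alpha` within the subject's group (linear-interpolation
quantile; only the upper tail is filtered, negative rates are retained).
Exclusion reasons are mutually exclusive; block-first trials are separately
flagged as unusable for the confidence regression (no previous-trial
predictors) without being excluded from the learning-rate analysis.
Confidence is z-scored within subject with the n−1 SD; constant confidence
is an error.  |delta| tertiles are per subject by default (a pooled mode is
behind a flag), linear-interpolation edges, ties to the lower bin.

Peri-change-point profiles average each measure at positions −4..+4 around
true change points whose full window fits inside a block; block-initial
forced resets are not counted as change points.

## Regressions

All three models are per-subject OLS with an intercept (statsmodels).  Hit
is coded 1/0.  The action response `alpha_t |delta_t|` equals the bucket
update projected onto the error direction.  Collinearity between `|delta|`
and `Omega|delta|` is tolerated unless the design is numerically
rank-deficient, which errors naming the offending columns; a predictor whose
hit factor has a single observed level (common in small-error-only refits,
where nearly every outcome is caught) is dropped as unidentifiable rather
than erroring.  The confidence model drops block-first trials only — the
response and its t−1 predictors are both well defined on block-final trials.
The small-error refit restricts the action model to small-tertile trials and
the confidence model to responses whose previous trial is small-tertile; the
coupling model is not refit (consecutive confidence differences do not
subset cleanly).  Beta comparisons are reported uncorrected across
predictors (a Bonferroni switch exists); the routing is Student t by
default, Welch t on a Levene rejection, rank-sum on a Shapiro–Wilk
rejection, all at alpha = .05, with the route logged.

## Group statistics

The rank-sum Z uses midranks, the tie-corrected variance and a 0.5
continuity correction; two-sided p from the normal approximation.  Effect
sizes: `r = |Z|/sqrt(N)` with N the total observations entering the test,
and `d = |t| sqrt(1/n1 + 1/n2)` (equal to the pooled-SD form for Student
inputs).  The mixed ANOVA takes its sums of squares from pingouin and
applies the Huynh–Feldt epsilon (capped at 1, and exactly 1 for a 2-level
within factor) to the within and interaction degrees of freedom.  The
Welch–James test is implemented for untrimmed means in Johansen's
linear-model formulation: the Wald statistic on the stacked group mean
vectors with block-diagonal `Sigma_j/n_j`, the A-correction summed over
groups, and `F = T/c` on `(q, q(q+2)/3A)` degrees of freedom; with two
groups and one measure it reduces exactly to Welch's t, which the tests
assert to 1e-8.  The three-group analysis uses Kruskal–Wallis (tie-corrected
chi-square) with the three pairwise rank-sum p values multiplied by 3 and
capped at 1.  Pearson correlations require at least 3 complete pairs and
error on zero variance.

## Numerical and scale choices

Problem sizes in the test and acceptance runs are chosen to make the checks
sharp at interactive cost: 1.2e5 trials for simulator calibration (3
binomial SEs around the hazard; 2% on the noise SD), 100 synthetic subjects
for regression recovery (±0.05 on mean betas), 500–1000 Monte-Carlo
replicates for type-I calibration ([0.03, 0.07] at nominal .05), and 20
cohorts of 73 subjects for the end-to-end pattern score.  The pattern
score's confidence clause is a true-null test by construction
(within-subject z-scores have mean ~0), so ~5% of seeds fail it by design;
the ≥18/20 margin absorbs this.  All angles are float degrees; quantiles
are the linear-interpolation dialect throughout so results are
bit-reproducible; every stochastic stage derives its seed from a single
master seed.

## Known limitations

* The observer's variance update and confidence map are adopted standard
  forms, not a transcription of the original implementation's appendix.
* The percentile filter pools trials across subjects within group; a
  per-subject variant is not provided.
* The Welch–James implementation does not support trimmed means.
* Group presets are qualitative stand-ins; none of the published group
  means, test statistics or p values on participant data are reproduction
  targets.
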