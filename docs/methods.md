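# Methods

This note documents the statistical procedures implemented in `scedmed`, the
choices made where the design was genuinely open, and what the synthetic data
do and do not establish about real data.

## Data model

One participant, two daily scores (a hypothesized mediator and an outcome) on
a shared integer time index (study day, 1-based, gaps allowed), with phase
labels forming contiguous blocks. The phase change is the manipulated
independent variable. Scores are stored as reals even when the instrument is
ordinal; declared `scale_bounds` are validated but nothing is rescaled.
`hypothesized_direction` declares, per variable, the sign of clinical
improvement (+1 higher-is-better, −1 lower-is-better); every significance
claim in the framework is gated on matching it.

**Missing data.** Two policies. `calendar` (default) keeps every day and lets
lag-based operations pair scores by calendar day, skipping incomplete pairs —
this preserves the timing information that mediation analysis depends on.
`listwise` deletes any day with either score missing and re-indexes time
consecutively, reproducing the common practice of analyzing the compressed
series; it distorts lags and is provided for comparability. Neither policy
imputes; imputation is out of scope.

## Tau-U

Between-phase level change counts all n_a·n_b later-minus-earlier pairwise
differences; S = P − N, Tau = S/n_pairs. Ties contribute 0 to S but stay in
the denominator. The within-phase trend uses the n(n−1)/2 forward-in-time
pairs (equivalently Kendall's S between scores and time). The
baseline-corrected variant subtracts the earlier phase's trend S from the
between-phase S while keeping the n_a·n_b denominator — the simplest reading
of "correcting the level change for baseline trend"; variants that enlarge
the denominator exist and are deliberately not implemented. The corrected Tau
can therefore exceed ±1 in extreme cases; it is reported unclipped.

**Inference.** Normal approximation on S. Between phases,
Var(S) = n_a·n_b·(n_a+n_b+1)/3 — four times the Mann–Whitney U variance,
since S = 2U − n_a·n_b; this is verified in tests against
`scipy.stats.mannwhitneyu`'s asymptotic p-value. Within phase,
Var(S) = n(n−1)(2n+5)/18, the Kendall S null variance. Confidence intervals
are Tau ± z·SD(S)/n_pairs, truncated to [−1, 1]; the default level is 0.90.
Limitations, stated as such: no tie correction in the variance, no continuity
correction, and independence of observations is assumed — positive
autocorrelation makes these tests anticonservative (quantified below).

## Piecewise regression

One joint OLS fit with cumulative coding: an intercept, global time re-zeroed
at the first observation, and per later phase an indicator switching on at
that phase's first observed day plus an interaction equal to time since that
day. With this coding the indicator coefficient *is* the immediacy estimate —
the gap at the boundary between the new phase's line and the previous
segment's extrapolation — and the interaction coefficient is the slope
change. The design is saturated per phase, so the joint fit reproduces the
per-phase separate regressions exactly (a tested identity). The within-phase
time origin at the *first observation of the new phase* is a choice; centering
at the last point of the previous phase would change the level-change estimate
when slopes differ, and is not offered.

Inference is classical OLS (homoskedastic, independent errors), two-sided
t-tests, no multiplicity adjustment, R² and the model F-test reported. No
autocorrelation correction is attempted — an AR-aware variant is explicitly a
non-goal. Degenerate inputs: a constant response gives a flagged fit with R²
and model p reported as not-applicable; rank-deficient designs (e.g., a phase
observed at a single day) raise an infeasibility error naming the terms.

## Cross-lagged correlations

r(k) is the Pearson correlation of the outcome at day t with the mediator at
day t + k, for k in −L..+L (default L = 5, a convention of interactive
time-series tools for SCEDs). Negative lags mean the mediator leads; they are
the mediation-relevant ones. Pairing is by calendar day (or compressed index
under listwise deletion) with pairwise-complete observations; n is reported
per lag because precision differs by lag; lags with fewer than 5 usable pairs
or zero variance are reported as not estimable rather than raised.

**Surrogate null.** Daily scores are autocorrelated, so the classical Pearson
test is invalid. Each observed series gets a lag-1 autocorrelation estimate
φ̂ (consecutive-day complete pairs, clipped to ±0.99); `reps` independent
Gaussian stationary AR(1) surrogate pairs are generated with the observed
lengths, φ̂'s and missingness patterns, and the empirical two-sided p at each
lag is (1 + #{|r_surrogate| ≥ |r_observed|}) / (1 + reps) — the standard
add-one Monte-Carlo convention, strictly positive and conservative by at most
1/(reps+1). The adjusted p compares |r_observed| against the null
distribution of the *maximum* |r| over all estimable lags, controlling the
family-wise error across lags; p_adjusted ≥ p always. Default reps = 5000; a
seed is required, making reports byte-reproducible. As φ̂ → 0 and n grows the
per-lag p converges to the classical Pearson p (tested at n = 500 within
0.02). An AR(1) null is a model choice: it captures the dominant serial
dependence of daily mood/symptom ratings but not seasonality or
heavy-tailedness; block permutation is not offered.

## The mediation framework

* **a path**: on the mediator, across the boundary between the first two
  phases — Tau-U between-phase level change, the trend-corrected variant
  *only when* the earlier phase's own trend is significant (otherwise there
  is nothing to correct), and the piecewise immediate-level-change and
  trend-change terms. Significant = any constituent test with p < α *and*
  sign matching the hypothesized improvement. This is deliberately a
  disjunction of complementary views (level, immediacy, trend) without
  multiplicity adjustment; the report lists each test so a user can apply a
  stricter conjunction. The cost is an inflated a-path type-I error (below).
* **c path**: identical machinery on the outcome; reported only.
* **b path**: cross-lagged correlations over the two phases spanning the
  intervention, using the *adjusted* p-values; significant = any lag ≤ 0
  with adjusted p < α and r matching the product of the two hypothesized
  directions. Strictly negative lags are "leading" support; lag 0 only
  "concurrent".
* **Temporal precedence** is graded: `supported` when the mediator changes at
  the boundary while the outcome's change emerges later (trend change without
  an immediate level change), or when a contiguous run of leading lags up to
  −1 is significant; `supported_with_caveats` when support is concurrent-only
  or from non-contiguous leading lags (a pattern that leaves the timing
  ambiguous); `not_supported` when the mediator shows no onset change and no
  leading/concurrent association exists.
* **Verdict**: joint significance — `consistent_with_mediation` iff a and b
  are both significant and precedence is not contradicted. The decision
  function does not take the c path as an argument, so a null total effect can
  never block the verdict. No numeric indirect effect (a·b product or c − c′)
  is computed: no agreed single-case analogue exists, and pretending
  otherwise would overstate the evidence.

How many days of lead still count as precedence is not a statistical
question; it is exposed as `max_lag` rather than resolved.

## Synthetic generator

`SynthConfig` defaults describe a realistic anxiety-treatment diary study:
three phases of 26/32/14 days, mediator base level 3 and outcome base level 6
on a 0–8 scale, intervention onset at the first day of phase two with an
immediate mediator shift `a_level = 2` and slope change `a_trend = 0.1`
points/day, mediator→outcome coefficient `b = −0.5` at a 2-day lag, AR(1)
noise with φ = 0.3 and innovation sd = 1.0, no missingness. The
`case_example_config()` preset adds 14.5% MCAR missingness, rounding to the
even grid {0,2,4,6,8}, and a withdrawal phase in which the intervention terms
are reversed (deterioration at follow-up). Missingness is MCAR only —
generating MNAR data would wrongly imply the analyses can handle it.
Discretisation is off by default because it breaks exact-recovery identities.

`simulate_operating_characteristics` estimates type-I error and power of each
path and of the joint verdict over an effect-size grid with binomial MC
standard errors.

**What passing tests show — and don't.** The generator produces Gaussian
AR(1) noise around piecewise-linear means with a single fixed lag and MCAR
missingness. Real diary data have floor/ceiling effects, integer scales,
possibly MNAR missingness (not reporting anxiety *because* of anxiety), drift
unrelated to treatment, and time-varying lags. Calibration and power results
on synthetic data are therefore statements about the methods under their own
assumptions, not about any particular clinical dataset.

## Measured operating characteristics (recomputed by the test suite and
`scripts/acceptance.py`)

Under a complete null (no effects, φ = 0.3, 26/32 days), the joint verdict
fires in well under 5% of replicates — the intersection of two ≈α-level gates
is strongly conservative — and detection of the verdict rises monotonically
with the a- and b-path effect sizes. The *individual* a-path disjunction is
calibrated near α on white-noise data (≈0.06 measured) but anticonservative
under φ = 0.3 (≈0.18–0.20 measured): each constituent test assumes
independence, and at φ = 0.3 a slope t-test's variance is understated by a
factor of about (1+φ)/(1−φ) ≈ 1.9. This is an honest property of the
implemented (and widely used) procedures, documented rather than patched; the
surrogate-based b path does not share it, which is why the joint verdict
stays conservative.

## Numerical details

* Tau p-values and CIs use `scipy.stats.norm`; S, P, N, ties are exact
  integer counts.
* OLS via `statsmodels`; design rank is checked before fitting.
* Surrogate AR(1) series via `scipy.signal.lfilter` with a stationary initial
  value; row-wise Pearson correlations are computed vectorised over all
  surrogates.
* All simulation entry points take integer seeds (numpy `default_rng` /
  `SeedSequence`); identical config + seed ⇒ byte-identical JSON reports.
* Problem sizes in the shipped simulations (e.g., 200–1000 replicates, 500
  surrogate draws) were chosen as the smallest runs whose binomial MC error
  is well below the margins being asserted.
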