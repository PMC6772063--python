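# scedmed

Mediation analysis for **single-case experimental designs** (SCEDs).

In an SCED, one participant is measured repeatedly — often daily — across
treatment phases (e.g., a baseline-like phase B, an intervention phase C, a
follow-up D). Clinicians and researchers often want to know not only *whether*
an intervention worked for that client but *through which mechanism*: did the
therapy improve a mediator (say, coping ability), and did that improvement in
turn drive the outcome (say, anxiety symptoms)? Group-level mediation tools
(the `a`/`b`/`c` path regressions of the single-mediator model) do not apply
to one participant's time series, so `scedmed` assembles the SCED equivalents:

* **a path** (phase → mediator) and **c path** (phase → outcome):
  * **Tau-U** — a nonoverlap effect size. All pairwise differences between a
    later and an earlier phase are counted by sign; with P positive, N
    negative pairs, S = P − N and Tau = S / n_pairs. A within-phase variant
    over forward-in-time pairs measures trend, and a corrected variant
    subtracts the earlier phase's trend S from the between-phase S.
    Inference uses the normal approximation for S
    (Var(S) = n_a·n_b·(n_a+n_b+1)/3 between phases; n(n−1)(2n+5)/18 within).
  * **Piecewise (segmented) regression** — one OLS fit whose coefficients are
    the first phase's level and trend plus, at each phase boundary, an
    immediate level change (the jump relative to the previous segment's
    extrapolated line) and a trend change.
* **b path** (mediator → outcome): **cross-lagged Pearson correlations**.
  A negative lag pairs each outcome score with an *earlier* mediator score
  (mediator leads). Because daily scores are autocorrelated, significance
  comes from a Monte-Carlo AR(1) surrogate null with a max-statistic
  correction across lags.
* **Verdict**: a *joint-significance* rule — evidence is
  `consistent_with_mediation` only when the a path and b path are both
  significant in the hypothesized directions *and* temporal precedence of the
  mediator's change is not contradicted. The c path (total effect) is
  reported but never required.

A ground-truth synthetic generator (`scedmed.synthetic`) emulates such
studies — bounded daily scores, phase-linked level/trend shifts, a lagged
mediator→outcome effect, AR(1) noise, MCAR missingness — so every stage and
the full framework are testable end to end.

## Worked example

Generate a synthetic study (26/32/14 days across phases B/C/D, an intervention
effect on the mediator from day 27, the outcome following the mediator with a
2-day lag) and analyze it:

```bash
scedmed simulate --out example.csv --seed 11
scedmed analyze --data example.csv --seed 11 --mc-reps 2000 --report report.json
```

which prints:

```
SCED mediation analysis
========================

a path (phase -> mediator): significant
  [+] tau_between[B->C]: stat=+0.971 p=0.0000
  [+] tau_between_corrected[B->C]: stat=+1.124 p=0.0000
  [+] piecewise_level_change: stat=+2.933 p=0.0000
  [+] piecewise_trend_change: stat=+0.179 p=0.0000
  ...

b path (mediator -> outcome): significant
  [+] crosslag[-2]: stat=-0.737 p=0.0010
  ...
  note: leading support at lag(s) [-5, -4, -3, -2, -1]

Temporal precedence: supported
  mediator shows a significant boundary-onset level change; outcome change
  emerges later (trend change without an immediate level change); ...

Verdict: consistent_with_mediation
```

Reading the numbers: the mediator's Tau-U of 0.97 between phases B and C means
near-complete nonoverlap (almost every phase-C score exceeds every phase-B
score); the piecewise level change of +2.93 is the immediate jump at the
boundary on the 0–8 score scale; the cross-lagged r = −0.74 at lag −2 says
higher coping *two days earlier* goes with lower anxiety today, with a
surrogate-adjusted p of 0.001. Both paths are significant in the hypothesized
directions and the mediator's change precedes the outcome's, so the pattern is
consistent with mediation. (It can never prove it: see `docs/methods.md`.)

The same analyses are available as library calls (`tau_between`,
`fit_piecewise`, `cross_lagged_correlations`, `mediation_report`, ...) and as
`scedmed tau` / `scedmed piecewise` subcommands.

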