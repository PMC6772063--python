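"""Joint-significance mediation framework for single-case designs.

The framework treats the phase change as the manipulated independent variable
and asks three questions, mirroring the a / b / c paths of the single-mediator
model:

* **a path** (phase -> mediator): did the mediator change at the intervention
  boundary?  Evidence: between-phase Tau-U level change (trend-corrected when
  the earlier phase itself shows a significant trend) and the piecewise
  immediate-level-change and trend-change terms.
* **b path** (mediator -> outcome): are mediator and outcome associated with
  the mediator leading?  Evidence: cross-lagged correlations at lags <= 0 with
  AR(1)-surrogate, max-statistic-adjusted p-values.
* **c path** (phase -> outcome): same machinery as the a path applied to the
  outcome.  It is reported for context but never gates the verdict - a
  significant total effect is not a prerequisite for mediation.

Evidence is combined by joint significance: the verdict is
``consistent_with_mediation`` only when the a path and the b path are both
significant (each with sign matching the hypothesized direction of
improvement) and temporal precedence of the mediator's change is not
contradicted.  Temporal precedence is graded: ``supported`` when the mediator
changes at the boundary while the outcome's change emerges later, or when a
contiguous run of strictly negative lags is significant; ``supported_with_
caveats`` when the support is concurrent (lag 0) or from non-contiguous
leading lags; ``not_supported`` otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import crosslag as _cl
from . import piecewise as _pw
from . import tau_u as _tau
from .core import (MissingPolicy, SCEDDataset, apply_missing_policy,
                   require_analyzable)
from .errors import InfeasibleError, SCEDError

__all__ = ["MediationConfig", "PathTest", "PathEvidence", "MediationEvidence",
           "evaluate_a_path", "evaluate_b_path", "evaluate_c_path",
           "assess_temporal_precedence", "mediation_report", "render_text"]


@dataclass(frozen=True)
class MediationConfig:
    """Analysis settings; ``seed`` drives the surrogate null and must be set."""

    seed: int
    alpha: float = 0.05
    ci_level: float = 0.90
    max_lag: int = 5
    reps: int = 5000
    missing: str = "calendar"

    def to_dict(self) -> dict:
        return {"seed": int(self.seed), "alpha": float(self.alpha),
                "ci_level": float(self.ci_level), "max_lag": int(self.max_lag),
                "reps": int(self.reps), "missing": self.missing}


@dataclass(frozen=True)
class PathTest:
    name: str
    statistic: float
    p_value: float
    direction_ok: bool

    def to_dict(self) -> dict:
        def num(x):
            return float(x) if np.isfinite(x) else None

        return {"name": self.name, "statistic": num(self.statistic),
                "p_value": num(self.p_value),
                "direction_ok": bool(self.direction_ok)}


@dataclass
class PathEvidence:
    """Evidence for one path: individual tests plus the gated conclusion.

    ``significant`` is true only if at least one constituent test has
    p < alpha AND its sign matches the hypothesized direction of improvement.
    """

    path: str
    tests: list = field(default_factory=list)
    significant: bool = False
    direction_ok: bool = False
    evaluable: bool = True
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"path": self.path, "tests": [t.to_dict() for t in self.tests],
                "significant": bool(self.significant),
                "direction_ok": bool(self.direction_ok),
                "evaluable": bool(self.evaluable), "notes": list(self.notes)}


@dataclass
class MediationEvidence:
    a: PathEvidence
    b: PathEvidence
    c: PathEvidence
    temporal_precedence: str
    precedence_rationale: str
    specificity_notes: list
    verdict: str
    config: MediationConfig
    tau_table: list = field(default_factory=list)
    piecewise_tables: dict = field(default_factory=dict)
    crosslag_table: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"a": self.a.to_dict(), "b": self.b.to_dict(),
                "c": self.c.to_dict(),
                "temporal_precedence": self.temporal_precedence,
                "precedence_rationale": self.precedence_rationale,
                "specificity_notes": list(self.specificity_notes),
                "verdict": self.verdict,
                "config": self.config.to_dict(),
                "tau": self.tau_table,
                "piecewise": self.piecewise_tables,
                "crosslag": self.crosslag_table}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _gate(tests: list, alpha: float) -> tuple[bool, bool]:
    sig = any(np.isfinite(t.p_value) and t.p_value < alpha and t.direction_ok
              for t in tests)
    direction = any(t.direction_ok for t in tests)
    return sig, direction


def _dir_ok(stat: float, expected_sign: int) -> bool:
    return bool(np.isfinite(stat) and stat != 0 and np.sign(stat) == expected_sign)


def _phase_change_tests(series, expected_sign: int, alpha: float,
                        ci_level: float, phases) -> tuple[list, dict]:
    """Tau-U and piecewise tests for a phase-driven change in one variable.

    The intervention boundary is between the first two phases.  The corrected
    Tau-U comparison is added only when the earlier phase's own trend is
    significant (otherwise there is nothing to correct for).
    """
    p0, p1 = phases[0], phases[1]
    a_vals = series.phase_values(p0)
    b_vals = series.phase_values(p1)
    tests: list = []
    extras: dict = {}

    tb = _tau.tau_between(a_vals, b_vals, ci_level, phases=(p0, p1))
    tests.append(PathTest(f"tau_between[{p0}->{p1}]", tb.tau, tb.p_value,
                          _dir_ok(tb.tau, expected_sign)))
    extras["tau_between"] = tb

    baseline_trend = _tau.tau_trend(a_vals, ci_level, phases=(p0,))
    extras["tau_trend_baseline"] = baseline_trend
    if baseline_trend.p_value < alpha:
        tc = _tau.tau_between_corrected(a_vals, b_vals, ci_level, phases=(p0, p1))
        tests.append(PathTest(f"tau_between_corrected[{p0}->{p1}]", tc.tau,
                              tc.p_value, _dir_ok(tc.tau, expected_sign)))
        extras["tau_between_corrected"] = tc

    fit = _pw.fit_piecewise(series)
    extras["piecewise_fit"] = fit
    level = fit.coef("phase")
    trend = fit.coef("phase_time2")
    tests.append(PathTest("piecewise_level_change", level, fit.pvalue("phase"),
                          _dir_ok(level, expected_sign)))
    tests.append(PathTest("piecewise_trend_change", trend,
                          fit.pvalue("phase_time2"),
                          _dir_ok(trend, expected_sign)))
    return tests, extras


def evaluate_a_path(ds: SCEDDataset, alpha: float = 0.05,
                    ci_level: float = 0.90) -> PathEvidence:
    """Phase -> mediator evidence across the intervention boundary."""
    require_analyzable(ds)
    expected = int(ds.hypothesized_direction["mediator"])
    ev = PathEvidence(path="a")
    try:
        tests, extras = _phase_change_tests(ds.mediator, expected, alpha,
                                            ci_level, ds.phase_order)
    except SCEDError as exc:
        ev.evaluable = False
        ev.notes.append(f"not evaluable: {exc}")
        return ev
    ev.tests = tests
    ev.significant, ev.direction_ok = _gate(tests, alpha)
    ev.notes.append("disjunction over Tau-U level change and piecewise "
                    "level/trend change; no multiplicity adjustment across "
                    "these complementary tests")
    ev._extras = extras  # stashed for the report builder
    return ev


def evaluate_c_path(ds: SCEDDataset, alpha: float = 0.05,
                    ci_level: float = 0.90) -> PathEvidence:
    """Phase -> outcome (total effect); reported, never required."""
    require_analyzable(ds)
    expected = int(ds.hypothesized_direction["outcome"])
    ev = PathEvidence(path="c")
    try:
        tests, extras = _phase_change_tests(ds.outcome, expected, alpha,
                                            ci_level, ds.phase_order)
    except SCEDError as exc:
        ev.evaluable = False
        ev.notes.append(f"not evaluable: {exc}")
        return ev
    ev.tests = tests
    ev.significant, ev.direction_ok = _gate(tests, alpha)
    ev._extras = extras
    return ev


def evaluate_b_path(ds: SCEDDataset, alpha: float = 0.05, max_lag: int = 5,
                    reps: int = 5000, seed: int | None = None) -> PathEvidence:
    """Mediator -> outcome evidence from cross-lagged correlations.

    Computed over the two phases spanning the intervention boundary.  A lag
    counts as support when its max-statistic adjusted p is below alpha and the
    sign of r matches the product of the two hypothesized improvement
    directions.  Strictly negative significant lags are "leading" support;
    lag 0 is only "concurrent".
    """
    require_analyzable(ds)
    expected = (int(ds.hypothesized_direction["mediator"])
                * int(ds.hypothesized_direction["outcome"]))
    sub = ds.subset_phases(ds.phase_order[:2])
    ev = PathEvidence(path="b")
    try:
        result = _cl.cross_lagged_correlations(sub.mediator, sub.outcome, max_lag)
        result = _cl.surrogate_p_values(sub.mediator, sub.outcome, result,
                                        reps=reps, seed=seed)
    except InfeasibleError as exc:
        ev.evaluable = False
        ev.notes.append(f"not evaluable: {exc}")
        return ev
    for k in result.lags:
        if k > 0:
            continue
        r = result.r[k]
        ev.tests.append(PathTest(f"crosslag[{k}]", r,
                                 result.p_adjusted.get(k, float("nan")),
                                 _dir_ok(r, expected)))
    ev.significant, ev.direction_ok = _gate(ev.tests, alpha)
    neg = sorted(k for k in result.lags
                 if k < 0 and np.isfinite(result.p_adjusted.get(k, np.nan))
                 and result.p_adjusted[k] < alpha
                 and _dir_ok(result.r[k], expected))
    lag0 = (np.isfinite(result.p_adjusted.get(0, np.nan))
            and result.p_adjusted[0] < alpha
            and _dir_ok(result.r.get(0, float("nan")), expected))
    if neg:
        ev.notes.append(f"leading support at lag(s) {neg}")
    if lag0:
        ev.notes.append("concurrent (lag 0) support")
    ev._crosslag = result
    ev._neg_sig = neg
    ev._lag0_sig = bool(lag0)
    return ev


def combine_verdict(a: PathEvidence, b: PathEvidence,
                    temporal_precedence: str) -> str:
    """Joint-significance decision rule.

    The c path is deliberately not an argument: a significant total effect is
    neither required nor able to block the verdict.
    """
    if not (a.evaluable and b.evaluable):
        return "inconclusive"
    if a.significant and b.significant \
            and temporal_precedence != "not_supported":
        return "consistent_with_mediation"
    if not a.significant and not b.significant:
        return "no_evidence"
    return "inconclusive"


def assess_temporal_precedence(fit_m: "_pw.PiecewiseFit | None",
                               fit_y: "_pw.PiecewiseFit | None",
                               clr: "_cl.CrossLagResult | None",
                               alpha: float,
                               directions: dict) -> tuple[str, str]:
    """Grade whether the mediator's change preceded the outcome's.

    Returns (flag, rationale) with flag in {supported, supported_with_caveats,
    not_supported}.
    """
    dir_m = int(directions["mediator"])
    dir_y = int(directions["outcome"])
    exp_b = dir_m * dir_y

    def term_sig(fit, term, sign):
        if fit is None or term not in fit.params.index:
            return False
        return (fit.pvalue(term) < alpha
                and _dir_ok(fit.coef(term), sign))

    med_level = term_sig(fit_m, "phase", dir_m)
    med_trend = term_sig(fit_m, "phase_time2", dir_m)
    out_level = term_sig(fit_y, "phase", dir_y)
    out_trend = term_sig(fit_y, "phase_time2", dir_y)
    med_onset = med_level or med_trend
    outcome_delayed = out_trend and not out_level

    neg_sig: list = []
    lag0_sig = False
    if clr is not None and clr.p_adjusted:
        for k in clr.lags:
            pa = clr.p_adjusted.get(k, float("nan"))
            if not np.isfinite(pa) or pa >= alpha:
                continue
            if not _dir_ok(clr.r[k], exp_b):
                continue
            if k < 0:
                neg_sig.append(k)
            elif k == 0:
                lag0_sig = True
    neg_sig.sort()
    contiguous = bool(neg_sig) and max(neg_sig) == -1 \
        and neg_sig == list(range(min(neg_sig), 0))

    reasons = []
    if med_onset:
        what = "level" if med_level else "trend"
        reasons.append(f"mediator shows a significant boundary-onset {what} change")
    if outcome_delayed:
        reasons.append("outcome change emerges later (trend change without an "
                       "immediate level change)")
    if neg_sig:
        kind = "contiguous" if contiguous else "non-contiguous"
        reasons.append(f"{kind} leading lag(s) {neg_sig} significant")
    if lag0_sig:
        reasons.append("concurrent (lag 0) association significant")

    if (med_onset and outcome_delayed) or contiguous:
        flag = "supported"
    elif med_onset or neg_sig or lag0_sig:
        flag = "supported_with_caveats"
    else:
        flag = "not_supported"
        reasons.append("no mediator onset change and no leading or concurrent "
                       "association")
    return flag, "; ".join(reasons)


def _specificity_notes(extras_m: dict, extras_y: dict, ds: SCEDDataset,
                       alpha: float, ci_level: float) -> list:
    notes = []
    fit_m = extras_m.get("piecewise_fit")
    if fit_m is not None:
        p = fit_m.pvalue("phase")
        verb = "significant" if p < alpha else "not significant"
        notes.append(f"mediator immediate level change at the intervention "
                     f"boundary is {verb} (p={p:.3g})")
    for name, series in (("mediator", ds.mediator), ("outcome", ds.outcome)):
        signs = []
        for ph in ds.phase_order:
            vals = series.phase_values(ph)
            if vals.size >= 3:
                signs.append((ph, np.sign(_tau.tau_trend(vals, ci_level).tau)))
        for (p0, s0), (p1, s1) in zip(signs, signs[1:]):
            if s0 != 0 and s1 != 0 and s0 != s1:
                notes.append(f"{name}: within-phase trend direction reverses "
                             f"between phases {p0} and {p1}")
    return notes


def mediation_report(ds: SCEDDataset, config: MediationConfig
                     ) -> MediationEvidence:
    """Run all stages and combine them into a verdict.

    Fully deterministic under a fixed config (the seed drives the surrogate
    null).  A stage that is infeasible on these data marks its path
    "not evaluable" and forces an inconclusive verdict rather than failing.
    """
    ds = apply_missing_policy(ds, MissingPolicy(config.missing))
    require_analyzable(ds)

    a = evaluate_a_path(ds, config.alpha, config.ci_level)
    c = evaluate_c_path(ds, config.alpha, config.ci_level)
    b = evaluate_b_path(ds, config.alpha, config.max_lag, config.reps,
                        config.seed)

    extras_m = getattr(a, "_extras", {})
    extras_y = getattr(c, "_extras", {})
    clr = getattr(b, "_crosslag", None)
    flag, rationale = assess_temporal_precedence(
        extras_m.get("piecewise_fit"), extras_y.get("piecewise_fit"), clr,
        config.alpha, ds.hypothesized_direction)

    verdict = combine_verdict(a, b, flag)

    tau_table = []
    for label, extras in (("mediator", extras_m), ("outcome", extras_y)):
        for key in ("tau_trend_baseline", "tau_between", "tau_between_corrected"):
            if key in extras:
                row = extras[key].to_dict()
                row["variable"] = label
                tau_table.append(row)
    piecewise_tables = {label: extras["piecewise_fit"].to_dict()
                        for label, extras in (("mediator", extras_m),
                                              ("outcome", extras_y))
                        if "piecewise_fit" in extras}
    crosslag_table = clr.to_dict() if clr is not None else {}
    spec_notes = _specificity_notes(extras_m, extras_y, ds, config.alpha,
                                    config.ci_level)
    return MediationEvidence(a, b, c, flag, rationale, spec_notes, verdict,
                             config, tau_table, piecewise_tables,
                             crosslag_table)


def render_text(ev: MediationEvidence) -> str:
    """Human-readable summary of a mediation report."""
    lines = ["SCED mediation analysis", "=" * 24]
    for path, label in (("a", "a path (phase -> mediator)"),
                        ("b", "b path (mediator -> outcome)"),
                        ("c", "c path (phase -> outcome, not required)")):
        pe: PathEvidence = getattr(ev, path)
        status = ("NOT EVALUABLE" if not pe.evaluable
                  else "significant" if pe.significant else "not significant")
        lines.append(f"\n{label}: {status}")
        for t in pe.tests:
            pv = "NA" if not np.isfinite(t.p_value) else f"{t.p_value:.4f}"
            arrow = "+" if t.direction_ok else "-"
            lines.append(f"  [{arrow}] {t.name}: stat={t.statistic:+.3f} p={pv}")
        for n in pe.notes:
            lines.append(f"  note: {n}")
    lines.append(f"\nTemporal precedence: {ev.temporal_precedence}")
    lines.append(f"  {ev.precedence_rationale}")
    if ev.specificity_notes:
        lines.append("Specificity:")
        for n in ev.specificity_notes:
            lines.append(f"  - {n}")
    lines.append(f"\nVerdict: {ev.verdict}")
    lines.append("(joint significance of the a and b paths; the c path never "
                 "gates the verdict)")
    return "\n".join(lines)
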