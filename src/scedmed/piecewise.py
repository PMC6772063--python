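"""Segmented (piecewise) OLS regression across phases.

One joint OLS model fits a separate line to each phase, parameterised so each
coefficient answers a clinical question directly.  With k phases the design
has 2k columns:

* ``intercept`` - expected score at the first observed time point,
* ``time1``     - slope (trend) in the first phase,
* per later phase j: an indicator that switches on at the first observation of
  phase j and stays on (its coefficient is the immediate level change at the
  phase boundary, i.e. the gap between the new line and the previous segment's
  extrapolation), and an interaction equal to time since the start of phase j
  (its coefficient is the change in slope at that boundary).

For three phases the terms are, in order: intercept, time1, phase,
phase_time2, phase2, phase2_time3.  Because the design is saturated per phase,
the joint fit reproduces exactly the per-phase separate simple regressions;
the parameterisation only changes what the coefficients mean.

Inference is classical OLS (homoskedastic, independent errors), two-sided
t-tests, no multiplicity adjustment.  Serial correlation in daily scores makes
these p-values approximate; no autocorrelation correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import SCEDSeries
from .errors import InfeasibleError

__all__ = ["PiecewiseDesign", "PiecewiseFit", "SegmentLines", "build_design",
           "fit_piecewise", "predict_segments", "term_names"]


def term_names(n_phases: int) -> list[str]:
    """Column names for a k-phase design (2k columns)."""
    names = ["intercept", "time1"]
    for j in range(2, n_phases + 1):
        base = "phase" if j == 2 else f"phase{j - 1}"
        names += [base, f"{base}_time{j}"]
    return names


@dataclass
class PiecewiseDesign:
    """Design matrix for a segmented fit, with the response aligned to it."""

    X: pd.DataFrame
    y: np.ndarray
    time: np.ndarray
    phase: np.ndarray
    phase_starts: dict  # phase label -> first observed time in that phase

    @property
    def terms(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class PiecewiseFit:
    """Coefficient table plus model-level summaries of a segmented OLS fit."""

    params: pd.DataFrame  # index = term; columns estimate, se, t, p
    r_squared: float
    model_p: float
    residuals: np.ndarray
    fitted: np.ndarray
    df_resid: int
    design: PiecewiseDesign
    degenerate: bool = False  # zero response variance: R^2 / model p undefined

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def to_dict(self) -> dict:
        def num(x):
            return float(x) if np.isfinite(x) else None

        rows = [{"term": t,
                 "estimate": num(r["estimate"]),
                 "se": num(r["se"]),
                 "t": num(r["t"]),
                 "p": num(r["p"])} for t, r in self.params.iterrows()]
        return {"terms": rows,
                "r_squared": None if self.degenerate else float(self.r_squared),
                "model_p": None if self.degenerate else float(self.model_p),
                "df_resid": int(self.df_resid),
                "degenerate": bool(self.degenerate)}


def build_design(series: SCEDSeries) -> PiecewiseDesign:
    """Build the cumulative-coding segmented design from a series.

    Missing observations are dropped; time columns use the series' own time
    index (calendar days, or the compressed index after listwise deletion).
    Requires >= 2 phases and, per phase, >= 3 non-missing observations at >= 2
    distinct time points.
    """
    keep = np.isfinite(series.value)
    t = series.time[keep].astype(float)
    y = series.value[keep]
    ph = series.phase[keep]
    phases = []
    for p in ph:
        if not phases or p != phases[-1]:
            phases.append(p)
    if len(phases) < 2:
        raise InfeasibleError("piecewise regression needs at least 2 phases")
    for p in phases:
        tp = t[ph == p]
        if tp.size < 3 or np.unique(tp).size < 2:
            raise InfeasibleError(
                f"phase {p!r}: need >= 3 non-missing observations at >= 2 "
                f"distinct time points")
    starts = {p: float(t[ph == p][0]) for p in phases}
    cols = {"intercept": np.ones_like(t), "time1": t - t[0]}
    names = term_names(len(phases))
    for j, p in enumerate(phases[1:], start=2):
        on = (t >= starts[p]).astype(float)
        base = names[2 * (j - 1)]
        cols[base] = on
        cols[f"{base}_time{j}"] = (t - starts[p]) * on
    X = pd.DataFrame(cols)[names]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise InfeasibleError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns); "
            f"terms {names} are collinear on these data")
    return PiecewiseDesign(X, y, t, ph, starts)


def fit_piecewise(series: SCEDSeries) -> PiecewiseFit:
    """OLS fit of the segmented design with classical standard errors."""
    design = build_design(series)
    res = sm.OLS(design.y, design.X).fit()
    params = pd.DataFrame({"estimate": res.params, "se": res.bse,
                           "t": res.tvalues, "p": res.pvalues})
    degenerate = bool(np.var(design.y) == 0.0)
    if degenerate:
        r2, model_p = float("nan"), float("nan")
    else:
        r2, model_p = float(res.rsquared), float(res.f_pvalue)
    return PiecewiseFit(params, r2, model_p, np.asarray(res.resid),
                        np.asarray(res.fittedvalues), int(res.df_resid),
                        design, degenerate)


@dataclass
class SegmentLines:
    """Per-phase fitted lines and per-boundary immediate level changes."""

    lines: list = field(default_factory=list)   # (phase, start_time, start_value, slope)
    gaps: list = field(default_factory=list)    # (phase, boundary_time, gap)


def predict_segments(fit: PiecewiseFit) -> SegmentLines:
    """Per-phase (start value, slope) and the vertical gap at each boundary.

    The gap is computed geometrically - new line minus the previous segment's
    extrapolation at the boundary time - and equals the corresponding phase
    indicator coefficient by construction of the design.
    """
    d = fit.design
    phases = list(d.phase_starts)
    names = term_names(len(phases))
    b = {t: fit.coef(t) for t in names}
    out = SegmentLines()
    t0 = d.time[0]

    def line_value(phase_idx: int, t: float) -> float:
        """Evaluate phase ``phase_idx``'s fitted line at time t (extrapolating)."""
        v = b["intercept"] + b["time1"] * (t - t0)
        for j in range(2, phase_idx + 2):
            base = names[2 * (j - 1)]
            v += b[base] + b[f"{base}_time{j}"] * (t - d.phase_starts[phases[j - 1]])
        return v

    for idx, p in enumerate(phases):
        st = d.phase_starts[p]
        sl = b["time1"] + sum(b[names[2 * (j - 1) + 1]] for j in range(2, idx + 2))
        out.lines.append((p, st, line_value(idx, st), sl))
        if idx > 0:
            gap = line_value(idx, st) - line_value(idx - 1, st)
            out.gaps.append((p, st, gap))
    return out
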