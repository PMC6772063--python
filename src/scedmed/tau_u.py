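"""Tau-U nonoverlap effect sizes for phase comparisons in single-case designs.

Tau-U compares every score of a later phase with every score of an earlier
phase (between-phase level change), or every forward-in-time pair within one
phase (within-phase trend).  With P positive, N negative and T tied pairwise
differences, S = P - N and Tau = S / n_pairs.  The baseline-trend-corrected
variant subtracts the earlier phase's within-phase S from the between-phase S
before scaling, so a pre-existing improvement trend is not credited to the
phase change.

Inference uses the large-sample normal approximation for the S statistic:
Var(S) = n_a * n_b * (n_a + n_b + 1) / 3 for between-phase comparisons (four
times the Mann-Whitney U variance, since S = 2U - n_a n_b) and
Var(S) = n (n - 1) (2 n + 5) / 18 for the within-phase trend (the Kendall S
variance).  Ties contribute zero to S but
stay in the denominator; no tie correction is applied to the variance, which
is a documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InfeasibleError


@dataclass(frozen=True)
class PairCounts:
    """Sign counts of pairwise difference scores."""

    positives: int
    negatives: int
    ties: int

    @property
    def s(self) -> int:
        return self.positives - self.negatives

    @property
    def n_pairs(self) -> int:
        return self.positives + self.negatives + self.ties


@dataclass(frozen=True)
class TauUResult:
    """One Tau-U comparison with its normal-approximation inference.

    ``kind`` is ``between_level``, ``within_trend`` or ``corrected_between``.
    For the corrected kind, ``trend_correction_s`` records the earlier phase's
    within-phase S that was subtracted; the tau = S / n_pairs identity holds
    only for the uncorrected kinds.
    """

    kind: str
    tau: float
    counts: PairCounts
    p_value: float
    ci: tuple[float, float]
    ci_level: float
    phases_compared: tuple = ()
    trend_correction_s: int = 0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "tau": float(self.tau),
            "p_value": float(self.p_value),
            "ci": [float(self.ci[0]), float(self.ci[1])],
            "ci_level": float(self.ci_level),
            "s": int(self.counts.s),
            "n_pairs": int(self.counts.n_pairs),
            "positives": int(self.counts.positives),
            "negatives": int(self.counts.negatives),
            "ties": int(self.counts.ties),
            "phases_compared": list(self.phases_compared),
            "trend_correction_s": int(self.trend_correction_s),
        }


def _clean(x, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InfeasibleError(f"{what}: need a non-empty 1-D score vector")
    if not np.all(np.isfinite(x)):
        raise InfeasibleError(f"{what}: missing values must be removed first")
    return x


def pair_counts_between(a, b) -> PairCounts:
    """Count signs of all later-minus-earlier pairwise differences.

    ``a`` holds the earlier phase's scores, ``b`` the later phase's; each of the
    len(a)*len(b) differences is b_j - a_i.
    """
    a = _clean(a, "earlier phase")
    b = _clean(b, "later phase")
    d = b[None, :] - a[:, None]
    return PairCounts(int((d > 0).sum()), int((d < 0).sum()), int((d == 0).sum()))


def pair_counts_trend(x) -> PairCounts:
    """Count signs of all forward-in-time pairs within one phase: n(n-1)/2 pairs."""
    x = _clean(x, "phase")
    if x.size < 2:
        raise InfeasibleError("within-phase trend needs at least 2 observations")
    i, j = np.triu_indices(x.size, k=1)
    d = x[j] - x[i]
    return PairCounts(int((d > 0).sum()), int((d < 0).sum()), int((d == 0).sum()))


def _var_s(kind: str, n_a: int, n_b: int) -> float:
    # Null variances of the S statistic itself (not of the Mann-Whitney U):
    # between phases S = 2U - n_a*n_b, so Var(S) = 4 Var(U).
    if kind == "within_trend":
        n = n_a
        return n * (n - 1) * (2 * n + 5) / 18.0
    return n_a * n_b * (n_a + n_b + 1) / 3.0


def tau_inference(counts: PairCounts, kind: str, n_a: int, n_b: int,
                  ci_level: float = 0.90, s: int | None = None
                  ) -> tuple[float, tuple[float, float]]:
    """Two-sided normal p-value and CI for an S statistic.

    ``s`` overrides ``counts.s`` (used by the trend-corrected comparison, whose
    numerator is not the raw between-phase S).  The CI is
    tau +/- z * SD(S)/n_pairs, truncated to [-1, 1].
    """
    s_val = counts.s if s is None else s
    sd = np.sqrt(_var_s(kind, n_a, n_b))
    if sd == 0:
        raise InfeasibleError("degenerate comparison: zero-variance S statistic")
    z = s_val / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    tau = s_val / counts.n_pairs
    zcrit = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    half = zcrit * sd / counts.n_pairs
    lo, hi = max(-1.0, tau - half), min(1.0, tau + half)
    return p, (float(lo), float(hi))


def tau_between(a, b, ci_level: float = 0.90, phases=()) -> TauUResult:
    """Between-phase level change: Tau = S / (n_a * n_b)."""
    a = _clean(a, "earlier phase")
    b = _clean(b, "later phase")
    counts = pair_counts_between(a, b)
    p, ci = tau_inference(counts, "between_level", a.size, b.size, ci_level)
    return TauUResult("between_level", counts.s / counts.n_pairs, counts, p, ci,
                      ci_level, tuple(phases))


def tau_trend(x, ci_level: float = 0.90, phases=()) -> TauUResult:
    """Within-phase trend: Tau over all n(n-1)/2 forward pairs."""
    x = _clean(x, "phase")
    counts = pair_counts_trend(x)
    p, ci = tau_inference(counts, "within_trend", x.size, x.size, ci_level)
    return TauUResult("within_trend", counts.s / counts.n_pairs, counts, p, ci,
                      ci_level, tuple(phases))


def tau_between_corrected(a, b, ci_level: float = 0.90, phases=()) -> TauUResult:
    """Between-phase level change corrected for the earlier phase's trend.

    The corrected numerator is S_between - S_trend(a); the denominator stays
    n_a * n_b and the between-phase variance is used for inference.
    """
    a = _clean(a, "earlier phase")
    b = _clean(b, "later phase")
    if a.size < 2:
        raise InfeasibleError("trend correction needs >= 2 earlier-phase scores")
    counts = pair_counts_between(a, b)
    s_trend = pair_counts_trend(a).s
    s_corr = counts.s - s_trend
    p, ci = tau_inference(counts, "corrected_between", a.size, b.size, ci_level,
                          s=s_corr)
    return TauUResult("corrected_between", s_corr / counts.n_pairs, counts, p, ci,
                      ci_level, tuple(phases), trend_correction_s=int(s_trend))
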