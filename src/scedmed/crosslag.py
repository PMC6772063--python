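"""Cross-lagged Pearson correlations with an AR(1) surrogate null.

The cross-lagged correlation at lag k pairs the outcome at day t with the
mediator at day t + k.  A *negative* lag therefore means the mediator leads:
at lag -1 each outcome score is compared with the mediator score of one day
earlier.  Lags are computed from -max_lag to +max_lag (default 5).

Daily scores are autocorrelated, so the classical Pearson test is
anticonservative.  Significance here comes from a Monte-Carlo surrogate null:
fit a lag-1 autocorrelation to each observed series, generate many independent
Gaussian AR(1) surrogate pairs with the same lengths, autocorrelations and
missingness pattern, and compare |r_observed| with the surrogate distribution.
A max-statistic adjusted p-value (comparing against the null distribution of
the maximum |r| across all lags) controls for testing many lags at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import SCEDSeries
from .errors import ConfigurationError, InfeasibleError

MIN_PAIRS = 5  # fewer usable pairs than this makes a lag unreportable


@dataclass
class CrossLagResult:
    lags: list
    r: dict            # lag -> Pearson r (NaN when not estimable)
    n: dict            # lag -> usable pairs
    p: dict = field(default_factory=dict)           # per-lag empirical p
    p_adjusted: dict = field(default_factory=dict)  # max-statistic adjusted p
    method: str = "monte_carlo"
    reps: int = 0
    seed: int | None = None
    notes: dict = field(default_factory=dict)       # lag -> reason not estimable
    phi: tuple = (0.0, 0.0)                         # fitted (phi_m, phi_y)

    def to_dict(self) -> dict:
        def num(x):
            return None if x is None or not np.isfinite(x) else float(x)
        return {"lags": [int(k) for k in self.lags],
                "r": {str(k): num(self.r[k]) for k in self.lags},
                "n": {str(k): int(self.n[k]) for k in self.lags},
                "p": {str(k): num(self.p.get(k, np.nan)) for k in self.lags},
                "p_adjusted": {str(k): num(self.p_adjusted.get(k, np.nan))
                               for k in self.lags},
                "method": self.method, "reps": int(self.reps),
                "seed": self.seed,
                "phi": [float(self.phi[0]), float(self.phi[1])],
                "notes": {str(k): v for k, v in self.notes.items()}}


def _lag_indices(m: SCEDSeries, y: SCEDSeries, lag: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Positions (into m, into y) pairing y at day t with m at day t + lag.

    Pairing is by the series' time index (calendar days, or the compressed
    index after listwise deletion); days absent from either index are skipped,
    as are pairs where either value is missing.
    """
    pos = {int(t): i for i, t in enumerate(m.time)}
    im, iy = [], []
    for j, t in enumerate(y.time):
        i = pos.get(int(t) + lag)
        if i is not None:
            im.append(i)
        else:
            continue
        iy.append(j)
    im = np.asarray(im, dtype=int)
    iy = np.asarray(iy, dtype=int)
    if im.size:
        ok = np.isfinite(m.value[im]) & np.isfinite(y.value[iy])
        im, iy = im[ok], iy[ok]
    return im, iy


def lagged_pairs(m: SCEDSeries, y: SCEDSeries, lag: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (mediator, outcome) values at a given lag.

    Raises :class:`InfeasibleError` when fewer than 5 usable pairs remain.
    """
    if abs(lag) >= len(m.time):
        raise InfeasibleError(f"|lag| {abs(lag)} >= series length {len(m.time)}")
    im, iy = _lag_indices(m, y, lag)
    if im.size < MIN_PAIRS:
        raise InfeasibleError(f"lag {lag}: only {im.size} usable pair(s); "
                              f"need >= {MIN_PAIRS}")
    return m.value[im], y.value[iy]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def cross_lagged_correlations(m: SCEDSeries, y: SCEDSeries,
                              max_lag: int = 5) -> CrossLagResult:
    """Pearson r at every lag in -max_lag..+max_lag.

    Lags with too few pairs or zero variance are reported as NaN with a note,
    not raised as errors.
    """
    usable_m = int(np.isfinite(m.value).sum())
    usable_y = int(np.isfinite(y.value).sum())
    if min(usable_m, usable_y) < max_lag + MIN_PAIRS:
        raise InfeasibleError(
            f"need >= {max_lag + MIN_PAIRS} usable points per series for "
            f"max_lag={max_lag}; have {usable_m} and {usable_y}")
    lags = list(range(-max_lag, max_lag + 1))
    r, n, notes = {}, {}, {}
    for k in lags:
        im, iy = _lag_indices(m, y, k)
        n[k] = int(im.size)
        if im.size < MIN_PAIRS:
            r[k] = float("nan")
            notes[k] = f"only {im.size} usable pairs"
            continue
        val = _pearson(m.value[im], y.value[iy])
        r[k] = val
        if not np.isfinite(val):
            notes[k] = "zero variance in a lagged slice"
    return CrossLagResult(lags, r, n, notes=notes)


# ---------------------------------------------------------------------------
# Surrogate null
# ---------------------------------------------------------------------------

def lag1_autocorr(series: SCEDSeries) -> float:
    """Lag-1 autocorrelation over consecutive-day complete pairs, clipped to
    (-0.99, 0.99); 0 when fewer than 5 such pairs exist."""
    im, iy = _lag_indices(series, series, -1)  # value at t vs value at t-1
    if im.size < MIN_PAIRS:
        return 0.0
    val = _pearson(series.value[im], series.value[iy])
    if not np.isfinite(val):
        return 0.0
    return float(np.clip(val, -0.99, 0.99))


def _ar1_matrix(rng: np.random.Generator, reps: int, n: int, phi: float
                ) -> np.ndarray:
    """reps x n stationary Gaussian AR(1) draws with unit innovation variance."""
    e = rng.standard_normal((reps, n))
    if phi != 0.0:
        e[:, 0] /= np.sqrt(1.0 - phi * phi)
        return lfilter([1.0], [1.0, -phi], e, axis=1)
    return e


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((A * A).sum(axis=1) * (B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (A * B).sum(axis=1) / denom


def surrogate_p_values(m: SCEDSeries, y: SCEDSeries, result: CrossLagResult,
                       reps: int = 5000, seed: int | None = None
                       ) -> CrossLagResult:
    """Fill per-lag empirical p and max-statistic adjusted p in ``result``.

    Surrogates are independent Gaussian AR(1) pairs matching each observed
    series' length, fitted lag-1 autocorrelation and missingness pattern, so
    the usable pair count per lag is identical to the observed one.  p-values
    use the (1 + count) / (1 + reps) Monte-Carlo convention and are
    deterministic under a fixed seed.
    """
    if reps < 100:
        raise ConfigurationError(f"reps must be >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    phi_m = lag1_autocorr(m)
    phi_y = lag1_autocorr(y)
    Msur = _ar1_matrix(rng, reps, len(m.time), phi_m)
    Ysur = _ar1_matrix(rng, reps, len(y.time), phi_y)
    # propagate the observed missingness so surrogate pair counts match
    Msur[:, ~np.isfinite(m.value)] = np.nan
    Ysur[:, ~np.isfinite(y.value)] = np.nan

    estimable = [k for k in result.lags if np.isfinite(result.r[k])]
    abs_r_sur = {}
    for k in estimable:
        im, iy = _lag_indices(m, y, k)
        abs_r_sur[k] = np.abs(_rowwise_pearson(Msur[:, im], Ysur[:, iy]))
    if estimable:
        max_abs = np.nanmax(np.column_stack([abs_r_sur[k] for k in estimable]),
                            axis=1)
    p, p_adj = {}, {}
    for k in result.lags:
        if k not in abs_r_sur:
            p[k] = float("nan")
            p_adj[k] = float("nan")
            continue
        obs = abs(result.r[k])
        sur = abs_r_sur[k]
        ok = np.isfinite(sur)
        p[k] = float((1 + np.sum(sur[ok] >= obs)) / (1 + ok.sum()))
        okm = np.isfinite(max_abs)
        p_adj[k] = float((1 + np.sum(max_abs[okm] >= obs)) / (1 + okm.sum()))
        p_adj[k] = max(p_adj[k], p[k])
    result.p = p
    result.p_adjusted = p_adj
    result.method = "monte_carlo"
    result.reps = reps
    result.seed = seed
    result.phi = (phi_m, phi_y)
    return result
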