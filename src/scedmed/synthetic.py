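"""Synthetic SCED mediation datasets with known ground truth.

The generator emulates a daily-diary single-case study: a bounded ordinal-ish
mediator (e.g., coping ability) and outcome (e.g., anxiety) rated once per day
across consecutive treatment phases.  The intervention turns on at the first
day of the second phase, shifting the mediator's level and/or trend; the
outcome follows the mediator with a fixed lag; both series carry AR(1) noise;
observations can be removed completely at random.

The data-generating model, with intervention onset o (first day of phase 2)
and optional withdrawal onset w (first day of the last phase):

    M_t = mu_M + s_M t + a_level 1[t>=o] + a_trend (t-o) 1[t>=o]
          - withdrawal * (a_level 1[t>=w] + a_trend (t-w) 1[t>=w]) + e_t^M
    Y_t = mu_Y + s_Y t + b M_{t-lag} + e_t^Y

where e^M, e^Y are independent stationary AR(1) processes with coefficients
phi_m, phi_y and innovation standard deviations sd_m, sd_y.  The mediator is
generated ``lag`` days before day 1 so Y has a real lagged driver from the
first day.  Optional discretisation rounds both series to the even-integer
grid {0, 2, 4, 6, 8} seen on plotted 0-8 response scales.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import SCEDDataset, SCEDSeries
from .errors import ConfigurationError

__all__ = ["SynthConfig", "generate_sced", "inject_missingness",
           "simulate_operating_characteristics", "case_example_config"]


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for one synthetic dataset.

    Defaults mirror the motivating case study where they are known: phase
    lengths 26/32/14 (a four-week exposure phase, a four-week exposure-plus-
    cognitive-therapy phase and a two-week follow-up), base levels on a 0-8
    scale.  Effect sizes default to a moderate mediation scenario (see
    docs/methods.md for the rationale).
    """

    phase_lengths: tuple = (26, 32, 14)
    phase_labels: tuple | None = None   # defaults to B, C, D, ...
    mediator_base: tuple = (3.0, 0.0)   # (level, slope per day)
    a_level: float = 2.0                # immediate mediator shift at onset
    a_trend: float = 0.1                # mediator slope change at onset
    b: float = -0.5                     # mediator -> outcome coefficient
    lag: int = 2                        # days the mediator leads the outcome
    outcome_base: tuple = (6.0, 0.0)
    phi_m: float = 0.3
    phi_y: float = 0.3
    sd_m: float = 1.0                   # innovation standard deviations
    sd_y: float = 1.0
    missing_rate: float = 0.0
    missing_variables: str = "both"     # "both" | "mediator" | "outcome" | "either"
    discretize: bool = False            # round to {0,2,4,6,8}
    withdrawal: bool = False            # reverse a-effects in the last phase
    seed: int | None = None

    def __post_init__(self):
        if len(self.phase_lengths) < 2:
            raise ConfigurationError("need at least 2 phases")
        if any(int(n) < 3 for n in self.phase_lengths):
            raise ConfigurationError("every phase length must be >= 3")
        if not (abs(self.phi_m) < 1 and abs(self.phi_y) < 1):
            raise ConfigurationError("|phi| must be < 1")
        if not 0 <= self.lag < min(self.phase_lengths):
            raise ConfigurationError("lag must satisfy 0 <= lag < shortest phase")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.missing_rate > 0.5:
            raise ConfigurationError("missing_rate above 0.5 is not supported")
        if self.sd_m < 0 or self.sd_y < 0:
            raise ConfigurationError("innovation sds must be >= 0")
        if self.missing_variables not in ("both", "mediator", "outcome", "either"):
            raise ConfigurationError("missing_variables must be both/mediator/"
                                     "outcome/either")
        if self.withdrawal and len(self.phase_lengths) < 3:
            raise ConfigurationError("withdrawal needs >= 3 phases")

    @property
    def labels(self) -> tuple:
        if self.phase_labels is not None:
            if len(self.phase_labels) != len(self.phase_lengths):
                raise ConfigurationError("phase_labels length mismatch")
            return tuple(self.phase_labels)
        return tuple(string.ascii_uppercase[1:1 + len(self.phase_lengths)])


def case_example_config(seed: int | None = None) -> SynthConfig:
    """Configuration emulating the motivating case study's observable features:
    26/32/14 days across three phases, 0-8 even-integer scores, 14.5% missing,
    an effect that appears in phase two and recedes at follow-up."""
    return SynthConfig(missing_rate=0.145, discretize=True, withdrawal=True,
                       seed=seed)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = rng.standard_normal(n) * sd
    if phi != 0.0:
        e[0] /= np.sqrt(1.0 - phi * phi)
        return lfilter([1.0], [1.0, -phi], e)
    return e


def _deterministic_paths(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless (time, mediator mean, outcome mean) trajectories."""
    total = int(sum(cfg.phase_lengths))
    t = np.arange(1, total + 1, dtype=float)
    onset = 1.0 + cfg.phase_lengths[0]
    mu, s = cfg.mediator_base
    m = mu + s * t
    on = t >= onset
    m = m + cfg.a_level * on + cfg.a_trend * (t - onset) * on
    if cfg.withdrawal:
        w = 1.0 + sum(cfg.phase_lengths[:-1])
        won = t >= w
        m = m - cfg.a_level * won - cfg.a_trend * (t - w) * won
    # mediator lag days before day 1 follows the pre-onset baseline
    t_pre = np.arange(1 - cfg.lag, 1, dtype=float)
    m_pre = mu + s * t_pre
    m_ext = np.concatenate([m_pre, m])
    mu_y, s_y = cfg.outcome_base
    y = mu_y + s_y * t + cfg.b * m_ext[: total]
    return t, m, y


def _discretize(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x / 2.0) * 2.0, 0.0, 8.0)


def generate_sced(cfg: SynthConfig) -> tuple[SCEDDataset, dict]:
    """Generate one dataset plus a ground-truth record.

    The truth record carries the noiseless mean trajectories, onset days and
    the config, and suffices to recompute the noiseless dataset independently.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    total = int(sum(cfg.phase_lengths))
    t, m_det, y_det = _deterministic_paths(cfg)

    # mediator noise extended `lag` days back so Y's driver is the noisy M
    noise_m_ext = _ar1(rng, total + cfg.lag, cfg.phi_m, cfg.sd_m)
    noise_y = _ar1(rng, total, cfg.phi_y, cfg.sd_y)
    mu, s = cfg.mediator_base
    t_ext = np.arange(1 - cfg.lag, total + 1, dtype=float)
    m_det_ext = np.concatenate([mu + s * t_ext[: cfg.lag], m_det]) \
        if cfg.lag else m_det
    m_ext = m_det_ext + noise_m_ext
    m = m_ext[cfg.lag:]
    mu_y, s_y = cfg.outcome_base
    y = mu_y + s_y * t + cfg.b * m_ext[: total] + noise_y

    bounds = None
    if cfg.discretize:
        m = _discretize(m)
        y = _discretize(y)
        bounds = (0.0, 8.0)

    labels = cfg.labels
    phase = np.repeat(np.asarray(labels, dtype=object),
                      np.asarray(cfg.phase_lengths, dtype=int))
    time = np.arange(1, total + 1, dtype=np.int64)
    dir_y = int(np.sign(cfg.b)) if cfg.b != 0 else -1
    ds = SCEDDataset(
        SCEDSeries(time, m, phase, scale_bounds=bounds, name="mediator"),
        SCEDSeries(time, y, phase.copy(), scale_bounds=bounds, name="outcome"),
        phase_order=list(labels),
        hypothesized_direction={"mediator": +1, "outcome": dir_y})
    if cfg.missing_rate > 0:
        sub = int(rng.integers(2 ** 31))
        ds = inject_missingness(ds, cfg.missing_rate, seed=sub,
                                variables=cfg.missing_variables)
    truth = {"time": time.tolist(), "mediator_mean": m_det.tolist(),
             "outcome_mean": y_det.tolist(),
             "onset": 1 + int(cfg.phase_lengths[0]),
             "withdrawal_onset": (1 + int(sum(cfg.phase_lengths[:-1]))
                                  if cfg.withdrawal else None),
             "config": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in cfg.__dict__.items()}}
    return ds, truth


def inject_missingness(ds: SCEDDataset, rate: float, seed: int | None = None,
                       variables: str = "both") -> SCEDDataset:
    """Mark round(rate * n) days missing completely at random.

    ``variables`` chooses which side(s) go missing at a selected day.  A phase
    is never left with fewer than 3 days complete on both variables; if the
    requested rate cannot be reached under that constraint, a configuration
    error is raised.
    """
    if not 0.0 <= rate <= 0.5:
        raise ConfigurationError("rate must be in [0, 0.5]")
    if variables not in ("both", "mediator", "outcome", "either"):
        raise ConfigurationError("variables must be both/mediator/outcome/either")
    out = SCEDDataset(ds.mediator.copy(), ds.outcome.copy(),
                      phase_order=list(ds.phase_order),
                      hypothesized_direction=dict(ds.hypothesized_direction),
                      time_basis=ds.time_basis,
                      time_name=ds.time_name, phase_name=ds.phase_name)
    n = len(out.mediator.time)
    k = int(round(rate * n))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    complete = np.isfinite(out.mediator.value) & np.isfinite(out.outcome.value)
    budget = {}
    for ph in out.phase_order:
        mask = out.mediator.phase_mask(ph)
        budget[ph] = int((complete & mask).sum()) - 3
    if sum(max(0, v) for v in budget.values()) < k:
        raise ConfigurationError(
            f"cannot mark {k} day(s) missing while keeping >= 3 complete "
            f"days per phase")
    marked = 0
    for i in rng.permutation(n):
        if marked == k:
            break
        ph = out.mediator.phase[i]
        if not complete[i] or budget[ph] <= 0:
            continue
        which = variables
        if variables == "either":
            which = ("mediator", "outcome", "both")[rng.integers(3)]
        if which in ("mediator", "both"):
            out.mediator.value[i] = np.nan
        if which in ("outcome", "both"):
            out.outcome.value[i] = np.nan
        budget[ph] -= 1
        marked += 1
    if marked < k:
        raise ConfigurationError(
            f"could only mark {marked} of {k} requested missing day(s)")
    return out


def simulate_operating_characteristics(base: SynthConfig,
                                       a_levels, b_values,
                                       reps: int = 200,
                                       alpha: float = 0.05,
                                       seed: int | None = None,
                                       surrogate_reps: int = 500,
                                       max_lag: int = 5) -> pd.DataFrame:
    """Monte-Carlo type-I error / power over a grid of (a_level, b) effects.

    For each cell, ``reps`` datasets are generated from ``base`` with the
    cell's effects substituted (a null cell also zeroes ``a_trend``), the full
    mediation framework is run, and the fraction of replicates with a
    significant a path, a significant b path and a
    ``consistent_with_mediation`` verdict is recorded with binomial
    Monte-Carlo standard errors.
    """
    from .mediation import MediationConfig, mediation_report

    if reps < 100:
        raise ConfigurationError("reps must be >= 100")
    ss = np.random.SeedSequence(seed)
    rows = []
    for a_level in a_levels:
        for b in b_values:
            cfg0 = replace(base, a_level=float(a_level), b=float(b),
                           a_trend=base.a_trend if a_level != 0 else 0.0)
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            hits = {"a": 0, "b": 0, "joint": 0}
            for _ in range(reps):
                data_seed = int(rng.integers(2 ** 31))
                mc_seed = int(rng.integers(2 ** 31))
                ds, _ = generate_sced(replace(cfg0, seed=data_seed))
                ev = mediation_report(ds, MediationConfig(
                    seed=mc_seed, alpha=alpha, reps=surrogate_reps,
                    max_lag=max_lag))
                hits["a"] += ev.a.significant
                hits["b"] += ev.b.significant
                hits["joint"] += ev.verdict == "consistent_with_mediation"
            row = {"a_level": float(a_level), "b": float(b), "reps": reps}
            for key, cnt in hits.items():
                p = cnt / reps
                row[f"rate_{key}"] = p
                row[f"se_{key}"] = float(np.sqrt(p * (1 - p) / reps))
            rows.append(row)
    return pd.DataFrame(rows)
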