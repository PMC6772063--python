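"""Core containers, validation, CSV I/O, missing-data policies and plotting.

A single-case experimental design (SCED) measures one participant repeatedly
across treatment phases.  The containers here hold one participant's mediator
and outcome series on a shared integer time index (study day, 1-based), with
phase labels forming contiguous blocks in time.  Missing scores are carried as
NaN in memory and as empty cells (or ``NA``) in CSV, so a write/read round-trip
is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleError, ValidationError

log = logging.getLogger("scedmed")

#: CSV tokens interpreted as missing scores.
NA_TOKENS = ("", "NA")

DEFAULT_COLUMNS = {
    "time": "time",
    "phase": "phase",
    "mediator": "mediator",
    "outcome": "outcome",
}


@dataclass(frozen=True)
class MissingPolicy:
    """How incomplete days are treated before analysis.

    ``listwise``
        Drop every day on which either variable is missing and re-index time
        consecutively (1..n).  This compresses the calendar and therefore
        distorts lags; it reproduces the common practice of deleting missing
        rows before analysis.
    ``calendar``
        Keep all days.  Downstream lag operations pair scores by calendar day
        and silently skip pairs with a missing side.  This is the default.
    """

    mode: str = "calendar"

    def __post_init__(self):
        if self.mode not in ("listwise", "calendar"):
            raise ConfigurationError(
                f"missing policy mode must be 'listwise' or 'calendar', got {self.mode!r}"
            )


@dataclass
class SCEDSeries:
    """One repeatedly measured score with a time index and phase labels.

    Parameters
    ----------
    time : array of int
        Study day, strictly increasing; gaps allowed.
    value : array of float
        Score per day; NaN marks a missing observation.
    phase : array of str
        Phase label per day; labels must form contiguous blocks in time order.
    scale_bounds : (float, float), optional
        Declared measurement-scale range.  Non-missing values outside it are
        rejected.  Scores are stored as reals even for ordinal instruments.
    name : str
        Variable name, used in reports and CSV headers.
    """

    time: np.ndarray
    value: np.ndarray
    phase: np.ndarray
    scale_bounds: tuple[float, float] | None = None
    name: str = "score"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.value) == len(self.phase)):
            raise ValidationError("time, value and phase must have equal length",
                                  code="length_mismatch")
        if len(self.time) == 0:
            raise ValidationError("series is empty", code="empty")
        dt = np.diff(self.time)
        if np.any(dt == 0):
            dups = self.time[1:][dt == 0]
            raise ValidationError(f"duplicate time values: {sorted(set(dups.tolist()))}",
                                  code="duplicate_time")
        if np.any(dt < 0):
            raise ValidationError("time index is not strictly increasing",
                                  code="nonmonotone_time")
        self._check_contiguous_phases()
        if self.scale_bounds is not None:
            lo, hi = self.scale_bounds
            v = self.value[np.isfinite(self.value)]
            bad = (v < lo) | (v > hi)
            if np.any(bad):
                raise ValidationError(
                    f"{self.name}: {int(bad.sum())} value(s) outside declared bounds "
                    f"[{lo}, {hi}]", code="out_of_bounds")

    def _check_contiguous_phases(self):
        seen: list = []
        offending: list = []
        for t, p in zip(self.time, self.phase):
            if seen and p != seen[-1]:
                if p in seen:
                    offending.append(int(t))
                seen.append(p)
            elif not seen:
                seen.append(p)
        if offending:
            raise ValidationError(
                f"non-contiguous phase: label reappears at time point(s) {offending}",
                code="noncontiguous_phase")

    # -- convenience -------------------------------------------------------

    @property
    def phases(self) -> list:
        """Phase labels in time order (each appears once)."""
        out: list = []
        for p in self.phase:
            if not out or p != out[-1]:
                out.append(p)
        return out

    def phase_mask(self, label) -> np.ndarray:
        return np.asarray([p == label for p in self.phase])

    def phase_values(self, label, drop_missing: bool = True) -> np.ndarray:
        v = self.value[self.phase_mask(label)]
        return v[np.isfinite(v)] if drop_missing else v

    def phase_times(self, label) -> np.ndarray:
        return self.time[self.phase_mask(label)]

    def n_complete_by_phase(self) -> dict:
        return {p: int(np.isfinite(self.phase_values(p, drop_missing=False)).sum())
                for p in self.phases}

    def subset_phases(self, labels) -> "SCEDSeries":
        labels = list(labels)
        mask = np.asarray([p in labels for p in self.phase])
        return SCEDSeries(self.time[mask], self.value[mask], self.phase[mask],
                          scale_bounds=self.scale_bounds, name=self.name)

    def copy(self) -> "SCEDSeries":
        return SCEDSeries(self.time.copy(), self.value.copy(), self.phase.copy(),
                          scale_bounds=self.scale_bounds, name=self.name)


@dataclass
class SCEDDataset:
    """Mediator and outcome series on a shared time index, plus design metadata.

    ``hypothesized_direction`` maps ``"mediator"``/``"outcome"`` to the expected
    sign of clinical improvement: +1 if higher scores are better (e.g., coping
    ability), -1 if lower scores are better (e.g., anxiety symptoms).
    """

    mediator: SCEDSeries
    outcome: SCEDSeries
    phase_order: list = field(default_factory=list)
    hypothesized_direction: dict = field(
        default_factory=lambda: {"mediator": +1, "outcome": -1})
    time_basis: str = "calendar"  # "calendar" | "compressed"
    time_name: str = "time"
    phase_name: str = "phase"

    def __post_init__(self):
        if not np.array_equal(self.mediator.time, self.outcome.time):
            raise ValidationError("mediator and outcome must share the time index",
                                  code="index_mismatch")
        if list(self.mediator.phase) != list(self.outcome.phase):
            raise ValidationError("mediator and outcome must share phase labels",
                                  code="phase_mismatch")
        observed = self.mediator.phases
        if not self.phase_order:
            self.phase_order = list(observed)
        if list(self.phase_order) != list(observed):
            raise ValidationError(
                f"phase_order {list(self.phase_order)} must cover the observed "
                f"phases {observed} exactly once, in order", code="phase_order")
        for k in ("mediator", "outcome"):
            if int(self.hypothesized_direction.get(k, 0)) not in (-1, +1):
                raise ConfigurationError(
                    f"hypothesized_direction[{k!r}] must be +1 or -1")

    @property
    def n_phases(self) -> int:
        return len(self.phase_order)

    def subset_phases(self, labels) -> "SCEDDataset":
        return SCEDDataset(self.mediator.subset_phases(labels),
                           self.outcome.subset_phases(labels),
                           phase_order=[p for p in self.phase_order if p in labels],
                           hypothesized_direction=dict(self.hypothesized_direction),
                           time_basis=self.time_basis,
                           time_name=self.time_name, phase_name=self.phase_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.time_name: self.mediator.time,
            self.phase_name: self.mediator.phase,
            self.mediator.name: self.mediator.value,
            self.outcome.name: self.outcome.value,
        })


def require_analyzable(ds: SCEDDataset, min_per_phase: int = 3) -> None:
    """Check the minimum structure every analysis needs.

    At least two phases and at least ``min_per_phase`` non-missing observations
    of each variable per phase.
    """
    if ds.n_phases < 2:
        raise ValidationError("at least two phases are required for analysis",
                              code="too_few_phases")
    for series in (ds.mediator, ds.outcome):
        for ph, n in series.n_complete_by_phase().items():
            if n < min_per_phase:
                raise InfeasibleError(
                    f"{series.name}: phase {ph!r} has only {n} non-missing "
                    f"observation(s); need >= {min_per_phase}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_sced_csv(path, column_map: dict | None = None,
                  scale_bounds: tuple[float, float] | None = None,
                  phase_order: list | None = None,
                  hypothesized_direction: dict | None = None) -> SCEDDataset:
    """Read a long-format SCED CSV (one row per day) into a validated dataset.

    ``column_map`` names the time / phase / mediator / outcome columns; it
    defaults to those literal names.  Empty cells and ``NA`` are missing scores.
    Rows are sorted by time before validation.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype={cmap["phase"]: str}, keep_default_na=False,
                     na_values=list(NA_TOKENS))
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"column(s) {missing_cols} not found in {path}; available: "
            f"{list(df.columns)}")
    try:
        time = df[cmap["time"]].astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"time column {cmap['time']!r} is not integer: {exc}")
    order = np.argsort(time, kind="stable")
    df = df.iloc[order]
    time = time[order]

    med = SCEDSeries(time, df[cmap["mediator"]].astype(float).to_numpy(),
                     df[cmap["phase"]].to_numpy(), scale_bounds=scale_bounds,
                     name=cmap["mediator"])
    out = SCEDSeries(time, df[cmap["outcome"]].astype(float).to_numpy(),
                     df[cmap["phase"]].to_numpy(), scale_bounds=scale_bounds,
                     name=cmap["outcome"])
    ds = SCEDDataset(med, out, phase_order=list(phase_order) if phase_order else [],
                     hypothesized_direction=hypothesized_direction
                     or {"mediator": +1, "outcome": -1},
                     time_name=cmap["time"], phase_name=cmap["phase"])
    for series in (med, out):
        counts = {p: int(np.sum(~np.isfinite(series.phase_values(p, drop_missing=False))))
                  for p in series.phases}
        log.info("%s: missing by phase %s", series.name, counts)
    return ds


def write_sced_csv(ds: SCEDDataset, path) -> None:
    """Write a dataset back to long-format CSV; missing scores become empty cells."""
    ds.to_frame().to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Missing-data policy
# ---------------------------------------------------------------------------

def apply_missing_policy(ds: SCEDDataset, policy: MissingPolicy) -> SCEDDataset:
    """Apply a missing-data policy, returning a new dataset.

    Listwise mode drops every day with either variable missing and re-indexes
    time 1..n (compressing the calendar).  Calendar mode drops nothing; the
    returned dataset is tagged so lag operations pair by calendar day.
    """
    if policy.mode == "calendar":
        out = SCEDDataset(ds.mediator.copy(), ds.outcome.copy(),
                          phase_order=list(ds.phase_order),
                          hypothesized_direction=dict(ds.hypothesized_direction),
                          time_basis="calendar",
                          time_name=ds.time_name, phase_name=ds.phase_name)
        return out
    keep = np.isfinite(ds.mediator.value) & np.isfinite(ds.outcome.value)
    new_time = np.arange(1, int(keep.sum()) + 1, dtype=np.int64)
    med = SCEDSeries(new_time, ds.mediator.value[keep], ds.mediator.phase[keep],
                     scale_bounds=ds.mediator.scale_bounds, name=ds.mediator.name)
    out = SCEDSeries(new_time, ds.outcome.value[keep], ds.outcome.phase[keep],
                     scale_bounds=ds.outcome.scale_bounds, name=ds.outcome.name)
    result = SCEDDataset(med, out, phase_order=[p for p in ds.phase_order
                                                if p in med.phases],
                         hypothesized_direction=dict(ds.hypothesized_direction),
                         time_basis="compressed",
                         time_name=ds.time_name, phase_name=ds.phase_name)
    for ph, n in med.n_complete_by_phase().items():
        if n < 3:
            raise InfeasibleError(
                f"listwise deletion leaves phase {ph!r} with {n} usable "
                f"observation(s); need >= 3")
    return result


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_dataset(ds: SCEDDataset, out=None):
    """Two-panel mediator/outcome plot with vertical phase-boundary lines.

    Missing days are rendered as gaps (no interpolation).  Returns the
    matplotlib Figure; writes it to ``out`` when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    boundaries = _phase_boundaries(ds)
    for ax, series in zip(axes, (ds.mediator, ds.outcome)):
        ax.plot(series.time, series.value, marker="o", markersize=3, lw=1)
        for b in boundaries:
            ax.axvline(b, color="k", ls="--", lw=0.8)
        ax.set_ylabel(series.name)
        if series.scale_bounds is not None:
            ax.set_ylim(series.scale_bounds[0] - 0.5, series.scale_bounds[1] + 0.5)
    axes[-1].set_xlabel(ds.time_name)
    fig.tight_layout()
    if out is not None:
        try:
            fig.savefig(out, dpi=120)
        except OSError as exc:
            raise SCEDIOError(f"cannot write plot to {out}: {exc}")
    return fig


class SCEDIOError(ConfigurationError):
    code = "io"


def _phase_boundaries(ds: SCEDDataset) -> list:
    """Boundary x-positions: midpoint before the first day of each later phase."""
    out = []
    for ph in ds.phase_order[1:]:
        t0 = int(ds.mediator.phase_times(ph)[0])
        out.append(t0 - 0.5)
    return out
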