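"""Cleaning, event-anchored hourly gridding, imputation and tabular encoding.

The temporal skeleton of the pipeline is the hourly time index ``T``:
measurements of a resuscitated visit are anchored to the CPR execution
time, everything else (no-event visits and death-only/DNR-analog visits)
to the last measurement time,

    T = ceil((t_measurement - t_anchor) / 3600),

so the event sits in the ``T = 0`` bin and history occupies ``T < 0``.
Measurements after the CPR time (``T > 0``) are discarded: prediction
precedes the event.

Missing hourly cells are filled by carrying the most recent earlier value
of the same channel forward; cells with no earlier observation fall back
to the per-channel median.  Medians (and the per-feature modes used for
tabular imputation) are fitted on the training partition only, so the
test partition never leaks into the statistics.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CHANNELS, Measurement, RawVisit, TriageRecord, TRIAGE_FEATURES, VitalChannel

__all__ = [
    "VALID_RANGES",
    "clean_value",
    "anchor_time",
    "compute_time_index",
    "HourlyGrid",
    "EmptyGridError",
    "build_hourly_grid",
    "ImputationStats",
    "fit_imputation_stats",
    "impute_grid",
    "TabularEncoder",
]

# Physiologic validity intervals; (lo, hi, hi_closed).  Values outside are
# treated as recording errors and removed.
VALID_RANGES: dict[VitalChannel, tuple[float, float, bool]] = {
    VitalChannel.SBP: (0.0, 300.0, False),
    VitalChannel.DBP: (0.0, 300.0, False),
    VitalChannel.HR: (0.0, 300.0, False),
    VitalChannel.SPO2: (0.0, 100.0, True),
    VitalChannel.BT: (0.0, 50.0, False),
    VitalChannel.RR: (0.0, 50.0, False),
}

# Fallback medians when a channel is never observed in the training split
# (physiologic normals; only reachable on degenerate cohorts).
_FALLBACK_MEDIANS = {
    VitalChannel.SBP: 120.0, VitalChannel.DBP: 75.0, VitalChannel.HR: 80.0,
    VitalChannel.SPO2: 97.0, VitalChannel.BT: 36.5, VitalChannel.RR: 16.0,
}


def clean_value(channel: VitalChannel, raw: str) -> float | None:
    """Clean one raw vital-sign string; ``None`` means missing.

    Full-width characters are mapped to half-width (NFKC), non-numeric
    strings become missing, and numeric values outside the channel's
    validity interval are removed.
    """
    if channel not in VALID_RANGES:
        raise KeyError(f"unknown vital channel {channel!r}")
    if raw is None:
        return None
    text = unicodedata.normalize("NFKC", str(raw)).strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    if not np.isfinite(value):
        return None
    lo, hi, hi_closed = VALID_RANGES[channel]
    if value < lo or value > hi or (value == hi and not hi_closed):
        return None
    return value


def anchor_time(visit: RawVisit) -> int:
    """Seconds defining ``T = 0``: CPR execution time, else last measurement."""
    if visit.outcome.cpr:
        if visit.outcome.cpr_time_s is None:
            raise ValueError(f"visit {visit.visit_id}: cpr=True without cpr_time")
        return visit.outcome.cpr_time_s
    times = [m.time_s for m in visit.measurements]
    times.append(visit.triage.triage_time_s)
    return max(times)


def compute_time_index(measurement_time_s: int, visit: RawVisit) -> int:
    """Hourly time index ``T = ceil((t - anchor) / 3600)`` (exact on integers)."""
    delta = int(measurement_time_s) - anchor_time(visit)
    return -((-delta) // 3600)


class EmptyGridError(ValueError):
    """A visit has no in-range measurement at ``T <= 0``."""


@dataclass
class HourlyGrid:
    """Per-visit 6 x L matrix of vitals on the hourly index ``t_min .. 0``.

    ``observed_mask`` records which cells held a real measurement; it is
    preserved through imputation as provenance.
    """

    visit_id: str
    t_min: int
    values: np.ndarray        # (6, L), nan where missing pre-imputation
    observed_mask: np.ndarray  # (6, L) bool
    label_cpr: bool
    label_ca: bool
    imputed: bool = False

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def column_index(self, t: int) -> int:
        """Array column holding time index ``t`` (``t_min <= t <= 0``)."""
        return t - self.t_min


def _cleaned_timed_values(visit: RawVisit):
    """Yield (time_s, channel, value) for the triage panel plus all measurements."""
    for ch, raw in visit.triage.vitals.items():
        v = clean_value(ch, raw)
        if v is not None:
            yield visit.triage.triage_time_s, ch, v
    for m in visit.sorted_measurements():
        v = clean_value(m.channel, m.raw_value)
        if v is not None:
            yield m.time_s, m.channel, v


def build_hourly_grid(visit: RawVisit) -> HourlyGrid:
    """Bin the cleaned measurements (triage panel included as the earliest
    instance) onto the hourly grid; within a bin the latest timestamp wins;
    measurements after the CPR time are dropped."""
    entries = []
    for t_s, ch, v in _cleaned_timed_values(visit):
        T = compute_time_index(t_s, visit)
        if T > 0:
            continue
        entries.append((T, t_s, ch, v))
    if not entries:
        raise EmptyGridError(f"visit {visit.visit_id}: no valid measurement at T <= 0")
    t_min = min(e[0] for e in entries)
    L = -t_min + 1
    values = np.full((len(CHANNELS), L), np.nan)
    mask = np.zeros((len(CHANNELS), L), dtype=bool)
    latest = np.full((len(CHANNELS), L), -np.inf)
    ch_index = {c: i for i, c in enumerate(CHANNELS)}
    for T, t_s, ch, v in entries:
        i, j = ch_index[ch], T - t_min
        if t_s >= latest[i, j]:
            latest[i, j] = t_s
            values[i, j] = v
            mask[i, j] = True
    return HourlyGrid(
        visit_id=visit.visit_id, t_min=t_min, values=values, observed_mask=mask,
        label_cpr=visit.outcome.cpr, label_ca=visit.outcome.ca,
    )


@dataclass
class ImputationStats:
    """Training-partition statistics reused verbatim at inference time."""

    medians: dict[VitalChannel, float]
    modes: dict[str, str] = field(default_factory=dict)
    numeric_mean: dict[str, float] = field(default_factory=dict)
    numeric_std: dict[str, float] = field(default_factory=dict)

    # -- flat key-value serialization so inference reuses training stats ----
    def to_text(self) -> str:
        lines = []
        for ch, v in self.medians.items():
            lines.append(f"median.{ch.value}={v!r}")
        for k, v in self.modes.items():
            lines.append(f"mode.{k}={v}")
        for k, v in self.numeric_mean.items():
            lines.append(f"numeric_mean.{k}={v!r}")
        for k, v in self.numeric_std.items():
            lines.append(f"numeric_std.{k}={v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ImputationStats":
        medians: dict[VitalChannel, float] = {}
        modes: dict[str, str] = {}
        nmean: dict[str, float] = {}
        nstd: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kind, _, name = key.partition(".")
            if kind == "median":
                medians[VitalChannel(name)] = float(val)
            elif kind == "mode":
                modes[name] = val
            elif kind == "numeric_mean":
                nmean[name] = float(val)
            elif kind == "numeric_std":
                nstd[name] = float(val)
        return cls(medians, modes, nmean, nstd)


def fit_imputation_stats(training_visits: list[RawVisit]) -> ImputationStats:
    """Fit per-channel medians and per-feature modes on the training split.

    Mode ties break to the alphabetically first category (deterministic).
    """
    if not training_visits:
        raise ValueError("training partition is empty")
    per_channel: dict[VitalChannel, list[float]] = {c: [] for c in CHANNELS}
    for visit in training_visits:
        for _, ch, v in _cleaned_timed_values(visit):
            per_channel[ch].append(v)
    medians = {
        ch: (float(np.median(vals)) if vals else _FALLBACK_MEDIANS[ch])
        for ch, vals in per_channel.items()
    }

    modes: dict[str, str] = {}
    nmean: dict[str, float] = {}
    nstd: dict[str, float] = {}
    for feat, kind in TRIAGE_FEATURES.items():
        observed = [v.triage.features[feat] for v in training_visits
                    if not pd.isna(v.triage.features[feat])]
        if not observed:
            continue
        as_str = [str(x) for x in observed]
        counts = pd.Series(as_str).value_counts()
        top = counts.max()
        modes[feat] = sorted(c for c in counts.index if counts[c] == top)[0]
        if kind == "numeric":
            arr = np.asarray([float(x) for x in observed])
            nmean[feat] = float(arr.mean())
            nstd[feat] = float(arr.std()) or 1.0
    return ImputationStats(medians, modes, nmean, nstd)


def impute_grid(grid: HourlyGrid, stats: ImputationStats) -> HourlyGrid:
    """Carry the most recent earlier value forward; median fallback at the
    start of each channel.  Observed cells are untouched; idempotent."""
    values = grid.values.copy()
    for i, ch in enumerate(CHANNELS):
        row = values[i]
        last = stats.medians[ch]
        for j in range(row.size):
            if np.isnan(row[j]):
                row[j] = last
            else:
                last = row[j]
    return replace(grid, values=values, observed_mask=grid.observed_mask.copy(),
                   imputed=True)


class TabularEncoder:
    """One-hot layout for the 14 triage features, fixed by a fitted manifest.

    Categorical features expand to one-hot blocks over the categories seen
    in training (sorted); missing or unseen categories map to the training
    mode.  Numeric features pass through unscaled by default; set
    ``standardize=True`` to z-score them with training mean/std.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize
        self.categories_: dict[str, list[str]] = {}
        self.stats_: ImputationStats | None = None
        self.feature_names_: list[str] = []

    def fit(self, training_visits: list[RawVisit],
            stats: ImputationStats | None = None) -> "TabularEncoder":
        self.stats_ = stats if stats is not None else fit_imputation_stats(training_visits)
        self.categories_ = {}
        self.feature_names_ = []
        for feat, kind in TRIAGE_FEATURES.items():
            if kind == "numeric":
                self.feature_names_.append(feat)
                continue
            seen = {str(v.triage.features[feat]) for v in training_visits
                    if not pd.isna(v.triage.features[feat])}
            seen.add(self.stats_.modes.get(feat, ""))
            cats = sorted(c for c in seen if c != "")
            if not cats:
                cats = ["__missing__"]
            self.categories_[feat] = cats
            self.feature_names_.extend(f"{feat}={c}" for c in cats)
        return self

    @property
    def n_features_(self) -> int:
        return len(self.feature_names_)

    def encode(self, triage: TriageRecord) -> np.ndarray:
        if self.stats_ is None:
            raise RuntimeError("encoder not fitted")
        out: list[float] = []
        for feat, kind in TRIAGE_FEATURES.items():
            raw = triage.features.get(feat)
            missing = raw is None or pd.isna(raw)
            if kind == "numeric":
                if missing:
                    raw = self.stats_.modes.get(feat, 0)
                x = float(raw)
                if self.standardize:
                    x = (x - self.stats_.numeric_mean.get(feat, 0.0)) \
                        / self.stats_.numeric_std.get(feat, 1.0)
                out.append(x)
            else:
                cats = self.categories_[feat]
                val = self.stats_.modes.get(feat) if missing else str(raw)
                if val not in cats:  # unseen at inference -> training mode
                    val = self.stats_.modes.get(feat, cats[0])
                    if val not in cats:
                        val = cats[0]
                block = [1.0 if c == val else 0.0 for c in cats]
                out.extend(block)
        return np.asarray(out)

    def encode_cohort(self, visits: list[RawVisit]) -> np.ndarray:
        return np.stack([self.encode(v.triage) for v in visits])
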