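"""Domain types and delimited-table readers/writers for ED visit cohorts.

Two comma-delimited UTF-8 tables describe a cohort:

``triage.csv``
    one row per ED visit: the 14 triage/demographic features, the six
    triage vital-sign values, the triage timestamp, and the outcome columns
    ``cpr``, ``dead``, ``cpr_time``.

``vitals.csv``
    long format, one row per recorded vital-sign value:
    ``visit_id,time_s,channel,value``.  Channel tokens are exactly
    ``SBP,DBP,HR,SPO2,BT,RR``.  ``value`` is kept as a raw string; cleaning
    (typo removal, range checks) happens in :mod:`edewarn.preprocess`.

Timestamps are integer seconds; they may be absolute or relative to the
visit start — only differences ever matter downstream.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VitalChannel",
    "Measurement",
    "TriageRecord",
    "Outcome",
    "RawVisit",
    "TRIAGE_FEATURES",
    "read_visits",
    "write_visits",
    "apply_cohort_filters",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates referential integrity."""


class VitalChannel(str, enum.Enum):
    SBP = "SBP"
    DBP = "DBP"
    HR = "HR"
    SPO2 = "SPO2"
    BT = "BT"
    RR = "RR"

    def __str__(self) -> str:  # CSV token
        return self.value


CHANNELS: tuple[VitalChannel, ...] = tuple(VitalChannel)

# The 14 non-vital triage features and their encoding kind.
TRIAGE_FEATURES: dict[str, str] = {
    "age": "numeric",
    "sex": "categorical",
    "season": "categorical",
    "revisit": "categorical",
    "is_job_related": "categorical",
    "department": "categorical",
    "day_zone": "categorical",
    "arrival_by_ambulance": "categorical",
    "major_disease": "categorical",
    "judgement_code": "categorical",
    "triage": "categorical",
    "pain_index": "numeric",
    "gcs": "numeric",
    "acute_change": "categorical",
}

_VITAL_COLS = {c: c.value.lower() for c in CHANNELS}


@dataclass(frozen=True)
class Measurement:
    visit_id: str
    time_s: int
    channel: VitalChannel
    raw_value: str


@dataclass
class TriageRecord:
    """Triage-station snapshot: 14 features plus the first vital-sign panel."""

    features: dict[str, object]
    vitals: dict[VitalChannel, str]  # raw strings; cleaned downstream
    triage_time_s: int

    def __post_init__(self):
        missing = set(TRIAGE_FEATURES) - set(self.features)
        extra = set(self.features) - set(TRIAGE_FEATURES)
        if missing or extra:
            raise SchemaError(
                f"triage features must be exactly the 14 declared ones; "
                f"missing={sorted(missing)} extra={sorted(extra)}")
        tri = self.features.get("triage")
        if tri is not None and not pd.isna(tri) and int(tri) not in range(1, 6):
            raise ValueError(f"triage level must be in 1..5, got {tri}")
        pain = self.features.get("pain_index")
        if pain is not None and not pd.isna(pain) and not (0 <= float(pain) <= 10):
            raise ValueError(f"pain index must be in [0, 10], got {pain}")


@dataclass
class Outcome:
    cpr: bool
    dead: bool
    cpr_time_s: int | None = None

    @property
    def ca(self) -> bool:
        """Cardiac arrest is the union of CPR and death."""
        return self.cpr or self.dead

    def __post_init__(self):
        if self.cpr and self.cpr_time_s is None:
            raise ValueError("cpr=True requires cpr_time_s")
        if not self.cpr and self.cpr_time_s is not None:
            raise ValueError("cpr_time_s present but cpr=False")


@dataclass
class RawVisit:
    visit_id: str
    triage: TriageRecord
    measurements: list[Measurement] = field(default_factory=list)
    outcome: Outcome = field(default_factory=lambda: Outcome(False, False))

    @property
    def n_instances(self) -> int:
        """Distinct measurement timestamps (one 'instance' may carry several channels)."""
        return len({m.time_s for m in self.measurements})

    @property
    def under_length(self) -> bool:
        """Fewer than two vital-sign measurement instances: flagged for exclusion."""
        return self.n_instances < 2

    def sorted_measurements(self) -> list[Measurement]:
        return sorted(self.measurements, key=lambda m: m.time_s)


_REQUIRED_TRIAGE_COLS = (
    ["visit_id"] + list(TRIAGE_FEATURES) + list(_VITAL_COLS.values())
    + ["triage_time_s", "cpr", "dead", "cpr_time"]
)
_REQUIRED_VITALS_COLS = ["visit_id", "time_s", "channel", "value"]


def read_visits(triage_path, measurements_path) -> list[RawVisit]:
    """Read a cohort from the two-table dialect.

    Duplicate ``(visit_id, time_s, channel)`` measurement rows are resolved
    to the last occurrence in file order (logged).  A measurement whose
    visit id has no triage row is a referential-integrity error.
    """
    tri = pd.read_csv(triage_path, dtype={"visit_id": str})
    vit = pd.read_csv(measurements_path, dtype={"visit_id": str, "value": str})

    for col in _REQUIRED_TRIAGE_COLS:
        if col not in tri.columns:
            raise SchemaError(f"triage table missing required column {col!r}")
    for col in _REQUIRED_VITALS_COLS:
        if col not in vit.columns:
            raise SchemaError(f"vitals table missing required column {col!r}")

    bad = set(vit["channel"]) - {c.value for c in CHANNELS}
    if bad:
        raise SchemaError(f"unknown vital channels {sorted(bad)}")

    known_ids = set(tri["visit_id"])
    orphans = set(vit["visit_id"]) - known_ids
    if orphans:
        raise SchemaError(
            f"measurement rows reference visit ids with no triage row: {sorted(orphans)}")

    dup = vit.duplicated(subset=["visit_id", "time_s", "channel"], keep="last")
    if dup.any():
        logger.warning("dropping %d duplicate measurement rows (keeping last)", dup.sum())
        vit = vit[~dup]

    by_visit: dict[str, list[Measurement]] = {}
    for row in vit.itertuples(index=False):
        by_visit.setdefault(row.visit_id, []).append(
            Measurement(row.visit_id, int(row.time_s),
                        VitalChannel(row.channel), str(row.value)))

    visits: list[RawVisit] = []
    for row in tri.itertuples(index=False):
        d = row._asdict()
        features = {k: d[k] for k in TRIAGE_FEATURES}
        vitals = {c: "" if pd.isna(d[col]) else str(d[col])
                  for c, col in _VITAL_COLS.items()}
        cpr = bool(int(d["cpr"]))
        cpr_time = None if pd.isna(d["cpr_time"]) else int(d["cpr_time"])
        outcome = Outcome(cpr=cpr, dead=bool(int(d["dead"])),
                          cpr_time_s=cpr_time if cpr else None)
        visits.append(RawVisit(
            visit_id=str(d["visit_id"]),
            triage=TriageRecord(features, vitals, int(d["triage_time_s"])),
            measurements=by_visit.get(str(d["visit_id"]), []),
            outcome=outcome,
        ))
    return visits


def write_visits(visits: list[RawVisit], triage_path, measurements_path) -> None:
    """Write a cohort back to the two-table dialect (inverse of :func:`read_visits`)."""
    tri_rows = []
    vit_rows = []
    for v in visits:
        row: dict[str, object] = {"visit_id": v.visit_id}
        row.update(v.triage.features)
        for c, col in _VITAL_COLS.items():
            row[col] = v.triage.vitals.get(c, "")
        row["triage_time_s"] = v.triage.triage_time_s
        row["cpr"] = int(v.outcome.cpr)
        row["dead"] = int(v.outcome.dead)
        row["cpr_time"] = "" if v.outcome.cpr_time_s is None else v.outcome.cpr_time_s
        tri_rows.append(row)
        for m in v.sorted_measurements():
            vit_rows.append({"visit_id": m.visit_id, "time_s": m.time_s,
                             "channel": m.channel.value, "value": m.raw_value})
    pd.DataFrame(tri_rows).to_csv(triage_path, index=False)
    pd.DataFrame(vit_rows, columns=_REQUIRED_VITALS_COLS).to_csv(
        measurements_path, index=False)


def apply_cohort_filters(visits: list[RawVisit], task: str) -> list[RawVisit]:
    """Apply the cohort-definition filters for a prediction task.

    ``task="CA"`` keeps every in-hospital visit; ``task="CPR"`` additionally
    drops the death-only (DNR-analog) visits, i.e. those with ``ca`` true but
    ``cpr`` false.  Visits with fewer than two measurement instances are
    dropped for both tasks.
    """
    if task not in ("CA", "CPR"):
        raise ValueError(f"task must be 'CA' or 'CPR', got {task!r}")
    kept = [v for v in visits if not v.under_length]
    if task == "CPR":
        kept = [v for v in kept if not (v.outcome.ca and not v.outcome.cpr)]
    return kept
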