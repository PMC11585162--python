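"""Declarative rule-based early-warning scores (EDICAS, MEWS, NEWS).

A score is a table of items; each item carries a positive integer point
value and one or more clauses, any of which firing awards the points
(e.g. "heart rate < 60 or > 90", or "GCS < 15 or acute change").  Vital
signs are read from the last real column of the hourly grid at the
scoring horizon (carry-forward semantics); tabular variables come from
the triage record.  A missing variable never fires a clause.

Tables ship as editable YAML files under ``edewarn/ews_tables/`` and are
validated on load: every referenced variable must be one of the six vital
channels or one of the 14 triage features, clauses of the same variable
must not overlap within a score, and points must be >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .io import TRIAGE_FEATURES, TriageRecord, VitalChannel
from .preprocess import HourlyGrid

__all__ = ["Clause", "ScoreItem", "ScoreDefinition", "EWSResult",
           "load_score", "bundled_score_names", "score_visit", "evaluate_ews"]

_OPS = ("lt", "le", "gt", "ge", "eq")
_VITAL_TOKENS = {c.value for c in VitalChannel}


@dataclass(frozen=True)
class Clause:
    variable: str
    # conjunction of the present bounds; eq is exclusive with the others
    lt: float | None = None
    le: float | None = None
    gt: float | None = None
    ge: float | None = None
    eq: object | None = None

    def matches(self, value) -> bool:
        if value is None or (np.isscalar(value) and pd.isna(value)):
            return False
        if self.eq is not None:
            try:
                return float(value) == float(self.eq)
            except (TypeError, ValueError):
                return str(value) == str(self.eq)
        try:
            x = float(value)
        except (TypeError, ValueError):
            return False
        if self.lt is not None and not x < self.lt:
            return False
        if self.le is not None and not x <= self.le:
            return False
        if self.gt is not None and not x > self.gt:
            return False
        if self.ge is not None and not x >= self.ge:
            return False
        return True


@dataclass(frozen=True)
class ScoreItem:
    name: str
    points: int
    clauses: tuple[Clause, ...]

    def fires(self, lookup) -> bool:
        return any(c.matches(lookup(c.variable)) for c in self.clauses)


@dataclass
class ScoreDefinition:
    name: str
    items: list[ScoreItem]

    @property
    def max_score(self) -> int:
        return sum(item.points for item in self.items)

    def validate(self) -> None:
        for item in self.items:
            if item.points < 1:
                raise ValueError(f"{self.name}/{item.name}: points must be >= 1")
            if not item.clauses:
                raise ValueError(f"{self.name}/{item.name}: no clauses")
            for c in item.clauses:
                if c.variable not in _VITAL_TOKENS and c.variable not in TRIAGE_FEATURES:
                    raise ValueError(
                        f"{self.name}/{item.name}: unknown variable {c.variable!r}")
        # non-overlap: no numeric value may fire two items through the same variable
        by_var: dict[str, list[tuple[ScoreItem, Clause]]] = {}
        for item in self.items:
            for c in item.clauses:
                by_var.setdefault(c.variable, []).append((item, c))
        for var, pairs in by_var.items():
            probes = set()
            for _, c in pairs:
                for bound in (c.lt, c.le, c.gt, c.ge, c.eq):
                    if bound is not None and not isinstance(bound, str):
                        b = float(bound)
                        probes.update((b - 0.05, b, b + 0.05))
            for x in probes:
                hits = {id(item) for item, c in pairs if c.matches(x)}
                if len(hits) > 1:
                    raise ValueError(
                        f"{self.name}: overlapping conditions on {var!r} at {x}")


def _parse_clause(variable: str, spec: dict) -> Clause:
    unknown = set(spec) - set(_OPS)
    if unknown:
        raise ValueError(f"unknown clause keys {sorted(unknown)} for {variable!r}")
    return Clause(variable=variable, **spec)


def load_score(source) -> ScoreDefinition:
    """Load and validate a score table from a YAML path, text, or mapping."""
    if isinstance(source, dict):
        doc = source
    else:
        text = source.read_text() if hasattr(source, "read_text") else None
        if text is None:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, TypeError):
                text = str(source)
        doc = yaml.safe_load(text)
    items = []
    for raw in doc["items"]:
        clauses = []
        when = raw["when"]
        if isinstance(when, dict):
            when = [when]
        for clause_spec in when:
            spec = dict(clause_spec)
            variable = spec.pop("variable", raw.get("variable"))
            if variable is None:
                raise ValueError(f"{doc['name']}: clause without a variable")
            clauses.append(_parse_clause(variable, spec))
        items.append(ScoreItem(name=raw.get("name", raw.get("variable", "item")),
                               points=int(raw["points"]), clauses=tuple(clauses)))
    defn = ScoreDefinition(name=doc["name"], items=items)
    defn.validate()
    return defn


def bundled_score_names() -> list[str]:
    root = resources.files("edewarn") / "ews_tables"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_bundled_score(name: str) -> ScoreDefinition:
    path = resources.files("edewarn") / "ews_tables" / f"{name.lower()}.yaml"
    return load_score(path)


@dataclass
class EWSResult:
    visit_id: str
    horizon: int
    score: int
    contributions: dict[str, int] = field(default_factory=dict)


def score_visit(defn: ScoreDefinition, triage: TriageRecord, grid: HourlyGrid,
                k: int = 0) -> EWSResult:
    """Score one visit at horizon ``k``: vitals from the grid column at
    ``T = -k`` (carry-forward values), tabular variables from triage."""
    if not grid.imputed:
        raise ValueError("scoring requires an imputed grid")
    col = grid.column_index(-k)
    if col < 0:
        raise ValueError(f"grid does not reach horizon {k}")
    channel_index = {c.value: i for i, c in enumerate(VitalChannel)}

    def lookup(variable: str):
        if variable in channel_index:
            return grid.values[channel_index[variable], col]
        return triage.features.get(variable)

    contributions = {}
    for item in defn.items:
        if item.fires(lookup):
            contributions[item.name] = contributions.get(item.name, 0) + item.points
    score = sum(contributions.values())
    return EWSResult(visit_id=grid.visit_id, horizon=k, score=score,
                     contributions=contributions)


def evaluate_ews(defn: ScoreDefinition, triages: list[TriageRecord],
                 grids: list[HourlyGrid], horizons=(0, 8),
                 labels: list[bool] | None = None):
    """Rank a labelled test cohort by integer score at each horizon.

    Returns an :class:`edewarn.training.EvalReport` computed by the shared
    metrics engine, with the integer score as the ranking statistic.
    Visits whose grid has no observed history at ``T <= -k`` drop out at
    horizon ``k``, mirroring the deep model's eligibility rule.
    """
    from .training import EvalReport, compute_metrics
    from .windowing import window_at

    if labels is None:
        labels = [g.label_ca for g in grids]
    report = EvalReport(name=defn.name)
    for k in horizons:
        scores, labs = [], []
        for triage, grid, lab in zip(triages, grids, labels):
            if window_at(grid, k) is None:
                continue
            scores.append(score_visit(defn, triage, grid, k).score)
            labs.append(bool(lab))
        row = compute_metrics(np.asarray(scores, dtype=float),
                              np.asarray(labs, dtype=float))
        row.horizon = k
        report.rows[k] = row
    return report
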