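"""End-to-end wiring: simulate -> preprocess -> train -> evaluate -> explain.

This module is the package's single high-level entry point; every stage
is also usable on its own.  A typical run:

>>> from edewarn import pipeline, simulate
>>> visits = simulate.simulate_cohort(simulate.SimConfig(n_visits=2000, seed=7))
>>> result = pipeline.run_experiment(visits, task="CA", seed=7)
>>> result.report.rows[0].auroc

``run_experiment`` returns a :class:`RunResult` carrying the trained
model, the per-horizon evaluation report, the training history, and the
attention-based token importance; pass ``out_dir`` to also write
``metrics.json``, ``history.csv`` and a config echo for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import RawVisit, apply_cohort_filters
from .model import ArrestRiskModel, ModelConfig
from .preprocess import (
    HourlyGrid,
    ImputationStats,
    TabularEncoder,
    build_hourly_grid,
    fit_imputation_stats,
    impute_grid,
)
from .training import (
    EvalReport,
    SplitSpec,
    TrainConfig,
    attention_importance,
    evaluate_horizons,
    max_f1_threshold,
    stratified_split,
    train,
)
from .windowing import WindowingConfig, augment_minority, windows_to_arrays
from . import ews as ews_mod

__all__ = ["PreparedCohort", "RunResult", "prepare_cohort", "run_experiment",
           "ablate", "score_ews"]


@dataclass
class SplitData:
    visits: list[RawVisit]
    grids: list[HourlyGrid]
    tabular: np.ndarray            # (n, d), row per visit
    labels: np.ndarray             # (n,) bool, task labels

    @property
    def tabular_by_visit(self) -> dict[str, np.ndarray]:
        return {v.visit_id: self.tabular[i] for i, v in enumerate(self.visits)}


@dataclass
class PreparedCohort:
    task: str
    stats: ImputationStats
    encoder: TabularEncoder
    splits: dict[str, SplitData]


def _task_label(visit: RawVisit, task: str) -> bool:
    return visit.outcome.cpr if task == "CPR" else visit.outcome.ca


def prepare_cohort(visits: list[RawVisit], task: str = "CA",
                   split: SplitSpec = SplitSpec(),
                   standardize_numeric: bool = False) -> PreparedCohort:
    """Filter, grid, split, fit imputation/encoding on train, impute all.

    The stratified split uses the raw (pre-imputation) grid lengths; the
    imputation medians and the tabular one-hot manifest are fitted on the
    training partition only and then applied to all three.
    """
    cohort = apply_cohort_filters(visits, task)
    raw_grids = [build_hourly_grid(v) for v in cohort]
    lengths = np.asarray([g.length for g in raw_grids])
    cpr = np.asarray([v.outcome.cpr for v in cohort])
    dead = np.asarray([v.outcome.dead for v in cohort])
    idx_tr, idx_va, idx_te = stratified_split(lengths, cpr, dead, split)

    train_visits = [cohort[i] for i in idx_tr]
    stats = fit_imputation_stats(train_visits)
    encoder = TabularEncoder(standardize=standardize_numeric).fit(train_visits, stats)

    splits: dict[str, SplitData] = {}
    for name, idx in (("train", idx_tr), ("val", idx_va), ("test", idx_te)):
        sub = [cohort[i] for i in idx]
        grids = [impute_grid(raw_grids[i], stats) for i in idx]
        tab = encoder.encode_cohort(sub) if sub else np.zeros((0, encoder.n_features_))
        labels = np.asarray([_task_label(v, task) for v in sub], dtype=bool)
        splits[name] = SplitData(sub, grids, tab, labels)
    return PreparedCohort(task=task, stats=stats, encoder=encoder, splits=splits)


def _augmented_arrays(split: SplitData, wcfg: WindowingConfig):
    windows = augment_minority(split.grids, wcfg, labels=list(split.labels))
    X, tl, y = windows_to_arrays(windows)
    by_visit = split.tabular_by_visit
    tab = np.stack([by_visit[w.visit_id] for w in windows])
    return tab, X, tl, y


@dataclass
class RunResult:
    task: str
    model: ArrestRiskModel
    prepared: PreparedCohort
    report: EvalReport
    history: list[dict]
    threshold: float
    importance: np.ndarray | None = None
    token_names: list[str] = field(default_factory=list)

    def metrics_dict(self) -> dict:
        out = self.report.as_dict()
        out["task"] = self.task
        out["threshold"] = self.threshold
        if self.importance is not None:
            out["attention_importance"] = dict(
                zip(self.token_names, map(float, self.importance)))
        return out


def run_experiment(visits: list[RawVisit], task: str = "CA",
                   wcfg: WindowingConfig | None = None,
                   mcfg: ModelConfig | None = None,
                   tcfg: TrainConfig | None = None,
                   split: SplitSpec | None = None,
                   horizons=(0, 8), seed: int = 0,
                   out_dir=None) -> RunResult:
    """The full pipeline on an in-memory cohort; see module docstring.

    ``seed`` feeds every stage whose config did not pin its own seed.
    """
    wcfg = wcfg or WindowingConfig()
    mcfg = mcfg or ModelConfig(seed=seed)
    tcfg = tcfg or TrainConfig(seed=seed)
    split = split or SplitSpec(seed=seed)

    prepared = prepare_cohort(visits, task=task, split=split)
    train_data = _augmented_arrays(prepared.splits["train"], wcfg)
    val_data = _augmented_arrays(prepared.splits["val"], wcfg)

    model = ArrestRiskModel(prepared.encoder.n_features_, mcfg)
    _, history = train(model, train_data, val_data, tcfg)

    # freeze the operating point on validation, then evaluate test horizons
    val_scores, _ = model.predict(*val_data[:3])
    threshold = (max_f1_threshold(val_scores, val_data[3])
                 if len(np.unique(val_data[3])) > 1 else 0.5)
    test = prepared.splits["test"]
    report = evaluate_horizons(model, test.grids, test.tabular_by_visit,
                               horizons=horizons, labels=list(test.labels),
                               wcfg=wcfg, threshold=threshold,
                               name=f"deep-{task}")

    importance, names = None, []
    if model.attn is not None:
        from .windowing import inference_windows
        pos = [g for g, lab in zip(test.grids, test.labels) if lab]
        wins = inference_windows(pos, 0, wcfg, labels=[True] * len(pos))
        if wins:
            X, tl, _ = windows_to_arrays(wins)
            by_visit = test.tabular_by_visit
            tab = np.stack([by_visit[w.visit_id] for w in wins])
            importance, names = attention_importance(model, tab, X, tl)

    result = RunResult(task=task, model=model, prepared=prepared, report=report,
                       history=history, threshold=threshold,
                       importance=importance, token_names=names)
    if out_dir is not None:
        _write_run(result, wcfg, mcfg, tcfg, split, Path(out_dir))
    return result


def ablate(visits: list[RawVisit], drop: str, task: str = "CA", **kwargs) -> RunResult:
    """Re-run the experiment with one component removed
    (``drop`` in {"base", "univariate", "multivariate", "attention"})."""
    seed = kwargs.pop("seed", 0)
    mcfg = kwargs.pop("mcfg", None) or ModelConfig(seed=seed, ablate=(drop,))
    if drop not in mcfg.ablate:
        mcfg = dataclasses.replace(mcfg, ablate=tuple(mcfg.ablate) + (drop,))
    result = run_experiment(visits, task=task, mcfg=mcfg, seed=seed, **kwargs)
    result.report.name += f"-minus-{drop}"
    return result


def score_ews(visits: list[RawVisit], score: str = "EDICAS", task: str = "CA",
              horizons=(0, 8), split: SplitSpec | None = None,
              prepared: PreparedCohort | None = None) -> EvalReport:
    """Evaluate a rule-based score on the same test partition and horizons
    as the deep model.  ``score`` is a bundled name (EDICAS/MEWS/NEWS) or a
    path to a YAML score table."""
    if prepared is None:
        prepared = prepare_cohort(visits, task=task, split=split or SplitSpec())
    name = str(score)
    if name.upper() in {n.upper() for n in ews_mod.bundled_score_names()}:
        defn = ews_mod.load_bundled_score(name.lower())
    else:
        defn = ews_mod.load_score(score)
    test = prepared.splits["test"]
    triages = [v.triage for v in test.visits]
    return ews_mod.evaluate_ews(defn, triages, test.grids, horizons=horizons,
                                labels=list(test.labels))


def _write_run(result: RunResult, wcfg, mcfg, tcfg, split, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "metrics.json").write_text(
        json.dumps(result.metrics_dict(), indent=2) + "\n")
    with open(out_dir / "history.csv", "w") as fh:
        fh.write("epoch,loss,val_auprc\n")
        for row in result.history:
            fh.write(f"{row['epoch']},{row['loss']:.6f},{row['val_auprc']:.6f}\n")
    config = {
        "task": result.task,
        "windowing": dataclasses.asdict(wcfg),
        "model": dataclasses.asdict(mcfg),
        "training": dataclasses.asdict(tcfg),
        "split": dataclasses.asdict(split),
    }
    (out_dir / "config.json").write_text(json.dumps(config, indent=2, default=list) + "\n")
    (out_dir / "imputation_stats.txt").write_text(result.prepared.stats.to_text())
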