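"""Splitting, training, horizon-based evaluation and attention importance.

Splitting is stratified on eight cells — (short / long stay) x the four
(cpr, dead) combinations — in an 8:1:1 ratio, so class balance and
length distribution are preserved across partitions.

Training uses Adam (lr 1e-4, batch 64) on binary cross-entropy with
early stopping when validation AUPRC has not improved for ``patience``
consecutive epochs; the parameters from the best-validation epoch are
returned.  Augmentation is applied to the training and validation
partitions only — the test partition is always evaluated on the single
window per horizon.

Metric conventions: AUROC is the probability that a random positive
outranks a random negative (ties count 0.5); AUPRC is the
non-interpolated step area (average precision).  Binary metrics use the
threshold that maximises F1 on the validation scores, frozen before
touching the test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .model import ArrestRiskModel, bce_loss
from .nn import Adam
from .preprocess import HourlyGrid
from .windowing import WindowingConfig, inference_windows, windows_to_arrays

__all__ = [
    "SplitSpec", "stratified_split",
    "TrainConfig", "train",
    "EvalRow", "EvalReport", "compute_metrics", "max_f1_threshold",
    "evaluate_horizons", "attention_importance",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[int, int, int] = (8, 1, 1)
    length_cutoff: int = 25   # hours; stays longer than one window are "long"
    seed: int = 0


def stratified_split(lengths, cpr_flags, dead_flags,
                     spec: SplitSpec = SplitSpec()):
    """Return (train_idx, val_idx, test_idx) index arrays.

    Within each stratum the seeded shuffle is split so that the test set
    gets ``ceil(n/10)``, validation ``floor(n/10)`` and training the rest
    (a stratum of 5 therefore splits 4/0/1).  Empty strata are skipped.
    """
    lengths = np.asarray(lengths)
    cpr_flags = np.asarray(cpr_flags, dtype=bool)
    dead_flags = np.asarray(dead_flags, dtype=bool)
    if not (len(lengths) == len(cpr_flags) == len(dead_flags)):
        raise ValueError("length/label arrays disagree")
    total = sum(spec.ratios)
    frac_val = spec.ratios[1] / total
    frac_test = spec.ratios[2] / total
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    long_flag = lengths > spec.length_cutoff
    for is_long in (False, True):
        for cpr in (False, True):
            for dead in (False, True):
                idx = np.flatnonzero((long_flag == is_long)
                                     & (cpr_flags == cpr) & (dead_flags == dead))
                if idx.size == 0:
                    continue
                idx = idx[rng.permutation(idx.size)]
                n = idx.size
                n_test = int(np.ceil(n * frac_test))
                n_val = int(np.floor(n * frac_val))
                n_train = n - n_val - n_test
                train.extend(idx[:n_train])
                val.extend(idx[n_train:n_train + n_val])
                test.extend(idx[n_train + n_val:])
    return (np.sort(np.asarray(train, dtype=int)),
            np.sort(np.asarray(val, dtype=int)),
            np.sort(np.asarray(test, dtype=int)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    patience: int = 80        # epochs without val-AUPRC improvement
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")


class EarlyStopper:
    """Stop when the monitored value has not improved for ``patience``
    consecutive updates (strictly-greater counts as improvement; NaN never
    improves)."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = -np.inf
        self.stale = 0

    def update(self, value: float) -> bool:
        """Record one epoch's value; returns True when training should stop."""
        if value > self.best:
            self.best = value
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def train(model: ArrestRiskModel, train_data, val_data,
          cfg: TrainConfig = TrainConfig()):
    """Fit the model; returns ``(best_state, history)``.

    ``train_data`` / ``val_data`` are ``(tabular, windows, true_lengths,
    labels)`` tuples as produced by
    :func:`edewarn.windowing.windows_to_arrays` plus the matching tabular
    matrix.  ``history`` is a list of per-epoch dicts with keys
    ``epoch``, ``loss``, ``val_auprc``.  The returned state is the
    parameter snapshot from the epoch with the best validation AUPRC.
    """
    tab_tr, X_tr, tl_tr, y_tr = train_data
    tab_va, X_va, tl_va, y_va = val_data
    n = X_tr.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    best_auprc = -np.inf
    best_state = model.state_copy()
    stale = 0
    history: list[dict] = []
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            probs, _ = model.forward(tab_tr[sel], X_tr[sel], tl_tr[sel], rng=rng)
            loss = bce_loss(probs, y_tr[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        epoch_loss /= n
        scores, _ = model.predict(tab_va, X_va, tl_va)
        val_auprc = float(average_precision_score(y_va, scores)) \
            if len(np.unique(y_va)) > 1 else float("nan")
        history.append({"epoch": epoch, "loss": epoch_loss, "val_auprc": val_auprc})
        if val_auprc > best_auprc:
            best_auprc = val_auprc
            best_state = model.state_copy()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state(best_state)
    return best_state, history


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalRow:
    auprc: float
    auroc: float
    recall: float
    precision: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int
    horizon: int | None = None
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None   # (recall, precision)
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)

    def as_dict(self) -> dict:
        return {
            "horizon": self.horizon, "auprc": self.auprc, "auroc": self.auroc,
            "recall": self.recall, "precision": self.precision, "f1": self.f1,
            "threshold": self.threshold, "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


@dataclass
class EvalReport:
    name: str = ""
    rows: dict[int, EvalRow] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"name": self.name,
                "rows": {str(k): r.as_dict() for k, r in self.rows.items()}}


def max_f1_threshold(scores, labels) -> float:
    """Score cutoff maximising F1 (ties resolve to the lowest such cutoff)."""
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # last precision/recall point (recall 0) has no threshold
    f1 = np.zeros(len(thresholds))
    p, r = precision[:-1], recall[:-1]
    ok = (p + r) > 0
    f1[ok] = 2 * p[ok] * r[ok] / (p[ok] + r[ok])
    order = np.argsort(thresholds, kind="stable")
    f1o, to = f1[order], thresholds[order]
    return float(to[int(np.argmax(f1o))])


def compute_metrics(scores, labels, threshold: float | None = None,
                    keep_curves: bool = True) -> EvalRow:
    """Ranking and binary metrics for one horizon.

    ``threshold=None`` selects the max-F1 cutoff from these scores (only
    appropriate on validation data); pass a frozen validation threshold
    when evaluating the test partition.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics require at least one positive and one negative")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    if threshold is None:
        threshold = max_f1_threshold(scores, labels)
    pred = scores >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    row = EvalRow(auprc=auprc, auroc=auroc, recall=recall, precision=precision,
                  f1=f1, threshold=float(threshold), n_pos=n_pos, n_neg=n_neg)
    if keep_curves:
        p, r, _ = precision_recall_curve(labels, scores)
        fpr, tpr, _ = roc_curve(labels, scores)
        row.pr_curve = (r, p)
        row.roc_curve = (fpr, tpr)
    return row


# ---------------------------------------------------------------------------
# horizon evaluation and interpretability
# ---------------------------------------------------------------------------

def evaluate_horizons(model: ArrestRiskModel, grids: list[HourlyGrid],
                      tabular_by_visit: dict[str, np.ndarray],
                      horizons=(0, 8), labels=None,
                      wcfg: WindowingConfig = WindowingConfig(),
                      threshold: float = 0.5, name: str = "") -> EvalReport:
    """Evaluate a trained model at each horizon on an untouched test
    partition.  A horizon with no eligible positives (or negatives) is
    reported as an undefined row (NaN metrics, counts kept)."""
    report = EvalReport(name=name)
    for k in horizons:
        wins = inference_windows(grids, k, wcfg, labels=labels)
        if not wins:
            report.rows[k] = EvalRow(*([float("nan")] * 5), threshold, 0, 0, horizon=k)
            continue
        X, tl, y = windows_to_arrays(wins)
        tab = np.stack([tabular_by_visit[w.visit_id] for w in wins])
        scores, _ = model.predict(tab, X, tl)
        n_pos = int(y.sum())
        n_neg = int(len(y) - n_pos)
        if n_pos == 0 or n_neg == 0:
            row = EvalRow(*([float("nan")] * 5), threshold, n_pos, n_neg, horizon=k)
        else:
            row = compute_metrics(scores, y, threshold=threshold)
            row.horizon = k
        report.rows[k] = row
    return report


def attention_importance(model: ArrestRiskModel, tabular: np.ndarray,
                         windows: np.ndarray, true_lengths: np.ndarray):
    """Attention received by each token, averaged over heads, query rows
    and windows, normalised to sum to one.

    Returns ``(importance, token_names)`` with importance descending order
    available via ``np.argsort(-importance)``; typically called on the
    positive-labelled test windows.
    """
    if windows.shape[0] == 0:
        raise ValueError("attention importance requires at least one window")
    if model.attn is None:
        raise ValueError("interaction layer is ablated; no attention to report")
    _, attn = model.predict(tabular, windows, true_lengths)
    # attn: (B, heads, T, T); softmax rows sum to 1 over keys
    received = attn.mean(axis=(0, 1, 2))
    received = received / received.sum()
    return received, list(model.token_names)
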