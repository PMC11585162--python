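"""Split rules, metric oracles, early-stopping semantics, horizon protocol."""

import numpy as np
import pytest

from edewarn.training import (
    EarlyStopper,
    SplitSpec,
    compute_metrics,
    max_f1_threshold,
    stratified_split,
)


# ---------------------------------------------------------------------------
# exhaustive brute-force oracles, independent of the sklearn-backed engine
# ---------------------------------------------------------------------------

def auroc_oracle(scores, labels):
    """Pairwise concordance: P(random positive outranks random negative)."""
    num = den = 0.0
    for sp, lp in zip(scores, labels):
        if lp != 1:
            continue
        for sn, ln in zip(scores, labels):
            if ln != 0:
                continue
            den += 1
            num += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return num / den


def auprc_oracle(scores, labels):
    """Non-interpolated step area over all cut points (average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = float(np.sum(pred * labels))
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestMetricsAgainstOracles:
    def test_all_small_random_instances_match(self, rng):
        """AUROC/AUPRC equal exhaustive enumeration on every n <= 12 draw."""
        for trial in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n).astype(float)
            if labels.sum() in (0, n):
                continue
            # integer scores force plenty of ties
            scores = rng.integers(0, 5, size=n).astype(float)
            row = compute_metrics(scores, labels, threshold=0.5, keep_curves=False)
            assert row.auroc == pytest.approx(auroc_oracle(scores, labels), abs=1e-12)
            assert row.auprc == pytest.approx(auprc_oracle(scores, labels), abs=1e-12)

    def test_perfect_separation(self):
        row = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert row.auroc == 1.0 and row.auprc == 1.0

    def test_constant_scores_auroc_half(self):
        row = compute_metrics([3, 3, 3, 3], [1, 0, 1, 0], threshold=0.5)
        assert row.auroc == 0.5

    def test_auroc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(float)
        labels[0], labels[1] = 1, 0
        base = compute_metrics(scores, labels, 0.0, keep_curves=False).auroc
        for f in (lambda s: 3 * s + 7, np.tanh, lambda s: np.exp(s / 4)):
            row = compute_metrics(f(scores), labels, 0.0, keep_curves=False)
            assert row.auroc == pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])

    def test_f1_is_harmonic_mean_at_threshold(self):
        row = compute_metrics([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0], threshold=0.5)
        expected = 2 * row.precision * row.recall / (row.precision + row.recall)
        assert row.f1 == pytest.approx(expected)

    def test_max_f1_threshold_frozen_then_applied(self):
        val_scores = np.array([0.9, 0.7, 0.3, 0.2, 0.1])
        val_labels = np.array([1, 1, 0, 0, 0])
        t = max_f1_threshold(val_scores, val_labels)
        assert t <= 0.7  # classifies both positives correctly
        row = compute_metrics([0.8, 0.1], [1, 0], threshold=t)
        assert row.recall == 1.0 and row.precision == 1.0


class TestStratifiedSplit:
    def _split_sizes(self, n, **kw):
        lengths = np.full(n, 10)
        flags = np.zeros(n, dtype=bool)
        tr, va, te = stratified_split(lengths, flags, flags, SplitSpec(**kw))
        return len(tr), len(va), len(te)

    def test_100_splits_80_10_10(self):
        assert self._split_sizes(100) == (80, 10, 10)

    def test_stratum_of_5_splits_4_0_1(self):
        assert self._split_sizes(5) == (4, 0, 1)

    def test_partitions_disjoint_and_exhaustive(self, rng):
        n = 157
        lengths = rng.integers(1, 60, size=n)
        cpr = rng.random(n) < 0.1
        dead = rng.random(n) < 0.15
        tr, va, te = stratified_split(lengths, cpr, dead, SplitSpec(seed=4))
        combined = np.concatenate([tr, va, te])
        assert len(combined) == n
        assert len(np.unique(combined)) == n

    def test_fixed_seed_reproducible(self, rng):
        n = 80
        lengths = rng.integers(1, 60, size=n)
        cpr = rng.random(n) < 0.2
        dead = rng.random(n) < 0.2
        a = stratified_split(lengths, cpr, dead, SplitSpec(seed=11))
        b = stratified_split(lengths, cpr, dead, SplitSpec(seed=11))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_strata_ratios_preserved(self, rng):
        # a large single stratum of positives keeps ~10% in test
        n = 400
        lengths = np.full(n, 30)
        cpr = np.zeros(n, dtype=bool)
        cpr[:100] = True
        dead = np.zeros(n, dtype=bool)
        tr, va, te = stratified_split(lengths, cpr, dead, SplitSpec(seed=0))
        assert np.isin(np.flatnonzero(cpr), te).sum() == 10


class TestEarlyStopping:
    def test_patience_one_stops_after_two_worsening_epochs(self):
        stopper = EarlyStopper(patience=1)
        assert not stopper.update(0.9)   # epoch 0: improvement
        assert stopper.update(0.8)       # epoch 1: no improvement -> stop
        assert stopper.best == 0.9

    def test_patience_counts_consecutive_non_improvements(self):
        stopper = EarlyStopper(patience=3)
        values = [0.5, 0.4, 0.6, 0.55, 0.55, 0.55]
        stops = [stopper.update(v) for v in values]
        assert stops == [False, False, False, False, False, True]

    def test_ties_are_not_improvements(self):
        stopper = EarlyStopper(patience=2)
        assert [stopper.update(v) for v in [0.7, 0.7, 0.7]] == [False, False, True]

    def test_nan_never_improves(self):
        stopper = EarlyStopper(patience=2)
        assert [stopper.update(v) for v in [float("nan")] * 2] == [False, True]

    def test_invalid_patience(self):
        with pytest.raises(ValueError):
            EarlyStopper(patience=0)


class TestHorizonProtocol:
    def test_test_windows_independent_of_training_max_shift(self):
        """Evaluation at k=0 uses identical test windows whatever S was."""
        from edewarn.windowing import WindowingConfig, inference_windows
        from test_windowing import make_grid
        rng = np.random.default_rng(5)
        grids = [make_grid(int(L), label=bool(lab), visit_id=f"G{i}", seed=i)
                 for i, (L, lab) in enumerate(zip(rng.integers(2, 50, 12),
                                                  rng.random(12) < 0.4))]
        for k in (0, 3):
            a = inference_windows(grids, k, WindowingConfig(max_shift=0))
            b = inference_windows(grids, k, WindowingConfig(max_shift=13))
            assert len(a) == len(b)
            for wa, wb in zip(a, b):
                np.testing.assert_array_equal(wa.values, wb.values)
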