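"""Contracts of the multi-modal network: shapes, determinism, padding
invariance, channel independence, ablations, loss closed forms, checkpoints."""

import numpy as np
import pytest

from edewarn.model import ArrestRiskModel, ModelConfig, bce_loss
from edewarn.nn import Adam, Tensor


CENTERS = np.array([120.0, 75.0, 85.0, 96.0, 36.8, 18.0])
SPREADS = np.array([20.0, 12.0, 15.0, 2.0, 0.5, 4.0])


def make_batch(rng, B=4, W=25, n_tab=20, true_lengths=None):
    """Physiologically plausible windows (per-channel centre/spread)."""
    tab = rng.normal(size=(B, n_tab))
    X = CENTERS[None, :, None] + SPREADS[None, :, None] * rng.normal(size=(B, 6, W))
    tl = np.full(B, W) if true_lengths is None else np.asarray(true_lengths)
    for b in range(B):
        X[b, :, tl[b]:] = 0.0  # end padding
    return tab, X, tl


@pytest.fixture(scope="module")
def model():
    return ArrestRiskModel(20, ModelConfig(seed=7))


class TestForwardContracts:
    def test_shapes_and_probability_range(self, model, rng):
        tab, X, tl = make_batch(rng)
        p, attn = model.predict(tab, X, tl)
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))
        assert attn.shape == (4, 4, 8, 8)

    def test_attention_rows_sum_to_one(self, model, rng):
        tab, X, tl = make_batch(rng)
        _, attn = model.predict(tab, X, tl)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)

    def test_identical_inputs_identical_outputs(self, model, rng):
        tab, X, tl = make_batch(rng, B=2)
        tab[1], X[1], tl[1] = tab[0], X[0], tl[0]
        p, _ = model.predict(tab, X, tl)
        assert p[0] == p[1]

    def test_true_length_below_one_rejected(self, model, rng):
        tab, X, tl = make_batch(rng)
        tl[0] = 0
        with pytest.raises(ValueError):
            model.predict(tab, X, tl)


class TestPaddingInvariance:
    def test_prediction_depends_only_on_real_columns(self, model, rng):
        # same 10 real columns, every possible pad count of the rest
        tab, X, _ = make_batch(rng, B=1)
        real = X[0, :, :10]
        probs = []
        for pad_value in (0.0, 0.0, 123.0, -55.0):
            Xp = np.full((1, 6, 25), pad_value)
            Xp[0, :, :10] = real
            p, _ = model.predict(tab[:1], Xp, np.array([10]))
            probs.append(p[0])
        assert len(set(np.round(probs, 15))) == 1

    def test_same_prefix_different_pad_counts_equal_tokens(self, model, rng):
        tab, X, _ = make_batch(rng, B=2)
        X[1] = 0.0
        X[1, :, :10] = X[0, :, :10] = rng.uniform(60, 140, size=(6, 10))
        X[0, :, 10:] = 0.0
        p, _ = model.predict(tab[:1].repeat(2, axis=0), X, np.array([10, 10]))
        assert p[0] == p[1]


class TestChannelIndependence:
    def test_perturbing_one_channel_moves_only_its_token(self, model, rng):
        tab, X, tl = make_batch(rng, B=1)
        hr_row = list(np.array([c.value for c in
                                __import__("edewarn").VitalChannel])).index("HR")
        X2 = X.copy()
        X2[0, hr_row, :] += 10.0
        h1 = model.gru(Tensor((X - 120.0) / 20.0), tl).data
        h2 = model.gru(Tensor((X2 - 120.0) / 20.0), tl).data
        changed = [not np.allclose(h1[0, c], h2[0, c]) for c in range(6)]
        assert changed[hr_row] and sum(changed) == 1

    def test_constant_channel_token_depends_only_on_value_and_length(self, model, rng):
        # same channel fed the same constant in two different windows gives
        # the same token, whatever the other channels carry
        x1 = rng.normal(size=(1, 6, 25))
        x2 = rng.normal(size=(1, 6, 25))
        x1[0, 2, :] = x2[0, 2, :] = 0.4
        h1 = model.gru(Tensor(x1), np.array([25])).data
        h2 = model.gru(Tensor(x2), np.array([25])).data
        np.testing.assert_allclose(h1[0, 2], h2[0, 2], atol=1e-12)


class TestAblations:
    @pytest.mark.parametrize("drop,n_tokens", [
        ("base", 7), ("univariate", 2), ("multivariate", 7), ("attention", 8)])
    def test_each_ablation_is_runnable(self, drop, n_tokens, rng):
        m = ArrestRiskModel(20, ModelConfig(seed=0, ablate=(drop,)))
        assert m.n_tokens == n_tokens
        tab, X, tl = make_batch(rng)
        p, attn = m.predict(tab, X, tl)
        assert np.all((p > 0) & (p < 1))
        if drop == "attention":
            assert attn is None

    def test_invalid_flag_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(ablate=("bogus",))


class TestLoss:
    def test_half_probability_positive_label_is_ln2(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
            np.log(2), abs=1e-9)

    def test_symmetric_cases_equal(self):
        a = bce_loss(np.array([0.9]), np.array([1.0]))
        b = bce_loss(np.array([0.1]), np.array([0.0]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_perfect_prediction_loss_vanishes(self):
        assert bce_loss(np.array([1 - 1e-12, 1e-12]),
                        np.array([1.0, 0.0])) < 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5, 0.5]), np.array([1.0]))

    def test_tensor_and_array_paths_agree(self, rng):
        p = rng.uniform(0.01, 0.99, size=8)
        y = (rng.random(8) < 0.5).astype(float)
        assert bce_loss(Tensor(p), y).data == pytest.approx(bce_loss(p, y))


class TestCheckpoint:
    def test_roundtrip_reproduces_forward_bitwise(self, tmp_path, rng):
        m = ArrestRiskModel(12, ModelConfig(seed=3))
        tab, X, tl = make_batch(rng, n_tab=12)
        p0, _ = m.predict(tab, X, tl)
        path = tmp_path / "ckpt.npz"
        m.save(path)
        m2 = ArrestRiskModel.load(path)
        p1, _ = m2.predict(tab, X, tl)
        np.testing.assert_array_equal(p0, p1)

    def test_mismatched_manifest_refused(self, tmp_path):
        m = ArrestRiskModel(12, ModelConfig(seed=3))
        path = tmp_path / "ckpt.npz"
        m.save(path)
        import json
        import numpy as np_
        with np_.load(path) as data:
            meta = json.loads(str(data["meta_json"]))
            cfg = json.loads(meta["fingerprint"])
            cfg["n_tabular_features"] = 13
            meta["fingerprint"] = json.dumps(cfg)
            arrays = {k: data[k] for k in data.files if k != "meta_json"}
        np_.savez(path, meta_json=np_.array(json.dumps(meta)), **arrays)
        with pytest.raises(ValueError):
            ArrestRiskModel.load(path)


def test_capacity_overfits_tiny_window_set(rng):
    """Gradient plumbing: the full model drives BCE below 0.01 on 32 windows."""
    m = ArrestRiskModel(10, ModelConfig(seed=1, dropout=0.0))
    tab, X, tl = make_batch(rng, B=32, n_tab=10)
    y = (rng.random(32) < 0.5).astype(float)
    opt = Adam(m.parameters(), lr=3e-3)
    loss_val = np.inf
    for epoch in range(500):
        probs, _ = m.forward(tab, X, tl)
        from edewarn.model import bce_loss as bce
        loss = bce(probs, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_val = float(loss.data)
        if loss_val < 0.01:
            break
    assert loss_val < 0.01
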