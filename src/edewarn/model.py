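"""The hybrid arrest-risk network.

Four stages mirror the pipeline's multi-modal design:

1. *Base encoder* — an attentive (TabNet-style) encoder turns the one-hot
   triage vector, first projected to a fixed 32-wide feature space, into
   one 8-dimensional token.
2. *Multivariate temporal encoder* — a dilated causal TCN over the full
   6-channel window yields a second token.
3. *Univariate temporal encoders* — six independent GRUs, one per vital
   sign, yield six more tokens, insulating sparsely measured channels
   (e.g. SpO2) from the rest.
4. *Interaction layer* — 4-head self-attention over the 8 tokens; the
   fused tokens are concatenated and passed through a small feed-forward
   head ending in a sigmoid.

Short stays are end-padded; every temporal encoder reads its output at
``true_length - 1`` ("read early"), so predictions depend only on real
columns.  Each component can be ablated independently, which changes the
token count (7 / 2 / 7 tokens, or 8 with attention bypassed).

Training minimises binary cross-entropy; see :func:`bce_loss`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import CHANNELS, VitalChannel
from .nn import (
    Adam,  # noqa: F401  (re-exported for callers configuring training)
    AttentiveTabularEncoder,
    Dropout,
    GRUBank,
    Linear,
    Module,
    MultiHeadSelfAttention,
    TemporalConvNet,
    Tensor,
    concat,
    no_grad,
)

__all__ = ["ModelConfig", "ArrestRiskModel", "bce_loss", "TOKEN_NAMES"]

ABLATABLE = ("base", "univariate", "multivariate", "attention")

# Fixed affine normalisation of raw vital units before the temporal
# encoders (physiologic centre / spread; not data-dependent, so inference
# needs no extra state).  Padding is appended after normalisation and the
# read-early rule keeps it out of every token.
_NORM = {
    VitalChannel.SBP: (120.0, 25.0),
    VitalChannel.DBP: (75.0, 15.0),
    VitalChannel.HR: (85.0, 20.0),
    VitalChannel.SPO2: (96.0, 4.0),
    VitalChannel.BT: (36.8, 0.8),
    VitalChannel.RR: (18.0, 5.0),
}
_NORM_CENTER = np.array([[_NORM[c][0]] for c in CHANNELS])
_NORM_SCALE = np.array([[_NORM[c][1]] for c in CHANNELS])


@dataclass(frozen=True)
class ModelConfig:
    base_input_dim: int = 32
    token_dim: int = 8
    n_heads: int = 4
    tab_steps: int = 2
    uni_hidden: int = 16
    tcn_width: int = 32
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    head_hidden: int = 64
    dropout: float = 0.1
    seed: int = 0
    ablate: tuple[str, ...] = ()

    def __post_init__(self):
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        bad = set(self.ablate) - set(ABLATABLE)
        if bad:
            raise ValueError(f"unknown ablation flags {sorted(bad)}")


def bce_loss(probs, labels):
    """Binary cross-entropy, ``-(1/N) sum[y ln x + (1-y) ln(1-x)]``.

    Accepts a :class:`Tensor` (training path, differentiable) or a plain
    array (metric path); probabilities are clamped away from {0, 1}.
    """
    y = np.asarray(labels, dtype=float)
    if isinstance(probs, Tensor):
        if probs.data.shape != y.shape:
            raise ValueError("probs and labels length mismatch")
        p = probs.clip(1e-12, 1.0 - 1e-12)
        yt = Tensor(y)
        return -((yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean())
    p = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0 - 1e-12)
    if p.shape != y.shape:
        raise ValueError("probs and labels length mismatch")
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


class ArrestRiskModel(Module):
    """Base + multivariate + six univariate encoders fused by self-attention."""

    def __init__(self, n_tabular_features: int, config: ModelConfig = ModelConfig()):
        self.config = config
        self.n_tabular_features = n_tabular_features
        rng = np.random.default_rng(config.seed)
        d = config.token_dim
        C = len(CHANNELS)

        self.base = None
        if "base" not in config.ablate:
            self.base = AttentiveTabularEncoder(
                n_tabular_features, config.base_input_dim, d, config.tab_steps, rng)

        self.tcn = None
        if "multivariate" not in config.ablate:
            self.tcn = TemporalConvNet(C, config.tcn_width, config.tcn_kernel,
                                       config.tcn_dilations, rng)
            self.tcn_proj = Linear(config.tcn_width, d, rng)

        self.gru = None
        if "univariate" not in config.ablate:
            self.gru = GRUBank(C, config.uni_hidden, rng)
            lim = np.sqrt(6.0 / (config.uni_hidden + d))
            self.gru_proj_W = Tensor(
                rng.uniform(-lim, lim, size=(C, config.uni_hidden, d)),
                requires_grad=True)
            self.gru_proj_b = Tensor(np.zeros((C, d)), requires_grad=True)

        self.attn = None
        if "attention" not in config.ablate:
            self.attn = MultiHeadSelfAttention(d, config.n_heads, rng)

        self.n_tokens = ((self.base is not None) + (self.tcn is not None)
                         + (6 if self.gru is not None else 0))
        if self.n_tokens == 0:
            raise ValueError("all encoders ablated; nothing to predict from")
        self.drop = Dropout(config.dropout)
        self.fc1 = Linear(self.n_tokens * d, config.head_hidden, rng)
        self.fc2 = Linear(config.head_hidden, 1, rng)
        self.token_names = self._token_names()

    def _token_names(self) -> list[str]:
        names = []
        if self.base is not None:
            names.append("tabular")
        if self.tcn is not None:
            names.append("multivariate")
        if self.gru is not None:
            names.extend(c.value for c in CHANNELS)
        return names

    # -- forward --------------------------------------------------------------
    def forward(self, tabular: np.ndarray, windows: np.ndarray,
                true_lengths: np.ndarray,
                rng: np.random.Generator | None = None):
        """Score a batch.

        Parameters: ``tabular`` (B, n_tab), ``windows`` (B, 6, W) in raw
        units with end padding, ``true_lengths`` (B,).  Returns
        ``(probs, attention)`` where ``probs`` is a Tensor of shape (B,)
        and ``attention`` is an (B, heads, T, T) array or ``None`` when the
        interaction layer is ablated.
        """
        true_lengths = np.asarray(true_lengths, dtype=int)
        if np.any(true_lengths < 1):
            raise ValueError("true_length must be >= 1")
        B = windows.shape[0]
        d = self.config.token_dim
        x = Tensor((windows - _NORM_CENTER) / _NORM_SCALE)

        tokens: list[Tensor] = []
        if self.base is not None:
            tokens.append(self.base(Tensor(tabular)).reshape(B, 1, d))
        if self.tcn is not None:
            feat = self.tcn(x, true_lengths)
            tokens.append(self.tcn_proj(feat).reshape(B, 1, d))
        if self.gru is not None:
            h = self.gru(x, true_lengths)  # (B, 6, H)
            C, H = h.shape[1], h.shape[2]
            uni = (h.reshape(B, C, 1, H) @ self.gru_proj_W).reshape(B, C, d) \
                + self.gru_proj_b
            tokens.append(uni)
        seq = concat(tokens, axis=1)  # (B, n_tokens, d)

        attention = None
        if self.attn is not None:
            seq, attention = self.attn(seq)
        flat = seq.reshape(B, self.n_tokens * d)
        hidden = self.drop(self.fc1(flat).relu(), rng)
        # clamp keeps the (0,1) contract even when float64 sigmoid saturates
        probs = self.fc2(hidden).sigmoid().reshape(B).clip(1e-12, 1.0 - 1e-12)
        return probs, attention

    def predict(self, tabular, windows, true_lengths, batch_size: int = 256):
        """Inference-mode probabilities (and attention) without a tape."""
        self.eval()
        probs_parts, attn_parts = [], []
        with no_grad():
            for lo in range(0, windows.shape[0], batch_size):
                hi = lo + batch_size
                p, a = self.forward(tabular[lo:hi], windows[lo:hi],
                                    true_lengths[lo:hi])
                probs_parts.append(p.data)
                if a is not None:
                    attn_parts.append(a)
        probs = np.concatenate(probs_parts) if probs_parts else np.empty(0)
        attn = np.concatenate(attn_parts) if attn_parts else None
        return probs, attn

    # -- checkpointing --------------------------------------------------------
    def fingerprint(self) -> str:
        cfg = asdict(self.config)
        cfg["ablate"] = list(cfg["ablate"])
        cfg["tcn_dilations"] = list(cfg["tcn_dilations"])
        cfg["n_tabular_features"] = self.n_tabular_features
        return json.dumps(cfg, sort_keys=True)

    def save(self, path, extra: dict | None = None) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {"fingerprint": self.fingerprint()}
        if extra:
            meta.update(extra)
        np.savez(path, meta_json=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "ArrestRiskModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta_json"]))
            cfg = json.loads(meta["fingerprint"])
            n_tab = cfg.pop("n_tabular_features")
            cfg["ablate"] = tuple(cfg["ablate"])
            cfg["tcn_dilations"] = tuple(cfg["tcn_dilations"])
            model = cls(n_tab, ModelConfig(**cfg))
            params = model.parameters()
            for i, p in enumerate(params):
                arr = data[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint does not match model manifest")
                p.data = arr.copy()
        return model

    def state_copy(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state):
            p.data = arr.copy()
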