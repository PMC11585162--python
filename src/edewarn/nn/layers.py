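"""Neural building blocks for the arrest-risk model.

All layers hold their parameters as :class:`~edewarn.nn.autograd.Tensor`
objects with ``requires_grad=True`` and expose ``parameters()`` returning
them in a stable order (needed for checkpointing and for Adam state).
Initialisation is Glorot-uniform from a caller-supplied
``numpy.random.Generator`` so a model is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "Dropout",
    "GRUBank",
    "TemporalConvNet",
    "MultiHeadSelfAttention",
    "AttentiveTabularEncoder",
]


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name in sorted(vars(self)):
            v = getattr(self, name)
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for name in vars(self):
            v = getattr(self, name)
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout driven by an external generator (seeded per step)."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class GRUBank(Module):
    """Six independent single-input GRUs run in lock-step.

    One GRU per vital-sign channel; the channels share no weights but are
    advanced together so one numpy matmul per gate covers all of them
    (weights carry a leading channel axis and broadcast against the batch).
    The hidden state is read at ``true_length - 1`` for each sample, which
    makes end-padding invisible to the output.
    """

    def __init__(self, n_channels: int, hidden: int, rng: np.random.Generator):
        self.n_channels = n_channels
        self.hidden = hidden
        # input weights (C, 1, 3H), recurrent weights (C, H, 3H), bias (C, 3H)
        self.Wx = Tensor(_glorot(rng, n_channels, 1, 3 * hidden), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, n_channels, hidden, 3 * hidden), requires_grad=True)
        self.b = Tensor(np.zeros((n_channels, 3 * hidden)), requires_grad=True)

    def __call__(self, x: Tensor, true_lengths: np.ndarray) -> Tensor:
        """x: (B, C, L) -> hidden states at true_length-1, shape (B, C, H)."""
        B, C, L = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, C, H)))
        outs = []
        for t in range(L):
            xt = x[:, :, t].reshape(B, C, 1, 1)  # (B, C, 1, 1)
            gates = (xt @ self.Wx).reshape(B, C, 3 * H) \
                + (h.reshape(B, C, 1, H) @ self.Wh).reshape(B, C, 3 * H) \
                + self.b
            z = gates[:, :, :H].sigmoid()
            r = gates[:, :, H:2 * H].sigmoid()
            # candidate uses the reset-gated hidden state
            n_in = (xt @ self.Wx)[:, :, 0, 2 * H:] + \
                ((r * h).reshape(B, C, 1, H) @ self.Wh)[:, :, 0, 2 * H:] + \
                self.b[:, 2 * H:]
            n = n_in.tanh()
            h = z * h + (1.0 - z) * n
            outs.append(h)
        seq = stack(outs, axis=1)  # (B, L, C, H)
        idx = np.clip(true_lengths - 1, 0, L - 1)
        return seq[np.arange(B), idx]  # (B, C, H)


class _CausalConv1d(Module):
    """Dilated causal convolution on (B, L, C_in) -> (B, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.dilation = dilation
        self.W = Tensor(_glorot(rng, kernel * c_in, c_out).reshape(kernel, c_in, c_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        pad = (self.kernel - 1) * self.dilation
        xp = concat([Tensor(np.zeros((B, pad, x.shape[2]))), x], axis=1)
        out = None
        for j in range(self.kernel):
            start = j * self.dilation
            term = xp[:, start:start + L, :] @ self.W[j]
            out = term if out is None else out + term
        return out + self.b


class _TCNBlock(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.conv1 = _CausalConv1d(c_in, c_out, kernel, dilation, rng)
        self.conv2 = _CausalConv1d(c_out, c_out, kernel, dilation, rng)
        self.down = Linear(c_in, c_out, rng) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu()).relu()
        skip = x if self.down is None else self.down(x)
        return y + skip


class TemporalConvNet(Module):
    """Stack of dilated causal residual blocks (the multivariate encoder).

    With kernel 3 and dilations (1, 2, 4, 8) each block adds 2*(k-1)*d to the
    receptive field; the default stack sees 61 steps, comfortably covering a
    25-hour window.  Output is read at ``true_length - 1`` (read-early), so
    end padding cannot leak into the token.
    """

    def __init__(self, c_in: int, width: int, kernel: int,
                 dilations: tuple[int, ...], rng: np.random.Generator):
        blocks = []
        prev = c_in
        for d in dilations:
            blocks.append(_TCNBlock(prev, width, kernel, d, rng))
            prev = width
        self.blocks = blocks

    def __call__(self, x: Tensor, true_lengths: np.ndarray) -> Tensor:
        """x: (B, C, L) -> features at true_length-1, shape (B, width)."""
        B, C, L = x.shape
        h = x.transpose(0, 2, 1)  # (B, L, C)
        for blk in self.blocks:
            h = blk(h)
        idx = np.clip(true_lengths - 1, 0, L - 1)
        return h[np.arange(B), idx]


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the token sequence.

    Bare attention (no residual / layer-norm sublayers): the token sequence
    is short (at most 8) and the fused representation is consumed by a
    feed-forward head immediately afterwards.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"token dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)

    def __call__(self, tokens: Tensor) -> tuple[Tensor, np.ndarray]:
        """tokens: (B, T, dim) -> (fused (B, T, dim), attention (B, heads, T, T))."""
        B, T, D = tokens.shape
        hd = D // self.n_heads

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.n_heads, hd).transpose(0, 2, 1, 3)

        q, k, v = heads(self.Wq(tokens)), heads(self.Wk(tokens)), heads(self.Wv(tokens))
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(hd)
        attn = scores.softmax(axis=-1)  # (B, heads, T, T); rows sum to 1
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.Wo(mixed), attn.data


class AttentiveTabularEncoder(Module):
    """Sequential-attention tabular encoder (TabNet-style, simplified).

    The one-hot triage vector is first projected to a fixed 32-wide feature
    space; each decision step then computes a softmax attention mask over
    those 32 features, multiplies it in, and passes the masked features
    through a small transform whose outputs are summed across steps —
    the soft feature-selection idea of attentive tabular models, without
    sparsemax or ghost batch-norm.
    """

    def __init__(self, n_in: int, feat_dim: int, out_dim: int, n_steps: int,
                 rng: np.random.Generator):
        self.proj = Linear(n_in, feat_dim, rng)
        self.mask_layers = [Linear(feat_dim, feat_dim, rng) for _ in range(n_steps)]
        self.transforms = [Linear(feat_dim, feat_dim, rng) for _ in range(n_steps)]
        self.out = Linear(feat_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.proj(x).relu()
        state = f
        agg = None
        for mask_l, trans_l in zip(self.mask_layers, self.transforms):
            mask = mask_l(state).softmax(axis=-1)
            step = trans_l(f * mask).relu()
            agg = step if agg is None else agg + step
            state = step
        return self.out(agg)
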