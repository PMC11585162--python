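"""Fixed-size window extraction and minority-class window-shift augmentation.

The model consumes 6 x W windows (W = 25 hours by default) whose right
edge sits at ``T = -k`` for shift/horizon ``k``.  Stays shorter than the
window are zero-padded *at the end* (after reordering oldest -> newest)
and the encoders read their output at ``true_length - 1``, so the padding
is never seen.

Augmentation shifts the window left one hour at a time, but only for the
minority (event) class and only while the shifted window is fully
unpadded: a grid of length L yields shifts ``k = 0 .. min(S, L - W)``
(window 0 is always emitted, padded if necessary).  The test partition is
never augmented; at inference, horizon ``k`` uses the single window whose
right edge is ``T = -k`` for every visit that has any observed history at
or before that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import HourlyGrid

__all__ = ["WindowingConfig", "Window", "window_at", "augment_minority",
           "inference_windows"]


@dataclass(frozen=True)
class WindowingConfig:
    window_size: int = 25       # W, hours
    stride: int = 1             # hours; the shifting stride is one hour
    max_shift: int = 13         # S; 13 for the CA task, swept 0..8 for CPR
    minority_only: bool = True

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.stride != 1:
            raise ValueError("window shifting stride is fixed at one hour")


@dataclass
class Window:
    """One model input: 6 x W values ordered oldest -> newest, end-padded."""

    visit_id: str
    shift: int                 # k: right edge sits at T = -k
    values: np.ndarray         # (6, W)
    true_length: int           # number of real (unpadded) columns, 1..W
    label: bool

    @property
    def pad_count(self) -> int:
        return self.values.shape[1] - self.true_length


def window_at(grid: HourlyGrid, k: int, cfg: WindowingConfig = WindowingConfig(),
              label: bool | None = None) -> Window | None:
    """Extract the window with right edge at ``T = -k``; ``None`` if the grid
    has no originally observed cell at ``T <= -k``."""
    if k < 0:
        raise ValueError("shift k must be >= 0")
    if not grid.imputed:
        raise ValueError("window extraction requires an imputed grid")
    W = cfg.window_size
    right = -k
    left = right - (W - 1)
    # eligibility: at least one originally observed cell at T <= -k
    hi = grid.column_index(right)
    if hi < 0 or not grid.observed_mask[:, :hi + 1].any():
        return None
    lo = max(left, grid.t_min)
    block = grid.values[:, grid.column_index(lo):hi + 1]
    true_length = block.shape[1]
    values = np.zeros((grid.values.shape[0], W))
    values[:, :true_length] = block
    if label is None:
        label = grid.label_ca
    return Window(visit_id=grid.visit_id, shift=k, values=values,
                  true_length=true_length, label=bool(label))


def n_training_windows(length: int, positive: bool, cfg: WindowingConfig) -> int:
    """Window count contributed by one grid under the augmentation rule."""
    if not positive and cfg.minority_only:
        return 1
    return 1 + max(0, min(cfg.max_shift, length - cfg.window_size))


def augment_minority(grids: list[HourlyGrid], cfg: WindowingConfig = WindowingConfig(),
                     labels: list[bool] | None = None) -> list[Window]:
    """Window-shift augmentation for a training/validation partition.

    Majority grids contribute the single window ``k = 0``; minority grids
    contribute ``k = 0 .. min(S, L - W)`` — the ``k = 0`` window always,
    shifted windows only while fully unpadded.  Every window inherits the
    grid's label.
    """
    if labels is None:
        labels = [g.label_ca for g in grids]
    out: list[Window] = []
    for grid, lab in zip(grids, labels):
        n = n_training_windows(grid.length, bool(lab), cfg)
        for k in range(n):
            w = window_at(grid, k, cfg, label=lab)
            if w is not None:
                out.append(w)
    return out


def inference_windows(grids: list[HourlyGrid], k: int,
                      cfg: WindowingConfig = WindowingConfig(),
                      labels: list[bool] | None = None) -> list[Window]:
    """Horizon-``k`` evaluation windows: one per grid where the window exists.

    At ``k = 0`` every visit contributes; at ``k > 0`` only visits with
    observed history at or before ``T = -k`` remain, so the positive count
    can only shrink with the horizon.
    """
    if labels is None:
        labels = [g.label_ca for g in grids]
    out = []
    for grid, lab in zip(grids, labels):
        w = window_at(grid, k, cfg, label=lab)
        if w is not None:
            out.append(w)
    return out


def windows_to_arrays(windows: list[Window]):
    """Stack windows into model-ready arrays (values, true_lengths, labels)."""
    X = np.stack([w.values for w in windows])
    tl = np.asarray([w.true_length for w in windows], dtype=int)
    y = np.asarray([w.label for w in windows], dtype=float)
    return X, tl, y
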