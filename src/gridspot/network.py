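"""Fully convolutional grid-cell regression network and its training losses.

The model is a U-Net whose every encoding step is [``convs_per_block``
3x3 convolutions -> squeeze-and-excitation -> spatial dropout -> 2x
max-pool]; decoding steps share the layout without dropout; a skip
connection carries the bottleneck input across the bottleneck block.  A
second encoder then reduces the full-resolution representation by
log2(cell_size) further pooling steps, and a 1x1 convolution with a
logistic head emits, per grid-cell, a spot probability and two
within-cell offsets — three channels, all in (0, 1).

The objective is J = J_class + 2 * J_loc: a soft-dice loss on the
probability channel plus, with double weight, the RMSE of the offset
channels over ground-truth spot cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from ._nn import Parameter, Tensor

__all__ = [
    "NetworkConfig",
    "LossBreakdown",
    "GridNet",
    "build_network",
    "dice_loss",
    "localization_loss",
    "combined_loss",
]

DICE_EPS = 1e-7


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    cell_size
        Side length in pixels of one grid-cell; must be a power of two.
        Trades classification class-imbalance (small cells) against the
        risk of multiple spots per cell (large cells).
    filters
        Constant channel width used in every convolutional layer.
    unet_depth
        Number of pooling steps in the U-Net encoder.
    convs_per_block
        3x3 convolutions per block.
    se_reduction
        Channel reduction ratio of the squeeze-and-excitation bottleneck.
    dropout_rate
        Spatial (whole-feature-map) dropout rate before each pooling step.
    use_se, use_bottleneck_skip, use_dropout
        Ablation switches for the squeeze-and-excitation blocks, the skip
        across the bottleneck, and spatial dropout.
    """

    cell_size: int = 4
    filters: int = 64
    unet_depth: int = 3
    convs_per_block: int = 3
    se_reduction: int = 16
    dropout_rate: float = 0.3
    use_se: bool = True
    use_bottleneck_skip: bool = True
    use_dropout: bool = True

    def __post_init__(self):
        if not _is_power_of_two(self.cell_size):
            raise ValueError(
                f"cell_size must be a power of two >= 1, got {self.cell_size}"
            )
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.unet_depth < 0:
            raise ValueError("unet_depth must be >= 0")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def divisor(self) -> int:
        """Required divisibility of input height/width."""
        return (2 ** self.unet_depth) * self.cell_size

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LossBreakdown:
    """The objective J = J_class + 2 * J_loc and its parts."""

    j_class: float
    j_loc: float
    j: float
    n_spot_cells: int


class GridNet:
    """The network as a parameterized callable: images in, grids out.

    Parameters are float32 numpy arrays wrapped as autodiff leaves; the
    forward pass builds the graph used for backpropagation during
    training.  Calling the instance runs plain inference.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self._params: list[tuple[str, Parameter]] = []
        rng = np.random.default_rng(seed)
        f = config.filters
        d = config.unet_depth
        k = config.convs_per_block

        def conv_p(name, ci, co):
            w = Parameter(rng.normal(0.0, math.sqrt(2.0 / (9 * ci)),
                                     (3, 3, ci, co)).astype(np.float32))
            b = Parameter(np.zeros(co, dtype=np.float32))
            self._params += [(name + ".w", w), (name + ".b", b)]
            return w, b

        def dense_p(name, ci, co):
            w = Parameter(rng.normal(0.0, math.sqrt(2.0 / ci),
                                     (ci, co)).astype(np.float32))
            b = Parameter(np.zeros(co, dtype=np.float32))
            self._params += [(name + ".w", w), (name + ".b", b)]
            return w, b

        def block_p(name, ci):
            convs = [conv_p(f"{name}.conv{i}", ci if i == 0 else f, f)
                     for i in range(k)]
            se = None
            if config.use_se:
                hidden = max(1, f // config.se_reduction)
                se = (dense_p(f"{name}.se_fc1", f, hidden),
                      dense_p(f"{name}.se_fc2", hidden, f))
            return {"convs": convs, "se": se}

        self.enc = [block_p(f"enc{i}", 1 if i == 0 else f) for i in range(d)]
        self.bottleneck = block_p("bottleneck", 1 if d == 0 else f)
        bott_out = f + (1 if d == 0 else f) if config.use_bottleneck_skip else f
        self.dec = []
        ci = bott_out
        for i in reversed(range(d)):
            self.dec.append(block_p(f"dec{i}", ci + f))
            ci = f
        n_second = int(math.log2(config.cell_size))
        self.second = [block_p(f"second{i}", ci if i == 0 else f)
                       for i in range(n_second)]
        head_in = ci if n_second == 0 else f
        hw = Parameter(rng.normal(0.0, math.sqrt(1.0 / head_in),
                                  (head_in, 3)).astype(np.float32))
        hb = Parameter(np.zeros(3, dtype=np.float32))
        self._params += [("head.w", hw), ("head.b", hb)]
        self.head = (hw, hb)

    # -- parameter access ---------------------------------------------------

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self._params]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self._params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self._params:
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {name!r}: shape {arr.shape} != {p.data.shape}"
                )
            p.data = arr.copy()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward ------------------------------------------------------------

    def _block(self, h: Tensor, params: dict) -> Tensor:
        for w, b in params["convs"]:
            h = _nn.relu(_nn.conv3x3(h, w, b))
        if params["se"] is not None:
            (w1, b1), (w2, b2) = params["se"]
            s = _nn.global_avg_pool(h)
            s = _nn.relu(_nn.dense(s, w1, b1))
            s = _nn.sigmoid(_nn.dense(s, w2, b2))
            h = _nn.channel_gate(h, s)
        return h

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Map (N,H,W) images to (N, H/cs, W/cs, 3) grid tensors."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError(f"expected (N,H,W) images, got shape {x.shape}")
        n, hgt, wid = x.shape
        div = self.config.divisor
        if hgt % div or wid % div:
            raise ValueError(
                f"image shape ({hgt},{wid}) not divisible by "
                f"2^unet_depth*cell_size = {div}"
            )
        if training and self.config.use_dropout and rng is None:
            rng = np.random.default_rng()
        cfg = self.config
        drop = cfg.dropout_rate if (training and cfg.use_dropout) else 0.0

        h = Tensor(x[..., None])
        skips = []
        for blk in self.enc:
            h = self._block(h, blk)
            skips.append(h)
            h = _nn.spatial_dropout(h, drop, rng, training)
            h = _nn.maxpool2(h)
        pre = h
        h = self._block(h, self.bottleneck)
        if cfg.use_bottleneck_skip:
            h = _nn.concat(h, pre)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = _nn.upsample2(h)
            h = _nn.concat(h, skip)
            h = self._block(h, blk)
        for blk in self.second:
            h = self._block(h, blk)
            h = _nn.spatial_dropout(h, drop, rng, training)
            h = _nn.maxpool2(h)
        return _nn.sigmoid(_nn.conv1x1(h, *self.head))

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """Inference: returns the (N, H/cs, W/cs, 3) grid as an ndarray."""
        return self.forward(images, training=False).data


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> GridNet:
    """Construct a randomly initialized grid-regression network."""
    return GridNet(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# loss surface on plain arrays (single implementation shared with training
# via the _nn ops)
# ---------------------------------------------------------------------------


def dice_loss(pred_p: np.ndarray, true_p: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft-dice loss between probability grids, pooled over the whole batch.

    1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps); 0 for a perfect
    prediction and ~1 for disjoint support.
    """
    pred_p = np.asarray(pred_p, dtype=np.float64)
    true_p = np.asarray(true_p, dtype=np.float64)
    if pred_p.shape != true_p.shape:
        raise ValueError("probability grids must share a shape")
    inter = (pred_p * true_p).sum()
    return float(1.0 - (2.0 * inter + eps) / (pred_p.sum() + true_p.sum() + eps))


def localization_loss(pred_offsets: np.ndarray, true_offsets: np.ndarray,
                      spot_mask: np.ndarray) -> float:
    """RMSE of within-cell offsets over ground-truth spot cells.

    Each spot cell contributes the squared error of both offset channels
    and counts once in n; an empty mask yields 0.
    """
    pred_offsets = np.asarray(pred_offsets, dtype=np.float64)
    true_offsets = np.asarray(true_offsets, dtype=np.float64)
    mask = np.asarray(spot_mask, dtype=bool)
    if pred_offsets.shape != true_offsets.shape:
        raise ValueError("offset grids must share a shape")
    if mask.shape != pred_offsets.shape[:-1]:
        raise ValueError("mask shape must match the grid's spatial shape")
    n = int(mask.sum())
    if n == 0:
        return 0.0
    diff = pred_offsets[mask] - true_offsets[mask]
    return float(np.sqrt((diff * diff).sum() / n))


def combined_loss(pred_grid: np.ndarray, true_grid: np.ndarray) -> LossBreakdown:
    """Total objective J = J_class + 2 * J_loc on (..., 3) grids."""
    pred_grid = np.asarray(pred_grid, dtype=np.float64)
    true_grid = np.asarray(true_grid, dtype=np.float64)
    if pred_grid.shape != true_grid.shape:
        raise ValueError("grids must share a shape")
    if pred_grid.shape[-1] != 3:
        raise ValueError("grids must have 3 channels")
    j_class = dice_loss(pred_grid[..., 0], true_grid[..., 0])
    mask = true_grid[..., 0] == 1.0
    j_loc = localization_loss(pred_grid[..., 1:], true_grid[..., 1:], mask)
    return LossBreakdown(
        j_class=j_class,
        j_loc=j_loc,
        j=j_class + 2.0 * j_loc,
        n_spot_cells=int(mask.sum()),
    )
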