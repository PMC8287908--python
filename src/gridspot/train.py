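"""Training: the SpotDetector estimator, configuration, and checkpoints.

:class:`SpotDetector` is a scikit-learn style estimator: ``fit`` takes a
stack of 2D images and per-image coordinate tables, optimizes the
grid-cell network under J = J_class + 2*J_loc with an AMSGrad optimizer,
keeps the checkpoint with the best validation loss, and ``predict``
returns sub-pixel coordinate tables for new images.

Defaults follow the published operating point: cell-size 4, dropout 0.3,
batch size 2, learning rate 1e-4, AMSGrad, 200 epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nn
from .grid import encode_coordinates, decode_grid
from .metrics import f1_integral
from .network import GridNet, NetworkConfig, build_network
from .detect import pad_to_divisor, predict_image, standardize_image

__all__ = [
    "TrainConfig",
    "default_config",
    "SpotDetector",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Training hyperparameters with their published defaults."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 200
    optimizer: str = "amsgrad"
    augment: bool = True
    seed: int = 42

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("amsgrad", "adam"):
            raise ValueError("optimizer must be 'amsgrad' or 'adam'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        net = d.pop("network", {})
        return cls(network=NetworkConfig(**net), **d)


def default_config() -> TrainConfig:
    """The default training configuration (cell-size 4, dropout 0.3,
    batch 2, lr 1e-4, AMSGrad, 200 epochs)."""
    return TrainConfig()


class SpotDetector(BaseEstimator):
    """Grid-cell spot detector with a scikit-learn estimator interface.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`.
    ``fit(X, y)`` trains on a stack/list of 2D images ``X`` and a list of
    per-image (n_i, 2) coordinate arrays ``y``; pass ``X_valid``/
    ``y_valid`` for checkpoint selection on held-out data (otherwise the
    training set doubles as validation).  ``predict(X)`` returns one
    coordinate array per image; ``score(X, y)`` is the mean F1 integral.

    Attributes set by fit: ``model_`` (the network holding the best
    checkpoint), ``history_`` (per-epoch losses and validation F1
    integral), ``best_epoch_``, ``best_valid_loss_``.
    """

    def __init__(self, cell_size=4, filters=64, unet_depth=3,
                 convs_per_block=3, se_reduction=16, dropout_rate=0.3,
                 use_se=True, use_bottleneck_skip=True, use_dropout=True,
                 learning_rate=1e-4, batch_size=2, epochs=200,
                 optimizer="amsgrad", augment=True, prob_threshold=0.5,
                 seed=42):
        self.cell_size = cell_size
        self.filters = filters
        self.unet_depth = unet_depth
        self.convs_per_block = convs_per_block
        self.se_reduction = se_reduction
        self.dropout_rate = dropout_rate
        self.use_se = use_se
        self.use_bottleneck_skip = use_bottleneck_skip
        self.use_dropout = use_dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.augment = augment
        self.prob_threshold = prob_threshold
        self.seed = seed

    # -- config plumbing ----------------------------------------------------

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            cell_size=self.cell_size, filters=self.filters,
            unet_depth=self.unet_depth, convs_per_block=self.convs_per_block,
            se_reduction=self.se_reduction, dropout_rate=self.dropout_rate,
            use_se=self.use_se, use_bottleneck_skip=self.use_bottleneck_skip,
            use_dropout=self.use_dropout,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            network=self._network_config(), learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs,
            optimizer=self.optimizer, augment=self.augment, seed=self.seed,
        )

    @classmethod
    def from_config(cls, config: TrainConfig,
                    prob_threshold: float = 0.5) -> "SpotDetector":
        net = config.network
        return cls(
            cell_size=net.cell_size, filters=net.filters,
            unet_depth=net.unet_depth, convs_per_block=net.convs_per_block,
            se_reduction=net.se_reduction, dropout_rate=net.dropout_rate,
            use_se=net.use_se, use_bottleneck_skip=net.use_bottleneck_skip,
            use_dropout=net.use_dropout, learning_rate=config.learning_rate,
            batch_size=config.batch_size, epochs=config.epochs,
            optimizer=config.optimizer, augment=config.augment,
            prob_threshold=prob_threshold, seed=config.seed,
        )

    # -- data preparation ---------------------------------------------------

    def _prepare(self, X, y, divisor):
        images, tables = [], []
        if len(X) != len(y):
            raise ValueError(f"{len(X)} images but {len(y)} label tables")
        for img, coords in zip(X, y):
            img = np.asarray(img, dtype=np.float64)
            if img.ndim != 2:
                raise ValueError("each image must be 2D")
            images.append(pad_to_divisor(standardize_image(img), divisor))
            tables.append(np.asarray(coords, dtype=np.float64).reshape(-1, 2))
        shapes = {im.shape for im in images}
        if len(shapes) > 1:
            raise ValueError(f"images must share one padded shape, got {shapes}")
        return images, tables

    @staticmethod
    def _augment_sample(img, coords, rng):
        """Random dihedral transform of an image and its coordinates."""
        h, w = img.shape
        coords = coords.copy()
        if rng.random() < 0.5:  # vertical flip (rows)
            img = img[::-1]
            coords[:, 0] = (h - 1) - coords[:, 0]
        if rng.random() < 0.5:  # horizontal flip (cols)
            img = img[:, ::-1]
            coords[:, 1] = (w - 1) - coords[:, 1]
        if h == w:
            k = int(rng.integers(4))
            for _ in range(k):
                img = np.rot90(img)
                coords = np.column_stack([(w - 1) - coords[:, 1], coords[:, 0]])
        # pixel-center flips map [0, H) onto (-1, H-1]; clamp the sub-pixel
        # sliver at the border back into the image
        if len(coords):
            coords[:, 0] = np.clip(coords[:, 0], 0.0, h - 1e-6)
            coords[:, 1] = np.clip(coords[:, 1], 0.0, w - 1e-6)
        return np.ascontiguousarray(img), coords

    def _encode_batch(self, images, tables, idx, rng, augment):
        xs, ys = [], []
        cs = self.cell_size
        for i in idx:
            img, coords = images[i], tables[i]
            if augment:
                img, coords = self._augment_sample(img, coords, rng)
            xs.append(img)
            ys.append(encode_coordinates(coords, img.shape, cs).cells)
        return np.stack(xs), np.stack(ys).astype(np.float32)

    # -- training -----------------------------------------------------------

    def fit(self, X, y, X_valid=None, y_valid=None):
        if len(X) == 0:
            raise ValueError("training split is empty")
        if (X_valid is None) != (y_valid is None):
            raise ValueError("pass X_valid and y_valid together")
        has_valid = X_valid is not None and len(X_valid) > 0
        config = self._network_config()
        net = build_network(config, seed=self.seed)
        images, tables = self._prepare(X, y, config.divisor)
        if has_valid:
            v_images, v_tables = self._prepare(X_valid, y_valid, config.divisor)
        else:
            v_images, v_tables = images, tables
        v_targets = [
            encode_coordinates(c, im.shape, self.cell_size).cells
            for im, c in zip(v_images, v_tables)
        ]

        opt = _nn.Adam(net.parameters(), lr=self.learning_rate,
                       amsgrad=(self.optimizer == "amsgrad"))
        root = np.random.SeedSequence(self.seed)
        shuffle_rng, aug_rng, drop_rng = (
            np.random.default_rng(s) for s in root.spawn(3)
        )

        n = len(images)
        best_state, best_loss, best_epoch = None, np.inf, -1
        history = []
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = self._encode_batch(images, tables, idx, aug_rng,
                                            self.augment)
                opt.zero_grad()
                loss = self._loss(net.forward(xb, training=True,
                                              rng=drop_rng), yb)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite training loss {value} at epoch {epoch}, "
                        f"batch {start // self.batch_size}; try a lower "
                        "learning rate"
                    )
                loss.backward()
                opt.step()
                losses.append(value)
            valid_loss, valid_f1 = self._validate(net, v_images, v_targets,
                                                  v_tables)
            history.append({
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "valid_loss": valid_loss,
                "valid_f1_integral": valid_f1,
            })
            if valid_loss < best_loss:
                best_loss, best_epoch = valid_loss, epoch
                best_state = net.state_dict()

        net.load_state_dict(best_state)
        self.model_ = net
        self.config_ = self._train_config()
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.best_valid_loss_ = float(best_loss)
        return self

    def _loss(self, pred: _nn.Tensor, target: np.ndarray) -> _nn.Tensor:
        j_class = _nn.dice_loss_op(_nn.slice_channels(pred, 0, 1),
                                   target[..., 0:1])
        j_loc = _nn.offset_rmse_op(_nn.slice_channels(pred, 1, 3),
                                   target[..., 1:3], target[..., 0])
        return _nn.add_scaled(j_class, j_loc, 2.0)

    def _validate(self, net, images, targets, tables):
        losses, f1s = [], []
        for start in range(0, len(images), max(self.batch_size, 8)):
            stop = start + max(self.batch_size, 8)
            xb = np.stack(images[start:stop])
            yb = np.stack(targets[start:stop]).astype(np.float32)
            pred = net.forward(xb, training=False)
            losses.append(self._loss(pred, yb).item())
            for grid, truth in zip(pred.data, tables[start:stop]):
                coords = decode_grid(grid, cell_size=self.cell_size,
                                     prob_threshold=self.prob_threshold)
                f1s.append(f1_integral(coords, truth))
        return float(np.mean(losses)), float(np.mean(f1s))

    # -- prediction ---------------------------------------------------------

    def predict(self, X, refine: bool = False) -> list[np.ndarray]:
        self._check_fitted()
        return [
            predict_image(self.model_, img, prob_threshold=self.prob_threshold,
                          refine=refine)
            for img in X
        ]

    def score(self, X, y) -> float:
        """Mean F1 integral of the predictions against ``y``."""
        preds = self.predict(X)
        return float(np.mean([f1_integral(p, t) for p, t in zip(preds, y)]))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("SpotDetector is not fitted; call fit() or "
                               "load a checkpoint")


def train_model(archive, config: TrainConfig | None = None):
    """Train on a DatasetArchive's train/valid splits.

    Returns the fitted :class:`SpotDetector` and its per-epoch history.
    """
    config = config or default_config()
    if len(archive.images("train")) == 0:
        raise ValueError("archive has an empty train split")
    if len(archive.images("valid")) == 0:
        raise ValueError("archive has an empty valid split")
    det = SpotDetector.from_config(config)
    det.fit(archive.images("train"), archive.labels("train"),
            X_valid=archive.images("valid"), y_valid=archive.labels("valid"))
    return det, det.history_


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(detector: SpotDetector, path) -> None:
    """Persist a fitted detector: parameters + configuration (npz)."""
    detector._check_fitted()
    state = detector.model_.state_dict()
    meta = {
        "format": "gridspot-checkpoint",
        "format_version": 1,
        "train_config": detector.config_.to_dict(),
        "prob_threshold": detector.prob_threshold,
        "best_epoch": int(detector.best_epoch_),
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SpotDetector:
    """Restore a fitted detector from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        if "__meta__" not in data:
            raise ValueError(f"{path}: not a gridspot checkpoint")
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != "gridspot-checkpoint":
            raise ValueError(f"{path}: not a gridspot checkpoint")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig.from_dict(meta["train_config"])
    det = SpotDetector.from_config(config,
                                   prob_threshold=meta["prob_threshold"])
    net = build_network(config.network, seed=config.seed)
    net.load_state_dict(state)
    det.model_ = net
    det.config_ = config
    det.history_ = pd.DataFrame()
    det.best_epoch_ = meta.get("best_epoch", -1)
    det.best_valid_loss_ = float("nan")
    return det
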