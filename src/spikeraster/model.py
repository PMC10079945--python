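"""Compact LeNet-style 2D CNN for classifying rasterized signal windows.

Architecture (for the default configuration): five 3x3 same-padded
convolution + ReLU + 2x2/2 max-pool stages with feature maps tapering
from 128 to 16, a batch-normalization layer between the fourth
convolution and its pool, a 512-unit fully connected layer with dropout,
and a softmax output (4 classes for the spike task, 2 for the EEG task).
A 320x320 single-channel input flattens to exactly 1x1600 after the
fifth pool (16 maps x 10 x 10).  Trained with RMSprop on categorical
cross-entropy.

Layer geometry is also exposed as standalone checked arithmetic
(:func:`conv_output_size`, :func:`pool_output_size`) so the framework
shapes can be cross-checked against the formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _net
from .raster import RasterImage

__all__ = [
    "CNNConfig",
    "CNNModel",
    "conv_output_size",
    "pool_output_size",
    "build_model",
    "train",
    "predict",
    "resize_for_model",
    "save_model",
    "load_model",
]


def conv_output_size(n_c: int, p_c: int, k_c: int, s_c: int) -> int:
    """Feature-map output size: floor((N + 2P - K)/S) + 1."""
    if n_c < 0 or p_c < 0 or k_c < 1 or s_c < 1:
        raise ValueError("invalid convolution geometry")
    out = (n_c + 2 * p_c - k_c) // s_c + 1
    if out < 1:
        raise ValueError("convolution output smaller than one pixel")
    return out


def pool_output_size(n_p: int, k_p: int, s_p: int) -> int:
    """Pooling output size: floor((N - K)/S) + 1."""
    if k_p < 1 or s_p < 1:
        raise ValueError("invalid pooling geometry")
    if n_p < k_p:
        raise ValueError("pooling input smaller than kernel")
    return (n_p - k_p) // s_p + 1


@dataclass(frozen=True)
class CNNConfig:
    """Hyper-parameters of the classifier.

    input_size
        (H, W) of the single-channel input after resizing, default
        320x320 (the geometry that flattens to 1x1600).
    conv_feature_maps
        Feature maps of the five convolution stages, default
        [128, 64, 32, 32, 16], monotone non-increasing.
    batch_norm_after_conv
        1-based index of the convolution followed by batch norm
        (between that convolution and its pool), default 4.
    """

    input_size: tuple[int, int] = (320, 320)
    conv_feature_maps: tuple[int, ...] = (128, 64, 32, 32, 16)
    batch_norm_after_conv: int = 4
    kernel: int = 3
    conv_stride: int = 1
    conv_padding: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    fc_size: int = 512
    dropout_rate: float = 0.5
    n_classes: int = 4
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_feature_maps) != 5:
            raise ValueError("expected five convolution stages")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def layer_sizes(self) -> list[tuple[int, int]]:
        """(H, W) after each conv+pool stage, chained from the formulas."""
        h, w = self.input_size
        sizes = []
        for _ in self.conv_feature_maps:
            h = conv_output_size(h, self.conv_padding, self.kernel, self.conv_stride)
            w = conv_output_size(w, self.conv_padding, self.kernel, self.conv_stride)
            h = pool_output_size(h, self.pool_kernel, self.pool_stride)
            w = pool_output_size(w, self.pool_kernel, self.pool_stride)
            sizes.append((h, w))
        return sizes

    @property
    def flatten_size(self) -> int:
        h, w = self.layer_sizes()[-1]
        return self.conv_feature_maps[-1] * h * w


class CNNModel:
    """Sequential CNN with train/predict; see :func:`build_model`."""

    def __init__(self, config: CNNConfig) -> None:
        self.config = config
        self.classes: list[str] | None = None
        self.history = pd.DataFrame(columns=["epoch", "loss", "accuracy"])
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng((config.seed, 1))
        self.layers: list[_net.Layer] = []
        in_ch = 1
        for i, maps in enumerate(config.conv_feature_maps, start=1):
            self.layers.append(_net.Conv2D(
                in_ch, maps, kernel=config.kernel, stride=config.conv_stride,
                pad=config.conv_padding, rng=rng))
            self.layers.append(_net.ReLU())
            if i == config.batch_norm_after_conv:
                self.layers.append(_net.BatchNorm2D(maps))
            self.layers.append(_net.MaxPool2D(config.pool_kernel, config.pool_stride))
            in_ch = maps
        self.layers.append(_net.Flatten())
        self.layers.append(_net.Dense(config.flatten_size, config.fc_size, rng=rng))
        self.layers.append(_net.ReLU())
        self.layers.append(_net.Dropout(config.dropout_rate, rng=self._dropout_rng))
        self.layers.append(_net.Dense(config.fc_size, config.n_classes, rng=rng))

    # -- geometry ---------------------------------------------------------
    def tensor_shapes(self) -> list[tuple[int, ...]]:
        """Per-layer output shapes (C, H, W) / (D,) from a probe forward."""
        x = np.zeros((1, 1, *self.config.input_size), dtype=_net.F32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            shapes.append(tuple(x.shape[1:]))
        return shapes

    def parameter_count(self) -> int:
        return sum(int(p.size) for ly in self.layers for p in ly.params().values())

    # -- forward ----------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=_net.F32)
        if images.ndim == 3:
            images = images[:, None, :, :]
        if images.shape[2:] != tuple(self.config.input_size):
            raise ValueError(
                f"images of shape {images.shape[2:]} do not match "
                f"configured input {self.config.input_size}")
        return images

    # -- training ---------------------------------------------------------
    def fit(self, images: np.ndarray, labels, *, verbose: bool = False,
            log=None) -> "CNNModel":
        cfg = self.config
        images = self._as_batch(images)
        labels = list(labels)
        if len(labels) == 0:
            raise ValueError("empty training set")
        if self.classes is None:
            self.classes = sorted(set(labels))
        if len(self.classes) > cfg.n_classes:
            raise ValueError(
                f"{len(self.classes)} classes exceed the {cfg.n_classes}-way output")
        missing = [c for c in self.classes if c not in set(labels)]
        if missing:
            import warnings
            warnings.warn(f"classes absent from training labels: {missing}")
        class_index = {c: i for i, c in enumerate(self.classes)}
        # one-hot width follows the output layer; trailing columns stay
        # unused when fewer classes are present than the output is wide
        y = np.zeros((len(labels), cfg.n_classes), dtype=_net.F32)
        for i, lbl in enumerate(labels):
            if lbl not in class_index:
                raise ValueError(f"unknown label {lbl!r}")
            y[i, class_index[lbl]] = 1.0

        rng = np.random.default_rng((cfg.seed, 2))
        opt = _net.RMSprop(self.layers, lr=cfg.learning_rate)
        rows = []
        n = images.shape[0]
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = images[idx], y[idx]
                logits = self._forward(xb, train=True)
                loss, probs, dlogits = _net.softmax_cross_entropy(logits, yb)
                losses.append(loss * len(idx))
                correct += int((probs.argmax(1) == yb.argmax(1)).sum())
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()
            row = {"epoch": epoch, "loss": sum(losses) / n, "accuracy": correct / n}
            rows.append(row)
            if log is not None:
                log(f"epoch {epoch}/{cfg.epochs} "
                    f"loss={row['loss']:.4f} acc={row['accuracy']:.4f}")
            elif verbose:
                print(f"epoch {epoch}: loss={row['loss']:.4f} acc={row['accuracy']:.4f}")
        self.history = pd.DataFrame(rows)
        return self

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        if self.classes is None:
            raise RuntimeError("model is untrained")
        images = self._as_batch(images)
        out = []
        for start in range(0, images.shape[0], batch_size):
            logits = self._forward(images[start:start + batch_size], train=False)
            out.append(_net.softmax(logits.astype(np.float64)))
        return np.vstack(out)

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, list[str]]:
        probs = self.predict_proba(images)
        labels = [self.classes[i]
                  for i in probs[:, :len(self.classes)].argmax(axis=1)]
        return probs, labels


def build_model(cfg: CNNConfig) -> CNNModel:
    """Construct the (untrained) network for a configuration."""
    return CNNModel(cfg)


def train(model: CNNModel, images: np.ndarray, labels,
          cfg: CNNConfig | None = None, **kwargs) -> CNNModel:
    """Train ``model`` on one-hot labels derived from ``labels``."""
    if cfg is not None and cfg is not model.config:
        raise ValueError("config mismatch: build the model from this config")
    return model.fit(images, labels, **kwargs)


def predict(model: CNNModel, images: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Per-class probability rows plus argmax labels (ties -> lowest index)."""
    return model.predict(images)


def resize_for_model(img: RasterImage | np.ndarray,
                     target: tuple[int, int]) -> np.ndarray:
    """Downscale a binary grid by block max-pooling to ``target`` (H, W).

    A lit pixel anywhere in a source block lights the output pixel, so
    one-pixel-wide traces survive the downscale (interpolation would
    nearly erase them).  Upscaling is refused.
    """
    grid = img.grid if isinstance(img, RasterImage) else np.asarray(img)
    th, tw = target
    h, w = grid.shape
    if th > h or tw > w:
        raise ValueError(f"cannot upscale {grid.shape} to {target}")
    row_edges = np.linspace(0, h, th + 1).astype(int)
    col_edges = np.linspace(0, w, tw + 1).astype(int)
    rowmax = np.maximum.reduceat(grid, row_edges[:-1], axis=0)
    out = np.maximum.reduceat(rowmax, col_edges[:-1], axis=1)
    return out.astype(_net.F32)


def save_model(model: CNNModel, stem: str | Path) -> None:
    """Parameters as .npz + a JSON sidecar (config, classes, history)."""
    stem = Path(stem)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        for k, v in layer.params().items():
            arrays[f"{i}:{k}"] = v
        if isinstance(layer, _net.BatchNorm2D):
            arrays[f"{i}:running_mean"] = layer.running_mean
            arrays[f"{i}:running_var"] = layer.running_var
    np.savez(stem.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": {**asdict(model.config),
                   "input_size": list(model.config.input_size),
                   "conv_feature_maps": list(model.config.conv_feature_maps)},
        "classes": model.classes,
        "history": model.history.to_dict(orient="list"),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(stem: str | Path) -> CNNModel:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    raw = sidecar["config"]
    raw["input_size"] = tuple(raw["input_size"])
    raw["conv_feature_maps"] = tuple(raw["conv_feature_maps"])
    model = CNNModel(CNNConfig(**raw))
    model.classes = sidecar["classes"]
    model.history = pd.DataFrame(sidecar["history"])
    with np.load(stem.with_suffix(".npz")) as data:
        for i, layer in enumerate(model.layers):
            for k, v in layer.params().items():
                v[:] = data[f"{i}:{k}"]
            if isinstance(layer, _net.BatchNorm2D):
                layer.running_mean = data[f"{i}:running_mean"]
                layer.running_var = data[f"{i}:running_var"]
    return model
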