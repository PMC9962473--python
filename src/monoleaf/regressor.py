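"""The count-regression model.

The network maps a 299×299×3 image to one nonnegative-ish real number — the
leaf count estimate — and is trained with mean squared error against the
integer labels.  The head is the part that matters for counting-by-regression
and for Grad-CAM: global average pooling over the final convolutional feature
map followed by a *single-unit* dense layer, so the scalar output is a
weighted average of per-channel activation means.

The trunk is a compact strided-convolution backbone (the ``reduced`` family)
sized for CPU training on synthetic data; ``reduced_width_mult`` scales its
channel widths.  Training defaults follow counting-by-regression practice:
batch 16, RMSprop at learning rate 1e-4, MSE loss, 500 epochs — note the
learning rate/epoch budget is tuned for fine-tuning at scale; short CPU runs
on synthetic data want a larger rate and far fewer epochs (see
``docs/methods.md``).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from PIL import Image

from ._nn import Conv2d, ConvNet, Dense, ReLU, RMSprop

#: base channel widths of the reduced trunk at width multiplier 1.0
_BASE_WIDTHS = (8, 16, 24, 32)


@dataclass
class ModelConfig:
    input_size: int = 299
    backbone: str = "reduced"
    reduced_width_mult: float = 1.0
    batch_size: int = 16
    learning_rate: float = 0.0001
    optimizer: str = "rmsprop"
    loss: str = "mse"
    epochs: int = 500
    seed: int = 0
    pretrained_init: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainedRegressor:
    """A (possibly untrained) count regressor: network + config + history."""

    net: ConvNet
    config: ModelConfig
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})

    # -- image plumbing ------------------------------------------------
    def _to_batch(self, images: np.ndarray) -> np.ndarray:
        """HWC uint8 image(s) → NCHW float32 scaled to [-1, 1]."""
        arr = np.asarray(images)
        if arr.ndim == 3:
            arr = arr[None]
        s = self.config.input_size
        if arr.shape[1:] != (s, s, 3):
            raise ValueError(f"expected {s}x{s}x3 image(s), got shape {arr.shape[1:]}")
        x = arr.astype(np.float32) / 127.5 - 1.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def predict(self, image: np.ndarray) -> float:
        """Raw (unrounded) count estimate for one image."""
        return float(self.net.forward(self._to_batch(image), train=False)[0])

    def predict_batch(self, images: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Raw count estimates for a stack of images (chunked for memory)."""
        images = np.asarray(images)
        out = np.empty(len(images), dtype=np.float64)
        for i in range(0, len(images), chunk):
            out[i : i + chunk] = self.net.forward(
                self._to_batch(images[i : i + chunk]), train=False
            )
        return out

    def feature_map(self, image: np.ndarray) -> np.ndarray:
        """Final convolutional feature map (C, H, W), post-activation."""
        return self.net.features(self._to_batch(image))[0]

    def feature_gradients(self, image: np.ndarray) -> np.ndarray:
        """∂(scalar output)/∂(final feature map), shape (C, H, W).

        With the GAP + single-unit dense head the gradient is exact and
        input-independent: ``w_c / (H·W)`` for every spatial position of
        channel ``c``.
        """
        fmap = self.feature_map(image)
        w, _ = self.net.head_weights
        c, h, wd = fmap.shape
        return np.broadcast_to((w / (h * wd))[:, None, None], (c, h, wd)).copy()

    # -- persistence ---------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        arrays = self.net.state_arrays()
        meta = json.dumps({"config": asdict(self.config), "history": self.history})
        with open(path, "wb") as fh:  # exact filename, no .npz suffixing
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedRegressor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = ModelConfig(**meta["config"])
            model = build_model(config)
            model.history = meta["history"]
            model.net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        return model


def _reduced_trunk(width_mult: float, rng) -> tuple[list, int]:
    widths = [max(2, round(w * width_mult)) for w in _BASE_WIDTHS]
    layers: list = []
    c_in = 3
    # first layer strides 4 to bring 299 px down fast; then stride-2 stages
    specs = [(widths[0], 5, 4, 2)] + [(w, 3, 2, 1) for w in widths[1:]]
    for c_out, k, stride, pad in specs:
        layers.append(Conv2d(c_in, c_out, k, stride, pad, rng))
        layers.append(ReLU())
        c_in = c_out
    return layers, c_in


def build_model(config: ModelConfig) -> TrainedRegressor:
    """Construct an untrained regressor for the given config.

    Only the ``reduced`` backbone family is available; other names raise.
    """
    if config.backbone != "reduced":
        raise ValueError(
            f"unsupported backbone {config.backbone!r}; available: 'reduced'"
        )
    rng = np.random.default_rng(config.seed)
    trunk, c_feat = _reduced_trunk(config.reduced_width_mult, rng)
    head = Dense(c_feat, 1, rng)
    return TrainedRegressor(net=ConvNet(trunk, head), config=config)


class TrainingError(RuntimeError):
    pass


def _load_images(manifest, manifest_path, split: str, input_size: int):
    from .manifest import resolve_image_path

    rows = manifest[manifest["split"] == split]
    if len(rows) == 0:
        return np.zeros((0, input_size, input_size, 3), np.uint8), np.zeros(0)
    images = np.empty((len(rows), input_size, input_size, 3), dtype=np.uint8)
    for i, (_, row) in enumerate(rows.iterrows()):
        path = resolve_image_path(manifest_path, str(row["path"]))
        img = np.asarray(Image.open(path).convert("RGB"))
        if img.shape != (input_size, input_size, 3):
            raise ValueError(
                f"{path}: expected {input_size}x{input_size}x3, got {img.shape}"
            )
        images[i] = img
    return images, rows["leaf_count"].to_numpy(dtype=np.float32)


def train_arrays(
    model: TrainedRegressor,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int | None = None,
) -> TrainedRegressor:
    """Train on in-memory uint8 images; records per-epoch train/val loss.

    The head bias is initialized to the mean training label so early epochs
    refine the count rather than climb from zero (standard for regression
    heads).  Data order is shuffled each epoch from the config seed.
    """
    config = model.config
    if len(x_train) == 0:
        raise TrainingError("empty training split")
    epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed + 1)
    net = model.net
    net.head.b[0] = float(np.mean(y_train))
    opt = RMSprop(net.layers, lr=config.learning_rate)

    y_train = np.asarray(y_train, dtype=np.float32)
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = model._to_batch(x_train[idx])
            yb = y_train[idx]
            pred = net.forward(xb, train=True)
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward_from_output((2.0 / len(idx)) * resid.astype(np.float32))
            opt.step()
            losses.append(loss)
        model.history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None and len(x_val):
            val_pred = model.predict_batch(x_val)
            model.history["val_loss"].append(float(np.mean((val_pred - y_val) ** 2)))
    return model


def train(
    model: TrainedRegressor,
    manifest,
    manifest_path: str | os.PathLike,
    epochs: int | None = None,
) -> TrainedRegressor:
    """Train from a dataset manifest (train split; val split monitored)."""
    size = model.config.input_size
    x_train, y_train = _load_images(manifest, manifest_path, "train", size)
    x_val, y_val = _load_images(manifest, manifest_path, "val", size)
    return train_arrays(model, x_train, y_train, x_val, y_val, epochs=epochs)
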