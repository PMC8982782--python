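"""Landmark rasterization and the small attention-classification CNN.

Each valid frame's 34 landmarks are drawn as single white pixels on a black
32x32 image (one dot per landmark; coincident landmarks share a pixel). By
default the normalization box is the frame's own landmark bounding box with
a one-pixel margin, which makes the raster invariant to translation and
uniform scaling of the face; a fixed global box can be supplied instead to
preserve head-pose information across frames (this choice materially
affects what the network can learn — see docs/methods.md).

The classifier is a small convolutional network: two 3x3 convolution layers
of 32 and 64 feature maps, each followed by 2x2 max-pooling, then fully
connected layers of 62 and 1 units, 20% dropout before the output, ReLU in
hidden layers and a sigmoid output thresholded at 0.5. It is implemented
directly on numpy (im2col convolutions, Adam, logit binary cross-entropy)
in float64, so evaluation-mode predictions are deterministic given the seed
and batching-invariant to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ClassCoverageError, SchemaError, ValidationError
from .features import LABEL_CODE
from .io import SessionRecording

RASTER_SIZE = 32


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def frame_bounds(coords: np.ndarray, margin_px: int = 1, size: int = RASTER_SIZE):
    """Per-frame landmark bounding box, padded so dots keep a pixel margin."""
    coords = np.asarray(coords, dtype=float)
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    w = max(xmax - xmin, 1e-9)
    h = max(ymax - ymin, 1e-9)
    eff = size - 2 * margin_px - 1  # pad so extrema land inside the margin
    pad_x = w * margin_px / eff
    pad_y = h * margin_px / eff
    # tiny right/bottom overshoot keeps the max landmark off the clip edge
    return (xmin - pad_x, xmax + pad_x + 1e-9 * w, ymin - pad_y, ymax + pad_y + 1e-9 * h)


def rasterize_frame(
    coords: np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
    size: int = RASTER_SIZE,
) -> np.ndarray:
    """Map a frame's landmarks to a binary ``size x size`` image.

    Landmark (x, y) goes to pixel ``(floor((x - xmin) / w * size),
    floor((y - ymin) / h * size))``, clipped to the grid; column = x,
    row = y. Degenerate bounds raise a domain error.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("rasterize_frame requires finite coordinates")
    if bounds is None:
        bounds = frame_bounds(coords, size=size)
    xmin, xmax, ymin, ymax = bounds
    w = xmax - xmin
    h = ymax - ymin
    if w <= 0 or h <= 0:
        raise ValidationError("normalization box must have positive width and height")
    px = np.clip(np.floor((coords[:, 0] - xmin) / w * size).astype(int), 0, size - 1)
    py = np.clip(np.floor((coords[:, 1] - ymin) / h * size).astype(int), 0, size - 1)
    img = np.zeros((size, size), dtype=np.uint8)
    img[py, px] = 1
    return img


@dataclass
class RasterDataset:
    """Labeled raster images with participant ids (mirrors FeatureMatrix)."""

    images: np.ndarray  # (n, 32, 32) binary
    labels: np.ndarray  # int, 1 = attention
    participant_ids: np.ndarray
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=int)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.labels))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.images.ndim != 3 or self.images.shape[1:] != (RASTER_SIZE, RASTER_SIZE):
            raise SchemaError(
                f"images must be (n, {RASTER_SIZE}, {RASTER_SIZE}), got {self.images.shape}"
            )

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def subset_rows(self, idx: np.ndarray) -> "RasterDataset":
        return RasterDataset(
            self.images[idx], self.labels[idx], self.participant_ids[idx], self.frame_indices[idx]
        )


def rasterize_session(
    session: SessionRecording,
    frame_labels: np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
) -> RasterDataset:
    """Raster images for every valid, class-labeled frame of a session."""
    frame_labels = np.asarray(frame_labels)
    keep = session.valid_mask() & np.isin(frame_labels, ["attention", "inattention"])
    coords = session.coords_array()[keep]
    images = np.stack(
        [rasterize_frame(c, bounds=bounds) for c in coords]
    ) if len(coords) else np.empty((0, RASTER_SIZE, RASTER_SIZE), dtype=np.uint8)
    labels = np.array([LABEL_CODE[s] for s in frame_labels[keep]], dtype=int)
    return RasterDataset(
        images,
        labels,
        np.full(int(keep.sum()), session.participant_id, dtype=object),
        session.frame_indices()[keep],
    )


def save_raster_png(image: np.ndarray, path: str | Path) -> None:
    """Persist one raster as a black/white PNG for inspection."""
    from PIL import Image

    Image.fromarray((np.asarray(image) * 255).astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# network layers (numpy, float64)
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params_grads) -> None:
        self.t += 1
        for k, (p, g) in enumerate(params_grads):
            m, v = self.state.get(k, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[k] = (m, v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Conv3x3:
    """Valid 3x3 convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _cols(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(2, 3))
        # (n, c, oh, ow, 3, 3) -> (n, c*9, oh*ow)
        oh, ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, self.c_in * 9, oh * ow)
        self._shape = (x.shape, oh, ow)
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._cols(x)
        if train:
            self._cache = cols
        out = np.einsum("fk,nkl->nfl", self.W, cols) + self.b[None, :, None]
        _, oh, ow = self._shape
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (xshape, oh, ow) = self._shape
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, oh * ow)
        cols = self._cache
        self.dW = np.einsum("nfl,nkl->fk", dflat, cols)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", self.W, dflat)
        dcols = dcols.reshape(n, self.c_in, 3, 3, oh, ow)
        dx = np.zeros(xshape)
        for ki in range(3):
            for kj in range(3):
                dx[:, :, ki : ki + oh, kj : kj + ow] += dcols[:, :, ki, kj]
        return dx

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _MaxPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        v = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = np.argmax(v, axis=-1)
        self._shape = x.shape
        return v.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = dout.shape[2], dout.shape[3]
        hot = np.eye(4)[self._arg]  # (n, c, h2, w2, 4)
        dwin = hot * dout[..., None]
        dwin = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._shape)
        dx[:, :, : 2 * h2, : 2 * w2] = dwin.reshape(n, c, 2 * h2, 2 * w2)
        return dx

    def params_grads(self):
        return []


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params_grads(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params_grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params_grads(self):
        return []


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class CnnConfig:
    conv1_maps: int = 32
    conv2_maps: int = 64
    kernel: int = 3
    dense_units: int = 62
    dropout_rate: float = 0.20
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.kernel != 3:
            raise ValueError("only the published 3x3 kernel is supported")


class AttentionCnn:
    """The raster-input attention classifier network.

    Topology (valid convolutions, 32x32 single-channel input):
    conv 3x3 x32 -> pool 2x2 -> conv 3x3 x64 -> pool 2x2 -> flatten (2304)
    -> dense 62 (ReLU, 20% dropout) -> dense 1 (sigmoid).
    """

    def __init__(self, config: CnnConfig | None = None):
        self.config = config or CnnConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        # 32 -> 30 -> 15 -> 13 -> 6
        self._flat = ((RASTER_SIZE - 2) // 2 - 2) // 2
        n_flat = self._flat * self._flat * cfg.conv2_maps
        self.layers = [
            _Conv3x3(1, cfg.conv1_maps, rng),
            _ReLU(),
            _MaxPool2(),
            _Conv3x3(cfg.conv1_maps, cfg.conv2_maps, rng),
            _ReLU(),
            _MaxPool2(),
            _Flatten(),
            _Dense(n_flat, cfg.dense_units, rng),
            _ReLU(),
            _Dropout(cfg.dropout_rate, rng),
            _Dense(cfg.dense_units, 1, rng),
        ]
        self._rng = rng
        self.loss_history_: list[float] = []

    @property
    def parameter_count(self) -> int:
        return sum(
            layer.n_params for layer in self.layers if hasattr(layer, "n_params")
        )

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]  # logits

    def _backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim != 3 or images.shape[1:] != (RASTER_SIZE, RASTER_SIZE):
            raise SchemaError(
                f"expected (n, {RASTER_SIZE}, {RASTER_SIZE}) images, got {images.shape}"
            )
        return images[:, None, :, :]

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "AttentionCnn":
        """Train with Adam on logit binary cross-entropy.

        A ``val_fraction`` tail of a seeded shuffle is held out and its
        accuracy recorded per epoch in ``val_history_``.
        """
        cfg = self.config
        x = self._prep(images)
        y = np.asarray(labels, dtype=float)
        if len(np.unique(y)) < 2:
            raise ClassCoverageError("training data must contain both classes")
        n = len(y)
        perm = self._rng.permutation(n)
        n_val = int(round(cfg.val_fraction * n))
        val_idx, tr_idx = perm[: n_val], perm[n_val:]
        xtr, ytr = x[tr_idx], y[tr_idx]
        opt = _Adam(cfg.learning_rate)
        self.val_history_ = []
        for _ in range(cfg.epochs):
            order = self._rng.permutation(len(ytr))
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                z = self._forward(xtr[idx], train=True)
                yb = ytr[idx]
                loss = float(np.mean(np.logaddexp(0.0, z) - yb * z))
                p = 1.0 / (1.0 + np.exp(-z))
                self._backward((p - yb) / len(idx))
                pg = []
                for layer in self.layers:
                    pg.extend(layer.params_grads())
                opt.step(pg)
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / len(ytr))
            if n_val:
                acc = float(
                    np.mean((self.predict_scores(images[val_idx]) >= 0.5) == (y[val_idx] == 1))
                )
                self.val_history_.append(acc)
        return self

    def predict_scores(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid scores in [0, 1]; evaluation mode (dropout off)."""
        x = self._prep(images)
        out = []
        for start in range(0, len(x), batch_size):
            z = self._forward(x[start : start + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels (score >= 0.5 -> attention) and scores, deterministic."""
        scores = self.predict_scores(images)
        return (scores >= 0.5).astype(int), scores

    def save(self, path: str | Path) -> None:
        arrays = {}
        for k, layer in enumerate(self.layers):
            if hasattr(layer, "W"):
                arrays[f"W{k}"] = layer.W
                arrays[f"b{k}"] = layer.b
        np.savez(
            path,
            **arrays,
            _config=np.array(
                [
                    self.config.conv1_maps,
                    self.config.conv2_maps,
                    self.config.dense_units,
                    self.config.seed,
                ]
            ),
            _dropout=np.array([self.config.dropout_rate]),
        )

    @staticmethod
    def load(path: str | Path) -> "AttentionCnn":
        data = np.load(path)
        c1, c2, du, seed = (int(v) for v in data["_config"])
        cfg = CnnConfig(
            conv1_maps=c1, conv2_maps=c2, dense_units=du, seed=seed,
            dropout_rate=float(data["_dropout"][0]),
        )
        net = AttentionCnn(cfg)
        for k, layer in enumerate(net.layers):
            if hasattr(layer, "W"):
                layer.W = data[f"W{k}"]
                layer.b = data[f"b{k}"]
        return net


@dataclass
class AttentionCnnModel:
    """Evaluation-harness adapter: fit/predict on :class:`RasterDataset`."""

    config: CnnConfig = field(default_factory=CnnConfig)
    net_: AttentionCnn | None = None

    def fit(self, train: RasterDataset) -> "AttentionCnnModel":
        self.net_ = AttentionCnn(self.config).fit(train.images, train.labels)
        return self

    def predict(self, data: RasterDataset) -> tuple[np.ndarray, np.ndarray]:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        return self.net_.predict(data.images)
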