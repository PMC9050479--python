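"""Patch-based nuclei classification with a 2-D CNN.

The same architecture is trained once on RGB patches (input 101x101x3)
and once on hyperspectral patches (101x101x87) so the value of the extra
spectral information can be read off the accuracy difference.  The
architecture is nine valid-padded convolutions (first kernel 5x5, the
rest 3x3, stride 1) with filter counts 256, 256, | pool |, 384, 512, 768,
| pool |, 768, 1024, 1536, 2048, a 13x13 global average pool, a
2048-unit ReLU dense layer and a 1-unit sigmoid output.  ReLU plus
dropout (10% rising linearly to 30%) follows each convolution.  The two
max pools use kernel 2 stride 2; the first floors an odd input
(95 -> 47), the second ceils it (41 -> 21), reproducing the published
feature-map chain exactly.  Optimizer Adam (lr 1e-5, beta1 0.9,
beta2 0.999), loss binary cross-entropy, batch size 16, early stop when
validation accuracy stops increasing.

Training patches are 4x augmented by rotation (0/90/180/270 deg); at
evaluation each patch is scored as the mean sigmoid output over four
deterministic views (identity, 90 deg rotation, horizontal and vertical
reflection).  The decision threshold is chosen on the validation ROC by
maximizing Youden's J.

The engine is plain numpy (float32, GEMM-based convolution); a
``width_multiplier`` scales every filter count for desk-scale runs while
leaving the layer structure, and hence the spatial size chain, intact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CNNConfig",
    "PredictionRecord",
    "Model",
    "LeakageError",
    "build_model",
    "output_shapes",
    "augment_train",
    "augment_eval",
    "train",
    "predict_proba",
    "select_threshold",
]

logger = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """Train/validation patient sets overlap."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training protocol for the patch classifier."""

    input_channels: int = 87
    patch_size: int = 101
    kernel_sizes: tuple[int, ...] = (5, 3, 3, 3, 3, 3, 3, 3, 3)
    filters: tuple[int, ...] = (256, 256, 384, 512, 768, 768, 1024, 1536, 2048)
    #: Max-pool inserted after these (0-based) conv indices; bool = ceil mode.
    pool_after: tuple[tuple[int, bool], ...] = ((1, False), (4, True))
    dense_units: int = 2048
    dropout_range: tuple[float, float] = (0.10, 0.30)
    #: "glorot_normal" is the full-width training protocol; "he_normal"
    #: preserves activation variance under ReLU and is needed for narrow
    #: (width-reduced) instantiations, whose forward signal otherwise
    #: attenuates below trainability.
    kernel_init: str = "glorot_normal"
    width_multiplier: float = 1.0
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 27
    patience: int = 3
    seed: int = 0
    allow_any_channels: bool = False

    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(max(1, round(f * self.width_multiplier)) for f in self.filters)

    def scaled_dense(self) -> int:
        return max(1, round(self.dense_units * self.width_multiplier))

    def dropout_rates(self) -> tuple[float, ...]:
        lo, hi = self.dropout_range
        n = len(self.filters)
        return tuple(lo + (hi - lo) * i / (n - 1) for i in range(n))


@dataclass
class PredictionRecord:
    """Per-nucleus prediction: mean probability over 4 views + decision."""

    nucleus_id: int
    probability: float
    decision: str
    threshold_used: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _init_std(init: str, fan_in: int, fan_out: int) -> float:
    if init == "glorot_normal":
        return float(np.sqrt(2.0 / (fan_in + fan_out)))
    if init == "he_normal":
        return float(np.sqrt(2.0 / fan_in))
    raise ValueError(f"unknown kernel_init {init!r}")


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        raise NotImplementedError


class Conv2D(_Layer):
    """Valid-padded stride-1 convolution, computed as k*k GEMMs."""

    def __init__(self, kernel: int, in_ch: int, out_ch: int,
                 rng: np.random.Generator, is_first: bool = False,
                 init: str = "glorot_normal"):
        super().__init__()
        self.k = kernel
        self.is_first = is_first  # first layer: no input gradient needed
        fan_in = kernel * kernel * in_ch
        fan_out = kernel * kernel * out_ch
        std = _init_std(init, fan_in, fan_out)
        self.w = rng.normal(0.0, std, size=(kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def out_shape(self, shape):
        h, w, _ = shape
        return (h - self.k + 1, w - self.k + 1, self.w.shape[3])

    def forward(self, x, training):
        self._x = x
        k = self.k
        bsz, h, w, _ = x.shape
        oh, ow = h - k + 1, w - k + 1
        y = np.broadcast_to(self.b, (bsz, oh, ow, self.b.size)).copy()
        for di in range(k):
            for dj in range(k):
                y += x[:, di:di + oh, dj:dj + ow, :] @ self.w[di, dj]
        return y

    def backward(self, dout):
        x = self._x
        assert x is not None
        k = self.k
        bsz, h, w, cin = x.shape
        oh, ow = h - k + 1, w - k + 1
        g2 = dout.reshape(-1, dout.shape[3])
        dw, db = self.grads
        dw[...] = 0.0
        db[...] = g2.sum(axis=0)
        dx = None if self.is_first else np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                patch = np.ascontiguousarray(x[:, di:di + oh, dj:dj + ow, :])
                dw[di, dj] = patch.reshape(-1, cin).T @ g2
                if dx is not None:
                    dx[:, di:di + oh, dj:dj + ow, :] += dout @ self.w[di, dj].T
        self._x = None
        if dx is None:
            return np.zeros((0,), dtype=dout.dtype)  # sentinel; never consumed
        return dx


class ReLU(_Layer):
    def __init__(self):
        super().__init__()
        self._mask: np.ndarray | None = None

    def out_shape(self, shape):
        return shape

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        mask = self._mask
        self._mask = None
        return np.where(mask, dout, 0.0)


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def out_shape(self, shape):
        return shape

    def forward(self, x, training):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        mask = self._mask
        self._mask = None
        return dout * mask


class MaxPool2(_Layer):
    """2x2 max pool, stride 2; ``ceil_mode`` pads odd inputs with -inf."""

    def __init__(self, ceil_mode: bool):
        super().__init__()
        self.ceil_mode = ceil_mode
        self._cache = None

    def out_shape(self, shape):
        h, w, c = shape
        if self.ceil_mode:
            return ((h + 1) // 2, (w + 1) // 2, c)
        return (h // 2, w // 2, c)

    def forward(self, x, training):
        bsz, h, w, c = x.shape
        if self.ceil_mode:
            ph, pw = h % 2, w % 2
            if ph or pw:
                x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)),
                           constant_values=-np.inf)
        else:
            x = x[:, : h - h % 2, : w - w % 2, :]
        bsz, h2, w2, c = x.shape
        xr = x.reshape(bsz, h2 // 2, 2, w2 // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._cache = (xr, out, (h, w))
        return out

    def backward(self, dout):
        xr, out, (h, w) = self._cache
        self._cache = None
        mask = xr == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4))
        dr = mask * (dout / counts)[:, :, None, :, None, :]
        bsz, hh, _, ww, _, c = xr.shape
        dx = dr.reshape(bsz, hh * 2, ww * 2, c)
        full = np.zeros((bsz, h, w, c), dtype=dout.dtype)
        full[:, : min(h, hh * 2), : min(w, ww * 2), :] = \
            dx[:, : min(h, hh * 2), : min(w, ww * 2), :]
        return full


class GlobalAvgPool(_Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def out_shape(self, shape):
        return (1, 1, shape[2])

    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        bsz, h, w, c = self._shape
        self._shape = None
        return np.broadcast_to(dout[:, None, None, :] / (h * w), (bsz, h, w, c)).copy()


class Dense(_Layer):
    def __init__(self, in_units: int, out_units: int, rng: np.random.Generator,
                 init: str = "glorot_normal"):
        super().__init__()
        std = _init_std(init, in_units, out_units)
        self.w = rng.normal(0.0, std, size=(in_units, out_units)).astype(np.float32)
        self.b = np.zeros(out_units, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def out_shape(self, shape):
        return (1, 1, self.w.shape[1])

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        x = self._x
        self._x = None
        self.grads[0][...] = x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Model:
    """Sequential CNN with a sigmoid scalar head and Adam updates."""

    def __init__(self, config: CNNConfig):
        if config.input_channels not in (3, 87) and not config.allow_any_channels:
            raise ValueError(
                f"input_channels={config.input_channels} is neither 3 (RGB) nor "
                "87 (HSI); pass allow_any_channels=True to override"
            )
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.layers: list[_Layer] = []
        filters = config.scaled_filters()
        rates = config.dropout_rates()
        pools = dict(config.pool_after)
        in_ch = config.input_channels
        for i, (k, f) in enumerate(zip(config.kernel_sizes, filters)):
            self.layers.append(Conv2D(k, in_ch, f, self.rng, is_first=(i == 0),
                                      init=config.kernel_init))
            self.layers.append(ReLU())
            self.layers.append(Dropout(rates[i], self.rng))
            if i in pools:
                self.layers.append(MaxPool2(ceil_mode=pools[i]))
            in_ch = f
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dense(in_ch, config.scaled_dense(), self.rng,
                                 init=config.kernel_init))
        self.layers.append(ReLU())
        self.layers.append(Dense(config.scaled_dense(), 1, self.rng,
                                 init=config.kernel_init))
        # Adam state
        self._step = 0
        self._m = [np.zeros_like(p) for layer in self.layers for p in layer.params]
        self._v = [np.zeros_like(p) for layer in self.layers for p in layer.params]

    # -- inference ----------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]

    def predict_proba_batch(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward_logits(x, training=False))

    # -- training -----------------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on a batch; returns the batch BCE loss."""
        logits = self.forward_logits(x, training=True)
        probs = _sigmoid(logits)
        eps = 1e-7
        loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
        dlogits = ((probs - y) / len(y)).astype(np.float32)[:, None]
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        self._adam_update()
        return loss

    def _adam_update(self) -> None:
        cfg = self.config
        if cfg.learning_rate == 0:
            return
        self._step += 1
        t = self._step
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                self._m[i] = cfg.beta1 * self._m[i] + (1 - cfg.beta1) * g
                self._v[i] = cfg.beta2 * self._v[i] + (1 - cfg.beta2) * g * g
                mhat = self._m[i] / (1 - cfg.beta1 ** t)
                vhat = self._v[i] / (1 - cfg.beta2 ** t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                i += 1

    # -- weights ------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1

    def save(self, path) -> None:
        """Checkpoint: weights as NPZ plus the architecture config JSON."""
        import dataclasses
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {f"param_{i:03d}": p for i, p in enumerate(self.get_weights())}
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2))

    @classmethod
    def load(cls, path) -> "Model":
        import json
        from pathlib import Path

        path = Path(path)
        payload = json.loads(path.with_suffix(".json").read_text())
        for key in ("kernel_sizes", "filters", "dropout_range"):
            payload[key] = tuple(payload[key])
        payload["pool_after"] = tuple((i, bool(c)) for i, c in payload["pool_after"])
        model = cls(CNNConfig(**payload))
        with np.load(path.with_suffix(".npz")) as data:
            model.set_weights([data[k] for k in sorted(data.files)])
        return model


def build_model(config: CNNConfig) -> Model:
    """Instantiate the architecture; weights Glorot-normal from the seed."""
    return Model(config)


def output_shapes(config: CNNConfig) -> list[tuple[str, tuple[int, int, int]]]:
    """The (height, width, channels) chain, layer by layer, by arithmetic.

    With ``width_multiplier`` 1 this reproduces the published feature-map
    sizes for either input channel count: 101 -> 97 -> 95 -> 47 -> 45 ->
    43 -> 41 -> 21 -> 19 -> 17 -> 15 -> 13 -> 2048 -> 2048 -> 1.
    """
    filters = config.scaled_filters()
    pools = dict(config.pool_after)
    shape = (config.patch_size, config.patch_size, config.input_channels)
    chain = [("input", shape)]
    for i, (k, f) in enumerate(zip(config.kernel_sizes, filters)):
        shape = (shape[0] - k + 1, shape[1] - k + 1, f)
        chain.append((f"conv{i + 1}", shape))
        if i in pools:
            if pools[i]:
                shape = ((shape[0] + 1) // 2, (shape[1] + 1) // 2, shape[2])
            else:
                shape = (shape[0] // 2, shape[1] // 2, shape[2])
            chain.append((f"maxpool_after_conv{i + 1}", shape))
    chain.append(("global_average_pool", (1, 1, shape[2])))
    chain.append(("dense_relu", (1, 1, config.scaled_dense())))
    chain.append(("dense_sigmoid", (1, 1, 1)))
    return chain


def standardize_patches(train_x: np.ndarray, *others: np.ndarray):
    """Per-channel standardization using training-partition statistics.

    Patches arrive as nonnegative transmittance (or RGB) with nearly
    constant channel means; feeding them raw lets the optimizer drive the
    first convolution's pre-activations negative and the ReLUs die.
    Centering/scaling by the training mean and standard deviation keeps
    the first layer alive.  Returns the standardized training array
    followed by each of ``others`` transformed with the same statistics.
    """
    train_x = np.asarray(train_x, dtype=np.float32)
    mu = train_x.mean(axis=(0, 1, 2), dtype=np.float64).astype(np.float32)
    sd = train_x.std(axis=(0, 1, 2), dtype=np.float64).astype(np.float32)
    sd = np.where(sd > 1e-8, sd, 1.0)
    out = [(train_x - mu) / sd]
    out.extend((np.asarray(o, dtype=np.float32) - mu) / sd for o in others)
    return out[0] if not others else tuple(out)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_train(patches: np.ndarray, labels: np.ndarray | None = None):
    """4x training augmentation: rotations by 0, 90, 180, 270 degrees."""
    patches = np.asarray(patches)
    if patches.shape[1] != patches.shape[2]:
        raise ValueError(f"patches must be square, got {patches.shape[1:3]}")
    views = [np.rot90(patches, k, axes=(1, 2)) for k in range(4)]
    out = np.concatenate(views, axis=0)
    if labels is None:
        return out
    return out, np.concatenate([np.asarray(labels)] * 4, axis=0)


def augment_eval(patch: np.ndarray) -> np.ndarray:
    """Four deterministic test-time views of one square patch.

    Identity, 90-degree rotation, horizontal reflection, vertical
    reflection.  The published protocol says "rotating and reflecting"
    without listing the quartet; this one is fixed here and declared in
    the run manifest.
    """
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square, got {patch.shape[:2]}")
    return np.stack([
        patch,
        np.rot90(patch, 1, axes=(0, 1)),
        patch[:, ::-1],
        patch[::-1, :],
    ])


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(
    model: Model,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    train_patients: set[str] | None = None,
    val_patients: set[str] | None = None,
    augment: bool = True,
    verbose: bool = False,
) -> list[dict]:
    """Train with rotation augmentation and early stopping; returns history.

    ``train_patients`` / ``val_patients`` are the provenance sets of the
    two partitions; any overlap is patient-level leakage and raises
    :class:`LeakageError`.  Early stopping: training ends when validation
    accuracy has not increased for ``config.patience`` epochs; the weights
    of the best epoch are restored.  Fully deterministic given the seed.
    """
    if train_patients is not None and val_patients is not None:
        overlap = set(train_patients) & set(val_patients)
        if overlap:
            raise LeakageError(f"patients in both partitions: {sorted(overlap)}")
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    train_x = np.asarray(train_x, dtype=np.float32)
    train_y = np.asarray(train_y, dtype=np.float32)
    n = len(train_x)
    n_virtual = 4 * n if augment else n

    history: list[dict] = []
    best_acc = -np.inf
    best_weights = model.get_weights()
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_virtual)
        losses = []
        for start in range(0, n_virtual, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if augment:
                base, rot = idx % n, idx // n
                batch = np.stack([
                    np.rot90(train_x[b], k, axes=(0, 1)) for b, k in zip(base, rot)
                ])
                yb = train_y[base]
            else:
                batch = train_x[idx]
                yb = train_y[idx]
            losses.append(model.train_step(np.ascontiguousarray(batch), yb))
        probs = predict_proba(model, val_x)
        val_acc = float(((probs >= 0.5) == (np.asarray(val_y) > 0.5)).mean())
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_accuracy": val_acc,
        })
        if verbose:
            logger.info("epoch %d loss %.4f val_acc %.3f", epoch,
                        history[-1]["train_loss"], val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.set_weights(best_weights)
    return history


def predict_proba(model: Model, patches: np.ndarray, tta: bool = True,
                  batch_size: int | None = None) -> np.ndarray:
    """Mean sigmoid probability per patch over the four evaluation views."""
    patches = np.asarray(patches, dtype=np.float32)
    bsz = batch_size or model.config.batch_size
    if not tta:
        return np.concatenate([
            model.predict_proba_batch(patches[i:i + bsz])
            for i in range(0, len(patches), bsz)
        ])
    probs = np.zeros(len(patches))
    buf: list[np.ndarray] = []
    idx: list[int] = []
    for i, patch in enumerate(patches):
        views = augment_eval(patch)
        buf.append(views)
        idx.append(i)
        if len(buf) * 4 >= bsz or i == len(patches) - 1:
            stacked = np.concatenate(buf, axis=0)
            p = model.predict_proba_batch(np.ascontiguousarray(stacked))
            for j, k in enumerate(idx):
                probs[k] = p[4 * j:4 * j + 4].mean()
            buf, idx = [], []
    return probs


def select_threshold(scores: np.ndarray, truths: np.ndarray) -> float:
    """ROC-optimal decision threshold by Youden's J on validation scores.

    Candidate cuts are midpoints between consecutive distinct scores
    (plus cuts below the minimum and above the maximum); the candidate
    maximizing J = sensitivity + specificity - 1 wins, ties resolved
    toward the cut nearest 0.5.  If no cut beats J = 0 (uninformative
    scores) the fallback 0.5 is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truths = np.asarray(truths, dtype=bool).ravel()
    if truths.all() or not truths.any():
        raise ValueError("threshold selection needs both classes present")
    uniq = np.unique(scores)
    cuts = [uniq[0] - 1e-6]
    cuts.extend((uniq[:-1] + uniq[1:]) / 2)
    cuts.append(uniq[-1] + 1e-6)
    n_pos = truths.sum()
    n_neg = (~truths).sum()
    best_j, best_cut = -np.inf, 0.5
    for cut in cuts:
        called = scores >= cut
        sens = (called & truths).sum() / n_pos
        spec = (~called & ~truths).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (
            abs(j - best_j) <= 1e-12 and abs(cut - 0.5) < abs(best_cut - 0.5)
        ):
            best_j, best_cut = j, cut
    if best_j <= 1e-12:
        warnings.warn("uninformative validation scores (J = 0); threshold 0.5",
                      stacklevel=2)
        return 0.5
    return float(best_cut)
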