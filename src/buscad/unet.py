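"""U-Net lesion segmentation with an empty-mask "normal" gate.

The segmenter is a symmetric encoder–decoder convolutional network with skip
connections: each encoder level applies two 3×3 convolutions (ReLU) and a
2×2 max-pool; the decoder mirrors it with nearest-neighbour upsampling, a
3×3 convolution, concatenation of the matching encoder feature map, and two
further 3×3 convolutions; a final 1×1 convolution produces per-pixel scores
over the two classes (background, tumor), normalized by a softmax.  Training
minimizes pixel-wise categorical cross-entropy with Adam.

Everything runs on a small numpy engine written here: im2col convolutions
backed by BLAS matrix products, explicit backward passes, and a float32
parameter store.  At desk scale (64×64 inputs, depth 3, base 16 filters)
training runs in minutes on one CPU core.

An input whose predicted mask is entirely empty is gated as a *normal* case
and excluded from the morphology/classification stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SegModel",
    "TrainConfig",
    "build_unet",
    "ce_loss",
    "train",
    "predict_mask",
    "predict_proba",
    "gate_normal",
    "iterations_per_epoch",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


# ----------------------------------------------------------------- layers --


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """'same' zero-padded stride-1 convolution, NCHW; returns (y, cols cache)."""
    N, C, H, Wd = x.shape
    F, _, k, _ = W.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))        # N,C,H,W,k,k
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
    cols = cols.reshape(N * H * Wd, C * k * k)
    y = cols @ W.reshape(F, -1).T
    y += b
    return y.reshape(N, H, Wd, F).transpose(0, 3, 1, 2), cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, W: np.ndarray, x_shape):
    N, C, H, Wd = x_shape
    F, _, k, _ = W.shape
    dyf = dy.transpose(0, 2, 3, 1).reshape(N * H * Wd, F)
    dW = (dyf.T @ cols).reshape(W.shape)
    db = dyf.sum(axis=0)
    dcols = dyf @ W.reshape(F, -1)
    # col2im: scatter-add the k*k taps back into the padded gradient
    pad = k // 2
    dxp = np.zeros((N, C, H + 2 * pad, Wd + 2 * pad), dtype=dy.dtype)
    dcols = dcols.reshape(N, H, Wd, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + Wd] += dcols[:, :, :, :, i, j]
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd] if pad else dxp
    return dx, dW, db


def _maxpool_forward(x: np.ndarray):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    N, C, H, W = x_shape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(N, C, H, W)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def _softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ------------------------------------------------------------------ model --


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the clinical-scale recipe
    (Adam, learning rate 1e-4, mini-batch 8, 10 epochs, 256×256×3 inputs)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 10
    input_size: tuple[int, int] = (256, 256)
    seed: int = 0
    val_fraction: float = 0.1
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or min(self.input_size) < 1:
            raise ValueError("sizes must be positive")


class SegModel:
    """Encoder–decoder segmentation network over C=2 pixel classes.

    Parameters live in ``self.params`` (name -> float32 array); the layer
    wiring is a pure function of (depth, base_filters), so the parameter
    count is deterministic and two models built with the same seed are
    identical.
    """

    def __init__(self, depth: int, base_filters: int, input_size: tuple[int, int],
                 in_channels: int = 3, n_classes: int = 2, seed: int = 0):
        H, W = input_size
        if H % (2 ** depth) or W % (2 ** depth):
            raise ValueError(
                f"input size {input_size} must be divisible by 2^depth = {2**depth}"
            )
        self.depth = depth
        self.base_filters = base_filters
        self.input_size = (H, W)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self._build(np.random.default_rng(seed))

    # -- construction

    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int) -> None:
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization for ReLU
        self.params[f"{name}.W"] = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(_DTYPE)
        self.params[f"{name}.b"] = np.zeros(cout, dtype=_DTYPE)

    def _build(self, rng) -> None:
        f = self.base_filters
        cin = self.in_channels
        for d in range(self.depth):
            cout = f * 2 ** d
            self._add_conv(rng, f"enc{d}.conv0", cin, cout, 3)
            self._add_conv(rng, f"enc{d}.conv1", cout, cout, 3)
            cin = cout
        cbot = f * 2 ** self.depth
        self._add_conv(rng, "bot.conv0", cin, cbot, 3)
        self._add_conv(rng, "bot.conv1", cbot, cbot, 3)
        cin = cbot
        for d in reversed(range(self.depth)):
            cout = f * 2 ** d
            self._add_conv(rng, f"dec{d}.up", cin, cout, 3)
            self._add_conv(rng, f"dec{d}.conv0", 2 * cout, cout, 3)
            self._add_conv(rng, f"dec{d}.conv1", cout, cout, 3)
            cin = cout
        self._add_conv(rng, "head", cin, self.n_classes, 1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward

    def _conv_relu(self, x, name, cache, relu=True):
        y, cols = _conv_forward(x, self.params[f"{name}.W"], self.params[f"{name}.b"])
        if relu:
            mask = y > 0
            y = y * mask
            cache[name] = (cols, x.shape, mask)
        else:
            cache[name] = (cols, x.shape, None)
        return y

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (N, in_channels, H, W) float -> per-pixel class probabilities."""
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        cache: dict = {"skips": {}, "pool": {}}
        h = x
        for d in range(self.depth):
            h = self._conv_relu(h, f"enc{d}.conv0", cache)
            h = self._conv_relu(h, f"enc{d}.conv1", cache)
            cache["skips"][d] = h
            h, idx = _maxpool_forward(h)
            cache["pool"][d] = (idx, cache["skips"][d].shape)
        h = self._conv_relu(h, "bot.conv0", cache)
        h = self._conv_relu(h, "bot.conv1", cache)
        for d in reversed(range(self.depth)):
            h = _upsample2(h)
            h = self._conv_relu(h, f"dec{d}.up", cache)
            h = np.concatenate([cache["skips"][d], h], axis=1)
            h = self._conv_relu(h, f"dec{d}.conv0", cache)
            h = self._conv_relu(h, f"dec{d}.conv1", cache)
        logits = self._conv_relu(h, "head", cache, relu=False)
        probs = _softmax(logits, axis=1)
        if want_cache:
            cache["probs"] = probs
            return probs, cache
        return probs

    def backward(self, probs: np.ndarray, onehot: np.ndarray, cache: dict):
        """Gradient of the mean pixel cross-entropy w.r.t. every parameter."""
        grads: dict[str, np.ndarray] = {}
        N, C, H, W = probs.shape
        dy = (probs - onehot).astype(_DTYPE) / (N * H * W)

        def back(name, dy):
            cols, x_shape, relu_mask = cache[name]
            if relu_mask is not None:
                dy = dy * relu_mask
            dx, dW, db = _conv_backward(dy, cols, self.params[f"{name}.W"], x_shape)
            grads[f"{name}.W"] = dW
            grads[f"{name}.b"] = db
            return dx

        dy = back("head", dy)
        dskip_acc: dict[int, np.ndarray] = {}
        for d in range(self.depth):
            dy = back(f"dec{d}.conv1", dy)
            dy = back(f"dec{d}.conv0", dy)
            nskip = cache["skips"][d].shape[1]
            dskip_acc[d] = dy[:, :nskip]
            dy = back(f"dec{d}.up", dy[:, nskip:])
            dy = _upsample2_backward(dy)
        dy = back("bot.conv1", dy)
        dy = back("bot.conv0", dy)
        for d in reversed(range(self.depth)):
            idx, pre_shape = cache["pool"][d]
            dy = _maxpool_backward(dy, idx, pre_shape)
            dy = dy + dskip_acc[d]
            dy = back(f"enc{d}.conv1", dy)
            dy = back(f"enc{d}.conv0", dy)
        return grads


def build_unet(depth: int, base_filters: int, input_size: tuple[int, int],
               seed: int = 0, in_channels: int = 3) -> SegModel:
    """Construct a seeded, untrained segmentation network."""
    return SegModel(depth=depth, base_filters=base_filters, input_size=input_size,
                    in_channels=in_channels, seed=seed)


# ------------------------------------------------------------------- loss --


def ce_loss(pred: np.ndarray, target: np.ndarray, reduction: str = "sum",
            floor: float = 1e-12) -> float:
    """Pixel-wise categorical cross-entropy −Σ_i Σ_c y_ic log ŷ_ic.

    ``pred`` and ``target`` are (..., C) or (N, C, H, W) arrays; ``target``
    must be one-hot.  The summed form is the contract; ``reduction="mean"``
    (per pixel) is what training optimizes.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    if pred.ndim == 4:  # NCHW -> (..., C)
        pred = np.moveaxis(pred, 1, -1)
        target = np.moveaxis(target, 1, -1)
    onehot_ok = np.all((target == 0) | (target == 1)) and np.allclose(
        target.sum(axis=-1), 1.0
    )
    if not onehot_ok:
        raise ValueError("target must be one-hot")
    total = -np.sum(target * np.log(np.clip(pred, floor, 1.0)))
    if reduction == "sum":
        return float(total)
    if reduction == "mean":
        n_pixels = target.size // target.shape[-1]
        return float(total / n_pixels)
    raise ValueError("reduction must be 'sum' or 'mean'")


# ---------------------------------------------------------------- training --


def iterations_per_epoch(n_train: int, batch_size: int) -> int:
    """floor(n/batch): the incomplete trailing batch is dropped."""
    return n_train // batch_size


def _to_batch(pairs, input_size) -> tuple[np.ndarray, np.ndarray]:
    """Stack (image, mask) pairs into network tensors.

    Grayscale images are replicated to three identical channels here — at
    the network boundary only; masks become one-hot (background, tumor).
    """
    H, W = input_size
    xs, ys = [], []
    for image, mask in pairs:
        if image.shape != (H, W) or mask.shape != (H, W):
            raise ValueError(
                f"pair shape {image.shape}/{mask.shape} != input size {(H, W)}"
            )
        xs.append(np.broadcast_to(image, (3, H, W)))
        m = mask.astype(bool)
        ys.append(np.stack([~m, m]))
    return (np.stack(xs).astype(_DTYPE), np.stack(ys).astype(_DTYPE))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(params[k].dtype)


def _batch_metrics(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, float]:
    loss = ce_loss(probs, onehot, reduction="mean")
    acc = float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())
    return loss, acc


def train(model: SegModel, train_pairs, val_pairs, cfg: TrainConfig):
    """Mini-batch training under the stated protocol.

    Runs ``floor(n_train / batch_size)`` iterations per epoch (trailing
    incomplete batch dropped — with 624 training images and batch 8 this is
    the 78-iterations-per-epoch arithmetic), shuffling with a seeded
    generator each epoch.  Records per-iteration training loss/pixel-accuracy
    and per-epoch validation metrics.  Returns ``(model, curves)`` where
    ``curves`` is a DataFrame (epoch, iteration, split, loss, accuracy).
    """
    if cfg.optimizer != "adam":
        raise ValueError("only the adam optimizer is supported")
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("empty training set")
    n_iter = iterations_per_epoch(len(train_pairs), cfg.batch_size)
    if n_iter == 0:
        raise ValueError(
            f"batch size {cfg.batch_size} exceeds training set size {len(train_pairs)}"
        )
    X, Y = _to_batch(train_pairs, cfg.input_size)
    val = _to_batch(list(val_pairs), cfg.input_size) if val_pairs else None

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, lr=cfg.learning_rate)
    rows = []
    it_global = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        for it in range(n_iter):
            sel = order[it * cfg.batch_size : (it + 1) * cfg.batch_size]
            xb, yb = X[sel], Y[sel]
            probs, cache = model.forward(xb, want_cache=True)
            grads = model.backward(probs, yb, cache)
            opt.step(model.params, grads)
            loss, acc = _batch_metrics(probs, yb)
            it_global += 1
            rows.append({"epoch": epoch, "iteration": it_global,
                         "split": "train", "loss": loss, "accuracy": acc})
        if val is not None:
            vloss, vacc, nv = 0.0, 0.0, 0
            for s in range(0, len(val[0]), cfg.batch_size):
                xb, yb = val[0][s : s + cfg.batch_size], val[1][s : s + cfg.batch_size]
                probs = model.forward(xb)
                l, a = _batch_metrics(probs, yb)
                vloss += l * len(xb)
                vacc += a * len(xb)
                nv += len(xb)
            rows.append({"epoch": epoch, "iteration": it_global, "split": "val",
                         "loss": vloss / nv, "accuracy": vacc / nv})
    curves = pd.DataFrame(rows, columns=["epoch", "iteration", "split", "loss", "accuracy"])
    return model, curves


# --------------------------------------------------------------- inference --


def predict_proba(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (2, H, W) for one grayscale image."""
    H, W = model.input_size
    if image.shape != (H, W):
        raise ValueError(
            f"image shape {image.shape} != model input {model.input_size}; "
            "resize the pair first"
        )
    x = np.broadcast_to(image, (1, 3, H, W)).astype(_DTYPE)
    return model.forward(x)[0]


def predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Argmax mask over {background, tumor}; ties go to background."""
    probs = predict_proba(model, image)
    return probs[1] > probs[0]


def gate_normal(mask: np.ndarray, min_area: int = 0) -> bool:
    """True iff the predicted mask is (effectively) empty — a normal case.

    ``min_area`` > 0 tolerates that many speckle-induced foreground pixels.
    """
    return int(np.count_nonzero(mask)) <= min_area


# ------------------------------------------------------------ persistence --


def save_model(model: SegModel, path: str) -> None:
    """Single-file checkpoint (.npz) with the architecture config embedded."""
    config = json.dumps({
        "depth": model.depth, "base_filters": model.base_filters,
        "input_size": list(model.input_size), "in_channels": model.in_channels,
        "n_classes": model.n_classes, "seed": model.seed,
    })
    np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8),
             **model.params)


def load_model(path: str) -> SegModel:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        model = SegModel(
            depth=config["depth"], base_filters=config["base_filters"],
            input_size=tuple(config["input_size"]), in_channels=config["in_channels"],
            n_classes=config["n_classes"], seed=config["seed"],
        )
        for k in model.params:
            model.params[k] = data[k]
    return model
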