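"""ConvNet classifiers for raw and spectrogram sEMG windows.

A compact CPU ConvNet engine (conv2d, batch norm, ReLU, dropout, max-pool,
global average pooling, linear head, softmax cross-entropy, Adam, manual
backprop) sized for 250 ms sEMG windows, plus the two benchmark
architectures:

* ``build_raw_convnet`` — five Conv(3×11, 16 filters, bias-free) + BN
  blocks on the single channels×samples input map, global average pooling,
  11-way linear head: 34,667 trainable parameters, independent of input
  size (the same net serves both armbands).
* ``build_spectrogram_convnet`` — stages C1 Conv(3×3, 64) / P2 pool /
  C3 Conv(3×3, 96) / P4 pool / C5 Conv(2×3, 64), each conv bias-free with
  BN, then GAP and an 11-way head: 95,627 trainable parameters on the
  4×10×51 input.  The narrowband armband's 4×8×11 input is too small for
  the last pooling/conv stages, so its variant drops P4 and C5.

Training follows the benchmark protocol: Adam (raw lr 0.0404709,
spectrogram lr 0.00681292), plateau annealing by a factor of 5 with a
patience of 5 epochs monitored on a stratified 10% held-out split, batch
size 512 (capped at the dataset size), dropout 0.5, stop when the learning
rate falls below 1/125 of its initial value.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RAW_LR",
    "SPECTROGRAM_LR",
    "Sequential",
    "TrainingConfig",
    "architecture_summary",
    "build_raw_convnet",
    "build_spectrogram_convnet",
    "count_parameters",
    "predict",
    "train",
]

RAW_LR = 0.0404709
SPECTROGRAM_LR = 0.00681292

_DTYPE = np.float32


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _im2col(xp: np.ndarray, kh: int, kw: int, h: int, w: int) -> np.ndarray:
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v.transpose(0, 2, 3, 1, 4, 5).reshape(xp.shape[0] * h * w, -1)


class Conv2d(Layer):
    """2-D convolution with 'same' padding (bias-free by default: BN follows)."""

    def __init__(self, cin: int, cout: int, kernel: tuple[int, int], bias: bool = False):
        self.cin, self.cout = cin, cout
        self.kh, self.kw = kernel
        self.weight = Param(np.zeros((cout, cin, self.kh, self.kw)))
        self.bias = Param(np.zeros(cout)) if bias else None
        self._chunk_rows = 6_000_000  # cap im2col buffers to ~O(100 MB)

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.cin * self.kh * self.kw
        self.weight.value = (rng.standard_normal(self.weight.value.shape)
                             * math.sqrt(2.0 / fan_in)).astype(_DTYPE)
        if self.bias is not None:
            self.bias.value = np.zeros(self.cout, dtype=_DTYPE)

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self, x):
        pt, pl = (self.kh - 1) // 2, (self.kw - 1) // 2
        pb, pr = self.kh - 1 - pt, self.kw - 1 - pl
        return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))), (pt, pb, pl, pr)

    def _batch_chunks(self, b, h, w):
        per = max(1, self._chunk_rows // max(h * w * self.cin * self.kh * self.kw, 1))
        for i in range(0, b, per):
            yield i, min(i + per, b)

    def forward(self, x, train=False, rng=None):
        b, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input maps, got {c}")
        if h < self.kh or w < self.kw:
            raise ValueError(
                f"input plane {h}x{w} smaller than the {self.kh}x{self.kw} kernel")
        self._x = x
        xp, _ = self._pad(x)
        wmat = self.weight.value.reshape(self.cout, -1)
        y = np.empty((b, self.cout, h, w), dtype=_DTYPE)
        for i, j in self._batch_chunks(b, h, w):
            col = _im2col(xp[i:j], self.kh, self.kw, h, w)
            out = col @ wmat.T
            if self.bias is not None:
                out += self.bias.value
            y[i:j] = out.reshape(j - i, h, w, self.cout).transpose(0, 3, 1, 2)
        return y

    def backward(self, dout):
        x = self._x
        b, _, h, w = x.shape
        xp, (pt, pb, pl, pr) = self._pad(x)
        wmat = self.weight.value.reshape(self.cout, -1)
        dw = np.zeros_like(wmat, dtype=np.float64)
        dxp = np.zeros_like(xp)
        for i, j in self._batch_chunks(b, h, w):
            col = _im2col(xp[i:j], self.kh, self.kw, h, w)
            dmat = dout[i:j].transpose(0, 2, 3, 1).reshape(-1, self.cout)
            dw += dmat.T.astype(np.float64) @ col.astype(np.float64)
            dcol = (dmat @ wmat).reshape(j - i, h, w, self.cin, self.kh, self.kw)
            for ki in range(self.kh):
                for kj in range(self.kw):
                    dxp[i:j, :, ki:ki + h, kj:kj + w] += \
                        dcol[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self.weight.grad = dw.reshape(self.weight.value.shape).astype(_DTYPE)
        if self.bias is not None:
            self.bias.grad = dout.sum(axis=(0, 2, 3)).astype(_DTYPE)
        he = xp.shape[2] - pb
        we = xp.shape[3] - pr
        return dxp[:, :, pt:he, pl:we]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=_DTYPE)
        self.run_var = np.ones(c, dtype=_DTYPE)

    def init_params(self, rng):
        self.gamma.value = np.ones(self.c, dtype=_DTYPE)
        self.beta.value = np.zeros(self.c, dtype=_DTYPE)
        self.run_mean = np.zeros(self.c, dtype=_DTYPE)
        self.run_var = np.ones(self.c, dtype=_DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        ax = (0, 2, 3)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        m = mean.reshape(1, -1, 1, 1)
        v = var.reshape(1, -1, 1, 1)
        self._inv = 1.0 / np.sqrt(v + self.eps)
        self._xhat = (x - m) * self._inv
        return (self.gamma.value.reshape(1, -1, 1, 1) * self._xhat
                + self.beta.value.reshape(1, -1, 1, 1)).astype(_DTYPE)

    def backward(self, dout):
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        ax = (0, 2, 3)
        self.gamma.grad = np.sum(dout * self._xhat, axis=ax).astype(_DTYPE)
        self.beta.grad = np.sum(dout, axis=ax).astype(_DTYPE)
        g = self.gamma.value.reshape(1, -1, 1, 1)
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=ax, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=ax, keepdims=True)) * self._inv
        return dx.astype(_DTYPE)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float = 0.5):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(_DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False, rng=None):
        s = self.size
        b, c, h, w = x.shape
        h2, w2 = h // s, w // s
        if h2 == 0 or w2 == 0:
            raise ValueError(f"input plane {h}x{w} too small for {s}x{s} pooling")
        self._in_shape = x.shape
        xc = x[:, :, :h2 * s, :w2 * s]
        r = xc.reshape(b, c, h2, s, w2, s).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, s * s)
        self._arg = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, dout):
        s = self.size
        b, c, h, w = self._in_shape
        h2, w2 = h // s, w // s
        dr = np.zeros((b, c, h2, w2, s * s), dtype=_DTYPE)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, :, :h2 * s, :w2 * s] = (
            dr.reshape(b, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 * s, w2 * s))
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(_DTYPE)


class Linear(Layer):
    def __init__(self, cin: int, cout: int):
        self.cin, self.cout = cin, cout
        self.weight = Param(np.zeros((cout, cin)))
        self.bias = Param(np.zeros(cout))

    def init_params(self, rng):
        self.weight.value = (rng.standard_normal((self.cout, self.cin))
                             * math.sqrt(2.0 / self.cin)).astype(_DTYPE)
        self.bias.value = np.zeros(self.cout, dtype=_DTYPE)

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        self.weight.grad = (dout.T @ self._x).astype(_DTYPE)
        self.bias.grad = dout.sum(axis=0).astype(_DTYPE)
        return (dout @ self.weight.value).astype(_DTYPE)


class AsImage(Layer):
    """Lift a (B, C, W) raw window batch to a single-map (B, 1, C, W) image."""

    def forward(self, x, train=False, rng=None):
        if x.ndim != 3:
            raise ValueError("raw input must be (batch, channels, samples)")
        return x[:, None, :, :]

    def backward(self, dout):
        return dout[:, 0]


class Sequential:
    def __init__(self, layers: Sequence[Layer], name: str = "model"):
        self.layers = list(layers)
        self.name = name
        self.classes_: np.ndarray | None = None

    def initialize(self, rng: np.random.Generator) -> "Sequential":
        for lay in self.layers:
            lay.init_params(rng)
        return self

    def params(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=False, rng=None):
        for lay in self.layers:
            x = lay.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def count_parameters(model: Sequential) -> int:
    return int(sum(p.value.size for p in model.params()))


def architecture_summary(model: Sequential) -> dict:
    layers = []
    for lay in model.layers:
        entry = {"type": type(lay).__name__,
                 "n_params": int(sum(p.value.size for p in lay.params()))}
        if isinstance(lay, Conv2d):
            entry.update(cin=lay.cin, cout=lay.cout, kernel=[lay.kh, lay.kw],
                         bias=lay.bias is not None)
        if isinstance(lay, Linear):
            entry.update(cin=lay.cin, cout=lay.cout)
        layers.append(entry)
    return {"name": model.name, "n_parameters": count_parameters(model), "layers": layers}


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -float(logp[np.arange(n), y].mean())
    p = np.exp(logp)
    p[np.arange(n), y] -= 1.0
    return loss, (p / n).astype(_DTYPE)


class Adam:
    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------

def build_raw_convnet(input_shape: tuple[int, int], n_classes: int = 11,
                      dropout: float = 0.5) -> Sequential:
    """Raw-window ConvNet: 5 × [Conv 3×11 ×16 (bias-free) + BN + ReLU + Drop],
    global average pooling, linear 11-way head.  34,667 trainable parameters
    for any input size (single input map + GAP)."""
    ch, samples = input_shape
    if ch < 3 or samples < 11:
        raise ValueError(f"input {ch}x{samples} incompatible with 3x11 receptive fields")
    layers: list[Layer] = [AsImage()]
    cin = 1
    for _ in range(5):
        layers += [Conv2d(cin, 16, (3, 11)), BatchNorm2d(16), ReLU(), Dropout(dropout)]
        cin = 16
    layers += [GlobalAvgPool(), Linear(16, n_classes)]
    return Sequential(layers, name="raw_convnet")


def build_spectrogram_convnet(input_shape: tuple[int, int, int], n_classes: int = 11,
                              dropout: float = 0.5,
                              myo_reduced: bool = False) -> Sequential:
    """Spectrogram ConvNet over channel × frequency planes with the time
    frames as input maps: C1 Conv(3×3, 64) / P2 / C3 Conv(3×3, 96) / P4 /
    C5 Conv(2×3, 64), all convs bias-free with BN, then GAP and the 11-way
    head.  95,627 trainable parameters on the 4×10×51 input; the reduced
    variant (small inputs) drops P4 and C5."""
    frames, ch, bins = input_shape
    plane_after_p4 = (ch // 2 // 2, bins // 2 // 2)
    full_fits = plane_after_p4[0] >= 2 and plane_after_p4[1] >= 3
    if myo_reduced and full_fits:
        raise ValueError(f"input {input_shape} fits the full architecture; "
                         "myo_reduced is for inputs too small for P4/C5")
    if not myo_reduced and not full_fits:
        raise ValueError(f"input {input_shape} too small for P4/C5; "
                         "build with myo_reduced=True")
    layers: list[Layer] = [
        Conv2d(frames, 64, (3, 3)), BatchNorm2d(64), ReLU(), Dropout(dropout),  # C1
        MaxPool2d(2),                                                            # P2
        Conv2d(64, 96, (3, 3)), BatchNorm2d(96), ReLU(), Dropout(dropout),       # C3
    ]
    if myo_reduced:
        layers += [GlobalAvgPool(), Linear(96, n_classes)]
        name = "spectrogram_convnet_reduced"
    else:
        layers += [
            MaxPool2d(2),                                                        # P4
            Conv2d(96, 64, (2, 3)), BatchNorm2d(64), ReLU(), Dropout(dropout),   # C5
            GlobalAvgPool(), Linear(64, n_classes),
        ]
        name = "spectrogram_convnet"
    return Sequential(layers, name=name)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    lr: float = RAW_LR
    anneal_factor: float = 5.0
    anneal_patience: int = 5
    batch_size: int = 512
    max_epochs: int = 100
    min_lr_divisor: float = 125.0   # stop when lr < lr / 5^3
    val_fraction: float = 0.1
    n_runs: int = 20
    seed_base: int = 0

    def __post_init__(self):
        if min(self.lr, self.anneal_factor, self.anneal_patience,
               self.batch_size, self.max_epochs) <= 0 or self.n_runs < 1:
            raise ValueError("training configuration values must be positive")


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    tr, va = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_val = int(round(frac * idx.size))
        if idx.size - n_val < 1:
            n_val = 0
        va.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    return np.sort(np.asarray(tr, int)), np.sort(np.asarray(va, int))


def train(model: Sequential, examples: np.ndarray, labels: np.ndarray,
          config: TrainingConfig = TrainingConfig(), seed: int = 0) -> dict:
    """Fit the model in place; returns the per-epoch training log.

    Adam at ``config.lr``; learning rate divided by ``anneal_factor`` when
    the validation loss (held-out stratified ``val_fraction`` of the
    training windows) has not improved for ``anneal_patience`` epochs;
    training stops at ``max_epochs`` or when the learning rate falls below
    ``lr / min_lr_divisor``.  Deterministic for a given seed.
    """
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    y = np.searchsorted(classes, y_raw)
    X = np.asarray(examples, dtype=_DTYPE)

    rng = np.random.default_rng(seed)
    model.initialize(rng)
    model.classes_ = classes

    tr_idx, va_idx = _stratified_split(y, config.val_fraction, rng)
    if va_idx.size == 0:
        tr_idx = np.arange(y.size)
        va_idx = tr_idx
    opt = Adam(model.params())
    lr = config.lr
    best_val = np.inf
    wait = 0
    log: list[dict] = []
    batch = min(config.batch_size, tr_idx.size)

    for epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for i in range(0, order.size, batch):
            b = order[i:i + batch]
            logits = model.forward(X[b], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y[b])
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        val_logits = _forward_batched(model, X[va_idx])
        val_loss, _ = softmax_cross_entropy(val_logits, y[va_idx])
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_loss": float(val_loss), "lr": lr})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            wait = 0
        else:
            wait += 1
            if wait > config.anneal_patience:
                lr /= config.anneal_factor
                wait = 0
        if lr < config.lr / config.min_lr_divisor:
            break
    return {"epochs": log, "final_lr": lr}


def _forward_batched(model: Sequential, X: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [model.forward(X[i:i + batch], train=False) for i in range(0, X.shape[0], batch)]
    return np.concatenate(outs, axis=0)


def predict(model: Sequential, examples: np.ndarray, batch: int = 256) -> np.ndarray:
    """Deterministic eval-mode class predictions."""
    logits = _forward_batched(model, np.asarray(examples, dtype=_DTYPE), batch)
    idx = np.argmax(logits, axis=1)
    if model.classes_ is not None:
        return model.classes_[idx]
    return idx
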