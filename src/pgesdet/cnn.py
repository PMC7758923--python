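"""Compact EEGNet-style convolutional detector, implemented in numpy.

The classifier maps a raw 10-montage, 10-second crop to the probability that
the window reaches the end of suppression. The layer sequence is

    temporal convolution (kernel 18 samples = 90 ms at 200 Hz)
    -> spatial convolution aggregating across all montages (101 filters)
    -> batch-norm / ReLU / dropout / average-pool
    -> depthwise temporal convolution (multiplier 2)
    -> pointwise (1x1) convolution
    -> batch-norm / ReLU / dropout / average-pool
    -> flatten -> fully connected -> sigmoid.

Training uses binary cross-entropy with optional inverse-frequency class
weights and the Adam optimizer. Forward and backward passes, batch
normalization, dropout and Adam are written directly on numpy arrays; all
convolutions are "valid" cross-correlations realised with stride-tricks
windows plus einsum, which keeps a full training run on the synthetic cohort
within minutes on one CPU.

The temporal layer is sized by its kernel LENGTH (18 samples; the filter
count, default 8, is separate) and the spatial layer by its output filter
COUNT (101 filters, each spanning all montages); both are plain
:class:`ArchConfig` fields, so alternative sizings are one config change
away.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .crops import CropSet
from .infer import crop_auc


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters of the crop classifier."""

    temporal_kernel_len: int = 18
    temporal_filters: int = 8
    spatial_filters: int = 101
    depthwise_multiplier: int = 2
    depthwise_kernel_len: int = 16
    pointwise_filters: int = 16
    dropout_rate: float = 0.25
    pool1: int = 4
    pool2: int = 8

    def __post_init__(self) -> None:
        for name in ("temporal_kernel_len", "temporal_filters", "spatial_filters",
                     "depthwise_multiplier", "depthwise_kernel_len",
                     "pointwise_filters", "pool1", "pool2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: BCE loss, Adam optimizer."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    class_balancing: str = "weighted"  # none | weighted

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.class_balancing not in ("none", "weighted"):
            raise ValueError("class_balancing must be 'none' or 'weighted'")


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}


class _TemporalConv(_Layer):
    """Valid cross-correlation along time, shared over montages.

    (B, C, T) -> (B, F, C, T-k+1).
    """

    def __init__(self, n_filters, k, rng, dtype):
        super().__init__()
        scale = np.sqrt(2.0 / k)
        self.params = {
            "W": (rng.standard_normal((n_filters, k)) * scale).astype(dtype),
            "b": np.zeros(n_filters, dtype=dtype),
        }

    def forward(self, x, training):
        self._x = x
        W, b = self.params["W"], self.params["b"]
        # one contiguous im2col copy, reused by backward
        self._win = np.ascontiguousarray(_windows(x, W.shape[1]))  # (B, C, T', k)
        out = self._win @ W.T  # (B, C, T', F)
        return np.moveaxis(out, -1, 1) + b[None, :, None, None]

    def backward(self, g, need_input_grad=True):
        W = self.params["W"]
        k = W.shape[1]
        self.grads = {
            "W": np.einsum("bfct,bctk->fk", g, self._win, optimize=True),
            "b": g.sum(axis=(0, 2, 3)),
        }
        if not need_input_grad:
            return None
        gpad = np.pad(g, ((0, 0), (0, 0), (0, 0), (k - 1, k - 1)))
        return np.einsum("bfctj,fj->bct", _windows(gpad, k), W[:, ::-1], optimize=True)


class _SpatialConv(_Layer):
    """Filters spanning every montage and every temporal feature map.

    (B, F1, C, T) -> (B, F2, T); each output filter is a learned weighting of
    all montages x temporal filters at one time point.
    """

    def __init__(self, n_filters, f_in, n_montages, rng, dtype):
        super().__init__()
        fan_in = f_in * n_montages
        self.fan_shape = (f_in, n_montages)
        scale = np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((n_filters, fan_in)) * scale).astype(dtype),
            "b": np.zeros(n_filters, dtype=dtype),
        }

    def forward(self, x, training):
        B, F1, C, T = x.shape
        self._xs = x.reshape(B, F1 * C, T)
        out = np.einsum("bpt,fp->bft", self._xs, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, g):
        self.grads = {
            "W": np.einsum("bft,bpt->fp", g, self._xs, optimize=True),
            "b": g.sum(axis=(0, 2)),
        }
        B, _, T = g.shape
        gx = np.einsum("bft,fp->bpt", g, self.params["W"], optimize=True)
        return gx.reshape(B, *self.fan_shape, T)


class _DepthwiseConv(_Layer):
    """Per-channel temporal convolution with a depth multiplier.

    (B, F, T) -> (B, F*D, T-k+1).
    """

    def __init__(self, f_in, multiplier, k, rng, dtype):
        super().__init__()
        scale = np.sqrt(2.0 / k)
        self.params = {
            "W": (rng.standard_normal((f_in, multiplier, k)) * scale).astype(dtype),
            "b": np.zeros(f_in * multiplier, dtype=dtype),
        }

    def forward(self, x, training):
        self._x = x
        W = self.params["W"]
        f, d, k = W.shape
        win = _windows(x, k)  # (B, F, T', k)
        out = np.einsum("bftk,fdk->bfdt", win, W, optimize=True)
        B, _, _, Tp = out.shape
        return out.reshape(B, f * d, Tp) + self.params["b"][None, :, None]

    def backward(self, g):
        W = self.params["W"]
        f, d, k = W.shape
        B = g.shape[0]
        gr = g.reshape(B, f, d, -1)
        win = _windows(self._x, k)
        self.grads = {
            "W": np.einsum("bfdt,bftk->fdk", gr, win, optimize=True),
            "b": g.sum(axis=(0, 2)),
        }
        gpad = np.pad(gr, ((0, 0), (0, 0), (0, 0), (k - 1, k - 1)))
        return np.einsum("bfdtj,fdj->bft", _windows(gpad, k), W[:, :, ::-1], optimize=True)


class _PointwiseConv(_Layer):
    """(B, P, T) -> (B, F, T) 1x1 convolution."""

    def __init__(self, n_filters, p_in, rng, dtype):
        super().__init__()
        scale = np.sqrt(2.0 / p_in)
        self.params = {
            "W": (rng.standard_normal((n_filters, p_in)) * scale).astype(dtype),
            "b": np.zeros(n_filters, dtype=dtype),
        }

    def forward(self, x, training):
        self._x = x
        return np.einsum("bpt,fp->bft", x, self.params["W"], optimize=True) + self.params["b"][None, :, None]

    def backward(self, g):
        self.grads = {
            "W": np.einsum("bft,bpt->fp", g, self._x, optimize=True),
            "b": g.sum(axis=(0, 2)),
        }
        return np.einsum("bft,fp->bpt", g, self.params["W"], optimize=True)


class _BatchNorm(_Layer):
    """Per-feature-channel batch normalization over (batch, time)."""

    def __init__(self, n_features, dtype, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = [1, x.shape[1]] + [1] * (x.ndim - 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes, self._shape = axes, shape
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._inv.reshape(shape)
        self._training = training
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, g):
        axes, shape = self._axes, self._shape
        self.grads = {
            "gamma": (g * self._xhat).sum(axis=axes),
            "beta": g.sum(axis=axes),
        }
        gxhat = g * self.params["gamma"].reshape(shape)
        if not self._training:
            return gxhat * self._inv.reshape(shape)
        m = g.size / g.shape[1]
        t1 = gxhat
        t2 = gxhat.mean(axis=axes).reshape(shape)
        t3 = self._xhat * (gxhat * self._xhat).mean(axis=axes).reshape(shape)
        return (t1 - t2 - t3) * self._inv.reshape(shape)


class _ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class _AvgPool(_Layer):
    """Non-overlapping mean pooling along time; remainder samples dropped."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, training):
        B, F, T = x.shape
        self._T = T
        Tp = T // self.p
        return x[:, :, : Tp * self.p].reshape(B, F, Tp, self.p).mean(axis=-1)

    def backward(self, g):
        B, F, Tp = g.shape
        out = np.zeros((B, F, self._T), dtype=g.dtype)
        out[:, :, : Tp * self.p] = np.repeat(g / self.p, self.p, axis=-1)
        return out


class _Dense(_Layer):
    """Flatten -> single logit."""

    def __init__(self, d_in, rng, dtype):
        super().__init__()
        scale = np.sqrt(1.0 / d_in)
        self.params = {
            "W": (rng.standard_normal(d_in) * scale).astype(dtype),
            "b": np.zeros(1, dtype=dtype),
        }

    def forward(self, x, training):
        self._xf = x.reshape(x.shape[0], -1)
        self._shape = x.shape
        return self._xf @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads = {"W": g @ self._xf, "b": np.array([g.sum()], dtype=g.dtype)}
        return np.outer(g, self.params["W"]).reshape(self._shape)


class EEGNetClassifier:
    """The crop-level suppression-end detector.

    Parameters
    ----------
    arch
        Architecture configuration.
    n_montages, n_samples
        Input shape of one crop (default 10 montages x 2000 samples, a 10 s
        window at 200 Hz).
    seed
        Seeds weight initialization and dropout.
    """

    def __init__(self, arch: ArchConfig = ArchConfig(), n_montages: int = 10,
                 n_samples: int = 2000, seed: int = 0, dtype=np.float32):
        if arch.temporal_kernel_len > n_samples:
            raise ValueError("temporal kernel longer than the input window")
        t1 = n_samples - arch.temporal_kernel_len + 1
        t2 = t1 // arch.pool1
        if arch.depthwise_kernel_len > t2:
            raise ValueError("depthwise kernel longer than the pooled feature map")
        t3 = t2 - arch.depthwise_kernel_len + 1
        t4 = t3 // arch.pool2
        if t4 < 1:
            raise ValueError("architecture pools the time axis away entirely")
        self.arch = arch
        self.n_montages, self.n_samples = n_montages, n_samples
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self.input_scale_ = 1.0
        drop = arch.dropout_rate
        self.layers = [
            _TemporalConv(arch.temporal_filters, arch.temporal_kernel_len, self.rng, dtype),
            _SpatialConv(arch.spatial_filters, arch.temporal_filters, n_montages, self.rng, dtype),
            _BatchNorm(arch.spatial_filters, dtype),
            _ReLU(),
            _Dropout(drop, self.rng),
            _AvgPool(arch.pool1),
            _DepthwiseConv(arch.spatial_filters, arch.depthwise_multiplier,
                           arch.depthwise_kernel_len, self.rng, dtype),
            _PointwiseConv(arch.pointwise_filters,
                           arch.spatial_filters * arch.depthwise_multiplier, self.rng, dtype),
            _BatchNorm(arch.pointwise_filters, dtype),
            _ReLU(),
            _Dropout(drop, self.rng),
            _AvgPool(arch.pool2),
            _Dense(arch.pointwise_filters * t4, self.rng, dtype),
        ]

    # -- plumbing ----------------------------------------------------------
    def num_params(self) -> int:
        return sum(int(np.prod(a.shape)) for l in self.layers for a in l.params.values())

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield (li, name), arr

    def state_dict(self):
        state = {k: v.copy() for k, v in self.parameters()}
        for li, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm):
                state[(li, "running_mean")] = layer.running_mean.copy()
                state[(li, "running_var")] = layer.running_var.copy()
        state[("meta", "input_scale")] = self.input_scale_
        return state

    def load_state_dict(self, state):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[(li, name)].copy()
            if isinstance(layer, _BatchNorm):
                layer.running_mean = state[(li, "running_mean")].copy()
                layer.running_var = state[(li, "running_var")].copy()
        self.input_scale_ = state[("meta", "input_scale")]

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != self.n_montages or X.shape[2] != self.n_samples:
            raise ValueError(
                f"expected crops of shape (n, {self.n_montages}, {self.n_samples}), got {X.shape}"
            )
        h = X.astype(self.dtype) * self.dtype(self.input_scale_)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, g_logit: np.ndarray) -> None:
        g = g_logit
        for layer in reversed(self.layers[1:]):
            g = layer.backward(g)
        # the first layer's input gradient is never consumed; skip its cost
        self.layers[0].backward(g, need_input_grad=False)

    def predict_proba_crops(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            z = self.forward_logits(X[i: i + batch_size], training=False)
            out.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(out)


class _Adam:
    def __init__(self, model: EEGNetClassifier, lr: float):
        self.model, self.lr = model, lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.parameters()}
        self.v = {k: np.zeros_like(v) for k, v in model.parameters()}

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.model.layers):
            for name, arr in layer.params.items():
                g = layer.grads[name].astype(arr.dtype)
                key = (li, name)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """Mean weighted binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = np.mean(weights * (np.logaddexp(0.0, z) - y * z))
    grad = (weights * (p - y) / len(y)).astype(logits.dtype)
    return float(loss), grad


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_cnn(
    train: CropSet, val: CropSet,
    arch: ArchConfig = ArchConfig(), tc: TrainConfig = TrainConfig(),
) -> tuple[EEGNetClassifier, TrainHistory]:
    """Train the CNN on labeled crops, retaining the best-validation weights.

    Records per-epoch mean training loss and validation crop-level AUC; the
    weights with the highest validation AUC are restored before returning.
    Fully deterministic for a fixed seed on one machine.
    """
    Xtr, ytr = train.stacked()
    Xva, yva = val.stacked()
    for name, y in (("training", ytr), ("validation", yva)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} crops contain a single class")
    model = EEGNetClassifier(
        arch, n_montages=Xtr.shape[1], n_samples=Xtr.shape[2], seed=tc.seed
    )
    # scale raw microvolt inputs to unit global RMS for well-conditioned training
    model.input_scale_ = float(1.0 / max(np.sqrt(np.mean(Xtr.astype(np.float64) ** 2)), 1e-12))
    if tc.class_balancing == "weighted":
        pos = ytr.mean()
        w_pos, w_neg = 0.5 / max(pos, 1e-9), 0.5 / max(1 - pos, 1e-9)
        weights = np.where(ytr == 1, w_pos, w_neg)
    else:
        weights = np.ones_like(ytr, dtype=float)
    opt = _Adam(model, tc.learning_rate)
    shuffle_rng = np.random.default_rng(tc.seed + 1)
    history = TrainHistory()
    best_auc, best_state = -np.inf, None
    for epoch in range(tc.epochs):
        order = shuffle_rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(order), tc.batch_size):
            sel = order[i: i + tc.batch_size]
            logits = model.forward_logits(Xtr[sel], training=True)
            loss, g = bce_loss_and_grad(logits, ytr[sel], weights[sel])
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))
        p_val = model.predict_proba_crops(Xva)
        auc = crop_auc(p_val, yva)
        history.val_auc.append(auc)
        if auc > best_auc:
            best_auc, best_state = auc, model.state_dict()
            history.best_epoch = epoch
    model.load_state_dict(best_state)
    return model, history
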