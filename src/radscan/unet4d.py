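"""Generalized 4D convolution and a U-shaped classifier over (volume, shape-matrix) input.

A nodule sample is a 4D tensor: a fourth "plane" axis of extent 2 carries the
grayscale 32x32x32 volume in plane 0 and the radial-scan shape matrix
(broadcast across one spatial axis) in plane 1.  The convolution generalizes
the familiar 2D form

    y[k,l] = phi( sum_c sum_i sum_j  w[c,i,j] x[c,k+i,l+j]  -  b )

to four axes (plane r, slice d, row i, col j).  ``conv2d_ref`` and
``conv4d_ref`` are direct single-filter reference implementations of these
formulas; the network uses batched numba-compiled direct kernels whose
equivalence to the references is exercised in the test suite.

The network itself is a U-Net: an encoder of ``depth`` levels (two
convolutions + 2x max-pooling per level, filters doubling from
``base_filters``), a mirrored decoder with nearest-neighbor upsampling and
skip concatenation, and a 1-extent convolution head whose globally averaged
activations feed a softmax over the classes.  Every non-head convolution is
followed by batch normalization (batch statistics while training, calibrated
running statistics for inference).  All parameters, gradients and the Adam
optimizer are plain NumPy; everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


@dataclass
class ConvSpec:
    """One convolution filter: weights, bias, activation, bias-sign convention.

    ``weights`` has shape (C_in, H, W) for the 2D form and (C_in, R, D, H, W)
    for the 4D form.  ``bias_sign`` of None selects the per-operation default:
    the 2D formula subtracts the bias while its 4D extension adds it; either
    convention can be forced explicitly.
    """

    weights: np.ndarray
    bias: float = 0.0
    activation: Callable[[np.ndarray], np.ndarray] = relu
    bias_sign: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(np.asarray(self.weights.shape) < 1):
            raise ValueError("all kernel extents must be >= 1")


def conv2d_ref(inp: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Valid (no padding) multi-channel correlation producing one 2D map.

    Implements the 2D convolution formula literally, including the
    subtracted bias (override with ``spec.bias_sign``).
    """
    inp = np.asarray(inp, dtype=np.float64)
    if inp.ndim != 3:
        raise ValueError("input must be (channels, H, W)")
    w = spec.weights
    if w.ndim != 3:
        raise ValueError("2D conv weights must be (C_in, H, W)")
    if w.shape[0] != inp.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {inp.shape[0]}, kernel {w.shape[0]}"
        )
    if any(k > s for k, s in zip(w.shape[1:], inp.shape[1:])):
        raise ValueError("kernel extents must not exceed input extents")
    win = sliding_window_view(inp, w.shape[1:], axis=(1, 2))
    lin = np.einsum("chwij,cij->hw", win, w)
    sign = -1.0 if spec.bias_sign is None else spec.bias_sign
    return spec.activation(lin + sign * spec.bias)


def conv4d_ref(inp: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Valid correlation over four axes producing one 4D map (bias added)."""
    inp = np.asarray(inp, dtype=np.float64)
    if inp.ndim != 5:
        raise ValueError("input must be (channels, R, D, H, W)")
    w = spec.weights
    if w.ndim != 5:
        raise ValueError("4D conv weights must be (C_in, R, D, H, W)")
    if w.shape[0] != inp.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {inp.shape[0]}, kernel {w.shape[0]}"
        )
    if any(k > s for k, s in zip(w.shape[1:], inp.shape[1:])):
        raise ValueError("kernel extents must not exceed input extents")
    win = sliding_window_view(inp, w.shape[1:], axis=(1, 2, 3, 4))
    lin = np.einsum("crdhwabij,cabij->rdhw", win, w)
    sign = 1.0 if spec.bias_sign is None else spec.bias_sign
    return spec.activation(lin + sign * spec.bias)


# ---------------------------------------------------------------------------
# batched fast path (numba direct loops) with explicit gradients
# ---------------------------------------------------------------------------

from numba import njit  # noqa: E402


@njit(fastmath=True, cache=True)
def _conv4d_valid(xp, w):
    """Valid batched correlation of padded input xp with filter bank w."""
    n_b, c_in, rp, dp, hp, wp = xp.shape
    f_out = w.shape[0]
    k_r, k_d, k_h, k_w = w.shape[2], w.shape[3], w.shape[4], w.shape[5]
    ro = rp - k_r + 1
    do = dp - k_d + 1
    ho = hp - k_h + 1
    wo = wp - k_w + 1
    out = np.zeros((n_b, f_out, ro, do, ho, wo), dtype=xp.dtype)
    for n in range(n_b):
        for f in range(f_out):
            for c in range(c_in):
                for r in range(k_r):
                    for d in range(k_d):
                        for i in range(k_h):
                            for j in range(k_w):
                                wv = w[f, c, r, d, i, j]
                                for a in range(ro):
                                    for bb in range(do):
                                        for cc in range(ho):
                                            for dd in range(wo):
                                                out[n, f, a, bb, cc, dd] += (
                                                    wv * xp[n, c, a + r,
                                                            bb + d, cc + i,
                                                            dd + j]
                                                )
    return out


@njit(fastmath=True, cache=True)
def _conv4d_wgrad(xp, dy, kern):
    """Weight gradient: correlate the padded input with the output gradient."""
    n_b, c_in = xp.shape[0], xp.shape[1]
    f_out = dy.shape[1]
    k_r, k_d, k_h, k_w = kern
    ro, do, ho, wo = dy.shape[2], dy.shape[3], dy.shape[4], dy.shape[5]
    dw = np.zeros((f_out, c_in, k_r, k_d, k_h, k_w), dtype=xp.dtype)
    # kernel offsets innermost: dy/xp rows stay cache-resident across the
    # 27-ish offset combinations
    for n in range(n_b):
        for f in range(f_out):
            for c in range(c_in):
                for a in range(ro):
                    for bb in range(do):
                        for cc in range(ho):
                            for r in range(k_r):
                                for d in range(k_d):
                                    for i in range(k_h):
                                        for j in range(k_w):
                                            s = xp[0, 0, 0, 0, 0, 0] * 0.0
                                            for dd in range(wo):
                                                s += (
                                                    dy[n, f, a, bb, cc, dd]
                                                    * xp[n, c, a + r, bb + d,
                                                         cc + i, dd + j]
                                                )
                                            dw[f, c, r, d, i, j] += s
    return dw


def _pad_input(x, pad):
    if not any(pad):
        return x
    return np.pad(x, ((0, 0), (0, 0)) + tuple((p, p) for p in pad))


def _conv4d_batch(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  pad: tuple[int, int, int, int]):
    """Batched multi-filter 4D correlation.

    x: (N, C, R, D, H, W); w: (F, C, kR, kD, kH, kW); b: (F,);
    pad: symmetric zero padding per (R, D, H, W) axis.
    Returns (y, xp) where xp is the padded input kept for the backward pass.
    """
    xp = np.ascontiguousarray(_pad_input(x, pad))
    y = _conv4d_valid(xp, np.ascontiguousarray(w))
    y += b[None, :, None, None, None, None]
    return y, xp


def _conv4d_batch_backward(dy, xp, w, pad):
    """Gradients of _conv4d_batch w.r.t. input, weights and bias."""
    dy = np.ascontiguousarray(dy)
    dw = _conv4d_wgrad(xp, dy, w.shape[2:])
    db = dy.sum(axis=(0, 2, 3, 4, 5))
    # input gradient = correlation of dy with the spatially flipped kernel,
    # channels and filters swapped, padding k-1-p per axis
    wt = np.ascontiguousarray(
        np.flip(w, axis=(2, 3, 4, 5)).transpose(1, 0, 2, 3, 4, 5)
    )
    padp = tuple(k - 1 - p for k, p in zip(w.shape[2:], pad))
    dxp = _conv4d_valid(
        np.ascontiguousarray(_pad_input(dy, padp)), wt
    )
    return dxp, dw, db


class _Conv4D:
    """Trainable 4D convolution layer (He-initialized, ReLU optional).

    With ``batch_norm`` the linear output is normalized per channel over the
    batch and all positions before the affine (gamma, beta) and activation;
    the convolution bias is then redundant and is excluded from the trainable
    parameters.  Training mode uses batch statistics and updates running
    averages; evaluation mode uses the running averages.
    """

    _BN_AXES = (0, 2, 3, 4, 5)
    _BN_EPS = 1e-5
    _BN_MOMENTUM = 0.1

    def __init__(self, c_in, c_out, kern, pad, rng, activation="relu",
                 dtype=np.float32, batch_norm=False):
        fan_in = c_in * int(np.prod(kern))
        std = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in, *kern)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.pad = pad
        self.activation = activation
        self.batch_norm = batch_norm
        self.training = True
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        if batch_norm:
            self.gamma = np.ones(c_out, dtype=dtype)
            self.beta = np.zeros(c_out, dtype=dtype)
            self.dgamma = np.zeros_like(self.gamma)
            self.dbeta = np.zeros_like(self.beta)
            self.running_mean = np.zeros(c_out, dtype=np.float64)
            self.running_var = np.ones(c_out, dtype=np.float64)
            self._accum = None
        self._xp = None
        self._mask = None

    def _bcast(self, v):
        return v[None, :, None, None, None, None]

    def forward(self, x):
        y, self._xp = _conv4d_batch(x, self.w, self.b, self.pad)
        if self.batch_norm:
            if self.training:
                mu = y.mean(axis=self._BN_AXES)
                var = y.var(axis=self._BN_AXES)
                if self._accum is not None:
                    y64 = y.astype(np.float64)
                    self._accum[0] += y64.sum(axis=self._BN_AXES)
                    self._accum[1] += (y64 * y64).sum(axis=self._BN_AXES)
                    self._accum[2] += y.size // y.shape[1]
                else:
                    m = self._BN_MOMENTUM
                    self.running_mean += m * (mu.astype(np.float64)
                                              - self.running_mean)
                    self.running_var += m * (var.astype(np.float64)
                                             - self.running_var)
            else:
                mu = self.running_mean.astype(y.dtype)
                var = self.running_var.astype(y.dtype)
            inv = 1.0 / np.sqrt(var + self._BN_EPS)
            xh = (y - self._bcast(mu)) * self._bcast(inv)
            self._xh, self._inv = xh, inv
            y = self._bcast(self.gamma) * xh + self._bcast(self.beta)
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        if self.batch_norm:
            xh, inv = self._xh, self._inv
            self.dgamma = (dy * xh).sum(axis=self._BN_AXES)
            self.dbeta = dy.sum(axis=self._BN_AXES)
            dxh = dy * self._bcast(self.gamma)
            dy = self._bcast(inv) * (
                dxh
                - dxh.mean(axis=self._BN_AXES, keepdims=True)
                - xh * (dxh * xh).mean(axis=self._BN_AXES, keepdims=True)
            )
            self._xh = self._inv = None
        dx, self.dw, self.db = _conv4d_batch_backward(
            dy, self._xp, self.w, self.pad
        )
        self._xp = None
        self._mask = None
        return dx

    @property
    def params(self):
        if self.batch_norm:
            return [(self.w, self.dw), (self.gamma, self.dgamma),
                    (self.beta, self.dbeta)]
        return [(self.w, self.dw), (self.b, self.db)]


class _MaxPool:
    """2x max-pooling over the three spatial axes (D, H, W); the plane axis
    R is never pooled."""

    def forward(self, x):
        n, c, r, d, h, w = x.shape
        xr = x.reshape(n, c, r, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(4, 6, 8))
        # gradient mask; ties share the gradient equally
        mask = xr == y[:, :, :, :, None, :, None, :, None]
        self._mask = mask / mask.sum(axis=(4, 6, 8), keepdims=True)
        self._shape = x.shape
        return y

    def backward(self, dy):
        g = self._mask * dy[:, :, :, :, None, :, None, :, None]
        out = g.reshape(self._shape)
        self._mask = None
        return out

    params: list = []


class _Upsample:
    """Nearest-neighbor 2x upsampling over (D, H, W)."""

    def forward(self, x):
        return np.repeat(np.repeat(np.repeat(x, 2, 3), 2, 4), 2, 5)

    def backward(self, dy):
        n, c, r, d, h, w = dy.shape
        return dy.reshape(n, c, r, d // 2, 2, h // 2, 2, w // 2, 2).sum(
            axis=(4, 6, 8)
        )

    params: list = []


@dataclass
class Tensor4DSample:
    """One classification sample: volume + shape matrix + label, all in [0,1]."""

    volume: np.ndarray  # (D, H, W)
    shape_matrix: np.ndarray  # (D, n_angles)
    label: int  # 0 = benign, 1 = malignant

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float32)
        self.shape_matrix = np.asarray(self.shape_matrix, dtype=np.float32)
        for name, arr in (("volume", self.volume),
                          ("shape_matrix", self.shape_matrix)):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")

    def tensor(self) -> np.ndarray:
        """The joint input tensor, shaped (1 batch, 1 channel, 2, D, H, W).

        Plane 0 of the extent-2 fourth axis holds the gray volume; plane 1
        broadcasts slice d's radial series across that slice's rows, so
        plane1[d, h, w] = matrix[d, w].
        """
        d, h, w = self.volume.shape
        if self.shape_matrix.shape != (d, w):
            raise ValueError(
                f"shape matrix {self.shape_matrix.shape} does not match "
                f"volume {(d, w)}"
            )
        t = np.empty((1, 1, 2, d, h, w), dtype=np.float32)
        t[0, 0, 0] = self.volume
        t[0, 0, 1] = self.shape_matrix[:, None, :]
        return t


def assemble_input(box, shape_matrix, label: int | str | None = None) -> Tensor4DSample:
    """Join a NoduleBox and its ShapeMatrix into a classification sample.

    Gray values are rescaled from [0, 255] to [0, 1]; the shape matrix is
    expected already normalized to [0, 1].
    """
    gray = np.asarray(box.gray, dtype=np.float32) / 255.0
    mat = np.asarray(getattr(shape_matrix, "matrix", shape_matrix),
                     dtype=np.float32)
    if label is None:
        label = box.label
    if isinstance(label, str):
        label = {"benign": 0, "malignant": 1}[label]
    sample = Tensor4DSample(volume=gray, shape_matrix=mat,
                            label=int(label) if label is not None else -1)
    sample.tensor()  # validate size consistency eagerly
    return sample


@dataclass
class UNetConfig:
    """U-Net hyper-parameters: the ablation axes plus training protocol."""

    depth: int = 3
    base_filters: int = 8
    n_classes: int = 2
    batch_norm: bool = True
    learning_rate: float = 5e-3
    epochs: int = 10
    batch_size: int = 8
    grad_clip: float = 5.0  # global gradient-norm ceiling; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class UNet4D:
    """U-shaped encoder-decoder over the joint 4D nodule tensor.

    The first convolution spans the full plane axis (extent R, valid) so the
    volume and shape-matrix planes are fused immediately; all later kernels
    have extent 1 on that axis and 3 (same-padded) on D, H, W.  The head is a
    1-extent convolution to ``n_classes`` channels followed by global
    averaging and softmax.
    """

    def __init__(self, cfg: UNetConfig, in_channels: int = 1,
                 in_extents: tuple[int, int, int, int] = (2, 32, 32, 32),
                 dtype=np.float32):
        r, d, h, w = in_extents
        div = 2 ** cfg.depth
        if d % div or h % div or w % div:
            raise ValueError(
                f"spatial extents {(d, h, w)} must be divisible by 2^depth={div}"
            )
        self.cfg = cfg
        self.in_extents = in_extents
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)

        def conv(ci, co, kern, pad):
            return _Conv4D(ci, co, kern, pad, rng, dtype=dtype,
                           batch_norm=cfg.batch_norm)

        k3 = (1, 3, 3, 3)
        p3 = (0, 1, 1, 1)
        self.enc: list[list[_Conv4D]] = []
        self.pools = [_MaxPool() for _ in range(cfg.depth)]
        c = in_channels
        for lvl in range(cfg.depth):
            f = cfg.base_filters * 2 ** lvl
            if lvl == 0:
                block = [conv(c, f, (r, 3, 3, 3), (0, 1, 1, 1)),
                         conv(f, f, k3, p3)]
            else:
                block = [conv(c, f, k3, p3), conv(f, f, k3, p3)]
            self.enc.append(block)
            c = f
        fb = cfg.base_filters * 2 ** cfg.depth
        self.bottleneck = [conv(c, fb, k3, p3), conv(fb, fb, k3, p3)]
        c = fb
        self.ups = [_Upsample() for _ in range(cfg.depth)]
        self.dec: list[list[_Conv4D]] = []
        for lvl in reversed(range(cfg.depth)):
            f = cfg.base_filters * 2 ** lvl
            self.dec.append([conv(c + f, f, k3, p3), conv(f, f, k3, p3)])
            c = f
        self.head = _Conv4D(c, cfg.n_classes, (1, 1, 1, 1), (0, 0, 0, 0),
                            rng, activation="linear", dtype=dtype)

    def train_mode(self, training: bool) -> None:
        """Switch batch-norm layers between batch and running statistics."""
        for layer in self._layers():
            layer.training = training

    def calibrate_norm(self, x: np.ndarray, batch_size: int = 8) -> None:
        """Set running batch-norm statistics to the exact per-channel
        statistics of the linear activations over ``x`` (batched forward
        passes in training mode)."""
        bn_layers = [lay for lay in self._layers()
                     if getattr(lay, "batch_norm", False)]
        if not bn_layers:
            return
        self.train_mode(True)
        for lay in bn_layers:
            c = lay.running_mean.shape[0]
            lay._accum = [np.zeros(c), np.zeros(c), 0]
        for start in range(0, len(x), batch_size):
            self.forward(x[start : start + batch_size])
        for lay in bn_layers:
            s, ss, n = lay._accum
            mean = s / n
            lay.running_mean = mean
            lay.running_var = np.maximum(ss / n - mean * mean, 0.0)
            lay._accum = None
        self.train_mode(False)

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for block in self.dec:
            yield from block
        yield self.head

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers() for p, _ in layer.params)

    def parameters(self):
        for layer in self._layers():
            yield from layer.params

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch of tensors (N, C, R, D, H, W) -> logits (N, n_classes)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.shape[2:] != self.in_extents:
            raise ValueError(
                f"input extents {x.shape[2:]} do not match model "
                f"{self.in_extents}"
            )
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._skip_channels = []
        for block, up, skip in zip(self.dec, self.ups, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for layer in block:
                h = layer.forward(h)
        h = self.head.forward(h)
        self._head_spatial = h.shape[2:]
        logits = h.mean(axis=(2, 3, 4, 5))
        return logits.astype(np.float64)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        n_sp = int(np.prod(self._head_spatial))
        dh = np.broadcast_to(
            dlogits.astype(self.dtype)[:, :, None, None, None, None] / n_sp,
            dlogits.shape + self._head_spatial,
        )
        dh = self.head.backward(np.ascontiguousarray(dh))
        skip_grads = []
        for block, up, sc in zip(reversed(self.dec), reversed(self.ups),
                                 reversed(self._skip_channels)):
            for layer in reversed(block):
                dh = layer.backward(dh)
            skip_grads.append(dh[:, :sc])
            dh = up.backward(dh[:, sc:])
        for layer in reversed(self.bottleneck):
            dh = layer.backward(dh)
        # skip_grads were collected walking decoder blocks from level 0 down,
        # so skip_grads[i] belongs to encoder level i; the encoder backward
        # walks levels deepest-first
        for block, pool, sg in zip(reversed(self.enc), reversed(self.pools),
                                   reversed(skip_grads)):
            dh = pool.backward(dh)
            dh = dh + sg
            for layer in reversed(block):
                dh = layer.backward(dh)


def build_unet(cfg: UNetConfig, in_channels: int = 1,
               in_extents: tuple[int, int, int, int] = (2, 32, 32, 32),
               dtype=np.float32) -> UNet4D:
    """Construct the seeded U-Net for the given configuration.

    ``dtype`` selects the parameter/activation precision; float32 for
    training speed, float64 for numerical verification.
    """
    return UNet4D(cfg, in_channels=in_channels, in_extents=in_extents,
                  dtype=dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels) -> float:
    """Mean negative log-likelihood of the labels under softmax(logits)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    c = logits.shape[1]
    if np.any(labels < 0) or np.any(labels >= c):
        raise ValueError(f"labels must lie in [0, {c})")
    p = softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-300)))


def _loss_and_grad(logits, labels):
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, _), m, v, g in zip(self.params, self.m, self.v, grads):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _stack(samples: list[Tensor4DSample]):
    x = np.concatenate([s.tensor() for s in samples], axis=0)
    y = np.asarray([s.label for s in samples], dtype=np.int64)
    return x, y


def train(model: UNet4D, samples: list[Tensor4DSample],
          cfg: UNetConfig | None = None):
    """Minimize the softmax cross-entropy on ``samples`` with Adam.

    Returns (model, history) where history is a list of per-epoch dicts with
    ``loss`` (mean batch loss) and ``accuracy`` (training accuracy).  The run
    is fully determined by cfg.seed.
    """
    cfg = cfg or model.cfg
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    history: list[dict] = []
    if cfg.epochs == 0:
        return model, history
    x, y = _stack(samples)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    n = len(y)
    model.train_mode(True)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x[idx])
            loss, dlogits = _loss_and_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            model.backward(dlogits)
            grads = [g for _, g in model.parameters()]
            if cfg.grad_clip:
                gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    grads = [g * scale for g in grads]
            opt.step(grads)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history.append(
            {"loss": float(np.sum(losses) / n), "accuracy": correct / n}
        )
    model.calibrate_norm(x, cfg.batch_size)
    model.train_mode(False)
    return model, history


def predict(model: UNet4D, samples: list[Tensor4DSample],
            batch_size: int = 8) -> np.ndarray:
    """Per-sample class probabilities, (N, n_classes)."""
    model.train_mode(False)
    x, _ = _stack(samples)
    out = []
    for start in range(0, len(samples), batch_size):
        out.append(softmax(model.forward(x[start : start + batch_size])))
    return np.concatenate(out, axis=0)
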