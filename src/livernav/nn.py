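"""A compact, dependency-free neural-network engine (numpy + BLAS).

Implements exactly what the segmentation U-Net needs: stride-1 same-padding
N-D convolutions (2D and 3D via a shared code path), ReLU, 2x max-pooling,
2x nearest-neighbour upsampling, channel concatenation, inverted dropout, a
sigmoid head with class-weighted binary cross-entropy, and Adam. Convolution
is an im2col gemm; its input gradient is again a same-padded convolution
with the channel-transposed, spatially flipped kernel, so both passes run on
BLAS. All layers support an explicit dtype (float32 for training, float64
for finite-difference gradient checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Conv", "ReLU", "MaxPool", "Upsample", "Dropout", "UNet", "Adam",
    "TrainConfig", "TrainHistory", "class_weights", "weighted_bce_with_logits",
    "sigmoid", "train_network", "predict_tiles", "DivergenceError",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv:
    """Stride-1, same-padding convolution with He-initialized weights."""

    def __init__(self, cin: int, cout: int, k: int, ndim: int,
                 rng: np.random.Generator, dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k, self.ndim = cin, cout, k, ndim
        fan_in = cin * k ** ndim
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin) + (k,) * ndim).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def _offset_slices(self, off, spatial):
        """Output/input slice pair for one kernel offset (same padding).

        With padding p = k//2 the contribution of offset ``off`` is
        y[pos] += (W_off · x)[pos + off - p] over the in-range positions.
        """
        pad = self.k // 2
        out_sl, in_sl = [], []
        for d, s in zip(off, spatial):
            delta = d - pad
            out_sl.append(slice(max(0, -delta), s - max(0, delta)))
            in_sl.append(slice(max(0, delta), s - max(0, -delta)))
        head = (slice(None), slice(None))
        return head + tuple(out_sl), head + tuple(in_sl)

    # Per-chunk product size target; keeps the stacked-GEMM output resident
    # in cache instead of streaming a k**ndim-fold intermediate through DRAM.
    _CHUNK_BYTES = 4 << 20

    def _apply_stacked(self, Wst, src, out, c_src, c_out, sp, flip):
        """out[pos] += sum_off (Wst_off · src)[pos + (off - pad) * sign].

        One GEMM per z-chunk over the (k**ndim)-stacked 1x1 kernels ``Wst``;
        each offset's product is added into ``out`` at its shifted position.
        ``flip`` negates the shift (used for the input gradient, which is the
        transpose of the forward scatter). Avoids materializing im2col patch
        tensors, whose copies dominate the runtime at these sizes.
        """
        n = src.shape[0]
        K = self.k ** self.ndim
        pad = self.k // 2
        Z, inplane = sp[0], int(np.prod(sp[1:]))
        sign = -1 if flip else 1
        itemsize = src.dtype.itemsize
        per_z = n * K * c_out * inplane * itemsize
        if per_z * Z <= 2 * self._CHUNK_BYTES:
            chunk = Z  # product is small; one GEMM beats many tiny ones
        else:
            chunk = max(4, self._CHUNK_BYTES // per_z)
        for z0 in range(0, Z, chunk):
            z1 = min(Z, z0 + chunk)
            zlo, zhi = max(0, z0 - pad), min(Z, z1 + pad)
            xs = src[:, :, zlo:zhi].reshape(n, c_src, -1)
            P = np.matmul(Wst, xs).reshape((n, K, c_out, zhi - zlo) + sp[1:])
            for o, off in enumerate(np.ndindex(*(self.k,) * self.ndim)):
                dz = sign * (off[0] - pad)
                pz0, pz1 = max(z0, -dz), min(z1, Z - dz)
                if pz0 >= pz1:
                    continue
                out_sl, in_sl = [slice(pz0, pz1)], [slice(pz0 + dz - zlo, pz1 + dz - zlo)]
                for d, s in zip(off[1:], sp[1:]):
                    delta = sign * (d - pad)
                    out_sl.append(slice(max(0, -delta), s - max(0, delta)))
                    in_sl.append(slice(max(0, delta), s - max(0, -delta)))
                out[(slice(None), slice(None), *out_sl)] += \
                    P[(slice(None), o, slice(None), *in_sl)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        n, sp = x.shape[0], x.shape[2:]
        K = self.k ** self.ndim
        Wst = np.ascontiguousarray(
            self.W.reshape(self.cout, self.cin, K).transpose(2, 0, 1)
        ).reshape(K * self.cout, self.cin)
        y = np.zeros((n, self.cout) + sp, dtype=x.dtype)
        self._apply_stacked(Wst, x, y, self.cin, self.cout, sp, flip=False)
        return y + self.b.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        n, sp = dy.shape[0], dy.shape[2:]
        K = self.k ** self.ndim
        gWm = self.gW.reshape(self.cout, self.cin, K)
        dym = dy.reshape(n, self.cout, -1)
        xm = x.reshape(n, self.cin, -1)
        self.gb += dym.sum(axis=(0, 2))
        # dx: transpose of the forward scatter (flipped shifts, W transposed)
        Wtr = np.ascontiguousarray(
            self.W.reshape(self.cout, self.cin, K).transpose(2, 1, 0)
        ).reshape(K * self.cin, self.cout)
        dx = np.zeros_like(x)
        self._apply_stacked(Wtr, dy, dx, self.cout, self.cin, sp, flip=True)
        dy_sh = np.empty_like(dy)
        for o, off in enumerate(np.ndindex(*(self.k,) * self.ndim)):
            out_sl, in_sl = self._offset_slices(off, sp)
            # dW_off = sum_n dy[out]^T x[in]; align dy to x in a zeroed
            # buffer so the contraction is one batched GEMM on contiguous
            # arrays instead of two strided copies per offset
            if out_sl == in_sl:
                src = dym
            else:
                dy_sh.fill(0.0)
                dy_sh[in_sl] = dy[out_sl]
                src = dy_sh.reshape(n, self.cout, -1)
            gWm[:, :, o] += np.matmul(src, xm.transpose(0, 2, 1)).sum(axis=0)
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool:
    """Factor-2 max pooling over every spatial axis (sizes must be even).

    Ties route the gradient to every tied input, each receiving an equal
    share, so the backward pass is a true subgradient even on plateaus.
    """

    def __init__(self, ndim: int):
        self.ndim = ndim
        self._cache = None

    def parameters(self):
        return []

    @staticmethod
    def _blocks(x: np.ndarray, ndim: int) -> np.ndarray:
        shape = [x.shape[0], x.shape[1]]
        for s in x.shape[2:]:
            shape += [s // 2, 2]
        # (N, C, d1, 2, d2, 2, ...) -> move the window axes to the end
        xb = x.reshape(shape)
        win_axes = tuple(3 + 2 * i for i in range(ndim))
        keep = tuple(a for a in range(xb.ndim) if a not in win_axes)
        return xb.transpose(keep + win_axes)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be even to pool, got {x.shape[2:]}")
        xb = self._blocks(x, self.ndim)
        red = tuple(range(xb.ndim - self.ndim, xb.ndim))
        y = xb.max(axis=red)
        if train:
            self._cache = (x.shape, xb, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xb, y = self._cache
        self._cache = None
        expand = y.reshape(y.shape + (1,) * self.ndim)
        mask = (xb == expand)
        counts = mask.sum(axis=tuple(range(mask.ndim - self.ndim, mask.ndim)),
                          keepdims=True)
        db = mask * (dy.reshape(y.shape + (1,) * self.ndim) / counts)
        # undo the transpose/reshape of _blocks
        inv = np.empty(db.ndim, dtype=int)
        win_axes = tuple(3 + 2 * i for i in range(self.ndim))
        keep = tuple(a for a in range(db.ndim) if a not in win_axes)
        for new_pos, old_pos in enumerate(keep + win_axes):
            inv[old_pos] = new_pos
        return db.transpose(tuple(inv)).reshape(x_shape)


class Upsample:
    """Factor-2 nearest-neighbour upsampling over every spatial axis."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = x
        for axis in range(2, 2 + self.ndim):
            y = np.repeat(y, 2, axis=axis)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = [dy.shape[0], dy.shape[1]]
        for s in dy.shape[2:]:
            shape += [s // 2, 2]
        db = dy.reshape(shape)
        red = tuple(3 + 2 * i for i in range(self.ndim))
        return db.sum(axis=red)


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    ``levels`` resolutions (default 5, i.e. 4 poolings); each level applies
    two 3^d convolutions with ReLU; dropout (default rate 0.5) follows the
    two deepest contracting levels. The decoder upsamples (nearest
    neighbour), halves the channels with a convolution, concatenates the
    skip tensor and applies two more convolutions; a final 1^d convolution
    produces a single logit channel. Filter counts double per level from
    ``base_filters``.
    """

    def __init__(self, in_channels: int = 5, ndim: int = 3, levels: int = 5,
                 base_filters: int = 64, dropout_rate: float = 0.5,
                 dropout_levels: tuple[int, ...] = (4, 5), seed: int = 0,
                 dtype=np.float32):
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if levels < 2:
            raise ValueError("need at least 2 levels")
        if base_filters < 1 or in_channels < 1:
            raise ValueError("in_channels and base_filters must be >= 1")
        self.in_channels, self.ndim, self.levels = in_channels, ndim, levels
        self.base_filters, self.dropout_rate = base_filters, dropout_rate
        self.dropout_levels = tuple(dropout_levels)
        self.seed, self.dtype = seed, dtype
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 63))
        filters = [base_filters * 2 ** i for i in range(levels)]

        def block(cin, cout):
            return [Conv(cin, cout, 3, ndim, rng, dtype), ReLU(),
                    Conv(cout, cout, 3, ndim, rng, dtype), ReLU()]

        self.enc = []
        cin = in_channels
        for i, f in enumerate(filters):
            layers = block(cin, f)
            if (i + 1) in self.dropout_levels and dropout_rate > 0:
                layers.append(Dropout(dropout_rate, self._drop_rng))
            self.enc.append(layers)
            cin = f
        self.pools = [MaxPool(ndim) for _ in range(levels - 1)]
        self.ups, self.up_convs, self.dec = [], [], []
        for i in range(levels - 2, -1, -1):
            self.ups.append(Upsample(ndim))
            self.up_convs.append(
                [Conv(filters[i + 1], filters[i], 3, ndim, rng, dtype), ReLU()])
            self.dec.append(block(2 * filters[i], filters[i]))
        self.head = Conv(filters[0], 1, 1, ndim, rng, dtype)
        # Zero-initialized head: training starts from the maximum-entropy
        # prediction (p = 0.5 everywhere), which is the optimum among constant
        # outputs under class-balanced weighting. Without this, the large
        # Adam step size (~learning_rate per parameter per step) drives the
        # network through a violent transient that collapses it onto a
        # constant prediction before any feature-label correlation can grow.
        self.head.W[:] = 0.0

    def _all_layers(self):
        for group in (*self.enc, *self.up_convs, *self.dec):
            yield from group
        yield from self.pools
        yield self.head

    def parameters(self):
        params = []
        for layer in self._all_layers():
            params.extend(layer.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(int(p.size) for p, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, in_channels, *spatial)``; spatial sizes
        must be divisible by 2**(levels-1)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 + self.ndim or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, {'*' * self.ndim}) input, got {x.shape}")
        div = 2 ** (self.levels - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {div}")
        skips = []
        for i, layers in enumerate(self.enc):
            for layer in layers:
                x = layer.forward(x, train)
            if i < self.levels - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = []
        for j in range(self.levels - 1):
            x = self.ups[j].forward(x, train)
            for layer in self.up_convs[j]:
                x = layer.forward(x, train)
            skip = skips[-(j + 1)]
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in self.dec[j]:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the latest training forward."""
        dx = self.head.backward(np.asarray(dlogits, dtype=self.dtype))
        dskips = []
        for j in range(self.levels - 2, -1, -1):
            for layer in reversed(self.dec[j]):
                dx = layer.backward(dx)
            c = self._skip_channels[j]
            dskips.append(dx[:, :c])
            dx = dx[:, c:]
            for layer in reversed(self.up_convs[j]):
                dx = layer.backward(dx)
            dx = self.ups[j].backward(dx)
        dskips.reverse()  # dskips[j] pairs with decoder stage j (deepest first)
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[self.levels - 2 - i]
            for layer in reversed(self.enc[i]):
                dx = layer.backward(dx)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities ``(N, *spatial)`` in evaluation mode."""
        return sigmoid(self.forward(x, train=False))[:, 0]


# ---------------------------------------------------------------------------
# Loss, optimizer, training loop
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray) -> tuple[float, float]:
    """(background, foreground) weights inversely proportional to class
    frequency, normalized to sum to 2 (both 1 at a 50/50 split)."""
    y = np.asarray(labels)
    n = y.size
    n_fg = int(np.count_nonzero(y))
    if n_fg == 0 or n_fg == n:
        raise ValueError("labels contain a single class; weights are undefined")
    w_bg, w_fg = n / (n - n_fg), n / n_fg
    s = w_bg + w_fg
    return 2.0 * w_bg / s, 2.0 * w_fg / s


def weighted_bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                             weights: tuple[float, float] = (1.0, 1.0),
                             eps: float = 1e-7):
    """Mean class-weighted binary cross-entropy and its logit gradient.

    Probabilities are clamped to [eps, 1-eps] inside the log only; the
    gradient is the exact analytic ``(w1*y*(p-1) + w0*(1-y)*p) / n``.
    """
    w0, w1 = weights
    y = np.asarray(targets, dtype=logits.dtype)
    p = sigmoid(np.asarray(logits, dtype=np.float64))
    pc = np.clip(p, eps, 1.0 - eps)
    loss = -float(np.mean(w1 * y * np.log(pc) + w0 * (1.0 - y) * np.log1p(-pc)))
    dlogits = ((w1 * y * (p - 1.0) + w0 * (1.0 - y) * p) / y.size).astype(logits.dtype)
    return loss, dlogits


class Adam:
    def __init__(self, params, lr: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 4
    learning_rate: float = 0.01
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainHistory:
    epoch_losses: list[float] = field(default_factory=list)
    batch_losses: list[float] = field(default_factory=list)
    n_tiles: int = 0
    class_weights: tuple[float, float] = (1.0, 1.0)


def train_network(net: UNet, x: np.ndarray, y: np.ndarray,
                  cfg: TrainConfig | None = None,
                  weights: tuple[float, float] | None = None) -> TrainHistory:
    """Minibatch Adam training on tiles ``x`` (N, C, *sp) with binary labels
    ``y`` (N, *sp). Shuffling is seeded; class weights default to inverse
    class frequency over all labels."""
    cfg = cfg or TrainConfig()
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or x.shape[2:] != y.shape[1:]:
        raise ValueError(f"tiles {x.shape} and labels {y.shape} do not match")
    if weights is None:
        weights = class_weights(y)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory(n_tiles=len(x), class_weights=weights)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x)) if cfg.shuffle else np.arange(len(x))
        losses = []
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, dlogits = weighted_bce_with_logits(
                logits[:, 0], y[idx], weights)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1}, batch {lo // cfg.batch_size}")
            net.backward(dlogits[:, None])
            opt.step()
            losses.append(loss)
            hist.batch_losses.append(loss)
        hist.epoch_losses.append(float(np.mean(losses)))
        logger.info("epoch %d/%d: loss %.4f", epoch + 1, cfg.epochs, hist.epoch_losses[-1])
    return hist


def predict_tiles(net: UNet, x: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Per-voxel probabilities for a stack of tiles, batched."""
    x = np.asarray(x)
    out = np.empty((len(x),) + x.shape[2:], dtype=np.float64)
    for lo in range(0, len(x), batch_size):
        out[lo:lo + batch_size] = net.predict_proba(x[lo:lo + batch_size])
    return out
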