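"""Minimal deterministic CNN primitives on NumPy.

This module provides exactly the building blocks the per-patient adversarial
training needs: 2D convolution, transposed convolution, batch normalization,
max pooling, dense layers, a U-Net generator, a strided-convolution critic and
an Adam optimizer.  Everything runs in float32 on the CPU and all randomness
flows through an explicit ``numpy.random.Generator``, so a fixed seed yields
bit-identical training runs on a fixed machine.

Gradients are hand-derived.  The critic additionally supports the
second-order path required by the gradient penalty: the gradient of the
penalty (a function of the critic's *input* gradient) with respect to the
critic's *weights*.  Leaky-ReLU derivative masks are held constant in that
path, which equals the almost-everywhere exact result reverse-mode autodiff
would produce for piecewise-linear networks.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.0, 0.9), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (p.m / c1) / (np.sqrt(p.v / c2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# convolution primitives (im2col + BLAS matmul)
# ---------------------------------------------------------------------------

def _pad2d(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x, W, b=None, stride=1, pad=0, return_padded=False):
    """Cross-correlation.  W: (O, C, k, k).  Returns (B, O, Ho, Wo).

    Computed as one einsum over a strided window view (no patch-matrix
    copy); the padded input can be returned for reuse by the weight
    gradient.
    """
    k = W.shape[2]
    xp = _pad2d(x, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    if stride > 1:
        win = win[:, :, ::stride, ::stride]
    out = np.einsum("bchwij,ocij->bohw", win, W, optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    if return_padded:
        return out, xp
    return out


def conv2d_weight_grad(xp, gout, k, stride=1):
    """dL/dW from the padded input and the output gradient (shifted GEMMs)."""
    B, O, Ho, Wo = gout.shape
    C = xp.shape[1]
    gm = np.ascontiguousarray(gout.transpose(1, 0, 2, 3)).reshape(O, -1)
    dW = np.empty((O, C, k, k), DTYPE)
    for di in range(k):
        for dj in range(k):
            xv = xp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
            xv = np.ascontiguousarray(xv.transpose(1, 0, 2, 3)).reshape(C, -1)
            dW[:, :, di, dj] = gm @ xv.T
    return dW


def conv2d_input_grad(gout, W, stride, pad, in_hw):
    """dL/dx of conv2d; also serves as transposed-convolution forward."""
    B, O, Ho, Wo = gout.shape
    k = W.shape[2]
    if stride > 1:
        d = np.zeros((B, O, (Ho - 1) * stride + 1, (Wo - 1) * stride + 1), DTYPE)
        d[:, :, ::stride, ::stride] = gout
    else:
        d = gout
    Wt = np.ascontiguousarray(W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx = conv2d(d, Wt, stride=1, pad=k - 1 - pad)
    H, Wd = in_hw
    if dx.shape[2] != H or dx.shape[3] != Wd:
        raise ValueError(
            f"size mismatch in conv input grad: got {dx.shape[2:]}, need {(H, Wd)}"
        )
    return dx


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, zero_init=False):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        fan_in = cin * k * k
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x_hw = x.shape[2:]
        out, self._xp = conv2d(
            x, self.W.value, self.b.value, self.stride, self.pad,
            return_padded=True
        )
        return out

    def backward(self, gout, accumulate=True):
        if accumulate:
            self.W.grad += conv2d_weight_grad(self._xp, gout, self.k, self.stride)
            self.b.grad += gout.sum(axis=(0, 2, 3))
        return conv2d_input_grad(gout, self.W.value, self.stride, self.pad, self._x_hw)


class ConvTranspose2d:
    """Stride-2 learned upsampling; the adjoint of a k=4, s=2, p=1 convolution."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        fan_in = cin * k * k
        # weight laid out as the conv weight whose adjoint this layer applies
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cin, cout, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        H, Wd = x.shape[2:]
        out = conv2d_input_grad(
            x, self.W.value, self.stride, self.pad, (H * self.stride, Wd * self.stride)
        )
        return out + self.b.value[None, :, None, None]

    def backward(self, gout, accumulate=True):
        gx, gp = conv2d(
            gout, self.W.value, stride=self.stride, pad=self.pad,
            return_padded=True
        )
        if accumulate:
            self.W.grad += conv2d_weight_grad(gp, self._x, self.k, self.stride)
            self.b.grad += gout.sum(axis=(0, 2, 3))
        return gx


class BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, DTYPE)
        self.running_var = np.ones(c, DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._train = train
        return (
            self.gamma.value[None, :, None, None] * self._xhat
            + self.beta.value[None, :, None, None]
        )

    def backward(self, gout, accumulate=True):
        xhat, istd = self._xhat, self._istd
        if accumulate:
            self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = gout * self.gamma.value[None, :, None, None]
        if not self._train:
            return g * istd[None, :, None, None]
        n = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gsum = g.sum(axis=(0, 2, 3), keepdims=False)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3))
        return (
            istd[None, :, None, None]
            / n
            * (n * g - gsum[None, :, None, None] - xhat * gx_sum[None, :, None, None])
        )


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout, accumulate=True):
        return gout * self._mask


class LeakyReLU:
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = np.where(x > 0, DTYPE(1.0), DTYPE(self.alpha))
        return x * self._mask

    def backward(self, gout, accumulate=True):
        return gout * self._mask


class MaxPool2d:
    """2x2 max pooling with stride 2."""

    def params(self):
        return []

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout, accumulate=True):
        B, C, H, W = self._in_shape
        gr = np.zeros((B, C, H // 2, W // 2, 4), DTYPE)
        np.put_along_axis(gr, self._arg[..., None], gout[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gr).reshape(B, C, H, W)


class Dense:
    def __init__(self, nin, nout, rng):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout, accumulate=True):
        if accumulate:
            self.W.grad += self._x.T @ gout
            self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T


# ---------------------------------------------------------------------------
# U-Net generator
# ---------------------------------------------------------------------------

class _ConvBlock:
    """3x3 conv -> batch norm -> ReLU, twice."""

    def __init__(self, cin, cout, rng):
        self.layers = [
            Conv2d(cin, cout, 3, pad=1, rng=rng),
            BatchNorm2d(cout),
            ReLU(),
            Conv2d(cout, cout, 3, pad=1, rng=rng),
            BatchNorm2d(cout),
            ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g, accumulate=True):
        for l in reversed(self.layers):
            g = l.backward(g, accumulate)
        return g


class UNetGenerator:
    """U-Net mapping a slice to an additive change map of the same size.

    The final 1x1 output convolution is zero-initialized so the network starts
    from the identity map (fake follow-up equals the input slice).
    """

    def __init__(self, levels=5, base_features=32, in_channels=1, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.levels = levels
        self.base_features = base_features
        feats = [base_features * 2 ** i for i in range(levels)]
        self.enc = []
        cin = in_channels
        for f in feats[:-1]:
            self.enc.append(_ConvBlock(cin, f, rng))
            cin = f
        self.pools = [MaxPool2d() for _ in feats[:-1]]
        self.bottleneck = _ConvBlock(cin, feats[-1], rng)
        self.ups = []
        self.dec = []
        cin = feats[-1]
        for f in reversed(feats[:-1]):
            self.ups.append(ConvTranspose2d(cin, f, rng=rng))
            self.dec.append(_ConvBlock(2 * f, f, rng))
            cin = f
        self.head = Conv2d(base_features, 1, 1, rng=rng, zero_init=True)

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            ps += up.params() + blk.params()
        ps += self.head.params()
        return ps

    def min_divisor(self):
        return 2 ** (self.levels - 1)

    def forward(self, x, train=True):
        x = np.asarray(x, DTYPE)
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            blk._cat_split = skip.shape[1]
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, gmap, accumulate=True):
        g = self.head.backward(gmap, accumulate)
        gskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec)):
            g = blk.backward(g, accumulate)
            split = blk._cat_split
            gskip, g = g[:, :split], g[:, split:]
            gskips.append(gskip)
            g = up.backward(g, accumulate)
        g = self.bottleneck.backward(g, accumulate)
        for blk, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(gskips)
        ):
            g = pool.backward(g, accumulate)
            g = g + gskip
            g = blk.backward(g, accumulate)
        return g

    # --- parameter snapshot/restore (for checkpoint ensembles) -----------
    def state(self):
        st = [p.value.copy() for p in self.params()]
        bn_state = []
        for obj in self._bn_layers():
            bn_state.append((obj.running_mean.copy(), obj.running_var.copy()))
        return {"params": st, "bn": bn_state}

    def load_state(self, st):
        for p, v in zip(self.params(), st["params"]):
            p.value[...] = v
        for obj, (m, v) in zip(self._bn_layers(), st["bn"]):
            obj.running_mean[...] = m
            obj.running_var[...] = v

    def _bn_layers(self):
        out = []
        blocks = list(self.enc) + [self.bottleneck] + list(self.dec)
        for blk in blocks:
            for l in blk.layers:
                if isinstance(l, BatchNorm2d):
                    out.append(l)
        return out


# ---------------------------------------------------------------------------
# critic (encoder with scalar output) and its double-backprop path
# ---------------------------------------------------------------------------

class SliceCritic:
    """Strided-conv encoder with LeakyReLU ending in a single scalar.

    No batch normalization: the gradient penalty requires per-sample critic
    gradients, which batch-coupled statistics would break.
    """

    def __init__(self, channels=(16, 32, 64, 128, 256), in_size=256, in_channels=1,
                 alpha=0.2, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.channels = tuple(channels)
        self.in_size = in_size
        self.alpha = alpha
        self.convs = []
        cin = in_channels
        size = in_size
        for c in channels:
            if size % 2 != 0:
                raise ValueError("input size not divisible through the conv stack")
            self.convs.append(Conv2d(cin, c, 4, stride=2, pad=1, rng=rng))
            cin = c
            size //= 2
        self.final_hw = size
        self.dense = Dense(cin * size * size, 1, rng)

    def params(self):
        ps = []
        for c in self.convs:
            ps += c.params()
        ps += self.dense.params()
        return ps

    def forward(self, x, train=True):
        x = np.asarray(x, DTYPE)
        self._masks = []
        h = x
        for conv in self.convs:
            z = conv.forward(h, train)
            m = np.where(z > 0, DTYPE(1.0), DTYPE(self.alpha))
            self._masks.append(m)
            h = z * m
        self._pre_dense_shape = h.shape
        y = self.dense.forward(h.reshape(h.shape[0], -1), train)
        return y[:, 0]

    def backward(self, gy, accumulate=True):
        """Backprop d(sum gy*y)/d(params and input).  gy: (B,)."""
        g = self.dense.backward(np.asarray(gy, DTYPE)[:, None], accumulate)
        g = g.reshape(self._pre_dense_shape)
        for conv, m in zip(reversed(self.convs), reversed(self._masks)):
            g = g * m
            g = conv.backward(g, accumulate)
        return g

    # -- gradient penalty support ----------------------------------------
    def input_gradient(self, x):
        """Per-sample gradient of the scalar output w.r.t. the input.

        Returns (g, cache); cache holds the intermediates of the
        input-gradient computation needed by :meth:`gp_backward`.
        """
        B = x.shape[0]
        self.forward(x, train=True)
        masks = self._masks
        W = self.dense.W.value[:, 0]
        u = np.broadcast_to(
            W.reshape(self._pre_dense_shape[1:]), self._pre_dense_shape
        ).astype(DTYPE)
        vs = []
        for conv, m in zip(reversed(self.convs), reversed(masks)):
            v = u * m
            vs.append(v)
            u = conv2d_input_grad(v, conv.W.value, conv.stride, conv.pad, conv._x_hw)
        cache = {"masks": masks, "vs": vs}
        return u, cache

    def gp_backward(self, t0, cache):
        """Accumulate d(penalty)/d(params) given t0 = d(penalty)/d(input_grad).

        Propagates the adjoint forward through the transposed network that
        computed the input gradient; activation masks are constants here.
        """
        masks, vs = cache["masks"], cache["vs"]
        t = np.asarray(t0, DTYPE)
        for conv, m, v in zip(self.convs, masks, reversed(vs)):
            # u_prev = conv_input_grad(v, W): adjoint wrt v is conv(t, W);
            # the weight gradient of <t, conv_input_grad(v, W)> is the
            # standard conv weight gradient with input t and output-grad v.
            s, tp = conv2d(
                t, conv.W.value, stride=conv.stride, pad=conv.pad,
                return_padded=True
            )
            conv.W.grad += conv2d_weight_grad(tp, v, conv.k, conv.stride)
            t = s * m
        # the dense weights seeded the backward pass (u_L = W per sample)
        self.dense.W.grad += t.reshape(t.shape[0], -1).sum(axis=0)[:, None]

    def state(self):
        return {"params": [p.value.copy() for p in self.params()]}

    def load_state(self, st):
        for p, v in zip(self.params(), st["params"]):
            p.value[...] = v
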