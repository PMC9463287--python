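"""Minimal differentiable layer stack backing the numpy backend.

Inference-only semantics: forward evaluation, gradients with respect to inputs
and intermediate activations, and a guided-ReLU backward variant.  No training
loop and no weight gradients -- attribution needs neither.

Array convention: channels-last.  A 3D volume is ``(X, Y, Z, C)``, a 2D image
``(H, W, C)``, a feature vector ``(C,)``.  Convolution kernels must have odd
extent per axis (zero-padded "same" convolution); this keeps the backward pass
an exact adjoint of the forward pass.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

_nonrelu_guided_logged = False


class Layer:
    """One differentiable operation: ``forward`` caches, ``backward`` replays."""

    #: True for layers whose output retains spatial axes (inspectable by CAM).
    spatial = True

    def forward(self, x):
        raise NotImplementedError

    def backward(self, g, cache, guided=False):
        raise NotImplementedError

    def output_shape(self, in_shape):
        """Declared output shape for a given input shape (shape inference)."""
        raise NotImplementedError


class Conv(Layer):
    """Same-padded n-D convolution, channels-last, odd kernels only.

    ``weights`` has shape ``(C_out, C_in, *kernel)``; bias ``(C_out,)``.
    """

    def __init__(self, weights, bias=None):
        weights = np.asarray(weights, dtype=np.float64)
        if any(k % 2 == 0 for k in weights.shape[2:]):
            raise ValueError("Conv kernels must have odd extent per axis")
        self.weights = weights
        self.bias = (
            np.zeros(weights.shape[0]) if bias is None else np.asarray(bias, float)
        )

    @property
    def c_out(self):
        return self.weights.shape[0]

    @property
    def c_in(self):
        return self.weights.shape[1]

    def forward(self, x):
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"Conv expects {self.c_in} input channels, got {x.shape[-1]}"
            )
        out = np.empty(x.shape[:-1] + (self.c_out,), dtype=np.float64)
        for o in range(self.c_out):
            acc = self.bias[o] * np.ones(x.shape[:-1])
            for i in range(self.c_in):
                acc = acc + ndi.correlate(
                    x[..., i], self.weights[o, i], mode="constant", cval=0.0
                )
            out[..., o] = acc
        return out, None

    def backward(self, g, cache, guided=False):
        gx = np.zeros(g.shape[:-1] + (self.c_in,), dtype=np.float64)
        for i in range(self.c_in):
            acc = np.zeros(g.shape[:-1])
            for o in range(self.c_out):
                # adjoint of same-padded correlation is same-padded convolution
                acc = acc + ndi.convolve(
                    g[..., o], self.weights[o, i], mode="constant", cval=0.0
                )
            gx[..., i] = acc
        return gx

    def output_shape(self, in_shape):
        return in_shape[:-1] + (self.c_out,)


class ReLU(Layer):
    def forward(self, x):
        return np.maximum(x, 0.0), x > 0

    def backward(self, g, cache, guided=False):
        g = g * cache
        if guided:
            g = g * (g > 0)
        return g

    def output_shape(self, in_shape):
        return in_shape


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, g, cache, guided=False):
        global _nonrelu_guided_logged
        if guided and not _nonrelu_guided_logged:
            logger.info(
                "guided backprop leaves non-ReLU activations unmodified (tanh)"
            )
            _nonrelu_guided_logged = True
        return g * (1.0 - cache**2)

    def output_shape(self, in_shape):
        return in_shape


class Dense(Layer):
    """Affine map on a flat feature vector: ``y = W x + b``."""

    spatial = False

    def __init__(self, weights, bias=None):
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = (
            np.zeros(self.weights.shape[0])
            if bias is None
            else np.asarray(bias, float)
        )

    def forward(self, x):
        if x.ndim != 1:
            raise ValueError("Dense expects a flat vector; add Flatten first")
        return self.weights @ x + self.bias, None

    def backward(self, g, cache, guided=False):
        return self.weights.T @ g

    def output_shape(self, in_shape):
        return (self.weights.shape[0],)


class Flatten(Layer):
    spatial = False

    def forward(self, x):
        return x.ravel(), x.shape

    def backward(self, g, cache, guided=False):
        return g.reshape(cache)

    def output_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dropout(Layer):
    """Inert at inference; kept so architecture listings match their spec."""

    spatial = False

    def __init__(self, rate=0.5):
        self.rate = rate

    def forward(self, x):
        return x, None

    def backward(self, g, cache, guided=False):
        return g

    def output_shape(self, in_shape):
        return in_shape


def _blocked(x, f, nsp):
    shape = []
    for s in x.shape[:nsp]:
        shape += [s // f, f]
    shape += list(x.shape[nsp:])
    axes = tuple(range(1, 2 * nsp, 2))
    return x.reshape(shape), axes


class AvgPool(Layer):
    """Block-mean downsampling by an integer factor on every spatial axis."""

    def __init__(self, factor=2):
        self.factor = factor

    def forward(self, x):
        nsp = x.ndim - 1
        if any(s % self.factor for s in x.shape[:nsp]):
            raise ValueError(
                f"spatial shape {x.shape[:nsp]} not divisible by pool factor "
                f"{self.factor}"
            )
        xb, axes = _blocked(x, self.factor, nsp)
        return xb.mean(axis=axes), x.shape

    def backward(self, g, cache, guided=False):
        nsp = len(cache) - 1
        scale = 1.0 / self.factor**nsp
        gx = g * scale
        for ax in range(nsp):
            gx = np.repeat(gx, self.factor, axis=ax)
        return gx

    def output_shape(self, in_shape):
        nsp = len(in_shape) - 1
        return tuple(s // self.factor for s in in_shape[:nsp]) + (in_shape[-1],)


class Upsample(Layer):
    """Nearest-neighbour upsampling by an integer factor (decoder side)."""

    def __init__(self, factor=2):
        self.factor = factor

    def forward(self, x):
        y = x
        for ax in range(x.ndim - 1):
            y = np.repeat(y, self.factor, axis=ax)
        return y, x.shape

    def backward(self, g, cache, guided=False):
        nsp = len(cache) - 1
        gb, axes = _blocked(g, self.factor, nsp)
        return gb.sum(axis=axes)

    def output_shape(self, in_shape):
        nsp = len(in_shape) - 1
        return tuple(s * self.factor for s in in_shape[:nsp]) + (in_shape[-1],)


class GlobalAvgPool(Layer):
    spatial = False

    def forward(self, x):
        nsp = x.ndim - 1
        return x.mean(axis=tuple(range(nsp))), x.shape

    def backward(self, g, cache, guided=False):
        nsp = len(cache) - 1
        n = int(np.prod(cache[:nsp]))
        return np.broadcast_to(g, cache).copy() / n

    def output_shape(self, in_shape):
        return (in_shape[-1],)


class ChannelMean(Layer):
    """Mean across channels, keeping a singleton channel axis."""

    def forward(self, x):
        return x.mean(axis=-1, keepdims=True), x.shape[-1]

    def backward(self, g, cache, guided=False):
        return np.repeat(g, cache, axis=-1) / cache

    def output_shape(self, in_shape):
        return in_shape[:-1] + (1,)


class Network:
    """Ordered, named layer sequence with recorded forward/backward passes."""

    def __init__(self, layers):
        """``layers`` is a list of ``(name, Layer)`` pairs; names unique."""
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.layers = list(layers)

    @property
    def layer_names(self):
        return [n for n, _ in self.layers]

    def get_layer(self, name):
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(name)

    def forward(self, x):
        y = np.asarray(x, dtype=np.float64)
        for _, layer in self.layers:
            y, _ = layer.forward(y)
        return y

    def forward_backward(self, x, g_out_fn, guided=False):
        """Forward pass, then backprop of ``g_out_fn(output)``.

        Returns ``(output, input_gradient, activations, backsignals)`` where the
        two dicts map layer name -> array at that layer's *output*.
        """
        y = np.asarray(x, dtype=np.float64)
        caches, activations = [], {}
        for name, layer in self.layers:
            y, cache = layer.forward(y)
            caches.append(cache)
            activations[name] = y
        output = y
        g = np.asarray(g_out_fn(output), dtype=np.float64)
        backsignals = {}
        for (name, layer), cache in zip(reversed(self.layers), reversed(caches)):
            backsignals[name] = g
            g = layer.backward(g, cache, guided=guided)
        return output, g, activations, backsignals

    def shape_trace(self, in_shape):
        """Output shape of every layer for a declared input shape."""
        shapes = []
        s = tuple(in_shape)
        for name, layer in self.layers:
            s = layer.output_shape(s)
            shapes.append((name, s))
        return shapes
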