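"""Spiking layer primitives, shape propagation and parameter counting.

Layers operate on whole spike sequences of shape ``(B, T, C, H, W)``
(convolutional stages) or ``(B, T, N)`` (dense stages).  Each weighted
layer applies its linear map per time bin and feeds the result through a
shared :class:`~spikegaze.neurons.CubaLifCell`; pooling is a logical OR
(max) over 2x2 windows per bin with ceil-mode padding; dense layers
optionally carry per-input integer synaptic delays, per-output weight
normalization and unit-level dropout.

Conventions forced by the reference architecture's arithmetic:
convolutions are unpadded with ``out = floor((in - k)/s) + 1``; pooling
uses ceil mode ``out = ceil(in / 2)``; no layer has a bias term (the
neuron bias ``b`` exists but defaults to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .neurons import CubaLifCell, CubaLifParams, SurrogateSpec

__all__ = [
    "LayerSpec", "propagate_shape", "count_parameters",
    "SpikingConv", "SpikingPool", "Flatten", "SpikingDense",
    "make_layer",
]

WEIGHTED_KINDS = ("conv", "dense", "output")
VALID_KINDS = WEIGHTED_KINDS + ("pool", "flatten")


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one network stage.

    ``kind`` is one of conv / pool / dense / output / flatten; ``output``
    is a dense stage without regularizers (the 2-unit readout).  Shapes
    follow the (W, H, C) convention of the architecture tables.
    """

    kind: str
    c_in: int = 0
    c_out: int = 0
    kernel: tuple[int, int] = (0, 0)
    stride: tuple[int, int] = (1, 1)
    neuron: CubaLifParams | None = None
    delay: bool = False
    weight_norm: bool = False
    dropout: float = 0.0

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv":
            if min(self.c_in, self.c_out, *self.kernel, *self.stride) < 1:
                raise ValueError("conv needs positive channels/kernel/stride")
        if self.kind in ("dense", "output"):
            if self.c_in < 1 or self.c_out < 1:
                raise ValueError("dense needs positive widths")
        if self.kind in ("pool", "flatten") and (self.delay or self.weight_norm
                                                 or self.dropout):
            raise ValueError(f"{self.kind} carries no weights or regularizers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def propagate_shape(layer: LayerSpec, in_shape):
    """Propagate a (W, H, C) shape (or flat width) through one layer.

    conv (no padding): out = floor((in - k)/s) + 1 per spatial axis;
    pool 2x2 stride 2 (ceil mode): out = ceil(in / 2);
    flatten: W*H*C; dense/output: c_out.
    """
    if layer.kind == "conv":
        w, h, c = in_shape
        kx, ky = layer.kernel
        sx, sy = layer.stride
        if kx > w or ky > h:
            raise ValueError(f"kernel {layer.kernel} larger than input {in_shape}")
        if c != layer.c_in:
            raise ValueError(f"channel mismatch: input {c}, layer {layer.c_in}")
        return ((w - kx) // sx + 1, (h - ky) // sy + 1, layer.c_out)
    if layer.kind == "pool":
        w, h, c = in_shape
        return (math.ceil(w / 2), math.ceil(h / 2), c)
    if layer.kind == "flatten":
        w, h, c = in_shape
        return w * h * c
    # dense / output
    n_in = in_shape if isinstance(in_shape, int) else int(np.prod(in_shape))
    if n_in != layer.c_in:
        raise ValueError(f"width mismatch: input {n_in}, layer {layer.c_in}")
    return layer.c_out


def count_parameters(obj) -> int:
    """Trainable weight count: conv = c_in*c_out*kx*ky, dense = in*out,
    everything else 0 (no biases anywhere)."""
    if isinstance(obj, LayerSpec):
        if obj.kind == "conv":
            return obj.c_in * obj.c_out * obj.kernel[0] * obj.kernel[1]
        if obj.kind in ("dense", "output"):
            return obj.c_in * obj.c_out
        return 0
    return sum(count_parameters(layer) for layer in obj)


# ---------------------------------------------------------------------------
# im2col helpers (unpadded, strided)
# ---------------------------------------------------------------------------

def _conv_geometry(h, w, kh, kw, sh, sw):
    return (h - kh) // sh + 1, (w - kw) // sw + 1


def _im2col(x, kh, kw, sh, sw):
    """Patch matrix in (n, oh, ow, c, kh, kw) layout so the convolution
    collapses to one large matmul."""
    n, c, h, w = x.shape
    oh, ow = _conv_geometry(h, w, kh, kw, sh, sw)
    cols = np.empty((n, oh, ow, c, kh, kw), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[..., i, j] = np.moveaxis(
                x[:, :, i:i + oh * sh:sh, j:j + ow * sw:sw], 1, -1)
    return cols


def _col2im(gcols, x_shape, sh, sw):
    n, c, h, w = x_shape
    kh, kw = gcols.shape[-2:]
    oh, ow = gcols.shape[1:3]
    gx = np.zeros(x_shape, dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + oh * sh:sh, j:j + ow * sw:sw] += np.moveaxis(
                gcols[..., i, j], -1, 1)
    return gx


# ---------------------------------------------------------------------------
# Runtime layers
# ---------------------------------------------------------------------------

class _LayerBase:
    spec: LayerSpec
    params: dict
    grads: dict
    cell: CubaLifCell | None = None

    def zero_grad(self):
        for k in self.grads:
            self.grads[k] = np.zeros_like(self.params[k])
        if self.cell is not None:
            self.cell.zero_grad()

    def all_params(self):
        """(name, value, grad-dict, key) tuples for the optimizer."""
        for k in self.params:
            yield k, self.params, self.grads
        if self.cell is not None:
            for k in self.cell.trainable_keys:
                yield k, self.cell.params, self.cell.grads

    def post_update(self):
        if self.cell is not None:
            self.cell.clamp()


class SpikingConv(_LayerBase):
    """Unpadded strided convolution feeding a CUBA-LIF population."""

    def __init__(self, spec: LayerSpec, rng: np.random.Generator,
                 surrogate: SurrogateSpec | None = None, mode: str = "hard",
                 init_gain: float = 2.5, dtype=np.float64):
        self.spec = spec
        kx, ky = spec.kernel
        fan_in = spec.c_in * kx * ky
        w = rng.normal(0.0, init_gain / math.sqrt(fan_in),
                       size=(spec.c_out, spec.c_in, ky, kx)).astype(dtype)
        self.params = {"weight": w}
        self.grads = {"weight": np.zeros_like(w)}
        self.cell = CubaLifCell(spec.neuron or CubaLifParams(),
                                surrogate, mode)
        self._cache = None

    def forward(self, x, train=False, rng=None):
        b, t = x.shape[:2]
        xt = x.reshape((b * t,) + x.shape[2:])
        kx, ky = self.spec.kernel
        sx, sy = self.spec.stride
        cols = _im2col(xt, ky, kx, sy, sx)
        n, oh, ow = cols.shape[:3]
        ckk = self.spec.c_in * ky * kx
        cols2 = cols.reshape(n * oh * ow, ckk)
        wmat = self.params["weight"].reshape(self.spec.c_out, -1)
        z = cols2 @ wmat.T
        z = np.ascontiguousarray(
            np.moveaxis(z.reshape(b, t, oh, ow, self.spec.c_out), 4, 2))
        self._cache = (cols2, xt.shape, (oh, ow))
        return self.cell.forward(z)

    def backward(self, gs):
        cols2, x_shape, (oh, ow) = self._cache
        gz = self.cell.backward(gs)
        b, t = gz.shape[:2]
        gz2 = np.moveaxis(gz, 2, 4).reshape(b * t * oh * ow, self.spec.c_out)
        gw = gz2.T @ cols2
        self.grads["weight"] += gw.reshape(self.params["weight"].shape)
        wmat = self.params["weight"].reshape(self.spec.c_out, -1)
        gcols2 = gz2 @ wmat
        kx, ky = self.spec.kernel
        gcols = gcols2.reshape(b * t, oh, ow, self.spec.c_in, ky, kx)
        gx = _col2im(gcols, x_shape, self.spec.stride[1], self.spec.stride[0])
        return gx.reshape((b, t) + x_shape[1:])


class SpikingPool(_LayerBase):
    """2x2 stride-2 max (OR on binary spikes), ceil mode via zero padding."""

    def __init__(self, spec: LayerSpec):
        self.spec = spec
        self.params = {}
        self.grads = {}
        self._cache = None

    def forward(self, x, train=False, rng=None):
        b, t, c, h, w = x.shape
        oh, ow = math.ceil(h / 2), math.ceil(w / 2)
        ph, pw = 2 * oh - h, 2 * ow - w
        if ph or pw:
            x = np.pad(x, ((0, 0),) * 3 + ((0, ph), (0, pw)))
        r = (x.reshape(b, t, c, oh, 2, ow, 2)
              .transpose(0, 1, 2, 3, 5, 4, 6)
              .reshape(b, t, c, oh, ow, 4))
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._cache = ((b, t, c, h, w), (oh, ow), idx)
        return y

    def backward(self, gy):
        (b, t, c, h, w), (oh, ow), idx = self._cache
        gr = np.zeros((b, t, c, oh, ow, 4), dtype=gy.dtype)
        np.put_along_axis(gr, idx[..., None], gy[..., None], axis=-1)
        gx = (gr.reshape(b, t, c, oh, ow, 2, 2)
                .transpose(0, 1, 2, 3, 5, 4, 6)
                .reshape(b, t, c, 2 * oh, 2 * ow))
        return gx[:, :, :, :h, :w]


class Flatten(_LayerBase):
    def __init__(self, spec: LayerSpec):
        self.spec = spec
        self.params = {}
        self.grads = {}
        self._shape = None

    def forward(self, x, train=False, rng=None):
        b, t = x.shape[:2]
        self._shape = x.shape
        return x.reshape(b, t, -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class SpikingDense(_LayerBase):
    """Fully connected CUBA-LIF stage.

    Optional features, applied in order: per-input integer synaptic
    delays (spike train of input i shifted later by ``delays[i]`` bins,
    zero-filled), unit dropout (a sampled input unit's whole train is
    zeroed for that sample, inverted scaling), weight normalization
    (w = g * v / ||v|| per output unit).
    """

    def __init__(self, spec: LayerSpec, rng: np.random.Generator,
                 surrogate: SurrogateSpec | None = None, mode: str = "hard",
                 init_gain: float = 2.5, max_delay: int | None = None,
                 dtype=np.float64):
        self.spec = spec
        fan_in = spec.c_in
        if spec.weight_norm:
            v = rng.normal(0.0, 1.0, size=(fan_in, spec.c_out)).astype(dtype)
            self.params = {"g": np.full(spec.c_out, init_gain, dtype=dtype),
                           "v": v}
        else:
            w = rng.normal(0.0, init_gain / math.sqrt(fan_in),
                           size=(fan_in, spec.c_out)).astype(dtype)
            self.params = {"weight": w}
        self.grads = {k: np.zeros_like(p) for k, p in self.params.items()}
        self.delays = np.zeros(fan_in, dtype=np.int64)
        self.max_delay = max_delay
        self.cell = CubaLifCell(spec.neuron or CubaLifParams(),
                                surrogate, mode)
        self._cache = None

    def set_delays(self, delays):
        """Install per-input delays (real values rounded to integer bins,
        clipped to [0, max_delay])."""
        d = np.rint(np.asarray(delays)).astype(np.int64)
        d = np.clip(d, 0, self.max_delay if self.max_delay is not None else None)
        if d.shape != (self.spec.c_in,):
            raise ValueError("one delay per input unit required")
        self.delays = d

    def _effective_weight(self):
        if self.spec.weight_norm:
            v = self.params["v"]
            norm = np.linalg.norm(v, axis=0)
            return self.params["g"] * v / norm, norm
        return self.params["weight"], None

    def _shift(self, x):
        if not self.spec.delay or not self.delays.any():
            return x
        out = np.zeros_like(x)
        for d in np.unique(self.delays):
            m = self.delays == d
            if d == 0:
                out[:, :, m] = x[:, :, m]
            elif d < x.shape[1]:
                out[:, d:, m] = x[:, :-d, m]
        return out

    def _unshift(self, g):
        if not self.spec.delay or not self.delays.any():
            return g
        out = np.zeros_like(g)
        for d in np.unique(self.delays):
            m = self.delays == d
            if d == 0:
                out[:, :, m] = g[:, :, m]
            elif d < g.shape[1]:
                out[:, :-d, m] = g[:, d:, m]
        return out

    def forward(self, x, train=False, rng=None):
        xd = self._shift(x)
        mask = None
        if train and self.spec.dropout > 0:
            if rng is None:
                raise ValueError("dropout in train mode needs an rng")
            p = self.spec.dropout
            mask = (rng.random((x.shape[0], x.shape[2])) >= p) / (1.0 - p)
            xd = xd * mask[:, None, :]
        w_eff, norm = self._effective_weight()
        z = xd @ w_eff
        self._cache = (xd, mask, w_eff, norm)
        return self.cell.forward(z)

    def backward(self, gs):
        xd, mask, w_eff, norm = self._cache
        gz = self.cell.backward(gs)
        gw_eff = np.einsum("btn,btm->nm", xd, gz, optimize=True)
        gxd = gz @ w_eff.T
        if self.spec.weight_norm:
            v = self.params["v"]
            w_dir = v / norm
            gg = (gw_eff * w_dir).sum(axis=0)
            self.grads["g"] += gg
            self.grads["v"] += (self.params["g"] / norm) * (
                gw_eff - w_dir * gg[None, :])
        else:
            self.grads["weight"] += gw_eff
        if mask is not None:
            gxd = gxd * mask[:, None, :]
        return self._unshift(gxd)


def make_layer(spec: LayerSpec, rng: np.random.Generator,
               surrogate: SurrogateSpec | None = None, mode: str = "hard",
               init_gain: float = 2.5, max_delay: int | None = None,
               dtype=np.float64):
    """Instantiate the runtime layer for a spec."""
    if spec.kind == "conv":
        return SpikingConv(spec, rng, surrogate, mode, init_gain, dtype)
    if spec.kind == "pool":
        return SpikingPool(spec)
    if spec.kind == "flatten":
        return Flatten(spec)
    if spec.kind in ("dense", "output"):
        return SpikingDense(spec, rng, surrogate, mode, init_gain, max_delay,
                            dtype)
    raise ValueError(spec.kind)
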