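"""Spiking-neuron dynamics and surrogate gradients.

The classifier uses the discrete-time current-based leaky
integrate-and-fire (CUBA-LIF) neuron.  Per step, with input current
``x[t]``:

    u[t] = (1 - alpha_u) * u[t-1] + x[t]          (synaptic current)
    v[t] = (1 - alpha_v) * v[t-1] + u[t] + b      (membrane potential)
    s[t] = H(v[t] - theta)                        (Heaviside spike)
    v[t] <- v[t] * (1 - s[t])                     (reset to zero)

Decoupling the current from the membrane gives two temporal filters
whose time constants (``tau = -dt / log(1 - alpha)``) set how the neuron
integrates event bursts versus isolated spikes.

The forward pass always thresholds exactly; training replaces only the
backward sensitivity of the Heaviside with a smooth kernel (surrogate
gradient).  A fully differentiable "soft" relaxation — spikes graded by
the kernel's antiderivative — is provided so backpropagation can be
verified against numerical differentiation.

A plain LIF cell with optional recurrence and a proportional reset term
is included as a reference model only; the classifier uses CUBA-LIF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CubaLifParams", "NeuronState", "LifParams", "SurrogateSpec",
    "surrogate_grad", "surrogate_soft",
    "cuba_lif_step", "lif_step",
    "decay_from_time_constants", "time_constants_from_decay",
    "CubaLifCell",
]


@dataclass
class CubaLifParams:
    """Per-layer CUBA-LIF parameters (shared across the layer's neurons).

    alpha_u, alpha_v: current/voltage decay factors in (0, 1]; alpha = 1
    means no memory (full decay each step).
    threshold: firing threshold > 0.
    bias: constant added to the membrane each step (voltage units).
    learnable: whether the training loop updates these values.
    """

    alpha_u: float = 0.25
    alpha_v: float = 0.03
    threshold: float = 1.25
    bias: float = 0.0
    learnable: bool = True
    learn_bias: bool = False

    def __post_init__(self):
        if not (0 < self.alpha_u <= 1 and 0 < self.alpha_v <= 1):
            raise ValueError("decay factors must lie in (0, 1]")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class NeuronState:
    """Per-neuron persistent state (zero at every segment start)."""

    u: np.ndarray
    v: np.ndarray

    @classmethod
    def zeros(cls, shape, dtype=np.float64):
        return cls(np.zeros(shape, dtype), np.zeros(shape, dtype))


@dataclass
class LifParams:
    """Reference LIF cell: U[t] = beta*U[t-1] + V_res*s[t-1] + I[t] - R*U[t-1].

    ``reset_mode`` 'subtract-proportional' applies the -R*U term,
    'none' drops it.  The proportional term acts on the previous-step
    membrane; the continuous-time normalization of this term is
    model-convention, so R is exposed as a plain scalar.
    """

    beta: float = 0.9
    threshold: float = 1.0
    reset_mode: str = "subtract-proportional"
    r: float = 0.1
    v_res: float = 0.0

    def __post_init__(self):
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")
        if self.reset_mode not in ("subtract-proportional", "none"):
            raise ValueError("reset mode must be 'subtract-proportional' or 'none'")


@dataclass(frozen=True)
class SurrogateSpec:
    """Backward-pass spike sensitivity.

    family 'exponential': grad = exp(-|a|/w) / (2w), the double-sided
    exponential kernel common in spike-layer error-reassignment
    training; 'fast-sigmoid': grad = 1 / (2w (1 + |a|/w)^2).  Both
    integrate to 1 over the real line, so the matching soft spike
    function is their antiderivative.  ``width`` sets the kernel scale;
    when no spec is given the cell defaults it to the firing threshold,
    wide enough that quiet neurons still receive usable gradient.
    """

    family: str = "exponential"
    width: float = 1.25

    def __post_init__(self):
        if self.family not in ("exponential", "fast-sigmoid"):
            raise ValueError("unknown surrogate family")
        if self.width <= 0:
            raise ValueError("surrogate width must be > 0")


def surrogate_grad(a: np.ndarray, spec: SurrogateSpec) -> np.ndarray:
    """Smooth stand-in for dH/da at membrane distance ``a = v - theta``."""
    w = spec.width
    if spec.family == "exponential":
        return np.exp(-np.abs(a) / w) / (2.0 * w)
    return 1.0 / (2.0 * w * (1.0 + np.abs(a) / w) ** 2)


def surrogate_soft(a: np.ndarray, spec: SurrogateSpec) -> np.ndarray:
    """Antiderivative of :func:`surrogate_grad`; a graded spike in [0, 1]."""
    w = spec.width
    if spec.family == "exponential":
        return np.where(a < 0, 0.5 * np.exp(np.minimum(a, 0) / w),
                        1.0 - 0.5 * np.exp(-np.maximum(a, 0) / w))
    x = a / w
    return 0.5 * (1.0 + x / (1.0 + np.abs(x)))


def cuba_lif_step(state: NeuronState, x: np.ndarray, params: CubaLifParams,
                  ) -> tuple[NeuronState, np.ndarray]:
    """One exact CUBA-LIF update; returns the new state and binary spikes."""
    x = np.asarray(x, dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("NaN in neuron input")
    u = (1.0 - params.alpha_u) * state.u + x
    v = (1.0 - params.alpha_v) * state.v + u + params.bias
    s = (v >= params.threshold).astype(np.float64)
    v = v * (1.0 - s)
    return NeuronState(u, v), s


def lif_step(state: NeuronState, i_in: np.ndarray, params: LifParams,
             s_prev: np.ndarray | None = None,
             ) -> tuple[NeuronState, np.ndarray]:
    """One reference-LIF update (state.u holds the membrane U)."""
    i_in = np.asarray(i_in, dtype=np.float64)
    if np.isnan(i_in).any():
        raise ValueError("NaN in neuron input")
    u = params.beta * state.u + i_in
    if s_prev is not None and params.v_res:
        u = u + params.v_res * s_prev
    if params.reset_mode == "subtract-proportional":
        u = u - params.r * state.u
    s = (u >= params.threshold).astype(np.float64)
    return NeuronState(u, state.v), s


def decay_from_time_constants(tau_syn: float, tau_mem: float, dt: float = 1.0,
                              ) -> tuple[float, float]:
    """Convert time constants to decay factors: alpha = 1 - exp(-dt/tau)."""
    if tau_syn <= 0 or tau_mem <= 0 or dt <= 0:
        raise ValueError("time constants and dt must be positive")
    return 1.0 - math.exp(-dt / tau_syn), 1.0 - math.exp(-dt / tau_mem)


def time_constants_from_decay(alpha_u: float, alpha_v: float, dt: float = 1.0,
                              ) -> tuple[float, float]:
    """Inverse of :func:`decay_from_time_constants`."""
    return -dt / math.log(1.0 - alpha_u), -dt / math.log(1.0 - alpha_v)


class CubaLifCell:
    """Sequence-level CUBA-LIF with backpropagation through time.

    Processes a whole injected-current sequence ``z`` of shape
    ``(B, T, ...)`` and caches the state trajectories needed for the
    backward pass.  ``mode='hard'`` is the real model: exact Heaviside
    forward, surrogate-kernel backward with the reset detached (the
    standard surrogate-gradient convention).  ``mode='soft'`` replaces
    the spike with the kernel's antiderivative and keeps every term of
    the reset differentiable, making the whole computation smooth — used
    to validate the backward pass against numerical gradients.
    """

    def __init__(self, params: CubaLifParams,
                 surrogate: SurrogateSpec | None = None, mode: str = "hard"):
        if mode not in ("hard", "soft"):
            raise ValueError("mode must be 'hard' or 'soft'")
        self.mode = mode
        self.learnable = params.learnable
        self.learn_bias = params.learnable and params.learn_bias
        if surrogate is None:
            surrogate = SurrogateSpec(width=params.threshold)
        self.surrogate = surrogate
        # 0-d arrays so the optimizer can update in place
        self.params = {
            "alpha_u": np.asarray(float(params.alpha_u)),
            "alpha_v": np.asarray(float(params.alpha_v)),
            "threshold": np.asarray(float(params.threshold)),
            "bias": np.asarray(float(params.bias)),
        }
        self.grads = {k: np.zeros(()) for k in self.params}
        self._cache = None

    @property
    def trainable_keys(self) -> tuple[str, ...]:
        if not self.learnable:
            return ()
        keys = ("alpha_u", "alpha_v", "threshold")
        return keys + ("bias",) if self.learn_bias else keys

    def forward(self, z: np.ndarray) -> np.ndarray:
        if np.isnan(z).any():
            raise ValueError("NaN in neuron input")
        au = float(self.params["alpha_u"])
        av = float(self.params["alpha_v"])
        th = float(self.params["threshold"])
        b = float(self.params["bias"])
        B, T = z.shape[:2]
        u_seq = np.empty_like(z)
        vpre_seq = np.empty_like(z)
        s_seq = np.empty_like(z)
        v_seq = np.empty_like(z)
        u = np.zeros(z.shape[:1] + z.shape[2:], dtype=z.dtype)
        v = np.zeros_like(u)
        for t in range(T):
            u = (1.0 - au) * u + z[:, t]
            vpre = (1.0 - av) * v + u + b
            a = vpre - th
            if self.mode == "hard":
                s = (a >= 0).astype(z.dtype)
            else:
                s = surrogate_soft(a, self.surrogate)
            v = vpre * (1.0 - s)
            u_seq[:, t] = u
            vpre_seq[:, t] = vpre
            s_seq[:, t] = s
            v_seq[:, t] = v
        self._cache = (z.shape, u_seq, vpre_seq, s_seq, v_seq)
        return s_seq

    def backward(self, gs: np.ndarray) -> np.ndarray:
        shape, u_seq, vpre_seq, s_seq, v_seq = self._cache
        au = float(self.params["alpha_u"])
        av = float(self.params["alpha_v"])
        th = float(self.params["threshold"])
        T = shape[1]
        gz = np.empty_like(gs)
        gu_future = np.zeros(shape[:1] + shape[2:], dtype=gs.dtype)
        gv_post = np.zeros_like(gu_future)
        g_th = 0.0
        g_b = 0.0
        g_au = 0.0
        g_av = 0.0
        for t in range(T - 1, -1, -1):
            vpre = vpre_seq[:, t]
            s = s_seq[:, t]
            sg = surrogate_grad(vpre - th, self.surrogate)
            ga = gs[:, t] * sg
            if self.mode == "soft":
                ga = ga - gv_post * vpre * sg
            gvpre = ga + gv_post * (1.0 - s)
            gu = gvpre + gu_future
            gz[:, t] = gu
            if self.learnable:
                g_th -= ga.sum()
                g_b += gvpre.sum()
                u_prev = u_seq[:, t - 1] if t > 0 else 0.0
                v_prev = v_seq[:, t - 1] if t > 0 else 0.0
                g_au -= (u_prev * gu).sum()
                g_av -= (v_prev * gvpre).sum()
            gu_future = (1.0 - au) * gu
            gv_post = (1.0 - av) * gvpre
        if self.learnable:
            self.grads["threshold"] += g_th
            self.grads["bias"] += g_b
            self.grads["alpha_u"] += g_au
            self.grads["alpha_v"] += g_av
        return gz

    def zero_grad(self):
        for k in self.grads:
            self.grads[k] = np.zeros(())

    def clamp(self):
        """Keep learnable parameters in their valid domains after an update."""
        self.params["alpha_u"] = np.clip(self.params["alpha_u"], 1e-4, 1.0)
        self.params["alpha_v"] = np.clip(self.params["alpha_v"], 1e-4, 1.0)
        self.params["threshold"] = np.clip(self.params["threshold"], 1e-3, None)
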