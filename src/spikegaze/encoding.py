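"""Binary spike-tensor encoding of event streams.

A stream segment is discretized into a binary tensor
``S[c, y, x, b] in {0, 1}`` with ``C = 2`` polarity channels and ``T``
temporal bins of width ``dt`` microseconds: an event at relative time
``t'`` lands in bin ``floor(t'/dt)`` and sets its cell to 1.  Repeated
hits saturate (assignment, not increment); events past the last bin are
dropped and tallied.  The per-cell spike rate is the mean over the time
axis.

Channel mapping is fixed: polarity -1 -> channel 0 (OFF),
polarity +1 -> channel 1 (ON).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .events import EventStream

__all__ = ["SpikeTensor", "encode", "spike_rate_map", "window_to_bins",
           "polarity_to_channel"]


def polarity_to_channel(p: np.ndarray) -> np.ndarray:
    """Map polarity {-1, +1} to channel {0 (OFF), 1 (ON)}."""
    return ((np.asarray(p) + 1) // 2).astype(np.int64)


@dataclass(frozen=True)
class SpikeTensor:
    """Binary (C=2, H, W, T) spike tensor.

    ``dt_us`` is the bin width, ``origin_us`` the absolute time of bin
    0's left edge, ``n_dropped`` the count of events past the last bin.
    """

    values: np.ndarray
    dt_us: int
    origin_us: int
    n_dropped: int = 0

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[0] != 2:
            raise ValueError("spike tensor must have shape (2, H, W, T)")
        if self.values.shape[3] < 1:
            raise ValueError("need at least one temporal bin")

    @property
    def n_bins(self) -> int:
        return self.values.shape[3]

    def to_sequence(self) -> np.ndarray:
        """Return the (T, C, H, W) float view used as network input."""
        return np.ascontiguousarray(
            np.moveaxis(self.values, 3, 0)).astype(np.float64)


def encode(stream: EventStream, dt_us: int, n_bins: int,
           origin_us: int | None = None) -> SpikeTensor:
    """Bin a stream into a binary spike tensor.

    ``origin_us`` defaults to the stream's ``t_start`` so every segment
    tensor starts at bin 0.  Events with negative relative time raise;
    events with bin index >= ``n_bins`` are dropped and tallied.
    """
    if dt_us <= 0:
        raise ValueError("bin width must be positive")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if origin_us is None:
        origin_us = stream.t_start
    values = np.zeros((2, stream.height, stream.width, n_bins), dtype=np.uint8)
    t_rel = stream.t - origin_us
    if t_rel.size and t_rel.min() < 0:
        raise ValueError("event before origin; pre-slice the stream")
    b = t_rel // dt_us
    keep = b < n_bins
    n_dropped = int((~keep).sum())
    values[polarity_to_channel(stream.p[keep]), stream.y[keep],
           stream.x[keep], b[keep]] = 1
    return SpikeTensor(values, int(dt_us), int(origin_us), n_dropped)


def spike_rate_map(tensor: SpikeTensor) -> np.ndarray:
    """Per-cell firing rate r[c, y, x] = (1/T) sum_t S[c, y, x, t]."""
    return tensor.values.mean(axis=3, dtype=np.float64)


def window_to_bins(window_ms: float, dt_us: int) -> int:
    """Number of bins covering a window: T = ceil(window * 1000 / dt).

    With the default 1 ms bin an N-ms accumulation window yields exactly
    N bins; non-divisible widths round up so the window is fully covered.
    """
    if window_ms <= 0 or dt_us <= 0:
        raise ValueError("window and bin width must be positive")
    return math.ceil(window_ms * 1000.0 / dt_us)
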