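"""The convolutional spiking classifier.

Architecture (geometry-parameterized; flatten width 11,264 at the
reference 360x260 sensor):

    Conv(2->8, 3x3, s2) -> Pool(2x2, s2) -> Conv(8->8, 3x3, s1)
    -> Pool(2x2, s2) -> Flatten -> Dense(flat->103, dropout 0.05,
    delays, weight-norm) -> Dense(103->117, dropout 0.05, delays,
    weight-norm) -> Output(117->2)

All weighted stages are CUBA-LIF populations; the two output neurons
spike, and the predicted class is the neuron with the higher mean firing
rate over the simulation window (ties -> lower index, i.e. fixation).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .layers import (LayerSpec, count_parameters, make_layer,
                     propagate_shape)
from .neurons import CubaLifParams, SurrogateSpec

__all__ = ["NetworkSpec", "ForwardTrace", "build_spiking_convnet",
           "SpikingConvNet", "decode_rate"]


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer specs plus input geometry (W, H) and bin count T."""

    layers: tuple[LayerSpec, ...]
    width: int
    height: int
    n_bins: int

    def shapes(self):
        """Per-layer output shapes starting from (W, H, 2)."""
        shape = (self.width, self.height, 2)
        out = []
        for layer in self.layers:
            shape = propagate_shape(layer, shape)
            out.append(shape)
        return out

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.layers)

    # -- human-readable serialization -------------------------------------
    def to_dict(self) -> dict:
        layers = []
        for ls in self.layers:
            d = asdict(ls)
            d["kernel"] = list(d["kernel"])
            d["stride"] = list(d["stride"])
            layers.append(d)
        return {"width": self.width, "height": self.height,
                "n_bins": self.n_bins, "layers": layers}

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        layers = []
        for d in data["layers"]:
            d = dict(d)
            neuron = d.pop("neuron", None)
            layers.append(LayerSpec(
                neuron=CubaLifParams(**neuron) if neuron else None,
                kernel=tuple(d.pop("kernel")), stride=tuple(d.pop("stride")),
                **d))
        return cls(tuple(layers), data["width"], data["height"],
                   data["n_bins"])

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class ForwardTrace:
    """Per-accounting-node spike counts (and optional sequences).

    ``counts[k]`` is a (B,) array of total spikes per sample at node k;
    accounting nodes are the outputs of every non-flatten layer.
    """

    counts: list[np.ndarray] = field(default_factory=list)
    sequences: list[np.ndarray] | None = None


def build_spiking_convnet(width: int = 360, height: int = 260,
                          n_bins: int = 33,
                          neuron: CubaLifParams | None = None) -> NetworkSpec:
    """Build the reference architecture at a given sensor geometry."""
    if neuron is None:
        neuron = CubaLifParams()
    conv1 = LayerSpec("conv", 2, 8, (3, 3), (2, 2), neuron=neuron)
    pool = LayerSpec("pool")
    conv2 = LayerSpec("conv", 8, 8, (3, 3), (1, 1), neuron=neuron)
    shape = propagate_shape(conv1, (width, height, 2))
    shape = propagate_shape(pool, shape)
    shape = propagate_shape(conv2, shape)
    shape = propagate_shape(pool, shape)
    flat = shape[0] * shape[1] * shape[2]
    layers = (
        conv1, pool, conv2, pool,
        LayerSpec("flatten"),
        LayerSpec("dense", flat, 103, neuron=neuron, delay=True,
                  weight_norm=True, dropout=0.05),
        LayerSpec("dense", 103, 117, neuron=neuron, delay=True,
                  weight_norm=True, dropout=0.05),
        LayerSpec("output", 117, 2, neuron=neuron),
    )
    return NetworkSpec(layers, width, height, n_bins)


def decode_rate(output_seq: np.ndarray) -> int:
    """Class = argmax of mean output firing rate; ties -> lower index."""
    if output_seq.ndim != 2 or output_seq.shape[0] < 1:
        raise ValueError("expected an (T, n_classes) output sequence")
    rates = output_seq.mean(axis=0)
    return int(np.argmax(rates))


class SpikingConvNet:
    """Runtime network: layer objects with weights and neuron cells."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 surrogate: SurrogateSpec | None = None, mode: str = "hard",
                 init_gain: float = 2.5, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        max_delay = min(spec.n_bins - 1, 62)
        self.layers = [make_layer(ls, rng, surrogate, mode, init_gain,
                                  max_delay=max_delay, dtype=dtype)
                       for ls in spec.layers]

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                record_sequences: bool = False,
                ) -> tuple[np.ndarray, ForwardTrace]:
        """Run a (B, T, 2, H, W) spike batch; returns (B, T, 2) output
        spikes and the per-node activity trace."""
        expected = (self.spec.n_bins, 2, self.spec.height, self.spec.width)
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} != {expected}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        trace = ForwardTrace(sequences=[] if record_sequences else None)
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
            if layer.spec.kind != "flatten":
                axes = tuple(range(1, out.ndim))
                trace.counts.append(out.sum(axis=axes))
                if record_sequences:
                    trace.sequences.append(out)
        return out, trace

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        g = g_out
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (key, param-dict, grad-dict) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name, params, grads in layer.all_params():
                yield f"layer{i}.{name}", params, grads

    def post_update(self):
        for layer in self.layers:
            layer.post_update()

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for key, params, _ in self.parameters():
            name = key.split(".", 1)[1]
            state[key] = np.array(params[name], copy=True)
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "delays"):
                state[f"layer{i}.delays"] = layer.delays.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for key, params, _ in self.parameters():
            name = key.split(".", 1)[1]
            params[name] = np.array(state[key], copy=True)
        for i, layer in enumerate(self.layers):
            dkey = f"layer{i}.delays"
            if hasattr(layer, "delays") and dkey in state:
                layer.delays = np.asarray(state[dkey], dtype=np.int64)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data))
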