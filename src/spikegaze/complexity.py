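"""SNN-vs-ANN computational-complexity accounting.

An equivalent ANN evaluates every unit of every stage each frame, so its
per-stage cost is counted in multiply-accumulates (MACs); the SNN only
pays an accumulate (AC, "synop") when a spike actually crosses a
synapse.  Accounting runs over seven nodes — the outputs of conv1,
pool1, conv2, pool2, dense1, dense2 and the readout — under a uniform
fan-out convention (border effects ignored):

    fan_out(conv)  = kx * ky * c_out / (sx * sy)
    fan_out(pool)  = 1
    fan_out(dense) = output width

    MACs(node k)   = units(node k-1) * fan_out(stage k),  k = 1..6
    synops(node k) = mean_events(node k-1) * fan_out(stage k)

Node 0 (the first conv output) has no upstream accounting node; its MAC
cell mirrors its own unit count by printed convention and is excluded
from the MAC total, while the activation total includes all seven nodes.
Sparsity ratios divide dense totals by event-driven totals, and the
energy model is

    E(F) = T * (fr * E_AC * O_AC + E_MAC * O_MAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .layers import LayerSpec
from .network import ForwardTrace, NetworkSpec

__all__ = ["ComplexityReport", "EnergyParams", "fan_out", "count_ann_macs",
           "count_snn_activity", "sparsity_ratios", "energy_estimate",
           "profile_network"]


@dataclass(frozen=True)
class EnergyParams:
    """Per-operation energies (J) and run parameters for the energy model.

    Defaults are the common 45 nm process figures (0.9 pJ per AC,
    4.6 pJ per MAC); they are configuration values, not measurements.
    """

    e_ac: float = 0.9e-12
    e_mac: float = 4.6e-12
    n_bins: int = 33
    firing_rate: float = 1.0

    def __post_init__(self):
        if self.e_ac <= 0 or self.e_mac <= 0:
            raise ValueError("energies must be positive")
        if not 0.0 <= self.firing_rate <= 1.0:
            raise ValueError("firing rate must lie in [0, 1]")


@dataclass
class ComplexityReport:
    """Per-node accounting mirroring the reference table's columns."""

    shapes: list
    activations: list[int]
    macs: list[int]
    events: list[float] | None = None
    synops: list[float | None] | None = None

    @property
    def total_activations(self) -> int:
        return int(sum(self.activations))

    @property
    def total_macs(self) -> int:
        # node 0's printed MAC cell is excluded from the total
        return int(sum(self.macs[1:]))

    @property
    def total_events(self) -> float:
        return float(sum(self.events)) if self.events else 0.0

    @property
    def total_synops(self) -> float:
        if not self.synops:
            return 0.0
        return float(sum(s for s in self.synops if s is not None))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.activations)
        data = {
            "shape": [str(s) for s in self.shapes],
            "activations": self.activations,
            "macs": self.macs,
        }
        if self.events is not None:
            data["events"] = np.round(self.events, 2)
            data["synops"] = [np.nan if s is None else round(s, 2)
                              for s in self.synops]
        frame = pd.DataFrame(data, index=[f"node-{k}" for k in range(n)])
        total = {"shape": "", "activations": self.total_activations,
                 "macs": self.total_macs}
        if self.events is not None:
            total["events"] = round(self.total_events, 2)
            total["synops"] = round(self.total_synops, 2)
        frame.loc["total"] = total
        return frame


def _accounting_stages(spec: NetworkSpec) -> list[tuple[LayerSpec, object]]:
    """(layer spec, output shape) for every non-flatten layer."""
    stages = []
    for layer, shape in zip(spec.layers, spec.shapes()):
        if layer.kind != "flatten":
            stages.append((layer, shape))
    return stages


def _units(shape) -> int:
    if isinstance(shape, int):
        return shape
    return int(np.prod(shape))


def fan_out(stage: LayerSpec) -> float:
    """Downstream operations one source unit/spike triggers (uniform
    convention, border effects ignored)."""
    if stage.kind == "conv":
        kx, ky = stage.kernel
        sx, sy = stage.stride
        return kx * ky * stage.c_out / (sx * sy)
    if stage.kind == "pool":
        return 1.0
    if stage.kind in ("dense", "output"):
        return float(stage.c_out)
    return 1.0  # flatten is transparent


def count_ann_macs(spec: NetworkSpec) -> ComplexityReport:
    """Equivalent-ANN MACs per accounting node, plus unit counts."""
    stages = _accounting_stages(spec)
    shapes = [shape for _, shape in stages]
    units = [_units(s) for s in shapes]
    macs = [units[0]]  # printed convention for node 0
    for k in range(1, len(stages)):
        macs.append(int(round(units[k - 1] * fan_out(stages[k][0]))))
    return ComplexityReport(shapes, units, macs)


def count_snn_activity(spec: NetworkSpec,
                       traces: Sequence[ForwardTrace]) -> ComplexityReport:
    """Mean events per sample at each node and the implied synops."""
    if not traces:
        raise ValueError("need at least one forward trace")
    stages = _accounting_stages(spec)
    n_nodes = len(stages)
    counts = [np.concatenate([np.atleast_1d(tr.counts[k]) for tr in traces])
              for k in range(n_nodes)]
    events = [float(np.mean(c)) for c in counts]
    report = count_ann_macs(spec)
    synops: list[float | None] = [None]
    for k in range(1, n_nodes):
        synops.append(events[k - 1] * fan_out(stages[k][0]))
    report.events = events
    report.synops = synops
    return report


def sparsity_ratios(report: ComplexityReport) -> tuple[float, float]:
    """(event sparsity, synapse sparsity), rounded to 2 decimals.

    Event sparsity = total activations / total events; synapse sparsity
    = total MACs / total synops.
    """
    if not report.total_events or not report.total_synops:
        raise ValueError("sparsity undefined for a silent network")
    return (round(report.total_activations / report.total_events, 2),
            round(report.total_macs / report.total_synops, 2))


def energy_estimate(o_ac: float, o_mac: float, params: EnergyParams) -> float:
    """E(F) = T * (fr * E_AC * O_AC + E_MAC * O_MAC), in joules."""
    if o_ac < 0 or o_mac < 0:
        raise ValueError("operation counts must be non-negative")
    return params.n_bins * (params.firing_rate * params.e_ac * o_ac
                            + params.e_mac * o_mac)


def profile_network(spec: NetworkSpec,
                    traces: Sequence[ForwardTrace] | None = None,
                    ) -> ComplexityReport:
    """Full report: architecture arithmetic, plus measured activity when
    traces are supplied."""
    if traces:
        return count_snn_activity(spec, traces)
    return count_ann_macs(spec)
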