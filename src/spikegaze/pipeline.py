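"""End-to-end pipeline: simulate -> encode -> train -> evaluate -> profile.

Every stage is a plain function over the library API; the CLI wraps
these.  All randomness derives deterministically from the single global
seed in :class:`RunConfig`, so a run is reproducible from its manifest
alone (the manifest records the full config, its hash, package versions
and the resulting metrics).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .complexity import EnergyParams, energy_estimate, profile_network, sparsity_ratios
from .events import (LabeledSegment, read_events, split_by_user, write_events)
from .network import SpikingConvNet, build_spiking_convnet
from .simulate import (EmulatorParams, default_kinematics, default_scene,
                       generate_dataset)
from .training import (TrainConfig, effective_fps, encode_segments, evaluate,
                       temporal_sweep, train)

logger = logging.getLogger("spikegaze")

__all__ = ["SimConfig", "RunConfig", "run_pipeline", "simulate_to_dir",
           "load_dataset_dir", "load_run_config"]


@dataclass
class SimConfig:
    """Synthetic-dataset stage configuration."""

    width: int = 64
    height: int = 64
    n_per_class: int = 20
    n_users: int = 10
    theta: float = 0.2
    noise_rate_hz: float = 0.1
    render_rate_hz: float = 2000.0


@dataclass
class RunConfig:
    """Full pipeline configuration with one global seed."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    train_users: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    test_users: tuple[int, ...] = (8, 9, 10)
    sweep_windows_ms: tuple[float, ...] = ()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = SimConfig(**data.pop("sim", {}))
        training = TrainConfig(**data.pop("training", {}))
        cfg = cls(sim=sim, training=training, **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in data.items()})
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f) or {})


def _derived_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    sim_s, train_s = (int(s.generate_state(1)[0] % (2 ** 31))
                      for s in ss.spawn(2))
    return {"sim": sim_s, "train": train_s}


def simulate_to_dir(cfg: RunConfig, outdir: Path) -> list[LabeledSegment]:
    """Generate the synthetic dataset and write it as CSV event files
    plus an index; returns the in-memory segments."""
    outdir = Path(outdir)
    (outdir / "segments").mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(cfg.seed)
    scene = default_scene(cfg.sim.width, cfg.sim.height)
    kin = default_kinematics(cfg.sim.width, cfg.sim.height)
    emu = EmulatorParams(theta=cfg.sim.theta,
                         render_rate_hz=cfg.sim.render_rate_hz,
                         noise_rate_hz=cfg.sim.noise_rate_hz)
    segments = generate_dataset(scene, kin, emu, cfg.sim.n_per_class,
                                seeds["sim"], n_users=cfg.sim.n_users)
    index = []
    for i, seg in enumerate(segments):
        name = f"segments/seg_{i:05d}.csv"
        write_events(outdir / name, seg.stream)
        index.append({"file": name, "label": seg.label,
                      "user_id": seg.user_id})
    pd.DataFrame(index).to_csv(outdir / "index.csv", index=False)
    return segments


def load_dataset_dir(datadir: Path) -> list[LabeledSegment]:
    datadir = Path(datadir)
    index = pd.read_csv(datadir / "index.csv")
    return [LabeledSegment(read_events(datadir / row.file), row.label,
                           int(row.user_id))
            for row in index.itertuples()]


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Returns the manifest dict (also written to ``manifest.json``).
    Stage failures abort with a stage-named diagnostic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(cfg.seed)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash,
                "seeds": seeds,
                "versions": {"spikegaze": __version__,
                             "numpy": np.__version__},
                "stages": {}}
    timings = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    try:
        stage("simulate")
        segments = simulate_to_dir(cfg, outdir / "dataset")
        stage("split")
        train_segs, test_segs = split_by_user(segments, cfg.train_users,
                                              cfg.test_users)
        stage("train")
        tc = dataclasses.replace(cfg.training, seed=seeds["train"])
        spec = build_spiking_convnet(cfg.sim.width, cfg.sim.height,
                                     n_bins=int(round(
                                         tc.window_ms * 1000 / tc.dt_us)))
        net = SpikingConvNet(spec, seed=seeds["train"],
                             init_gain=tc.init_gain)
        net, history = train(net, train_segs, tc)
        net.save(outdir / "checkpoint.npz")
        pd.DataFrame(history).to_csv(outdir / "history.csv", index=False)
        stage("evaluate")
        metrics = evaluate(net, test_segs, tc.window_ms, tc.dt_us)
        stage("profile")
        tensors, _ = encode_segments(test_segs, tc.window_ms, tc.dt_us)
        traces = []
        for t in tensors:
            _, tr = net.forward(t.to_sequence()[None])
            traces.append(tr)
        report = profile_network(spec, traces)
        report.to_frame().to_csv(outdir / "complexity.csv")
        ev_sp, syn_sp = sparsity_ratios(report)
        if cfg.sweep_windows_ms:
            stage("sweep")
            sweep = temporal_sweep(cfg.sweep_windows_ms, train_segs,
                                   test_segs, tc)
            pd.DataFrame([
                {"window_ms": r.window_ms, "fps": r.fps, "failed": r.failed,
                 "accuracy": r.metrics.accuracy if r.metrics else None,
                 "f1": r.metrics.f1 if r.metrics else None,
                 "final_loss": r.final_loss}
                for r in sweep.rows]).to_csv(outdir / "sweep.csv", index=False)
    except Exception as exc:
        failed = max(timings, key=timings.get) if timings else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    manifest["metrics"] = {
        "accuracy": metrics.accuracy, "precision": metrics.precision,
        "recall": metrics.recall, "f1": metrics.f1,
        "final_train_loss": history[-1]["train_loss"],
        "effective_fps": effective_fps(cfg.training.window_ms),
        "event_sparsity": ev_sp, "synapse_sparsity": syn_sp,
        "energy_j": energy_estimate(report.total_synops, 0.0,
                                    EnergyParams(n_bins=spec.n_bins)),
    }
    manifest["n_train"] = len(train_segs)
    manifest["n_test"] = len(test_segs)
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=list)
    return manifest
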