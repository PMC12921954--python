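"""Training and evaluation of the spiking classifier.

Training minimizes the spike-rate loss: output neurons are pushed toward
a target mean firing rate ``r_true`` for the labelled class and
``r_false`` for the other,

    r_hat = r_true * onehot(l) + r_false * (1 - onehot(l))
    L = 1/2 || mean_t s[t] - r_hat ||^2        (mean over the batch)

so no target spike trains are needed — only rates.  Gradients flow
through the exact spiking forward pass via surrogate-gradient BPTT and
are applied with Adam.  Evaluation decodes the class by output rate and
reports accuracy / precision / recall / F1 with the saccade as the
positive class.  The temporal sweep re-runs encode-train-evaluate over a
list of accumulation windows; each window's effective frame rate is
1000 / window (rounded to 2 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import encode, window_to_bins
from .events import LabeledSegment
from .network import NetworkSpec, SpikingConvNet, build_spiking_convnet, decode_rate

__all__ = ["TrainConfig", "Metrics", "SweepRow", "SweepResult", "Adam",
           "spike_rate_loss", "encode_segments", "train", "evaluate",
           "temporal_sweep"]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the reference setup: 100 epochs, batch size 8,
    learning rate 0.01, Adam.  ``r_true``/``r_false`` are the target
    output rates of the correct/incorrect class neuron (configurable;
    0.2 / 0.03 by default).  ``window_ms`` and ``dt_us`` control the
    encoder (1 ms bins, so T = window in ms).
    """

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 0.01
    r_true: float = 0.2
    r_false: float = 0.03
    seed: int = 0
    window_ms: float = 33.0
    dt_us: int = 1000
    val_fraction: float = 0.1
    select_best: bool = True
    init_gain: float = 2.5

    def __post_init__(self):
        if not (0.0 <= self.r_false < self.r_true <= 1.0):
            raise ValueError("need 0 <= r_false < r_true <= 1")


@dataclass(frozen=True)
class Metrics:
    """Binary classification metrics; saccade (class 1) is positive.

    Undefined precision/recall (zero denominator) is reported as 0 with
    ``zero_division`` set.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    zero_division: bool = False

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "Metrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        n = tp + fp + tn + fn
        zero_div = (tp + fp == 0) or (tp + fn == 0)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return cls((tp + tn) / n if n else 0.0, precision, recall, f1,
                   tp, fp, tn, fn, zero_div)


@dataclass(frozen=True)
class SweepRow:
    window_ms: float
    fps: float
    metrics: Metrics | None
    final_loss: float | None
    failed: bool = False
    error: str = ""


@dataclass(frozen=True)
class SweepResult:
    rows: tuple[SweepRow, ...]


class Adam:
    """Adaptive-moment optimizer over the network's parameter dicts."""

    def __init__(self, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, parameters):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, pdict, gdict in parameters:
            name = key.split(".", 1)[1]
            g = np.asarray(gdict[name], dtype=np.float64)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            pdict[name] = pdict[name] - self.lr * mhat / (np.sqrt(vhat)
                                                          + self.eps)


def _target_rates(labels, n_classes, r_true, r_false):
    labels = np.asarray(labels)
    target = np.full((labels.size, n_classes), r_false, dtype=np.float64)
    target[np.arange(labels.size), labels] = r_true
    return target


def spike_rate_loss(output_seq: np.ndarray, label, r_true: float,
                    r_false: float) -> float:
    """Spike-rate loss of one sample ((T, C) + int) or a batch
    ((B, T, C) + array); batches are averaged."""
    if not (0.0 <= r_false <= 1.0 and 0.0 <= r_true <= 1.0):
        raise ValueError("target rates must lie in [0, 1]")
    out = np.asarray(output_seq, dtype=np.float64)
    squeeze = out.ndim == 2
    if squeeze:
        out = out[None]
        label = [label]
    rates = out.mean(axis=1)
    target = _target_rates(label, out.shape[2], r_true, r_false)
    return float(0.5 * ((rates - target) ** 2).sum(axis=1).mean())


def _loss_and_grad(output_seq, labels, r_true, r_false):
    rates = output_seq.mean(axis=1)
    target = _target_rates(labels, output_seq.shape[2], r_true, r_false)
    diff = rates - target
    loss = float(0.5 * (diff ** 2).sum(axis=1).mean())
    b, t = output_seq.shape[:2]
    gs = np.broadcast_to((diff / (b * t))[:, None, :], output_seq.shape)
    return loss, np.ascontiguousarray(gs)


def encode_segments(segments: Sequence[LabeledSegment], window_ms: float,
                    dt_us: int):
    """Encode segments to spike tensors; returns (tensor list, labels)."""
    n_bins = window_to_bins(window_ms, dt_us)
    tensors = [encode(seg.stream, dt_us, n_bins) for seg in segments]
    labels = np.array([seg.label_index for seg in segments], dtype=np.int64)
    return tensors, labels


def _stack(tensors, idx):
    return np.stack([tensors[i].to_sequence() for i in idx])


def train(net: SpikingConvNet, segments: Sequence[LabeledSegment],
          config: TrainConfig):
    """Surrogate-gradient training; returns (net, history).

    ``history`` is a list of per-epoch dicts with the mean train loss
    and, when ``val_fraction > 0``, validation accuracy and loss on a
    seeded within-train split.  With ``select_best`` the weights of the
    epoch with the highest validation accuracy (remaining ties broken
    by lower validation loss, then recency) are restored at the end;
    spiking training trajectories oscillate, so selecting by validation
    is considerably more stable than keeping the final epoch.  NaN loss
    aborts with a diagnostic.
    """
    if not segments:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(config.seed)
    shuffle_rng, drop_rng, split_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))
    tensors, labels = encode_segments(segments, config.window_ms,
                                      config.dt_us)
    n = len(tensors)
    idx_all = np.arange(n)
    val_idx = np.array([], dtype=np.int64)
    if config.val_fraction > 0 and n >= 10:
        n_val = max(1, int(round(config.val_fraction * n)))
        val_idx = split_rng.choice(n, size=n_val, replace=False)
        idx_all = np.setdiff1d(idx_all, val_idx)

    optimizer = Adam(lr=config.learning_rate)
    history = []
    best = ((-1.0, 0.0), None)
    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(idx_all)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            x = _stack(tensors, batch)
            out, _ = net.forward(x, train=True, rng=drop_rng)
            loss, gs = _loss_and_grad(out, labels[batch], config.r_true,
                                      config.r_false)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch}")
            net.zero_grad()
            net.backward(gs)
            optimizer.step(net.parameters())
            net.post_update()
            losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_idx.size:
            vm, val_loss = _evaluate_tensors(
                net, [tensors[i] for i in val_idx], labels[val_idx],
                rate_targets=(config.r_true, config.r_false))
            record["val_accuracy"] = vm.accuracy
            record["val_loss"] = val_loss
            # accuracy first; val loss breaks ties on small val sets
            if config.select_best and (vm.accuracy, -val_loss) >= best[0]:
                best = ((vm.accuracy, -val_loss), net.state_dict())
        history.append(record)
    if best[1] is not None:
        net.load_state_dict(best[1])
    return net, history


def _evaluate_tensors(net, tensors, labels, batch_size=16,
                      rate_targets=None):
    preds = []
    losses = []
    for start in range(0, len(tensors), batch_size):
        sel = slice(start, start + batch_size)
        x = np.stack([t.to_sequence() for t in tensors[sel]])
        out, _ = net.forward(x, train=False)
        preds.extend(decode_rate(out[i]) for i in range(out.shape[0]))
        if rate_targets is not None:
            losses.append(spike_rate_loss(out.astype(np.float64),
                                          labels[sel], *rate_targets))
    metrics = Metrics.from_predictions(labels, preds)
    if rate_targets is None:
        return metrics
    return metrics, float(np.mean(losses))


def evaluate(net: SpikingConvNet, segments: Sequence[LabeledSegment],
             window_ms: float = 33.0, dt_us: int = 1000) -> Metrics:
    """Rate-decode every segment in eval mode and score it."""
    if not segments:
        raise ValueError("empty test set")
    tensors, labels = encode_segments(segments, window_ms, dt_us)
    return _evaluate_tensors(net, tensors, labels)


def effective_fps(window_ms: float) -> float:
    """Effective frame rate of an accumulation window: 1000/window,
    rounded to 2 decimals."""
    return round(1000.0 / window_ms, 2)


def temporal_sweep(windows_ms: Sequence[float],
                   train_segments: Sequence[LabeledSegment],
                   test_segments: Sequence[LabeledSegment],
                   config: TrainConfig) -> SweepResult:
    """Re-encode, train and evaluate at each accumulation window.

    A failing window is recorded as a flagged row and the sweep
    continues.  Geometry is taken from the first training segment.
    """
    if any(w <= 0 for w in windows_ms):
        raise ValueError("windows must be positive")
    geom = train_segments[0].stream
    rows = []
    for w in windows_ms:
        try:
            n_bins = window_to_bins(w, config.dt_us)
            spec = build_spiking_convnet(geom.width, geom.height, n_bins)
            net = SpikingConvNet(spec, seed=config.seed,
                                 init_gain=config.init_gain)
            cfg = TrainConfig(**{**config.__dict__, "window_ms": w})
            _, history = train(net, train_segments, cfg)
            metrics = evaluate(net, test_segments, w, config.dt_us)
            rows.append(SweepRow(w, effective_fps(w), metrics,
                                 history[-1]["train_loss"]))
        except Exception as exc:  # noqa: BLE001 - row-level isolation
            rows.append(SweepRow(w, effective_fps(w), None, None,
                                 failed=True, error=str(exc)))
    return SweepResult(tuple(rows))
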