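"""Spike-rate loss, metrics, gradient correctness, training loop, sweep."""

import numpy as np
import pytest

import spikegaze as sg
from spikegaze.network import SpikingConvNet
from spikegaze.training import (Metrics, TrainConfig, _loss_and_grad,
                                effective_fps, evaluate, spike_rate_loss,
                                temporal_sweep, train)


class TestSpikeRateLoss:
    def test_zero_at_exact_targets(self):
        seq = np.zeros((10, 2))
        seq[:2, 0] = 1  # rate 0.2 on the true neuron
        assert spike_rate_loss(seq, 0, 0.2, 0.0) == pytest.approx(0.0)

    def test_silent_output_closed_form(self):
        # L = 1/2 * (0.5 - 0)^2 = 0.125 for a silent pair, label 0
        assert spike_rate_loss(np.zeros((8, 2)), 0, 0.5, 0.0) \
            == pytest.approx(0.125)

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(20):
            seq = (rng.random((4, 9, 2)) < 0.5).astype(float)
            labels = rng.integers(0, 2, 4)
            expected = np.mean([
                0.5 * sum((seq[b, :, c].mean()
                           - (0.2 if labels[b] == c else 0.03)) ** 2
                          for c in range(2))
                for b in range(4)])
            assert spike_rate_loss(seq, labels, 0.2, 0.03) \
                == pytest.approx(expected)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            spike_rate_loss(np.zeros((4, 2)), 0, 1.5, 0.0)

    def test_loss_grad_is_analytic_derivative(self, rng):
        seq = (rng.random((3, 6, 2)) < 0.5).astype(np.float64)
        labels = np.array([0, 1, 0])
        loss, gs = _loss_and_grad(seq, labels, 0.2, 0.03)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 3, 1), (2, 5, 0)]:
            pert = seq.copy()
            pert[idx] += eps
            lp = spike_rate_loss(pert, labels, 0.2, 0.03)
            assert gs[idx] == pytest.approx((lp - loss) / eps, rel=1e-3)


class TestMetrics:
    def test_perfect_predictions(self):
        m = Metrics.from_predictions([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_all_one_class_balanced(self):
        m = Metrics.from_predictions([0, 0, 1, 1], [0, 0, 0, 0])
        assert m.accuracy == 0.5 and m.zero_division

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        m = Metrics.from_predictions(y_true, y_pred)
        assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert m.precision == pytest.approx(
            precision_score(y_true, y_pred, zero_division=0))
        assert m.recall == pytest.approx(
            recall_score(y_true, y_pred, zero_division=0))
        assert m.f1 == pytest.approx(
            f1_score(y_true, y_pred, zero_division=0))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        """On the fully differentiable (soft-spike) relaxation, BPTT
        gradients agree with central finite differences to 1e-3."""
        spec = sg.build_spiking_convnet(16, 16, 6)
        net = SpikingConvNet(spec, seed=5, mode="soft", dtype=np.float64,
                             init_gain=1.5)
        x = (rng.random((2, 6, 2, 16, 16)) < 0.15).astype(np.float64)
        labels = np.array([0, 1])

        def loss_of():
            out, _ = net.forward(x)
            return spike_rate_loss(out, labels, 0.2, 0.03)

        out, _ = net.forward(x)
        _, gs = _loss_and_grad(out, labels, 0.2, 0.03)
        net.zero_grad()
        net.backward(gs)

        eps = 1e-6
        checked = 0
        for key, pdict, gdict in net.parameters():
            name = key.split(".", 1)[1]
            p = pdict[name]
            flat = np.atleast_1d(p).ravel()
            i = rng.integers(0, flat.size)
            orig = flat[i]
            analytic = np.atleast_1d(gdict[name]).ravel()[i]
            flat[i] = orig + eps
            pdict[name] = flat.reshape(np.shape(p)) if np.ndim(p) else \
                np.asarray(flat[0])
            lp = loss_of()
            flat[i] = orig - eps
            pdict[name] = flat.reshape(np.shape(p)) if np.ndim(p) else \
                np.asarray(flat[0])
            lm = loss_of()
            flat[i] = orig
            pdict[name] = flat.reshape(np.shape(p)) if np.ndim(p) else \
                np.asarray(flat[0])
            numeric = (lp - lm) / (2 * eps)
            if abs(numeric) > 1e-10 or abs(analytic) > 1e-10:
                assert analytic == pytest.approx(numeric, rel=1e-3,
                                                 abs=1e-9), key
                checked += 1
        assert checked >= 5


def _mini_world(rng, n=12, width=24, t_end=20_000):
    """Synthetic separable segments: saccade-like dense vs sparse."""
    segs = []
    for i in range(n):
        label = "saccade" if i % 2 else "fixation"
        m = 400 if label == "saccade" else 15
        s = sg.EventStream.from_arrays(
            rng.integers(0, width, m), rng.integers(0, width, m),
            np.sort(rng.integers(0, t_end, m)), rng.choice((-1, 1), m),
            width, width, 0, t_end)
        segs.append(sg.events.LabeledSegment(s, label, user_id=i % 4 + 1))
    return segs


class TestTrainLoop:
    def test_one_epoch_two_samples(self, rng):
        segs = _mini_world(rng, n=2)
        net = SpikingConvNet(sg.build_spiking_convnet(24, 24, 10), seed=0)
        cfg = TrainConfig(epochs=1, window_ms=10, seed=1)
        _, history = train(net, segs, cfg)
        assert len(history) == 1
        assert np.isfinite(history[0]["train_loss"])

    def test_seed_determinism(self, rng):
        segs = _mini_world(rng)
        losses = []
        for _ in range(2):
            net = SpikingConvNet(sg.build_spiking_convnet(24, 24, 10),
                                 seed=2)
            _, h = train(net, segs, TrainConfig(epochs=2, window_ms=10,
                                                seed=7))
            losses.append(h[-1]["train_loss"])
        assert losses[0] == losses[1]

    def test_loss_decreases_on_separable_set(self, rng):
        segs = _mini_world(rng, n=24)
        net = SpikingConvNet(sg.build_spiking_convnet(24, 24, 10), seed=4)
        _, h = train(net, segs, TrainConfig(epochs=8, window_ms=10, seed=3))
        assert h[-1]["train_loss"] < h[0]["train_loss"]

    def test_empty_set_rejected(self):
        net = SpikingConvNet(sg.build_spiking_convnet(24, 24, 10))
        with pytest.raises(ValueError):
            train(net, [], TrainConfig())


class TestEvaluateAndSweep:
    def test_metrics_consistent_with_confusion_counts(self, rng):
        segs = _mini_world(rng, n=16)
        net = SpikingConvNet(sg.build_spiking_convnet(24, 24, 10), seed=0)
        m = evaluate(net, segs, window_ms=10, dt_us=1000)
        assert m.tp + m.fp + m.tn + m.fn == 16
        assert m.accuracy == pytest.approx((m.tp + m.tn) / 16)

    @pytest.mark.parametrize("window,fps", [(200, 5.00), (33, 30.30),
                                            (20, 50.00)])
    def test_effective_fps_rule(self, window, fps):
        assert effective_fps(window) == fps

    def test_sweep_returns_row_per_window(self, rng):
        segs = _mini_world(rng, n=20)
        cfg = TrainConfig(epochs=1, seed=0)
        res = temporal_sweep([10, 20], segs[:14], segs[14:], cfg)
        assert [r.window_ms for r in res.rows] == [10, 20]
        for r in res.rows:
            assert not r.failed
            assert np.isfinite(r.metrics.accuracy)
            assert r.fps == round(1000 / r.window_ms, 2)
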