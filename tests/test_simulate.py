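"""Gaze kinematics, scene rendering, and the DVS emulation model."""

import numpy as np
import pytest

import spikegaze as sg
from spikegaze.simulate import _raised_cosine_positions


class TestTrajectory:
    def test_zero_drift_fixations_constant(self):
        kin = sg.KinematicsParams(drift_sigma_px=0.0)
        traj = sg.simulate_trajectory(kin, 2000, seed=0, width=200,
                                      height=200)
        for iv in traj.intervals:
            if iv.label == "fixation":
                mask = (traj.times >= iv.t_start) & (traj.times < iv.t_end)
                seg = traj.positions[mask]
                assert np.ptp(seg, axis=0).max() == 0.0

    def test_raised_cosine_integrates_to_amplitude(self):
        # s(d)/A = 1 exactly for the sin^2 velocity profile
        for n in (7, 50, 333):
            frac = _raised_cosine_positions(n)
            assert frac[-1] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(frac) >= 0)

    def test_saccade_displacement_in_amplitude_range(self):
        kin = sg.KinematicsParams(saccade_amplitude_px=(20, 40),
                                  drift_sigma_px=0.0,
                                  peak_velocity_px_s=1e9)
        traj = sg.simulate_trajectory(kin, 5000, seed=3, width=1000,
                                      height=1000)
        checked = 0
        for iv in traj.intervals:
            if iv.label == "saccade" and iv.t_end <= traj.times[-1]:
                mask = (traj.times >= iv.t_start) & (traj.times < iv.t_end)
                seg = traj.positions[mask]
                disp = np.linalg.norm(seg[-1] - seg[0])
                assert 20 * 0.9 <= disp <= 40 * 1.001
                checked += 1
        assert checked >= 2

    def test_durations_within_physiological_ranges(self):
        kin = sg.KinematicsParams()
        traj = sg.simulate_trajectory(kin, 8000, seed=5, width=400,
                                      height=400)
        for iv in traj.intervals[:-1]:  # last may be truncated
            dur_ms = (iv.t_end - iv.t_start) / 1000
            lo, hi = (kin.fixation_duration_ms if iv.label == "fixation"
                      else kin.saccade_duration_ms)
            assert lo * 0.5 <= dur_ms <= hi * 1.01

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            sg.simulate_trajectory(sg.KinematicsParams(), 10, seed=0)


class TestRender:
    scene = sg.SceneModel(width=64, height=64, pupil_radius=6,
                          iris_radius=14)

    def test_central_symmetry(self):
        img = sg.render_frame(self.scene, (31.5, 31.5))
        np.testing.assert_allclose(img, img[::-1, ::-1], atol=1e-12)

    def test_intensity_extremes(self):
        img = sg.render_frame(self.scene, (32, 32))
        assert img.min() == pytest.approx(self.scene.pupil_level)
        assert img.max() == pytest.approx(self.scene.sclera_level)
        assert np.all(img > 0)

    def test_centroid_tracks_gaze_shift(self):
        dx = 7.0
        a = sg.render_frame(self.scene, (24, 32))
        b = sg.render_frame(self.scene, (24 + dx, 32))
        xs = np.arange(64)

        def centroid(img):
            mask = self.scene.sclera_level - img  # dark-disc weight
            return (mask.sum(axis=0) * xs).sum() / mask.sum()

        assert centroid(b) - centroid(a) == pytest.approx(dx, abs=0.5)


class TestEmit:
    def _params(self, **kw):
        kw.setdefault("noise_rate_hz", 0.0)
        return sg.EmulatorParams(**kw)

    def test_static_scene_silent(self):
        frame = sg.render_frame(TestRender.scene, (30, 30))
        stream = sg.emit_events([frame] * 10, np.arange(10) * 1000,
                                self._params())
        assert len(stream) == 0

    def test_multiple_crossings_emit_multiple_events(self):
        theta = 0.3
        base = np.full((4, 4), 0.5)
        stepped = base.copy()
        stepped[2, 1] = 0.5 * np.exp(2 * theta)
        stream = sg.emit_events([base, stepped], [0, 1000],
                                self._params(theta=theta))
        assert len(stream) == 2
        assert np.all(stream.p == 1)
        assert np.all(stream.x == 1) and np.all(stream.y == 2)

    def test_polarity_of_monotonic_brightening(self):
        theta = 0.2
        frames = [np.full((3, 3), 0.2 * np.exp(0.13 * k))
                  for k in range(12)]
        stream = sg.emit_events(frames, np.arange(12) * 1000,
                                self._params(theta=theta))
        assert len(stream) > 0 and np.all(stream.p == 1)

    def test_threshold_monotonicity(self):
        """Halving the contrast threshold never reduces event count."""
        rng = np.random.default_rng(0)
        frames = [np.exp(rng.normal(0, 0.2, (6, 6))) for _ in range(8)]
        times = np.arange(8) * 1000
        counts = [len(sg.emit_events(frames, times,
                                     self._params(theta=th)))
                  for th in (0.4, 0.2, 0.1)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_conservation_of_reference_advancement(self):
        """Signed event count x theta stays within theta of the total
        log-intensity change at every pixel."""
        theta = 0.25
        rng = np.random.default_rng(1)
        frames = [np.exp(rng.normal(0, 0.3, (5, 5))) for _ in range(6)]
        stream = sg.emit_events(frames, np.arange(6) * 1000,
                                self._params(theta=theta))
        total = np.log(frames[-1]) - np.log(frames[0])
        net = np.zeros((5, 5))
        np.add.at(net, (stream.y, stream.x), stream.p)
        assert np.all(np.abs(total - net * theta) < theta)

    def test_moving_disc_events_on_boundary(self):
        """Events from a translating dark disc concentrate on the
        pupil/iris boundary annulus."""
        scene = TestRender.scene
        xs = np.linspace(20, 40, 21)
        frames = [sg.render_frame(scene, (x, 32)) for x in xs]
        stream = sg.emit_events(frames, (np.arange(21) * 500),
                                self._params(theta=0.2))
        assert len(stream) > 100
        # distance of each event from the nearest swept disc centre
        centres = np.interp(stream.t, np.arange(21) * 500, xs)
        r = np.hypot(stream.x - centres, stream.y - 32)
        near_edge = ((np.abs(r - scene.pupil_radius) <= 2)
                     | (np.abs(r - scene.iris_radius) <= 2))
        assert near_edge.mean() >= 0.95

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sg.emit_events([np.ones((2, 2)), np.zeros((2, 2))], [0, 1000],
                           self._params())


class TestGenerateDataset:
    def test_balanced_and_labelled(self, tiny_dataset):
        labels = [s.label for s in tiny_dataset]
        assert labels.count("fixation") == labels.count("saccade") == 6

    def test_saccades_denser_than_fixations(self, tiny_dataset):
        sac = np.mean([len(s.stream) for s in tiny_dataset
                       if s.label == "saccade"])
        fix = np.mean([len(s.stream) for s in tiny_dataset
                       if s.label == "fixation"])
        assert sac > fix

    def test_seed_reproducibility(self):
        scene = sg.default_scene(48, 48)
        kin = sg.default_kinematics(48, 48)
        emu = sg.EmulatorParams(seed=0)
        a = sg.generate_dataset(scene, kin, emu, n_per_class=2, seed=5)
        b = sg.generate_dataset(scene, kin, emu, n_per_class=2, seed=5)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.stream == sb.stream
            assert (sa.label, sa.user_id) == (sb.label, sb.user_id)
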