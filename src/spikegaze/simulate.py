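"""Synthetic near-eye scene and event-camera emulation.

Generates labelled fixation/saccade event streams without any recorded
data.  A gaze trajectory alternates fixations (held position plus a
Gaussian drift random walk) with saccades (straight-line displacement
under a raised-cosine velocity profile).  A dark-pupil/iris disc scene is
rendered along the trajectory and run through an idealized DVS pixel
model: an event fires whenever the log intensity at a pixel moves a full
contrast threshold away from that pixel's reference level,

    L(x, y, t) - L_ref(x, y) >= theta   ->  +1 event,  L_ref += theta
    L(x, y, t) - L_ref(x, y) <= -theta  ->  -1 event,  L_ref -= theta

with one event per crossed threshold multiple and the reference advanced
by exactly the emitted multiple (never reset to the current value), so
event counts are conserved against total reference advancement.

Fixations produce sparse events (drift/tremor only); saccades sweep the
dark disc rapidly across the sensor and produce dense bursts.  That
density gap is the physical signal the classifier learns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .events import (FIXATION, SACCADE, EventStream, LabeledSegment,
                     LabelInterval, align_labels_to_events, balance_classes)

__all__ = [
    "GazeTrajectory", "SceneModel", "EmulatorParams", "KinematicsParams",
    "default_scene", "default_kinematics",
    "simulate_trajectory", "render_frame", "emit_events", "generate_dataset",
]


@dataclass(frozen=True)
class GazeTrajectory:
    """Pupil-centre position sampled on a uniform time grid.

    ``times`` are microseconds; ``positions`` is an (N, 2) float array of
    (x, y) pixel coordinates; ``labels`` is an (N,) array of class
    indices (0 fixation, 1 saccade); ``intervals`` are the ground-truth
    segment annotations implied by the label changes.
    """

    times: np.ndarray
    positions: np.ndarray
    labels: np.ndarray
    intervals: tuple[LabelInterval, ...]
    sample_rate_hz: float

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class SceneModel:
    """Concentric dark-pupil/iris disc scene on a bright sclera.

    Intensities are relative radiance on (0, 1]; they must be strictly
    positive because the emulator works in log intensity.
    """

    width: int
    height: int
    pupil_radius: float
    iris_radius: float
    pupil_level: float = 0.08
    iris_level: float = 0.35
    sclera_level: float = 0.90
    background_level: float = 0.90

    def __post_init__(self):
        if not (0 < self.pupil_radius < self.iris_radius):
            raise ValueError("need 0 < pupil radius < iris radius")
        for v in (self.pupil_level, self.iris_level, self.sclera_level,
                  self.background_level):
            if v <= 0:
                raise ValueError("intensity levels must be > 0 (log taken)")


@dataclass(frozen=True)
class EmulatorParams:
    """DVS pixel-model parameters.

    theta: contrast threshold in log-intensity units (typical DVS
    sensitivity is 0.1-0.3; default 0.2).
    render_rate_hz: scene sampling rate; should be at least twice the
    trajectory rate so inter-sample motion stays small (warned, not
    enforced).
    noise_rate_hz: homogeneous Poisson spurious-event rate per pixel
    (polarity equiprobable); real sensors show 0.01-1 Hz/px background
    activity, default 0.1.
    """

    theta: float = 0.2
    render_rate_hz: float = 2000.0
    noise_rate_hz: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("contrast threshold must be > 0")
        if self.noise_rate_hz < 0:
            raise ValueError("noise rate must be >= 0")


@dataclass(frozen=True)
class KinematicsParams:
    """Gaze kinematics, all spatial units in pixels.

    Durations follow oculomotor physiology: fixations 50-600 ms,
    saccades 20-200 ms.  The peak-velocity cap is the pixel-space analog
    of the ~700 deg/s physiological ceiling; the sensor's deg/px scale is
    unspecified, so the cap is an explicit configuration value.
    """

    fixation_duration_ms: tuple[float, float] = (50.0, 600.0)
    saccade_duration_ms: tuple[float, float] = (20.0, 200.0)
    saccade_amplitude_px: tuple[float, float] = (30.0, 120.0)
    drift_sigma_px: float = 0.05
    peak_velocity_px_s: float = 10000.0
    sample_rate_hz: float = 1000.0

    def __post_init__(self):
        for lo, hi in (self.fixation_duration_ms, self.saccade_duration_ms,
                       self.saccade_amplitude_px):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


def default_scene(width: int = 360, height: int = 260) -> SceneModel:
    """Scene scaled to the sensor: pupil ~9%, iris ~22% of the short side."""
    m = min(width, height)
    return SceneModel(width=width, height=height,
                      pupil_radius=0.09 * m, iris_radius=0.22 * m)


def default_kinematics(width: int = 360, height: int = 260) -> KinematicsParams:
    """Kinematics scaled to the sensor short side.

    Saccade amplitudes span 15-45% of the short side; the velocity cap is
    40 short-sides per second, generous enough that the raised-cosine
    peak 2A/d rarely clips at default durations.  Drift sigma is scaled
    so the fixational random walk wanders a fraction of a pixel over a
    typical fixation (ocular drift is orders of magnitude slower than a
    saccade), preserving the real saccade/fixation event-density gap.
    """
    m = min(width, height)
    return KinematicsParams(saccade_amplitude_px=(0.15 * m, 0.45 * m),
                            drift_sigma_px=2e-4 * m,
                            peak_velocity_px_s=40.0 * m)


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def _raised_cosine_positions(n: int) -> np.ndarray:
    """Cumulative displacement fractions of the sin^2 velocity profile.

    v(tau) = (2A/d) sin^2(pi tau / d) integrates to s(tau)/A =
    tau/d - sin(2 pi tau/d)/(2 pi); s(d) = A exactly.
    """
    tau = np.arange(1, n + 1) / n
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def simulate_trajectory(kin: KinematicsParams, total_duration_ms: float,
                        seed: int, width: int = 360, height: int = 260,
                        ) -> GazeTrajectory:
    """Simulate an alternating fixation/saccade gaze trajectory.

    Starts with a fixation.  Fixations hold position with a Gaussian
    drift random walk (``drift_sigma_px`` per sample); saccades displace
    in a straight line with a raised-cosine (sin^2) velocity profile.
    If a saccade's peak velocity 2A/d would exceed the cap, its
    amplitude is clamped (with a warning).  Targets landing outside a
    safety margin are redirected toward the sensor centre.
    """
    rng = np.random.default_rng(seed)
    dt_s = 1.0 / kin.sample_rate_hz
    dt_us = 1e6 * dt_s
    n_total = int(round(total_duration_ms * 1e-3 * kin.sample_rate_hz))
    min_len_ms = kin.fixation_duration_ms[0] + kin.saccade_duration_ms[0]
    if total_duration_ms < min_len_ms:
        raise ValueError("duration shorter than one fixation + one saccade")

    margin = 0.28 * min(width, height)
    lo = np.array([margin, margin])
    hi = np.array([width - 1 - margin, height - 1 - margin])
    pos = np.array([(width - 1) / 2.0, (height - 1) / 2.0])

    positions, labels, boundaries = [], [], []
    kind = FIXATION
    n_done = 0
    while n_done < n_total:
        if kind == FIXATION:
            dur_ms = rng.uniform(*kin.fixation_duration_ms)
            n = max(1, int(round(dur_ms * 1e-3 * kin.sample_rate_hz)))
            n = min(n, n_total - n_done)
            steps = rng.normal(0.0, kin.drift_sigma_px, size=(n, 2))
            seg = pos + np.cumsum(steps, axis=0)
            seg = np.clip(seg, lo, hi)
        else:
            dur_ms = rng.uniform(*kin.saccade_duration_ms)
            n = max(2, int(round(dur_ms * 1e-3 * kin.sample_rate_hz)))
            n = min(n, max(2, n_total - n_done))
            amp = rng.uniform(*kin.saccade_amplitude_px)
            peak_v = 2.0 * amp / (n * dt_s)
            if peak_v > kin.peak_velocity_px_s:
                amp = kin.peak_velocity_px_s * n * dt_s / 2.0
                warnings.warn("saccade amplitude clamped by peak-velocity cap",
                              stacklevel=2)
            # sample a direction whose full-amplitude target stays inside
            # the margin box; fall back to the most permissive direction
            target = None
            for _ in range(12):
                phi = rng.uniform(0, 2 * np.pi)
                cand = pos + amp * np.array([np.cos(phi), np.sin(phi)])
                if np.all(cand >= lo) and np.all(cand <= hi):
                    target = cand
                    break
            if target is None:
                centre = (lo + hi) / 2.0
                d = centre - pos
                nd = np.linalg.norm(d)
                direction = d / nd if nd > 1e-9 else np.array([1.0, 0.0])
                # farthest feasible step along the through-centre direction
                with np.errstate(divide="ignore"):
                    t_hi = np.where(direction > 0, (hi - pos) / direction,
                                    np.inf)
                    t_lo = np.where(direction < 0, (lo - pos) / direction,
                                    np.inf)
                reach = float(min(np.min(t_hi), np.min(t_lo)))
                target = pos + min(amp, reach) * direction
            frac = _raised_cosine_positions(n)
            seg = pos + frac[:, None] * (target - pos)
        positions.append(seg)
        labels.append(np.full(len(seg), 0 if kind == FIXATION else 1,
                              dtype=np.int64))
        boundaries.append((n_done, n_done + len(seg), kind))
        pos = seg[-1].copy()
        n_done += len(seg)
        kind = SACCADE if kind == FIXATION else FIXATION

    positions = np.concatenate(positions, axis=0)
    labels = np.concatenate(labels)
    times = (np.arange(len(positions)) * dt_us).astype(np.int64)
    intervals = tuple(
        LabelInterval(int(round(a * dt_us)), int(round(b * dt_us)), k)
        for a, b, k in boundaries)
    return GazeTrajectory(times, positions, labels, intervals,
                          kin.sample_rate_hz)


# ---------------------------------------------------------------------------
# Rendering and event emission
# ---------------------------------------------------------------------------

def render_frame(scene: SceneModel, gaze_xy) -> np.ndarray:
    """Render the (height, width) intensity image for one gaze position.

    Concentric anti-aliased discs: dark pupil inside iris on the base
    (sclera/background) level.  Positions are clamped into the sensor.
    All values are strictly positive.
    """
    cx = float(np.clip(gaze_xy[0], 0, scene.width - 1))
    cy = float(np.clip(gaze_xy[1], 0, scene.height - 1))
    yy = np.arange(scene.height, dtype=np.float64)[:, None] - cy
    xx = np.arange(scene.width, dtype=np.float64)[None, :] - cx
    r = np.sqrt(yy * yy + xx * xx)
    img = np.full((scene.height, scene.width), scene.background_level)
    # 1-px linear edge ramp for anti-aliasing
    a_iris = np.clip(scene.iris_radius - r + 0.5, 0.0, 1.0)
    img = img * (1 - a_iris) + scene.iris_level * a_iris
    a_pup = np.clip(scene.pupil_radius - r + 0.5, 0.0, 1.0)
    img = img * (1 - a_pup) + scene.pupil_level * a_pup
    return img


def emit_events(frames, times_us, params: EmulatorParams,
                width=None, height=None, rng=None,
                t_end=None) -> EventStream:
    """Run the per-pixel threshold-crossing model over a frame sequence.

    ``frames`` is an iterable of positive (H, W) intensity images at
    timestamps ``times_us`` (microseconds, increasing).  Per pixel a
    reference log intensity starts at the first frame's value; every
    full ``theta`` multiple the log intensity moves away from the
    reference emits one event (polarity = sign of change, timestamp
    linearly interpolated within the frame interval) and advances the
    reference by that multiple.  Optional Poisson noise events are
    mixed in at ``noise_rate_hz`` per pixel.
    """
    frames = iter(frames)
    times_us = np.asarray(times_us)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    first = np.asarray(next(frames), dtype=np.float64)
    if np.any(first <= 0):
        raise ValueError("intensity must be strictly positive")
    h, w = first.shape
    width = w if width is None else width
    height = h if height is None else height
    ref = np.log(first)
    theta = params.theta

    xs, ys, ts, ps = [], [], [], []
    t_prev = int(times_us[0])
    npix = w * h
    for i, frame in enumerate(frames, start=1):
        frame = np.asarray(frame, dtype=np.float64)
        if np.any(frame <= 0):
            raise ValueError("intensity must be strictly positive")
        t_cur = int(times_us[i])
        dlog = np.log(frame) - ref
        # small relative epsilon so a change of exactly k*theta yields
        # k events despite float rounding (the crossing rule is >=)
        n_cross = np.floor(np.abs(dlog) / theta + 1e-9).astype(np.int64)
        yy, xx = np.nonzero(n_cross)
        if yy.size:
            n = n_cross[yy, xx]
            sign = np.sign(dlog[yy, xx]).astype(np.int64)
            reps = np.repeat(np.arange(len(yy)), n)
            k = np.concatenate([np.arange(1, ni + 1) for ni in n]) \
                if yy.size else np.array([], dtype=np.int64)
            frac = (k * theta) / np.abs(dlog[yy, xx])[reps]
            t_ev = t_prev + frac * (t_cur - t_prev)
            xs.append(xx[reps])
            ys.append(yy[reps])
            ts.append(np.minimum(t_ev, t_cur - 1e-9).astype(np.int64))
            ps.append(sign[reps])
            ref[yy, xx] += sign * n * theta
        if params.noise_rate_hz > 0:
            lam = params.noise_rate_hz * npix * (t_cur - t_prev) * 1e-6
            n_noise = rng.poisson(lam)
            if n_noise:
                xs.append(rng.integers(0, w, n_noise))
                ys.append(rng.integers(0, h, n_noise))
                ts.append(rng.integers(t_prev, t_cur, n_noise))
                ps.append(rng.choice((-1, 1), n_noise))
        t_prev = t_cur

    if t_end is None:
        t_end = t_prev + 1
    if not xs:
        return EventStream.from_arrays([], [], [], [], width, height,
                                       int(times_us[0]), int(t_end))
    return EventStream.from_arrays(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(ts),
        np.concatenate(ps), width, height, int(times_us[0]), int(t_end))


def _render_and_emit(scene: SceneModel, traj: GazeTrajectory,
                     params: EmulatorParams, rng) -> EventStream:
    """Resample the trajectory at the render rate and emulate the sensor."""
    rate = params.render_rate_hz
    if rate < 2 * traj.sample_rate_hz:
        warnings.warn("render rate below 2x trajectory rate; motion may alias",
                      stacklevel=2)
    t_end = int(traj.times[-1] + 1e6 / traj.sample_rate_hz)
    times = np.arange(0, t_end, 1e6 / rate)
    px = np.interp(times, traj.times, traj.positions[:, 0])
    py = np.interp(times, traj.times, traj.positions[:, 1])
    frames = (render_frame(scene, (x, y)) for x, y in zip(px, py))
    return emit_events(frames, times.astype(np.int64), params,
                       width=scene.width, height=scene.height,
                       rng=rng, t_end=t_end)


def generate_dataset(scene: SceneModel, kin: KinematicsParams,
                     emulator: EmulatorParams, n_per_class: int, seed: int,
                     n_users: int = 10) -> list[LabeledSegment]:
    """Produce a balanced, user-tagged fixation/saccade segment set.

    Simulates trajectories in chunks until at least ``n_per_class``
    ground-truth segments of each class exist, renders and emulates each
    chunk, cuts the streams at the ground-truth intervals, balances the
    classes (seeded) and assigns synthetic user ids round-robin.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    mean_pair_ms = (sum(kin.fixation_duration_ms) / 2
                    + sum(kin.saccade_duration_ms) / 2)
    chunk_ms = max(2000.0, 1.15 * mean_pair_ms * n_per_class)

    segments: list[LabeledSegment] = []
    counts = {FIXATION: 0, SACCADE: 0}
    while min(counts.values()) < n_per_class:
        traj_seed, emu_seed = (int(s.generate_state(1)[0] % (2**31))
                               for s in ss.spawn(2))
        traj = simulate_trajectory(kin, chunk_ms, traj_seed,
                                   scene.width, scene.height)
        rng = np.random.default_rng(emu_seed)
        stream = _render_and_emit(scene, traj, emulator, rng)
        # drop the trailing interval: it is usually truncated by the chunk end
        intervals = traj.intervals[:-1] if len(traj.intervals) > 1 \
            else traj.intervals
        segs = align_labels_to_events(stream, intervals)
        segments.extend(segs)
        for s in segs:
            counts[s.label] += 1
        chunk_ms = max(2000.0,
                       1.2 * mean_pair_ms
                       * (n_per_class - min(counts.values())))

    balance_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    balanced = balance_classes(segments, n_per_class, balance_seed)
    for i, seg in enumerate(balanced):
        seg.user_id = (i % n_users) + 1
    return balanced
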