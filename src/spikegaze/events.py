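"""Event data model and plumbing.

An event camera reports per-pixel brightness changes as an asynchronous
stream of ``(x, y, t, p)`` records: column, row, timestamp in integer
microseconds, and polarity (+1 brightening, -1 darkening).  This module
holds the stream container, file I/O (CSV and HDF5), time slicing,
label-interval alignment, class balancing and the user-wise train/test
split used throughout the package.

Conventions
-----------
* Coordinates are 0-based, origin top-left; ``x`` indexes columns (width
  axis), ``y`` rows (height axis).
* All time intervals are half-open ``[t0, t1)`` so adjacent intervals
  never double-count an event.
* Polarity on disk is {-1, +1}; mapping to ON/OFF channels happens only
  in :mod:`spikegaze.encoding`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import h5py
import numpy as np

FIXATION = "fixation"
SACCADE = "saccade"
#: class index mapping used everywhere (fixation = 0, saccade = 1)
LABEL_TO_INDEX = {FIXATION: 0, SACCADE: 1}

__all__ = [
    "Event",
    "EventStream",
    "LabelInterval",
    "LabeledSegment",
    "FIXATION",
    "SACCADE",
    "LABEL_TO_INDEX",
    "read_events",
    "write_events",
    "read_labels",
    "write_labels",
    "slice_stream",
    "align_labels_to_events",
    "balance_classes",
    "split_by_user",
    "EventParseError",
]


class EventParseError(ValueError):
    """Raised when an event file contains a malformed row."""


class Event(NamedTuple):
    """A single camera event."""

    x: int
    y: int
    t: int
    p: int


@dataclass(frozen=True)
class EventStream:
    """An ordered event stream with sensor geometry.

    Events are stored as parallel integer arrays sorted by timestamp
    (non-decreasing).  ``t_start``/``t_end`` delimit the half-open span
    the stream covers, which may extend beyond the first/last event.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    p: np.ndarray
    width: int
    height: int
    t_start: int = 0
    t_end: int = 0

    @classmethod
    def from_arrays(cls, x, y, t, p, width, height, t_start=None, t_end=None,
                    validate=True):
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        t = np.asarray(t, dtype=np.int64)
        p = np.asarray(p, dtype=np.int64)
        if not (x.shape == y.shape == t.shape == p.shape):
            raise ValueError("event columns must have identical length")
        order = np.argsort(t, kind="stable")
        x, y, t, p = x[order], y[order], t[order], p[order]
        if t_start is None:
            t_start = int(t[0]) if t.size else 0
        if t_end is None:
            t_end = int(t[-1]) + 1 if t.size else 0
        stream = cls(x, y, t, p, int(width), int(height), int(t_start), int(t_end))
        if validate:
            stream.validate()
        return stream

    def validate(self) -> None:
        if self.x.size:
            if self.x.min() < 0 or self.x.max() >= self.width:
                raise ValueError(
                    f"x coordinate outside geometry [0, {self.width})")
            if self.y.min() < 0 or self.y.max() >= self.height:
                raise ValueError(
                    f"y coordinate outside geometry [0, {self.height})")
            if not np.isin(self.p, (-1, 1)).all():
                raise ValueError("polarity must be -1 or +1")
            if self.t.min() < self.t_start or self.t.max() >= self.t_end:
                raise ValueError("event timestamps outside [t_start, t_end)")

    def __len__(self) -> int:
        return int(self.t.size)

    def __iter__(self) -> Iterable[Event]:
        for xi, yi, ti, pi in zip(self.x, self.y, self.t, self.p):
            yield Event(int(xi), int(yi), int(ti), int(pi))

    @property
    def duration(self) -> int:
        """Span length in microseconds."""
        return self.t_end - self.t_start

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.width == other.width and self.height == other.height
            and self.t_start == other.t_start and self.t_end == other.t_end
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.p, other.p)
        )


@dataclass(frozen=True)
class LabelInterval:
    """A labelled half-open time interval of one recording."""

    t_start: int
    t_end: int
    label: str
    user_id: int = 0
    eye: str = "left"

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise ValueError("interval requires t_start < t_end")
        if self.label not in LABEL_TO_INDEX:
            raise ValueError(f"unknown label {self.label!r}")
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")


@dataclass
class LabeledSegment:
    """An event-stream segment carrying its class label and user id."""

    stream: EventStream
    label: str
    user_id: int = 0
    empty: bool = field(default=False)

    @property
    def label_index(self) -> int:
        return LABEL_TO_INDEX[self.label]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CSV_HEADER = ["t", "x", "y", "p"]


def write_events(path, stream: EventStream) -> None:
    """Write a stream to CSV (``t,x,y,p``) or HDF5 depending on suffix.

    The CSV dialect carries geometry and span in a leading comment line;
    the HDF5 container stores them as root attributes.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            for name in _CSV_HEADER:
                f.create_dataset(name, data=getattr(stream, name))
            f.attrs["width"] = stream.width
            f.attrs["height"] = stream.height
            f.attrs["t_start"] = stream.t_start
            f.attrs["t_end"] = stream.t_end
        return
    with open(path, "w", newline="") as f:
        f.write(f"# width={stream.width} height={stream.height} "
                f"t_start={stream.t_start} t_end={stream.t_end}\n")
        writer = csv.writer(f)
        writer.writerow(_CSV_HEADER)
        for ev in zip(stream.t, stream.x, stream.y, stream.p):
            writer.writerow([int(v) for v in ev])


def _parse_csv_events(path, width, height, t_start, t_end):
    rows = {name: [] for name in _CSV_HEADER}
    meta = {}
    with open(path, newline="") as f:
        lineno = 0
        header_seen = False
        for line in f:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = int(v)
                continue
            parts = [s.strip() for s in line.split(",")]
            if not header_seen:
                if parts != _CSV_HEADER:
                    raise EventParseError(
                        f"{path}:{lineno}: expected header {_CSV_HEADER}, got {parts}")
                header_seen = True
                continue
            if len(parts) != 4:
                raise EventParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                vals = [int(s) for s in parts]
            except ValueError as exc:
                raise EventParseError(f"{path}:{lineno}: {exc}") from None
            for name, v in zip(_CSV_HEADER, vals):
                rows[name].append(v)
    if width is None:
        width = meta.get("width")
    if height is None:
        height = meta.get("height")
    if width is None or height is None:
        raise ValueError(
            f"{path}: geometry not found in file header; pass width/height")
    t_start = meta.get("t_start", t_start)
    t_end = meta.get("t_end", t_end)
    return rows, width, height, t_start, t_end


def read_events(path, width=None, height=None) -> EventStream:
    """Load an event stream from CSV or HDF5.

    Geometry comes from the file (comment line / attributes) and may be
    overridden by explicit ``width``/``height``.  Events are re-sorted by
    timestamp; out-of-geometry coordinates raise ``ValueError``.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            data = {name: f[name][()] for name in _CSV_HEADER}
            width = width if width is not None else int(f.attrs["width"])
            height = height if height is not None else int(f.attrs["height"])
            t_start = int(f.attrs.get("t_start", 0))
            t_end = int(f.attrs.get("t_end", 0))
        if data["t"].size == 0:
            return EventStream.from_arrays([], [], [], [], width, height,
                                           t_start, t_end)
        return EventStream.from_arrays(
            data["x"], data["y"], data["t"], data["p"], width, height,
            t_start, t_end)
    rows, width, height, t_start, t_end = _parse_csv_events(
        path, width, height, None, None)
    if not rows["t"]:
        return EventStream.from_arrays([], [], [], [], width or 0, height or 0,
                                       t_start or 0, t_end or 0)
    return EventStream.from_arrays(rows["x"], rows["y"], rows["t"], rows["p"],
                                   width, height, t_start, t_end)


def write_labels(path, intervals: Sequence[LabelInterval]) -> None:
    """Write label intervals as CSV ``t_start,t_end,label,user_id,eye``."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["t_start", "t_end", "label", "user_id", "eye"])
        for iv in intervals:
            writer.writerow([iv.t_start, iv.t_end, iv.label, iv.user_id, iv.eye])


def read_labels(path) -> list[LabelInterval]:
    out = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        for row in reader:
            out.append(LabelInterval(int(row["t_start"]), int(row["t_end"]),
                                     row["label"], int(row["user_id"]),
                                     row["eye"]))
    return out


# ---------------------------------------------------------------------------
# Slicing / alignment / balancing / splitting
# ---------------------------------------------------------------------------

def slice_stream(stream: EventStream, t0: int, t1: int,
                 rezero: bool = False) -> EventStream:
    """Return the sub-stream with ``t in [t0, t1)``.

    Timestamps are preserved unless ``rezero`` shifts the slice so its
    span starts at 0.
    """
    if t0 >= t1:
        raise ValueError(f"slice requires t0 < t1, got [{t0}, {t1})")
    lo = int(np.searchsorted(stream.t, t0, side="left"))
    hi = int(np.searchsorted(stream.t, t1, side="left"))
    shift = t0 if rezero else 0
    return EventStream(
        stream.x[lo:hi].copy(), stream.y[lo:hi].copy(),
        stream.t[lo:hi] - shift, stream.p[lo:hi].copy(),
        stream.width, stream.height, t0 - shift, t1 - shift)


def _check_non_overlapping(intervals: Sequence[LabelInterval]) -> None:
    ivs = sorted(intervals, key=lambda iv: iv.t_start)
    for a, b in zip(ivs, ivs[1:]):
        if b.t_start < a.t_end:
            raise ValueError(
                f"overlapping intervals [{a.t_start},{a.t_end}) and "
                f"[{b.t_start},{b.t_end})")


def align_labels_to_events(stream: EventStream,
                           intervals: Sequence[LabelInterval],
                           ) -> list[LabeledSegment]:
    """Cut ``stream`` into one labelled segment per annotation interval.

    Each segment's events are exactly the half-open time slice of the
    interval; intervals covering no events are retained with the
    ``empty`` flag set so callers can filter or keep them.
    """
    _check_non_overlapping(intervals)
    segments = []
    for iv in intervals:
        sub = slice_stream(stream, iv.t_start, iv.t_end)
        segments.append(LabeledSegment(sub, iv.label, iv.user_id,
                                       empty=(len(sub) == 0)))
    return segments


def balance_classes(segments: Sequence[LabeledSegment], n_per_class: int,
                    seed: int) -> list[LabeledSegment]:
    """Downsample every class to ``n_per_class`` segments without
    replacement (seeded, order-deterministic).

    Mirrors the dataset-curation step where the majority class is
    downsampled for balance (e.g. 1850 saccades cut to match 1326
    fixations, then 1000 per class retained).
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, seg in enumerate(segments):
        by_class.setdefault(seg.label, []).append(i)
    chosen: list[int] = []
    for label in sorted(by_class):
        idx = by_class[label]
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {label!r} has only {len(idx)} segments, "
                f"need {n_per_class}")
        pick = rng.choice(len(idx), size=n_per_class, replace=False)
        chosen.extend(idx[j] for j in sorted(pick))
    chosen.sort()
    return [segments[i] for i in chosen]


def split_by_user(segments: Sequence[LabeledSegment],
                  train_users: Iterable[int], test_users: Iterable[int],
                  ) -> tuple[list[LabeledSegment], list[LabeledSegment]]:
    """User-wise split: no user's segments appear in both sets.

    Follows the protocol of training on one block of users and holding
    out the remainder (e.g. users 1-7 train / 8-10 test).  Segments from
    users in neither set are excluded with a warning.
    """
    train_users = set(train_users)
    test_users = set(test_users)
    overlap = train_users & test_users
    if overlap:
        raise ValueError(f"user sets overlap: {sorted(overlap)}")
    train, test, dropped = [], [], 0
    for seg in segments:
        if seg.user_id in train_users:
            train.append(seg)
        elif seg.user_id in test_users:
            test.append(seg)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} segments from unlisted users excluded",
                      stacklevel=2)
    return train, test
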