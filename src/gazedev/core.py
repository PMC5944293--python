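"""Domain types, screen-coordinate conventions, and session file I/O.

Coordinate frame
----------------
All gaze and target coordinates live in the normalized screen frame used by
screen-based eye trackers: the origin is the upper-left corner of the display,
``x`` grows rightward, ``y`` grows downward, and both axes span ``(0, 1)``
across the visible screen.  Gaze samples reported by a tracker may fall
outside that interval (a strongly deviating eye can "look" off-screen); such
samples are kept as-is and only clipped when an image is rasterized.

The acquisition protocol shows nine fixation targets, one at a time, on a
3 x 3 grid at ``{0.1, 0.5, 0.9} x {0.1, 0.5, 0.9}``, and records binocular
gaze at 60 Hz.  A gaze *pair* (simultaneous left-eye and right-eye sample) is
*effective* when at least one of the two gaze points lies strictly within a
distance threshold (default 0.05) of the current target; each target advances
after 100 effective pairs have been retained or after 10 s.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "TargetPoint",
    "GazePair",
    "ProtocolConfig",
    "GazeSession",
    "SessionFormatError",
    "NINE_TARGETS",
    "LABELS",
    "euclidean_deviation",
    "is_effective",
    "read_session",
    "write_session",
]

LABELS = ("normal", "strabismic", "unknown")

Point = tuple[float, float]


class SessionFormatError(ValueError):
    """Raised when a session file violates the expected tabular format."""


@dataclass(frozen=True)
class TargetPoint:
    """One of the nine fixation targets, indexed 1..9 in display order."""

    index: int
    position: Point

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 9:
            raise ValueError(f"target index must be in 1..9, got {self.index}")
        x, y = self.position
        if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
            raise ValueError(f"target position must lie in (0,1)^2, got {self.position}")


#: The nine canonical targets in display order: left-to-right within each row,
#: rows top to bottom.
NINE_TARGETS: tuple[TargetPoint, ...] = tuple(
    TargetPoint(index=1 + col + 3 * row, position=(x, y))
    for row, y in enumerate((0.1, 0.5, 0.9))
    for col, x in enumerate((0.1, 0.5, 0.9))
)


@dataclass(frozen=True)
class GazePair:
    """Simultaneous left/right gaze sample tied to one fixation target.

    ``sample_index`` is the 1-based index of the sample within its target's
    display period (counting every drawn sample, not only retained ones), and
    ``timestamp`` is seconds from that target's onset.
    """

    target_index: int
    sample_index: int
    left: Point
    right: Point
    timestamp: float

    def __post_init__(self) -> None:
        if not 1 <= self.target_index <= 9:
            raise ValueError(f"target_index must be in 1..9, got {self.target_index}")
        if self.sample_index < 1:
            raise ValueError(f"sample_index must be >= 1, got {self.sample_index}")
        for name, (x, y) in (("left", self.left), ("right", self.right)):
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"{name} gaze coordinates must be finite, got {(x, y)}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol parameters.

    Parameters
    ----------
    sampling_rate
        Tracker sampling rate in Hz.
    effectiveness_threshold
        Normalized-distance radius within which at least one eye must land
        for a pair to be retained (strict ``<`` comparison).
    pairs_per_target
        Number of effective pairs retained per target before advancing.
    max_display_time
        Maximum seconds a target stays on screen regardless of yield.
    """

    sampling_rate: float = 60.0
    effectiveness_threshold: float = 0.05
    pairs_per_target: int = 100
    max_display_time: float = 10.0
    targets: tuple[TargetPoint, ...] = NINE_TARGETS

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "effectiveness_threshold", "max_display_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pairs_per_target < 1:
            raise ValueError("pairs_per_target must be >= 1")
        if len({t.index for t in self.targets}) != len(self.targets):
            raise ValueError("target indices must be unique")

    def target(self, index: int) -> TargetPoint:
        for t in self.targets:
            if t.index == index:
                return t
        raise KeyError(f"no target with index {index}")


@dataclass
class GazeSession:
    """All retained gaze pairs of one subject across the nine targets."""

    subject_id: str
    label: str = "unknown"
    pairs: list[GazePair] = field(default_factory=list)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        valid = {t.index for t in self.protocol.targets}
        for p in self.pairs:
            if p.target_index not in valid:
                raise ValueError(f"pair references unknown target {p.target_index}")
        for j, n in self.per_target_counts.items():
            if n > self.protocol.pairs_per_target:
                raise ValueError(
                    f"target {j} holds {n} pairs, exceeding "
                    f"pairs_per_target={self.protocol.pairs_per_target}"
                )

    @property
    def per_target_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {t.index: 0 for t in self.protocol.targets}
        for p in self.pairs:
            counts[p.target_index] += 1
        return counts

    def pairs_for_target(self, index: int) -> list[GazePair]:
        return [p for p in self.pairs if p.target_index == index]

    def with_label(self, label: str) -> "GazeSession":
        return replace(self, label=label)


def euclidean_deviation(gaze: Point, target: Point) -> float:
    """Euclidean distance between a gaze point and a target, both normalized.

    This is the fixation-accuracy measure used throughout: small values mean
    accurate fixation.  Symmetric in its arguments and zero iff they coincide.
    """
    gx, gy = gaze
    tx, ty = target
    if not all(math.isfinite(v) for v in (gx, gy, tx, ty)):
        raise ValueError(f"coordinates must be finite, got gaze={gaze}, target={target}")
    return math.hypot(tx - gx, ty - gy)


def is_effective(pair: GazePair, target: TargetPoint, threshold: float) -> bool:
    """True iff at least one eye of the pair lands strictly within ``threshold``.

    One accurate eye suffices: the protocol only needs evidence that the
    subject attended the target, and the fellow eye of a strabismic subject
    may deviate arbitrarily.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    d_left = euclidean_deviation(pair.left, target.position)
    d_right = euclidean_deviation(pair.right, target.position)
    return min(d_left, d_right) < threshold


# --------------------------------------------------------------------------
# Session file I/O: flat CSV, one row per gaze pair.

_COLUMNS = (
    "subject_id",
    "label",
    "target_index",
    "sample_index",
    "timestamp",
    "lx",
    "ly",
    "rx",
    "ry",
)


def write_session(session: GazeSession, path) -> None:
    """Write a session as CSV with one row per gaze pair.

    Coordinates are written with ``repr`` (17 significant digits), so a
    read/write round trip is lossless.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for p in session.pairs:
            writer.writerow(
                [
                    session.subject_id,
                    session.label,
                    p.target_index,
                    p.sample_index,
                    repr(float(p.timestamp)),
                    repr(float(p.left[0])),
                    repr(float(p.left[1])),
                    repr(float(p.right[0])),
                    repr(float(p.right[1])),
                ]
            )


def read_session(path, protocol: ProtocolConfig | None = None) -> GazeSession:
    """Read a session CSV written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming the offending row for missing
    columns, non-numeric coordinates, or invalid target indices; an empty
    file (no data rows) is also an error.
    """
    protocol = protocol or ProtocolConfig()
    pairs: list[GazePair] = []
    subject_id: str | None = None
    label: str | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SessionFormatError(f"{path}: file is empty")
        if tuple(h.strip() for h in header) != _COLUMNS:
            raise SessionFormatError(
                f"{path}: header row must be {','.join(_COLUMNS)}, got {','.join(header)}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_COLUMNS):
                raise SessionFormatError(
                    f"{path}: row {row_no}: expected {len(_COLUMNS)} columns, got {len(row)}"
                )
            rec = dict(zip(_COLUMNS, row))
            if subject_id is None:
                subject_id = rec["subject_id"]
                label = rec["label"]
            elif rec["subject_id"] != subject_id:
                raise SessionFormatError(
                    f"{path}: row {row_no}: mixed subject ids "
                    f"({rec['subject_id']!r} vs {subject_id!r})"
                )
            try:
                target_index = int(rec["target_index"])
                sample_index = int(rec["sample_index"])
                timestamp = float(rec["timestamp"])
                left = (float(rec["lx"]), float(rec["ly"]))
                right = (float(rec["rx"]), float(rec["ry"]))
            except ValueError as exc:
                raise SessionFormatError(f"{path}: row {row_no}: {exc}") from exc
            if not 1 <= target_index <= 9:
                raise SessionFormatError(
                    f"{path}: row {row_no}: target_index must be in 1..9, got {target_index}"
                )
            try:
                pairs.append(
                    GazePair(
                        target_index=target_index,
                        sample_index=sample_index,
                        left=left,
                        right=right,
                        timestamp=timestamp,
                    )
                )
            except ValueError as exc:
                raise SessionFormatError(f"{path}: row {row_no}: {exc}") from exc
    if not pairs:
        raise SessionFormatError(f"{path}: no gaze pairs found")
    assert subject_id is not None and label is not None
    if label not in LABELS:
        raise SessionFormatError(f"{path}: unknown label {label!r}")
    return GazeSession(subject_id=subject_id, label=label, pairs=pairs, protocol=protocol)


def read_sessions(paths: Iterable, protocol: ProtocolConfig | None = None) -> list[GazeSession]:
    """Read several session files with a shared protocol."""
    return [read_session(p, protocol=protocol) for p in paths]
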