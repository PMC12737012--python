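"""Detections, trajectories and MOTChallenge plain-text I/O.

Conventions: frames are 1-based; pixel coordinates are floats with a
top-left origin and y increasing downward; boxes are stored corner-form
``(left, top, width, height)`` to match the file format, with explicit
conversion to centre form for the motion filters.

The exchange format is the MOTChallenge CSV dialect::

    frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z

Detections use ``id = -1``; ground truth and tracker output use positive
ids; the trailing three fields are unused 3-D slots written as ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "BBox",
    "Detection",
    "TrajectoryRecord",
    "TrajectorySet",
    "iou",
    "iou_matrix",
    "read_mot_file",
    "write_mot_file",
    "downsample",
    "MotParseError",
    "MotIntegrityError",
]


class MotParseError(ValueError):
    """A line of a MOT-format file could not be parsed."""


class MotIntegrityError(ValueError):
    """A trajectory set violates the one-box-per-(frame, id) invariant."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel bounding box in corner form (left, top, w, h)."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"invalid box: width and height must be positive, got "
                f"({self.width}, {self.height})"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def center(self) -> tuple[float, float]:
        """Box centre (xc, yc) in pixels."""
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    def to_cxcywh(self) -> tuple[float, float, float, float]:
        """Centre-form (xc, yc, w, h), used by the motion filters."""
        xc, yc = self.center
        return (xc, yc, self.width, self.height)

    @classmethod
    def from_cxcywh(cls, xc: float, yc: float, w: float, h: float) -> "BBox":
        return cls(xc - w / 2.0, yc - h / 2.0, w, h)

    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Detection:
    """One detector output: frame index, box, confidence score."""

    frame: int
    box: BBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame index must be >= 1, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class TrajectoryRecord:
    """One identity-labelled box at one frame."""

    frame: int
    id: int
    box: BBox
    confidence: float = 1.0


@dataclass
class TrajectorySet:
    """Identity-labelled boxes over frames.

    Serves as ground truth, tracker output, or the unit of a file
    round-trip.  No two records may share the same ``(frame, id)``.
    """

    records: list[TrajectoryRecord] = field(default_factory=list)
    frame_rate: float = 50.0
    frame_size: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        for rec in self.records:
            if rec.id < 1:
                raise MotIntegrityError(f"non-positive id {rec.id} at frame {rec.frame}")
            key = (rec.frame, rec.id)
            if key in seen:
                raise MotIntegrityError(f"duplicate (frame, id) = {key}")
            seen.add(key)

    def sorted_records(self) -> list[TrajectoryRecord]:
        return sorted(self.records, key=lambda r: (r.frame, r.id))

    @property
    def n_frames(self) -> int:
        return max((r.frame for r in self.records), default=0)

    def unique_ids(self) -> set[int]:
        return {r.id for r in self.records}

    def by_frame(self) -> dict[int, list[TrajectoryRecord]]:
        out: dict[int, list[TrajectoryRecord]] = {}
        for rec in self.sorted_records():
            out.setdefault(rec.frame, []).append(rec)
        return out

    def by_id(self) -> dict[int, list[TrajectoryRecord]]:
        out: dict[int, list[TrajectoryRecord]] = {}
        for rec in self.sorted_records():
            out.setdefault(rec.id, []).append(rec)
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrajectoryRecord]:
        return iter(self.records)


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; symmetric, 0 when disjoint."""
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area() + b.area() - inter
    return inter / union


def iou_matrix(rows: Sequence[BBox], cols: Sequence[BBox]):
    """Pairwise IoU as a (len(rows), len(cols)) numpy array."""
    import numpy as np

    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    a = np.array([(b.left, b.top, b.right, b.bottom) for b in rows])
    b = np.array([(c.left, c.top, c.right, c.bottom) for c in cols])
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    inter[(ix <= 0) | (iy <= 0)] = 0.0
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def _fmt(x: float) -> str:
    """Serialize a float at 6 significant digits, integers without a dot."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def read_mot_file(
    path: str | Path,
    frame_rate: float = 50.0,
    frame_size: tuple[int, int] = (640, 480),
) -> TrajectorySet:
    """Read a MOTChallenge-format CSV into a :class:`TrajectorySet`.

    Lines with ``id = -1`` (raw detections) are rejected here; use
    :func:`read_mot_detections` for detection files.
    """
    records = []
    for lineno, parts in _iter_mot_lines(path):
        frame, oid = int(float(parts[0])), int(float(parts[1]))
        box = _parse_box(parts, lineno, path)
        records.append(TrajectoryRecord(frame, oid, box, float(parts[6])))
    try:
        return TrajectorySet(records, frame_rate=frame_rate, frame_size=frame_size)
    except MotIntegrityError as exc:
        raise MotIntegrityError(f"{path}: {exc}") from exc


def read_mot_detections(path: str | Path) -> list[Detection]:
    """Read a MOTChallenge detection file (ids ignored) into Detections."""
    dets = []
    for lineno, parts in _iter_mot_lines(path):
        frame = int(float(parts[0]))
        box = _parse_box(parts, lineno, path)
        dets.append(Detection(frame, box, float(parts[6])))
    dets.sort(key=lambda d: d.frame)
    return dets


def _iter_mot_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotParseError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                [float(p) for p in parts[:7]]
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: {exc}") from exc
            yield lineno, parts


def _parse_box(parts: list[str], lineno: int, path) -> BBox:
    try:
        return BBox(float(parts[2]), float(parts[3]), float(parts[4]), float(parts[5]))
    except ValueError as exc:
        raise MotParseError(f"{path}:{lineno}: {exc}") from exc


def write_mot_file(tset: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory set as MOTChallenge CSV, sorted by (frame, id)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in tset.sorted_records():
            b = rec.box
            fh.write(
                f"{rec.frame},{rec.id},{_fmt(b.left)},{_fmt(b.top)},"
                f"{_fmt(b.width)},{_fmt(b.height)},{_fmt(rec.confidence)},-1,-1,-1\n"
            )


def write_mot_detections(dets: Iterable[Detection], path: str | Path) -> None:
    """Write detections (id column = -1) as MOTChallenge CSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in sorted(dets, key=lambda d: d.frame):
            b = d.box
            fh.write(
                f"{d.frame},-1,{_fmt(b.left)},{_fmt(b.top)},"
                f"{_fmt(b.width)},{_fmt(b.height)},{_fmt(d.confidence)},-1,-1,-1\n"
            )


def downsample(tset: TrajectorySet, keep_every: int) -> TrajectorySet:
    """Temporal downsampling: keep every ``keep_every``-th frame.

    Retains frames with ``(frame - 1) % keep_every == 0``, renumbers them
    consecutively from 1 and divides the frame rate accordingly — e.g.
    keep-every-4 turns a 50 fps sequence into 12.5 fps.
    """
    if keep_every < 1:
        raise ValueError(f"keep_every must be >= 1, got {keep_every}")
    records = [
        replace(rec, frame=(rec.frame - 1) // keep_every + 1)
        for rec in tset.records
        if (rec.frame - 1) % keep_every == 0
    ]
    return TrajectorySet(
        records,
        frame_rate=tset.frame_rate / keep_every,
        frame_size=tset.frame_size,
    )
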