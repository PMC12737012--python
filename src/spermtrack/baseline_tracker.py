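"""BoT-SORT-style tracking-by-detection baseline.

Each track carries an 8-dimensional constant-velocity linear Kalman
state ``(xc, yc, w, h, dxc, dyc, dw, dh)`` over box centre, size and
their per-frame rates.  Per frame the tracker predicts all tracks,
splits the detections by confidence, and associates in two stages:
high-confidence detections against live tracks first, low-confidence
detections against the remainder second (the ByteTrack association
policy).  Assignment is the optimal bipartite matching under the
1 - IoU cost, with pairs below a minimum IoU discarded afterwards.

Lifecycle: new tracks start tentative from unmatched high-confidence
detections, are promoted to confirmed after ``n_init`` consecutive
hits, drop to lost when unmatched, and are deleted after ``max_lost``
frames without a match.  Confirmed duplicate tracks with very high
mutual overlap are suppressed (younger deleted).  Only confirmed tracks
are emitted, so track ids strictly increase and are never reused.

Camera-motion compensation is omitted: the microscope stage is static.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from spermtrack.core_io import BBox, Detection, iou_matrix

__all__ = [
    "TrackStatus",
    "Track",
    "TrackerConfig",
    "BaselineTracker",
    "split_by_confidence",
    "associate",
    "kf8_predict",
    "kf8_update",
]

_DIM = 8
_F = np.eye(_DIM)
_F[:4, 4:] = np.eye(4)  # dt = 1 frame
_H8 = np.zeros((4, _DIM))
_H8[:4, :4] = np.eye(4)

# Box-size-relative noise scales, standard SORT-family practice.
_STD_POS = 1.0 / 20.0
_STD_VEL = 1.0 / 160.0


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    LOST = "lost"


@dataclass
class TrackerConfig:
    """Thresholds and lifecycle constants of the baseline tracker.

    ``tau_high`` / ``eta_low`` are the confidence split thresholds of
    the two-stage association (defaults 0.50 / 0.10, the operating
    point that balances recall against identity stability).
    ``iou_min_first`` / ``iou_min_second`` gate the two association
    stages; ``n_init`` consecutive hits confirm a track; ``max_lost``
    frames without a match delete it.
    """

    tau_high: float = 0.50
    eta_low: float = 0.10
    iou_min_first: float = 0.30
    iou_min_second: float = 0.30
    n_init: int = 3
    max_lost: int = 30
    duplicate_iou: float = 0.85
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta_low < self.tau_high <= 1.0):
            raise ValueError("need 0 <= eta_low < tau_high <= 1")
        for name in ("iou_min_first", "iou_min_second", "duplicate_iou"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_init < 1 or self.max_lost < 1:
            raise ValueError("n_init and max_lost must be >= 1")


@dataclass
class Track:
    """Bookkeeping for one baseline identity."""

    track_id: int
    kf_mean: np.ndarray
    kf_cov: np.ndarray
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    consecutive_misses: int = 0
    last_seen: int = 0
    age: int = 0

    @property
    def box(self) -> BBox:
        xc, yc, w, h = self.kf_mean[:4]
        return BBox.from_cxcywh(float(xc), float(yc), max(float(w), 1e-6), max(float(h), 1e-6))


def split_by_confidence(
    dets: Sequence[Detection], cfg: TrackerConfig
) -> tuple[list[Detection], list[Detection]]:
    """Partition one frame's detections into (high, low) confidence groups.

    High: score > tau_high.  Low: eta_low < score <= tau_high.  Scores
    at or below eta_low are discarded.  Order is preserved.
    """
    high = [d for d in dets if d.confidence > cfg.tau_high]
    low = [d for d in dets if cfg.eta_low < d.confidence <= cfg.tau_high]
    return high, low


def _process_noise(h: float, scale: float) -> np.ndarray:
    std = np.array([_STD_POS * h] * 2 + [_STD_POS * h] * 2 + [_STD_VEL * h] * 4)
    return np.diag((scale * std) ** 2)


def _measurement_noise(h: float, scale: float) -> np.ndarray:
    std = np.array([_STD_POS * h] * 4)
    return np.diag((scale * std) ** 2)


def _init_track(track_id: int, det: Detection, cfg: TrackerConfig, frame: int) -> Track:
    xc, yc, w, h = det.box.to_cxcywh()
    mean = np.array([xc, yc, w, h, 0.0, 0.0, 0.0, 0.0])
    std = np.array(
        [2 * _STD_POS * h] * 4 + [10 * _STD_VEL * h] * 4
    )
    cov = np.diag(std**2)
    return Track(track_id, mean, cov, TrackStatus.TENTATIVE, hits=1, last_seen=frame)


def kf8_predict(t: Track, cfg: TrackerConfig) -> Track:
    """Constant-velocity prediction of the 8-dim box state (in place)."""
    h = float(t.kf_mean[3])
    t.kf_mean = _F @ t.kf_mean
    t.kf_cov = _F @ t.kf_cov @ _F.T + _process_noise(h, cfg.process_noise_scale)
    t.age += 1
    return t


def kf8_update(t: Track, det: Detection, cfg: TrackerConfig, frame: int) -> Track:
    """Linear Kalman correction of a matched track with its detection."""
    z = np.array(det.box.to_cxcywh())
    h = float(t.kf_mean[3])
    R = _measurement_noise(h, cfg.measurement_noise_scale)
    S = _H8 @ t.kf_cov @ _H8.T + R
    try:
        K = np.linalg.solve(S.T, (t.kf_cov @ _H8.T).T).T
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError("singular innovation covariance") from exc
    t.kf_mean = t.kf_mean + K @ (z - _H8 @ t.kf_mean)
    cov = (np.eye(_DIM) - K @ _H8) @ t.kf_cov
    t.kf_cov = (cov + cov.T) / 2.0
    # keep the box physically valid
    t.kf_mean[2] = max(t.kf_mean[2], 1e-6)
    t.kf_mean[3] = max(t.kf_mean[3], 1e-6)
    t.hits += 1
    t.consecutive_misses = 0
    t.last_seen = frame
    if t.status is TrackStatus.LOST:
        t.status = TrackStatus.CONFIRMED
    if t.status is TrackStatus.TENTATIVE and t.hits >= cfg.n_init:
        t.status = TrackStatus.CONFIRMED
    return t


def associate(
    tracks: Sequence[Track],
    dets: Sequence[Detection],
    iou_min: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal IoU assignment of detections to tracks.

    Returns (matches, unmatched_track_indices, unmatched_det_indices),
    where matches are (track_index, det_index) pairs.  The assignment
    globally minimizes the summed 1 - IoU cost; pairs whose IoU falls
    below ``iou_min`` are removed afterwards and their members returned
    as unmatched.  Matches are reported sorted by track index.
    """
    if not tracks or not dets:
        return [], list(range(len(tracks))), list(range(len(dets)))
    ious = iou_matrix([t.box for t in tracks], [d.box for d in dets])
    cost = 1.0 - ious
    rows, cols = linear_sum_assignment(cost)
    matches = []
    matched_t, matched_d = set(), set()
    for r, c in sorted(zip(rows, cols)):
        if ious[r, c] >= iou_min and ious[r, c] > 0.0:
            matches.append((int(r), int(c)))
            matched_t.add(int(r))
            matched_d.add(int(c))
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_t]
    unmatched_dets = [j for j in range(len(dets)) if j not in matched_d]
    return matches, unmatched_tracks, unmatched_dets


class BaselineTracker:
    """Stateful frame-by-frame tracker; call :meth:`step` per frame."""

    def __init__(self, cfg: TrackerConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0

    def step(self, frame: int, frame_dets: Sequence[Detection]) -> list[tuple[int, BBox]]:
        """Advance one frame; returns (track_id, box) for confirmed tracks."""
        if frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing, got {frame} after {self._last_frame}"
            )
        for d in frame_dets:
            if d.frame != frame:
                raise ValueError(f"detection frame {d.frame} != step frame {frame}")
        self._last_frame = frame
        cfg = self.cfg

        for t in self.tracks:
            kf8_predict(t, cfg)

        high, low = split_by_confidence(frame_dets, cfg)

        # Stage 1: confirmed + lost tracks vs high-confidence detections.
        live_idx = [
            i for i, t in enumerate(self.tracks)
            if t.status in (TrackStatus.CONFIRMED, TrackStatus.LOST)
        ]
        live = [self.tracks[i] for i in live_idx]
        m1, um_live, um_high = associate(live, high, cfg.iou_min_first)
        for r, c in m1:
            kf8_update(live[r], high[c], cfg, frame)

        # Stage 2: remaining live tracks vs low-confidence detections.
        rem_live = [live[i] for i in um_live]
        m2, um_live2, _ = associate(rem_live, low, cfg.iou_min_second)
        for r, c in m2:
            kf8_update(rem_live[r], low[c], cfg, frame)

        # Tentative tracks see only the high-confidence leftovers (stage 1 only).
        tent = [t for t in self.tracks if t.status is TrackStatus.TENTATIVE]
        rem_high = [high[j] for j in um_high]
        m3, um_tent, um_high2 = associate(tent, rem_high, cfg.iou_min_first)
        for r, c in m3:
            kf8_update(tent[r], rem_high[c], cfg, frame)

        # Misses: live tracks go lost, then die after max_lost frames;
        # tentative tracks die on their first miss.
        dead: set[int] = set()
        for t in (rem_live[i] for i in um_live2):
            t.consecutive_misses += 1
            t.status = TrackStatus.LOST
            if t.consecutive_misses > cfg.max_lost:
                dead.add(t.track_id)
        for t in (tent[i] for i in um_tent):
            dead.add(t.track_id)

        # Births from unmatched high-confidence detections.
        for j in um_high2:
            self.tracks.append(_init_track(self._next_id, rem_high[j], cfg, frame))
            self._next_id += 1

        self.tracks = [t for t in self.tracks if t.track_id not in dead]
        self._suppress_duplicates()

        return [
            (t.track_id, t.box)
            for t in self.tracks
            if t.status is TrackStatus.CONFIRMED and t.last_seen == frame
        ]

    def _suppress_duplicates(self) -> None:
        confirmed = [t for t in self.tracks if t.status is TrackStatus.CONFIRMED]
        if len(confirmed) < 2:
            return
        ious = iou_matrix([t.box for t in confirmed], [t.box for t in confirmed])
        doomed: set[int] = set()
        for i in range(len(confirmed)):
            for j in range(i + 1, len(confirmed)):
                if ious[i, j] > self.cfg.duplicate_iou:
                    a, b = confirmed[i], confirmed[j]
                    if a.track_id in doomed or b.track_id in doomed:
                        continue
                    # delete the younger (higher id) of the pair
                    doomed.add(max(a.track_id, b.track_id))
        if doomed:
            self.tracks = [t for t in self.tracks if t.track_id not in doomed]
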