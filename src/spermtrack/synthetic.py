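"""Synthetic microscopy-detection simulator.

Generates ground-truth trajectories with the statistical structure the
tracking method assumes — curvilinear swimming produced by a per-frame
heading random walk over the unicycle motion map, inside a 640 x 480
px field at ~50 fps — and degrades them into detector-like output:
independent per-frame dropouts, contiguous burst dropouts (the
occlusion failure mode), isotropic centroid jitter and a confidence
mixture.  Density regimes span roughly 10 (low) to 65 (high) objects
per frame, the high end matching crowded samples of 60-70 cells per
frame.

Objects reflect off the frame edges, so the ground-truth identity
count is constant over the sequence: any identity overcount measured
against it is attributable to the tracker alone.

All randomness flows from one seeded generator; equal seeds give
byte-identical emitted files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from spermtrack.core_io import BBox, Detection, TrajectoryRecord, TrajectorySet

__all__ = ["SimConfig", "simulate_ground_truth", "degrade_to_detections", "scenario"]


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate a medium-density sample."""

    n_objects: int = 35
    frame_size: tuple[int, int] = (640, 480)
    frame_rate: float = 50.0
    n_frames: int = 150
    speed_mean: float = 3.0  # px/frame
    speed_sd: float = 1.0
    turn_rate_sd: float = 0.15  # rad/frame, heading random walk
    turn_rate_mean: float = 0.0  # constant-turn component (rad/frame)
    box_w: float = 15.0
    box_h: float = 15.0
    detection_noise_sd: float = 1.0  # px
    dropout_prob: float = 0.05
    burst_dropout: tuple[float, int, int] = (0.01, 3, 10)  # (per-frame start prob, min, max len)
    conf_high_range: tuple[float, float] = (0.60, 0.99)
    conf_low_range: tuple[float, float] = (0.15, 0.50)
    low_conf_prob: float = 0.15
    # Explicit occlusion windows: (object_index, start_frame, n_frames).
    forced_gaps: tuple[tuple[int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame_size must be positive")
        for name in ("dropout_prob", "low_conf_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.burst_dropout[0] <= 1.0):
            raise ValueError("burst start probability must be in [0, 1]")


def simulate_ground_truth(cfg: SimConfig) -> TrajectorySet:
    """Generate continuous ground-truth trajectories.

    Each object draws a speed from a truncated normal and walks the
    unicycle map with per-frame heading increments drawn from
    Normal(turn_rate_mean, turn_rate_sd); positions reflect at the
    frame edges (heading mirrored), keeping every identity present in
    every frame.
    """
    rng = np.random.default_rng(cfg.seed)
    W, H = cfg.frame_size
    n = cfg.n_objects

    x = rng.uniform(0, W, size=n)
    y = rng.uniform(0, H, size=n)
    theta = rng.uniform(-math.pi, math.pi, size=n)
    speed = np.maximum(rng.normal(cfg.speed_mean, cfg.speed_sd, size=n), 0.0)

    records: list[TrajectoryRecord] = []
    for frame in range(1, cfg.n_frames + 1):
        for i in range(n):
            records.append(
                TrajectoryRecord(
                    frame=frame,
                    id=i + 1,
                    box=BBox.from_cxcywh(float(x[i]), float(y[i]), cfg.box_w, cfg.box_h),
                    confidence=1.0,
                )
            )
        # advance to the next frame
        theta = theta + rng.normal(cfg.turn_rate_mean, cfg.turn_rate_sd, size=n)
        x = x + speed * np.cos(theta)
        y = y + speed * np.sin(theta)
        # reflective boundaries: fold position, mirror heading
        for i in range(n):
            xi, ti_flip_x = _reflect(x[i], W)
            yi, ti_flip_y = _reflect(y[i], H)
            x[i], y[i] = xi, yi
            if ti_flip_x:
                theta[i] = math.pi - theta[i]
            if ti_flip_y:
                theta[i] = -theta[i]
    return TrajectorySet(records, frame_rate=cfg.frame_rate, frame_size=cfg.frame_size)


def _reflect(p: float, limit: float) -> tuple[float, bool]:
    """Fold a coordinate back into [0, limit]; report whether it bounced."""
    bounced = False
    while p < 0 or p > limit:
        if p < 0:
            p = -p
        else:
            p = 2 * limit - p
        bounced = True
    return p, bounced


def degrade_to_detections(gt: TrajectorySet, cfg: SimConfig) -> list[Detection]:
    """Turn ground truth into detector-like output.

    Per object per frame the box is dropped with ``dropout_prob``, or
    because a burst dropout (contiguous occlusion window) covers the
    frame; surviving boxes get isotropic Gaussian centroid jitter and
    a confidence drawn from the low range with probability
    ``low_conf_prob``, else from the high range.  Frame indices are
    never moved — degradation only deletes or jitters.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    by_id = gt.by_id()
    ids = sorted(by_id)
    n_frames = gt.n_frames

    # occlusion windows per object: forced first, then random bursts
    occluded: dict[int, set[int]] = {oid: set() for oid in ids}
    for obj_idx, start, length in cfg.forced_gaps:
        oid = ids[obj_idx]
        occluded[oid].update(range(start, start + length))
    p_burst, bmin, bmax = cfg.burst_dropout
    if p_burst > 0:
        for oid in ids:
            f = 1
            while f <= n_frames:
                if rng.random() < p_burst:
                    length = int(rng.integers(bmin, bmax + 1))
                    occluded[oid].update(range(f, f + length))
                    f += length
                else:
                    f += 1

    dets: list[Detection] = []
    for oid in ids:
        for rec in by_id[oid]:
            if rec.frame in occluded[oid]:
                continue
            if cfg.dropout_prob > 0 and rng.random() < cfg.dropout_prob:
                continue
            xc, yc, w, h = rec.box.to_cxcywh()
            if cfg.detection_noise_sd > 0:
                xc += rng.normal(0, cfg.detection_noise_sd)
                yc += rng.normal(0, cfg.detection_noise_sd)
            if cfg.low_conf_prob > 0 and rng.random() < cfg.low_conf_prob:
                conf = rng.uniform(*cfg.conf_low_range)
            else:
                conf = rng.uniform(*cfg.conf_high_range)
            dets.append(Detection(rec.frame, BBox.from_cxcywh(xc, yc, w, h), float(conf)))
    dets.sort(key=lambda d: d.frame)
    return dets


_SCENARIOS = {
    "low": dict(n_objects=10),
    "medium": dict(n_objects=35),
    "high": dict(
        n_objects=65,
        dropout_prob=0.08,
        burst_dropout=(0.02, 3, 12),
        turn_rate_sd=0.20,
    ),
    # Strong curvilinearity: stresses heading prediction, used for the
    # heading-state ablation.
    "high_turn": dict(
        n_objects=30,
        n_frames=150,
        turn_rate_sd=0.30,
        detection_noise_sd=2.0,
        dropout_prob=0.05,
        burst_dropout=(0.02, 3, 12),
    ),
    # Controlled occlusion study: clean detections except for explicit
    # gaps, one of which exceeds the default lost-track buffer (30
    # frames, unrecoverable) while the others are short enough for the
    # reassignment layer to bridge.
    "gap_test": dict(
        n_objects=5,
        n_frames=150,
        turn_rate_sd=0.25,
        dropout_prob=0.0,
        burst_dropout=(0.0, 0, 0),
        low_conf_prob=0.0,
        forced_gaps=(
            (0, 40, 8),
            (1, 60, 10),
            (2, 80, 6),
            (3, 50, 36),  # longer than the 30-frame buffer
        ),
    ),
}


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named density/occlusion regimes used throughout the test battery."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update(overrides)
    return SimConfig(seed=seed, **params)
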