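"""CASA motility parameters from tracked centroid trajectories.

Three standard kinematic descriptors per cell:

* VCL (curvilinear velocity): total point-to-point path length divided
  by the trajectory duration, in px/s.
* VSL (straight-line velocity): distance from first to last observed
  point divided by duration, in px/s.
* LIN (linearity): VSL / VCL, dimensionless in [0, 1] by the triangle
  inequality.

The reciprocal ratio VCL / VSL is also reported, clearly labelled,
since some published summaries tabulate the ratio in that orientation;
emitting both lets either convention be checked directly.

Trajectories with gaps (frames where the identity was lost) are by
default segmented at the gaps for the VCL path sum — a straight hop
bridging a gap is not an observed path and would inflate VCL — while
VSL and the duration always use the first and last observed points.
Set ``bridge_gaps=True`` to sum hops across gaps as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from spermtrack.core_io import TrajectorySet

__all__ = ["CentroidTrajectory", "MotilityResult", "motility_params", "motility_table"]


@dataclass(frozen=True)
class CentroidTrajectory:
    """Centroid positions of one cell at retained frames.

    ``frames`` are the (1-based) frame indices of the points; when
    omitted, points are assumed consecutive.  Duration T spans first
    to last frame: T = (frame_last - frame_first) / frame_rate.
    """

    points: tuple[tuple[float, float], ...]
    frame_rate: float
    frames: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frames is not None:
            if len(self.frames) != len(self.points):
                raise ValueError("frames and points must have equal length")
            if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
                raise ValueError("frames must be strictly increasing")

    @property
    def duration(self) -> float:
        """Trajectory duration T in seconds."""
        if self.frames is None:
            return (len(self.points) - 1) / self.frame_rate
        return (self.frames[-1] - self.frames[0]) / self.frame_rate


@dataclass(frozen=True)
class MotilityResult:
    vcl: float  # px/s
    vsl: float  # px/s
    lin: Optional[float]  # VSL/VCL, None when VCL == 0
    vcl_over_vsl: Optional[float]  # reciprocal ratio, None when VSL == 0


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(b[0] - a[0], b[1] - a[1])


def motility_params(traj: CentroidTrajectory, bridge_gaps: bool = False) -> MotilityResult:
    """Compute VCL, VSL, LIN (and VCL/VSL) for one trajectory."""
    T = traj.duration
    if T <= 0:
        raise ValueError("trajectory duration must be positive")

    pts = traj.points
    frames = traj.frames or tuple(range(1, len(pts) + 1))
    path = 0.0
    for (fa, a), (fb, b) in zip(zip(frames, pts), zip(frames[1:], pts[1:])):
        if bridge_gaps or fb - fa == 1:
            path += _dist(a, b)
    vcl = path / T
    vsl = _dist(pts[0], pts[-1]) / T
    lin = vsl / vcl if vcl > 0 else None
    vcl_over_vsl = vcl / vsl if vsl > 0 else None
    return MotilityResult(vcl=vcl, vsl=vsl, lin=lin, vcl_over_vsl=vcl_over_vsl)


def motility_table(
    tset: TrajectorySet, frame_rate: Optional[float] = None, bridge_gaps: bool = False
) -> pd.DataFrame:
    """Per-id motility parameters of a tracked trajectory set.

    Returns a DataFrame with columns id, n_frames, VCL, VSL, LIN,
    VCL_over_VSL; identities observed in fewer than 2 frames are
    skipped (no velocity is defined for them).
    """
    fps = frame_rate if frame_rate is not None else tset.frame_rate
    rows = []
    for oid, recs in sorted(tset.by_id().items()):
        if len(recs) < 2:
            continue
        traj = CentroidTrajectory(
            points=tuple(r.box.center for r in recs),
            frame_rate=fps,
            frames=tuple(r.frame for r in recs),
        )
        res = motility_params(traj, bridge_gaps=bridge_gaps)
        rows.append(
            {
                "id": oid,
                "n_frames": len(recs),
                "VCL": res.vcl,
                "VSL": res.vsl,
                "LIN": res.lin if res.lin is not None else np.nan,
                "VCL_over_VSL": res.vcl_over_vsl if res.vcl_over_vsl is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["id", "n_frames", "VCL", "VSL", "LIN", "VCL_over_VSL"])
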