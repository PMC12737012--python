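"""Multi-object tracking evaluation: CLEAR-MOT, identity metrics,
unique-id overcount and track-duration statistics.

CLEAR-MOT performs per-frame matching with temporal continuity:
correspondences surviving from the previous frame (IoU still above the
threshold) are kept, the remainder are matched by optimal assignment
on IoU.  MOTA = 1 - (FN + FP + IDSW) / total ground-truth boxes; MOTP
is reported as the mean (1 - IoU) distance over matched pairs, a
dimensionless quantity in [0, 1].  An id switch is counted when a
ground-truth object's matched predicted id differs from the predicted
id it was last matched to.

Identity metrics (IDF1/IDP/IDR) come from a single global bipartite
matching between ground-truth and predicted trajectories that
minimizes total misses plus false positives under exclusive
one-to-one assignment, the standard trajectory-level formulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from spermtrack.core_io import TrajectorySet, iou, iou_matrix

__all__ = [
    "MetricsReport",
    "clear_mot",
    "identity_metrics",
    "overcount_stats",
    "duration_stats",
    "evaluate",
]


@dataclass
class MetricsReport:
    """All scalar evaluation outputs; ratios stored in [0, 1]."""

    idf1: Optional[float] = None
    idp: Optional[float] = None
    idr: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    mota: Optional[float] = None
    motp: Optional[float] = None
    idsw: Optional[int] = None
    fp: Optional[int] = None
    fn: Optional[int] = None
    unique_pred_ids: Optional[int] = None
    unique_gt_ids: Optional[int] = None
    overcount_ratio: Optional[float] = None
    extra_ids: Optional[int] = None
    duration_mean: Optional[float] = None
    duration_median: Optional[float] = None
    duration_iqr: Optional[float] = None

    def merged_with(self, other: "MetricsReport") -> "MetricsReport":
        """Combine two partial reports; non-None fields of other win."""
        data = asdict(self)
        for k, v in asdict(other).items():
            if v is not None:
                data[k] = v
        return MetricsReport(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_display_lines(self) -> list[str]:
        """Table-style text rendering: percentages to 2 decimals."""
        def pct(x):
            return f"{100 * x:.2f}%" if x is not None else "-"

        lines = [
            f"IDF1          {pct(self.idf1)}",
            f"ID Precision  {pct(self.idp)}",
            f"ID Recall     {pct(self.idr)}",
            f"Precision     {pct(self.precision)}",
            f"Recall        {pct(self.recall)}",
            f"ID Switches   {self.idsw if self.idsw is not None else '-'}",
            f"MOTA          {pct(self.mota)}",
            f"MOTP          {f'{self.motp:.6f}' if self.motp is not None else '-'}",
        ]
        if self.overcount_ratio is not None:
            lines.append(f"Unique IDs    {self.unique_pred_ids}")
            lines.append(f"Overcount     {self.overcount_ratio:.2f}x (+{self.extra_ids})")
        if self.duration_mean is not None:
            lines.append(f"Avg Duration  {self.duration_mean:.1f} frames")
        return lines


def clear_mot(gt: TrajectorySet, pred: TrajectorySet, iou_thresh: float = 0.5) -> MetricsReport:
    """Frame-level CLEAR-MOT scores of ``pred`` against ``gt``."""
    if len(gt) == 0:
        raise ValueError("ground truth is empty: MOTA undefined")
    gt_frames = gt.by_frame()
    pred_frames = pred.by_frame()
    all_frames = sorted(set(gt_frames) | set(pred_frames))

    total_gt = len(gt)
    tp = fp = fn = idsw = 0
    dist_sum = 0.0
    # gt id -> pred id last matched (for continuity and switch counting)
    last_match: dict[int, int] = {}

    for f in all_frames:
        g = gt_frames.get(f, [])
        p = pred_frames.get(f, [])
        g_ids = [r.id for r in g]
        p_ids = [r.id for r in p]
        p_index = {pid: j for j, pid in enumerate(p_ids)}

        matches: dict[int, int] = {}  # gt index -> pred index
        # (a) keep surviving correspondences from previous frames
        used_p: set[int] = set()
        for i, gid in enumerate(g_ids):
            pid = last_match.get(gid)
            if pid is not None and pid in p_index and p_index[pid] not in used_p:
                j = p_index[pid]
                if iou(g[i].box, p[j].box) >= iou_thresh:
                    matches[i] = j
                    used_p.add(j)
        # (b) optimal assignment for the rest
        free_g = [i for i in range(len(g)) if i not in matches]
        free_p = [j for j in range(len(p)) if j not in used_p]
        if free_g and free_p:
            ious = iou_matrix([g[i].box for i in free_g], [p[j].box for j in free_p])
            rows, cols = linear_sum_assignment(1.0 - ious)
            for r, c in zip(rows, cols):
                if ious[r, c] >= iou_thresh:
                    matches[free_g[r]] = free_p[c]
                    used_p.add(free_p[c])

        tp += len(matches)
        fn += len(g) - len(matches)
        fp += len(p) - len(matches)
        for i, j in matches.items():
            gid, pid = g_ids[i], p_ids[j]
            dist_sum += 1.0 - iou(g[i].box, p[j].box)
            if gid in last_match and last_match[gid] != pid:
                idsw += 1
            last_match[gid] = pid

    mota = 1.0 - (fn + fp + idsw) / total_gt
    motp = dist_sum / tp if tp > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    return MetricsReport(
        precision=precision, recall=recall, mota=mota, motp=motp,
        idsw=idsw, fp=fp, fn=fn,
    )


def identity_metrics(
    gt: TrajectorySet, pred: TrajectorySet, iou_thresh: float = 0.5
) -> MetricsReport:
    """Trajectory-level IDF1 / IDP / IDR via global optimal matching."""
    if len(gt) == 0:
        raise ValueError("ground truth is empty: identity metrics undefined")
    gt_tracks = gt.by_id()
    pred_tracks = pred.by_id()
    g_ids = sorted(gt_tracks)
    p_ids = sorted(pred_tracks)
    nG, nP = len(g_ids), len(p_ids)

    # overlap[i, j]: frames where gt i and pred j coincide above
    # threshold, accumulated frame by frame with vectorized IoU
    g_index = {gid: i for i, gid in enumerate(g_ids)}
    p_index = {pid: j for j, pid in enumerate(p_ids)}
    overlap = np.zeros((nG, nP))
    gt_frames = gt.by_frame()
    pred_frames = pred.by_frame()
    for f in set(gt_frames) & set(pred_frames):
        g = gt_frames[f]
        p = pred_frames[f]
        ious = iou_matrix([r.box for r in g], [r.box for r in p])
        hit_r, hit_c = np.nonzero(ious >= iou_thresh)
        for r, c in zip(hit_r, hit_c):
            overlap[g_index[g[r].id], p_index[p[c].id]] += 1

    g_len = np.array([len(gt_tracks[gid]) for gid in g_ids], dtype=float)
    p_len = np.array([len(pred_tracks[pid]) for pid in p_ids], dtype=float)

    # square cost matrix with dummy rows/cols for unmatched trajectories:
    # pairing (i, j) costs its misses + false positives; leaving a
    # trajectory unmatched costs its full length.
    n = nG + nP
    cost = np.zeros((n, n))
    cost[:nG, :nP] = (g_len[:, None] - overlap) + (p_len[None, :] - overlap)
    cost[:nG, nP:] = np.inf
    cost[nG:, :nP] = np.inf
    np.fill_diagonal(cost[:nG, nP:], g_len)
    np.fill_diagonal(cost[nG:, :nP], p_len)

    rows, cols = linear_sum_assignment(cost)
    idtp = 0.0
    for r, c in zip(rows, cols):
        if r < nG and c < nP:
            idtp += overlap[r, c]
    total_gt = float(g_len.sum())
    total_pred = float(p_len.sum())
    idfn = total_gt - idtp
    idfp = total_pred - idtp
    idp = idtp / (idtp + idfp) if idtp + idfp > 0 else 0.0
    idr = idtp / (idtp + idfn) if idtp + idfn > 0 else 0.0
    idf1 = 2 * idtp / (2 * idtp + idfp + idfn) if (2 * idtp + idfp + idfn) > 0 else 0.0
    return MetricsReport(idf1=idf1, idp=idp, idr=idr)


def overcount_stats(gt: TrajectorySet, pred: TrajectorySet) -> MetricsReport:
    """Unique-id inflation of the prediction relative to ground truth."""
    n_gt = len(gt.unique_ids())
    n_pred = len(pred.unique_ids())
    return overcount_from_counts(n_pred, n_gt)


def overcount_from_counts(n_pred: int, n_gt: int) -> MetricsReport:
    """Overcount ratio and extra-id count from raw unique-id counts."""
    if n_gt == 0:
        raise ValueError("no ground-truth ids: overcount ratio undefined")
    return MetricsReport(
        unique_pred_ids=n_pred,
        unique_gt_ids=n_gt,
        overcount_ratio=n_pred / n_gt,
        extra_ids=n_pred - n_gt,
    )


def duration_stats(pred: TrajectorySet) -> MetricsReport:
    """Per-id track durations: frames of actual presence (gaps excluded)."""
    if len(pred) == 0:
        raise ValueError("empty trajectory set: durations undefined")
    durations = np.array([len(v) for v in pred.by_id().values()], dtype=float)
    q25, q75 = np.percentile(durations, [25, 75])
    return MetricsReport(
        duration_mean=float(durations.mean()),
        duration_median=float(np.median(durations)),
        duration_iqr=float(q75 - q25),
    )


def evaluate(
    gt: TrajectorySet, pred: TrajectorySet, iou_thresh: float = 0.5
) -> MetricsReport:
    """Full report: CLEAR-MOT + identity + overcount + durations."""
    report = clear_mot(gt, pred, iou_thresh)
    report = report.merged_with(identity_metrics(gt, pred, iou_thresh))
    report = report.merged_with(overcount_stats(gt, pred))
    if len(pred) > 0:
        report = report.merged_with(duration_stats(pred))
    return report
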