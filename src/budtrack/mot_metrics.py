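"""Multiple-object-tracking benchmark metrics.

MOTA is computed with the standard formula

    MOTA = 1 - sum_t(FN_t + FP_t + IDSW_t) / sum_t GT_t

where per-frame matching between ground truth and prediction is the optimal
one-to-one IoU matching (pairs kept above IoU 0.5, the MOT-challenge
convention).  An identity switch is counted only the first time a ground-
truth trajectory transitions to a given predicted identity; the total time
spent matched to a non-original identity is reported separately as the
switch duration, since one permanent switch costs one IDSW but may require
hundreds of manual ID edits.

The link-based F-score follows the lineage-benchmark convention: a link is
a pair of consecutive points of one trajectory; precision = c/R and
recall = c/G with c the correctly predicted links, R the predicted links
and G the ground-truth links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_model import LabelFrame, LabelMovie, ShapeError

IOU_MATCH_THRESHOLD = 0.5


@dataclass
class MOTReport:
    fn_t: list[int] = field(default_factory=list)
    fp_t: list[int] = field(default_factory=list)
    idsw_t: list[int] = field(default_factory=list)
    gt_t: list[int] = field(default_factory=list)
    mota: float = 1.0
    switch_duration_frames: int = 0
    correct_links: int = 0
    pred_links: int = 0
    gt_links: int = 0
    precision: float = 0.0
    recall: float = 0.0
    fscore: float = 0.0

    @property
    def fn(self) -> int:
        return int(sum(self.fn_t))

    @property
    def fp(self) -> int:
        return int(sum(self.fp_t))

    @property
    def idsw(self) -> int:
        return int(sum(self.idsw_t))

    def to_dict(self) -> dict:
        return {
            "mota": self.mota,
            "fn": self.fn,
            "fp": self.fp,
            "idsw": self.idsw,
            "switch_duration_frames": self.switch_duration_frames,
            "correct_links": self.correct_links,
            "pred_links": self.pred_links,
            "gt_links": self.gt_links,
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
            "fn_t": self.fn_t,
            "fp_t": self.fp_t,
            "idsw_t": self.idsw_t,
            "gt_t": self.gt_t,
        }


def _iou_matrix(gt: LabelFrame, pred: LabelFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = gt.pixels.ravel()
    p = pred.pixels.ravel()
    gt_ids = gt.labels
    pred_ids = pred.labels
    iou = np.zeros((len(gt_ids), len(pred_ids)))
    if len(gt_ids) and len(pred_ids):
        gidx = {int(l): i for i, l in enumerate(gt_ids)}
        pidx = {int(l): j for j, l in enumerate(pred_ids)}
        both = (g > 0) & (p > 0)
        pairs, counts = np.unique(np.stack([g[both], p[both]]), axis=1, return_counts=True)
        g_area = {int(l): int((g == l).sum()) for l in gt_ids}
        p_area = {int(l): int((p == l).sum()) for l in pred_ids}
        for (gl, pl), inter in zip(pairs.T, counts):
            union = g_area[int(gl)] + p_area[int(pl)] - int(inter)
            iou[gidx[int(gl)], pidx[int(pl)]] = inter / union
    return iou, gt_ids, pred_ids


def match_frame(gt: LabelFrame, pred: LabelFrame) -> tuple[dict[int, int], int, int]:
    """Optimal one-to-one IoU matching of one frame.

    Returns (matches: gt label -> pred label, FN, FP); only pairs with
    IoU > 0.5 count as matches, unmatched ground truth as false negatives,
    unmatched predictions as false positives.
    """
    if gt.pixels.shape != pred.pixels.shape:
        raise ShapeError(f"frame shapes differ: {gt.pixels.shape} vs {pred.pixels.shape}")
    iou, gt_ids, pred_ids = _iou_matrix(gt, pred)
    matches: dict[int, int] = {}
    if iou.size:
        rows, cols = linear_sum_assignment(-iou)
        for i, j in zip(rows, cols):
            if iou[i, j] > IOU_MATCH_THRESHOLD:
                matches[int(gt_ids[i])] = int(pred_ids[j])
    fn = len(gt_ids) - len(matches)
    fp = len(pred_ids) - len(matches)
    return matches, fn, fp


def mota(gt: LabelMovie, pred: LabelMovie) -> MOTReport:
    """Full MOT report between a ground-truth and a predicted label movie.

    Trajectories are implied by the label values (one identity per label
    across frames).  IDSW_t counts a (gt trajectory, new predicted identity)
    transition only the first time it occurs; ``switch_duration_frames``
    accumulates every frame a trajectory spends matched to a non-original
    identity.
    """
    if len(gt) != len(pred):
        raise ValueError(f"movie lengths differ: {len(gt)} vs {len(pred)}")
    report = MOTReport()
    last_match: dict[int, int] = {}   # gt id -> last matched pred id
    first_match: dict[int, int] = {}  # gt id -> original pred id
    counted: set[tuple[int, int]] = set()
    per_frame_matches: list[dict[int, int]] = []

    for t in range(len(gt)):
        matches, fn, fp = match_frame(gt[t], pred[t])
        per_frame_matches.append(matches)
        idsw = 0
        for g, p in matches.items():
            if g in last_match and p != last_match[g] and (g, p) not in counted:
                idsw += 1
                counted.add((g, p))
            if g not in first_match:
                first_match[g] = p
            if p != first_match[g]:
                report.switch_duration_frames += 1
            last_match[g] = p
        report.fn_t.append(fn)
        report.fp_t.append(fp)
        report.idsw_t.append(idsw)
        report.gt_t.append(len(gt[t].labels))

    total_gt = sum(report.gt_t)
    errors = sum(report.fn_t) + sum(report.fp_t) + sum(report.idsw_t)
    report.mota = 1.0 - errors / total_gt if total_gt else 1.0

    _links(report, gt, pred, per_frame_matches)
    return report


def _links(report: MOTReport, gt: LabelMovie, pred: LabelMovie, matches: list[dict[int, int]]) -> None:
    gt_presence: dict[int, list[int]] = {}
    pred_presence: dict[int, list[int]] = {}
    for t in range(len(gt)):
        for l in map(int, gt[t].labels):
            gt_presence.setdefault(l, []).append(t)
        for l in map(int, pred[t].labels):
            pred_presence.setdefault(l, []).append(t)

    def n_links(presence: dict[int, list[int]]) -> int:
        # consecutive frames of one identity form a link
        return sum(
            sum(1 for a, b in zip(fr, fr[1:]) if b == a + 1) for fr in presence.values()
        )

    G = n_links(gt_presence)
    R = n_links(pred_presence)
    c = 0
    for l, fr in gt_presence.items():
        for a, b in zip(fr, fr[1:]):
            if b != a + 1:
                continue
            pa = matches[a].get(l)
            pb = matches[b].get(l)
            if pa is not None and pa == pb:
                c += 1
    report.gt_links = G
    report.pred_links = R
    report.correct_links = c
    report.precision = c / R if R else 0.0
    report.recall = c / G if G else 0.0
    denom = report.precision + report.recall
    report.fscore = 2 * report.precision * report.recall / denom if denom else 0.0


def link_fscore(gt: LabelMovie, pred: LabelMovie) -> tuple[int, int, int, float, float, float]:
    """(c, R, G, precision, recall, fscore) of the link-based benchmark."""
    report = mota(gt, pred)
    return (
        report.correct_links,
        report.pred_links,
        report.gt_links,
        report.precision,
        report.recall,
        report.fscore,
    )
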