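"""Footprint evaluation against ChIP-labelled motif sites.

Every labelled motif-predicted binding site receives a prediction
score (the tag count of an overlapping footprint, 0 when none
overlaps).  Accuracy is summarised by partial areas under the ROC
curve (at 100%, 10% and 1% FPR) and under the precision-recall curve
(at 100%, 10% and 1% recall), and methods are compared by summing
-log(r / (N + 1)) over the six measures, where r is a method's rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

FPR_CUTOFFS = (1.0, 0.1, 0.01)
RECALL_CUTOFFS = (1.0, 0.1, 0.01)


@dataclass
class RankedPredictionSet:
    """Per-site prediction scores with binary truth labels."""

    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(bool)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must align")
        if self.labels.all() or not self.labels.any():
            raise ValueError("need at least one positive and one negative label")


def _roc_points(rs: RankedPredictionSet) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-rs.scores, kind="stable")
    labels = rs.labels[order]
    scores = rs.scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(scores)), len(scores) - 1]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(~labels)[distinct]
    tpr = np.r_[0.0, tps / rs.labels.sum()]
    fpr = np.r_[0.0, fps / (~rs.labels).sum()]
    return fpr, tpr


def auc_at_fpr(rs: RankedPredictionSet, max_fpr: float = 1.0) -> float:
    """Trapezoidal ROC area restricted to FPR <= max_fpr, divided by max_fpr."""
    if not 0 < max_fpr <= 1:
        raise ValueError("max_fpr must be in (0, 1]")
    fpr, tpr = _roc_points(rs)
    cut = np.searchsorted(fpr, max_fpr, side="right")
    xs, ys = fpr[:cut], tpr[:cut]
    if xs[-1] < max_fpr:                         # interpolate the boundary point
        y_at = np.interp(max_fpr, fpr, tpr)
        xs, ys = np.r_[xs, max_fpr], np.r_[ys, y_at]
    return float(np.trapezoid(ys, xs) / max_fpr)


def aupr_at_recall(rs: RankedPredictionSet, max_recall: float = 1.0) -> float:
    """Step-interpolated precision-recall area to max_recall, normalised."""
    if not 0 < max_recall <= 1:
        raise ValueError("max_recall must be in (0, 1]")
    order = np.argsort(-rs.scores, kind="stable")
    labels = rs.labels[order]
    scores = rs.scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(scores)), len(scores) - 1]
    tps = np.cumsum(labels)[distinct].astype(float)
    fps = np.cumsum(~labels)[distinct].astype(float)
    recall = tps / rs.labels.sum()
    precision = tps / (tps + fps)
    area = 0.0
    prev_r = 0.0
    for r, p in zip(recall, precision):
        lo, hi = prev_r, min(r, max_recall)
        if hi > lo:
            area += (hi - lo) * p
        prev_r = r
        if r >= max_recall:
            break
    return float(area / max_recall)


def ranking_score(ranks: Sequence[float], n_methods: int) -> float:
    """Sum over measures of -ln(r / (N + 1)); higher is better."""
    ranks = np.asarray(ranks, dtype=float)
    if np.any(ranks < 1) or np.any(ranks > n_methods):
        raise ValueError("ranks must lie in [1, n_methods]")
    return float(np.sum(-np.log(ranks / (n_methods + 1))))


def rank_methods(values: np.ndarray) -> np.ndarray:
    """Per-measure ranks (1 = best = largest value; ties get average rank).

    ``values`` has shape (n_methods, n_measures); the result has the
    same shape.
    """
    values = np.asarray(values, dtype=float)
    return np.stack([rankdata(-values[:, m]) for m in range(values.shape[1])], axis=1)


def score_mpbs_by_footprints(mpbs: Sequence, footprints: Sequence, signal: np.ndarray,
                             region) -> np.ndarray:
    """Tag-count prediction score per motif site; 0 without an overlapping footprint.

    Overlap means at least one shared base; among overlapping
    footprints the largest tag count (over the union of footprint and
    motif interval) is used.
    """
    from .hmm import tag_count_score

    fp_arr = sorted(footprints, key=lambda f: f.start)
    starts = np.array([f.start for f in fp_arr])
    scores = np.zeros(len(mpbs))
    for i, m in enumerate(mpbs):
        j = np.searchsorted(starts, m.end)
        best = 0.0
        for f in fp_arr[:j]:
            if f.end > m.start:
                best = max(best, tag_count_score(f, signal, region, (m.start, m.end)))
        scores[i] = best
    return scores


def evaluation_table(rs: RankedPredictionSet) -> dict[str, float]:
    """The six partial-area measures for one prediction set."""
    out = {}
    for c in FPR_CUTOFFS:
        out[f"auc_{c:g}"] = auc_at_fpr(rs, c)
    for c in RECALL_CUTOFFS:
        out[f"aupr_{c:g}"] = aupr_at_recall(rs, c)
    return out
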