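"""Topology-aware and voxel-wise segmentation metrics.

Centerline metrics follow the airway-benchmark conventions: the tree
length detected rate (TR) is the fraction of ground-truth skeleton
voxels covered by the binarized prediction, and the branch detection
rate (BD) is the fraction of skeleton branches detected.  BD applies a
floor to each branch's coverage fraction, so by default a branch counts
only when *every* one of its skeleton voxels is predicted foreground;
``coverage`` relaxes this to a fractional threshold (0.8 is common
practice) since the strict rule is unusually harsh on long branches.

Voxel-wise scores are the usual precision / recall / F-measure over
TP, FP, FN counts.  Evaluation is whole-volume, not per patch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .skeleton import BranchSet
from .volumes import BinaryVolume, VoxelGrid

__all__ = ["MetricsReport", "binarize", "tree_length_rate",
           "branch_detection_rate", "voxel_scores", "evaluate"]


@dataclass
class MetricsReport:
    tr: float
    bd: float
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int
    n_branches: int

    def as_dict(self) -> dict:
        return asdict(self)


def _unwrap_binary(v) -> np.ndarray:
    arr = v.values if isinstance(v, VoxelGrid) else np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("expected a strictly binary volume")
    return arr.astype(bool)


def binarize(p, threshold: float = 0.5) -> BinaryVolume:
    """Threshold a likelihood volume; a voxel at the threshold maps to 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    arr = p.values if isinstance(p, VoxelGrid) else np.asarray(p)
    out = (np.asarray(arr, dtype=np.float64) >= threshold).astype(np.uint8)
    geom = p.geometry if isinstance(p, VoxelGrid) else None
    return BinaryVolume(out, geom) if geom is not None else BinaryVolume(out)


def tree_length_rate(skel_gt, pred) -> float:
    """TR = sum(s_i * p_hat_i) / sum(s_i) over the ground-truth skeleton."""
    s = _unwrap_binary(skel_gt)
    p = _unwrap_binary(pred)
    if s.shape != p.shape:
        raise ValueError("skeleton and prediction shapes differ")
    total = int(s.sum())
    if total == 0:
        raise ValueError("TR is undefined for an empty skeleton")
    return float((s & p).sum()) / total


def branch_detection_rate(branches: BranchSet, pred, coverage: float = 1.0) -> float:
    """BD = mean over branches of floor-at-``coverage`` detection.

    With ``coverage=1.0`` (default) the floor of each branch's covered
    fraction is taken literally: full coverage or nothing.  A smaller
    ``coverage`` counts a branch once at least that fraction of its
    voxels is predicted foreground.
    """
    if branches.n_branches < 1:
        raise ValueError("BD is undefined for an empty branch set")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    p = _unwrap_binary(pred)
    detected = 0
    for b in branches.branches:
        frac = float(p[tuple(b.T)].sum()) / len(b)
        if coverage >= 1.0:
            detected += int(np.floor(frac))
        else:
            detected += int(frac >= coverage)
    return detected / branches.n_branches


def voxel_scores(pred, gt) -> dict:
    """Voxel-wise TP/FP/FN with precision, recall and F-measure.

    Zero-denominator convention: a score whose denominator is 0 is
    reported as 0 (and as 1.0 only in the trivially perfect case of a
    prediction identical to a nonempty ground truth).
    """
    p = _unwrap_binary(pred)
    g = _unwrap_binary(gt)
    if p.shape != g.shape:
        raise ValueError("prediction and ground-truth shapes differ")
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"precision": precision, "recall": recall, "f_measure": f,
            "tp": tp, "fp": fp, "fn": fn}


def evaluate(pred, gt, skel_gt, branches: BranchSet,
             coverage: float = 1.0) -> MetricsReport:
    """Full report: TR, BD, and voxel-wise scores for one case."""
    vs = voxel_scores(pred, gt)
    return MetricsReport(
        tr=tree_length_rate(skel_gt, pred),
        bd=branch_detection_rate(branches, pred, coverage=coverage),
        n_branches=branches.n_branches,
        **vs,
    )
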