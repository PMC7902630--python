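"""Segmentation evaluation: voxel-overlap metrics, ROC-AUC, 3D Hausdorff
distance in millimetres, and the paired Wilcoxon signed-rank test.

Conventions: X is the predicted foreground set and Y the ground-truth
foreground set.  The 0/0 corner cases of ratio metrics are resolved as
agreement-on-emptiness: if both masks are empty the metric is 1.0, if exactly
one side is empty it is 0.0; such values are flagged in the report so that
summaries can exclude them if desired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import roc_auc_score

from .errors import ContractError, DegenerateDataError, UndefinedMetricError
from .volume_io import LabelVolume, Volume


@dataclass(frozen=True)
class ConfusionCounts:
    """Exact voxel counts of a prediction/ground-truth pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Per-volume values of the eight evaluation metrics.

    ``auc`` and ``hausdorff_mm`` are None when undefined (single-class ground
    truth, empty mask).  ``degenerate`` lists ratio metrics that hit a 0/0
    case and were resolved by the emptiness convention.
    """

    dice: float
    jaccard: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    auc: float | None = None
    hausdorff_mm: float | None = None
    degenerate: list = field(default_factory=list)

    METRIC_NAMES = (
        "dice", "jaccard", "accuracy", "precision",
        "recall", "specificity", "auc", "hausdorff_mm",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


def _as_bool(m: LabelVolume | np.ndarray) -> np.ndarray:
    a = m.data if isinstance(m, Volume) else np.asarray(m)
    return a.astype(bool)


def confusion(pred: LabelVolume, gt: LabelVolume) -> ConfusionCounts:
    """Exact TP/FP/FN/TN voxel counts; shapes must match."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, empty_agree: bool, flag: str, flags: list) -> float:
    if den == 0:
        flags.append(flag)
        return 1.0 if empty_agree else 0.0
    return num / den


def overlap_metrics(c: ConfusionCounts) -> MetricsReport:
    """Dice, Jaccard, accuracy, precision, recall, specificity from counts."""
    both_empty = (c.tp + c.fp == 0) and (c.tp + c.fn == 0)
    flags: list = []
    return MetricsReport(
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty, "dice", flags),
        jaccard=_ratio(c.tp, c.tp + c.fp + c.fn, both_empty, "jaccard", flags),
        accuracy=(c.tp + c.tn) / c.total,
        precision=_ratio(c.tp, c.tp + c.fp, both_empty, "precision", flags),
        recall=_ratio(c.tp, c.tp + c.fn, both_empty, "recall", flags),
        specificity=_ratio(c.tn, c.tn + c.fp, both_empty, "specificity", flags),
        degenerate=flags,
    )


def roc_auc(prob: Volume | np.ndarray, gt: LabelVolume | np.ndarray) -> float:
    """Voxelwise area under the ROC curve.

    Equals the Mann-Whitney probability that a random foreground voxel scores
    above a random background voxel, with half credit for ties.
    """
    p = (prob.data if isinstance(prob, Volume) else np.asarray(prob)).ravel()
    g = _as_bool(gt).ravel()
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: prob {p.shape} vs gt {g.shape}")
    if g.all() or not g.any():
        raise UndefinedMetricError("ROC-AUC undefined: ground truth has a single class")
    return float(roc_auc_score(g, p))


def hausdorff_3d(
    pred: LabelVolume,
    gt: LabelVolume,
    spacing: Sequence[float] | None = None,
) -> float:
    """Symmetric 3D Hausdorff distance over full foreground voxel sets, in mm.

    max{ sup_{x in X} inf_{y in Y} d(x,y), sup_{y in Y} inf_{x in X} d(x,y) }
    with d the Euclidean distance between voxel centres scaled by the voxel
    spacing.  Computed with exact Euclidean distance transforms; anisotropic
    spacing is honoured.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if spacing is None:
        spacing = pred.spacing if isinstance(pred, Volume) else (1.0, 1.0, 1.0)
    if not p.any() or not g.any():
        raise UndefinedMetricError("Hausdorff undefined for an empty mask")
    # distance from every voxel to the nearest foreground voxel of the other set
    dt_to_g = ndimage.distance_transform_edt(~g, sampling=spacing)
    dt_to_p = ndimage.distance_transform_edt(~p, sampling=spacing)
    d_pg = float(dt_to_g[p].max())
    d_gp = float(dt_to_p[g].max())
    return max(d_pg, d_gp)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_pvalue(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic, conditional on the
    observed (mid)ranks.  ``ranks2`` are ranks doubled to integers so midranks
    (k + 1/2) stay exact; ``w2`` is the doubled observed W+.

    Dynamic programme over the distribution of W+ under random signs: O(n * S)
    with S the doubled rank total.
    """
    total = int(ranks2.sum())
    # pmf over doubled W+ values 0..total, scaled by 2^n
    pmf = np.zeros(total + 1, dtype=np.float64)
    pmf[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = pmf + shifted
    pmf /= pmf.sum()
    w2i = int(round(w2))
    p_le = pmf[: w2i + 1].sum()
    p_ge = pmf[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(a: Sequence[float], b: Sequence[float], exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment); ties among
    the remaining |differences| receive midranks.  The null distribution is
    enumerated exactly for n <= ``exact_max_n`` effective pairs and a normal
    approximation with tie correction and continuity correction is used above.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("wilcoxon_paired needs two equal-length 1D sequences")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise DegenerateDataError(
            f"only {n} non-zero differences; need >= 5 for a meaningful test"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= exact_max_n:
        return _exact_signed_rank_pvalue(np.round(2 * ranks), 2 * w_plus)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# per-volume report
# ---------------------------------------------------------------------------

def evaluate_pair(
    pred: LabelVolume,
    gt: LabelVolume,
    prob: Volume | None = None,
    spacing: Sequence[float] | None = None,
) -> MetricsReport:
    """All eight metrics for one prediction/ground-truth pair.

    AUC needs the pre-threshold probability volume; Hausdorff needs both
    masks non-empty.  Undefined metrics come back as None rather than 0.
    """
    rep = overlap_metrics(confusion(pred, gt))
    if prob is not None:
        try:
            rep.auc = roc_auc(prob, gt)
        except UndefinedMetricError:
            rep.auc = None
    try:
        rep.hausdorff_mm = hausdorff_3d(pred, gt, spacing)
    except UndefinedMetricError:
        rep.hausdorff_mm = None
    return rep
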