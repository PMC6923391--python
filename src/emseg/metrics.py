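"""Segmentation evaluation: foreground-restricted RAND scores and overlap trio.

The RAND F-score compares two labelings through the joint distribution of
voxel labels.  With :math:`p_{ij}` the probability that a voxel carries
inferred id *i* and ground-truth id *j* (over the evaluated voxels),
:math:`s_i = \\sum_j p_{ij}` and :math:`t_j = \\sum_i p_{ij}`, the score is

.. math::

    V^{\\mathrm{Rand}}_\\alpha =
        \\frac{\\sum_{ij} p_{ij}^2}
             {\\alpha \\sum_k s_k^2 + (1-\\alpha) \\sum_k t_k^2},

with :math:`\\alpha = 0.5` by default.  The split score (:math:`\\alpha \\to 0`)
is the precision of classifying voxel pairs as co-members of an object; the
merge score (:math:`\\alpha \\to 1`) is the recall.  A perfect segmentation
scores 1 at every :math:`\\alpha`.

"Foreground-restricted" means voxels whose ground-truth id is 0 are excluded
from the joint counts — the convention of the connectomics segmentation
challenges, where unpainted background must not dominate the score.  Instance
mode compares ids as distinct objects; semantic mode first collapses both
volumes to binary foreground/background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryVolume, LabelVolume


class EmptyTableError(ValueError):
    """No voxels left to evaluate (e.g. all-background ground truth)."""


@dataclass
class ContingencyTable:
    """Joint label-overlap probabilities.

    ``p[i, j]`` is the joint probability for inferred row-object *i* and
    ground-truth column-object *j*; ``s`` and ``t`` are the marginals;
    ``n_eval`` is the number of voxels counted.
    """

    p: np.ndarray
    s: np.ndarray
    t: np.ndarray
    n_eval: int
    pred_ids: np.ndarray
    gt_ids: np.ndarray


@dataclass
class RandResult:
    alpha: float
    score: float
    split: float
    merge: float


def contingency(
    gt: LabelVolume,
    pred: LabelVolume,
    mode: str = "instance",
    foreground_restricted: bool = True,
) -> ContingencyTable:
    """Build the joint label-overlap table between ground truth and prediction.

    Parameters
    ----------
    mode : {"instance", "semantic"}
        Semantic mode collapses both volumes to {0, 1} before counting.
    foreground_restricted : bool
        Exclude voxels with ground-truth id 0 from the counts.
    """
    if mode not in ("instance", "semantic"):
        raise ValueError("mode must be 'instance' or 'semantic'")
    g = gt.labels
    q = pred.labels
    if g.shape != q.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {q.shape}")
    g = g.ravel()
    q = q.ravel()
    if mode == "semantic":
        g = (g != 0).astype(np.int32)
        q = (q != 0).astype(np.int32)
    if foreground_restricted:
        keep = g != 0
        g = g[keep]
        q = q[keep]
    n_eval = g.size
    if n_eval == 0:
        raise EmptyTableError(
            "no voxels to evaluate (all-background ground truth under "
            "foreground restriction)"
        )
    pred_ids, qi = np.unique(q, return_inverse=True)
    gt_ids, gi = np.unique(g, return_inverse=True)
    counts = np.zeros((len(pred_ids), len(gt_ids)), dtype=np.int64)
    np.add.at(counts, (qi, gi), 1)
    p = counts / n_eval
    return ContingencyTable(
        p=p,
        s=p.sum(axis=1),
        t=p.sum(axis=0),
        n_eval=n_eval,
        pred_ids=pred_ids,
        gt_ids=gt_ids,
    )


def rand_score(table: ContingencyTable, alpha: float = 0.5) -> RandResult:
    """RAND F-score of a contingency table, with its split/merge limits."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if table.n_eval == 0:
        raise EmptyTableError("undefined score for an empty table")
    sum_p2 = float((table.p**2).sum())
    sum_s2 = float((table.s**2).sum())
    sum_t2 = float((table.t**2).sum())
    score = sum_p2 / (alpha * sum_s2 + (1.0 - alpha) * sum_t2)
    return RandResult(
        alpha=alpha,
        score=score,
        split=sum_p2 / sum_t2,
        merge=sum_p2 / sum_s2,
    )


def evaluate_rand(
    gt: LabelVolume,
    pred: LabelVolume,
    mode: str = "instance",
    alpha: float = 0.5,
    foreground_restricted: bool = True,
) -> RandResult:
    """Convenience wrapper: contingency table followed by :func:`rand_score`."""
    return rand_score(contingency(gt, pred, mode, foreground_restricted), alpha)


#: Sentinel returned for the conformity coefficient when Dice is 0.
CONFORMITY_UNDEFINED = float("-inf")


def semantic_overlap(
    gt_mask: BinaryVolume, pred_mask: BinaryVolume
) -> tuple[float, float, float]:
    """Jaccard, Dice and conformity coefficients of two binary masks.

    ``jaccard = |A∩B| / |A∪B|``, ``dice = 2|A∩B| / (|A|+|B|)`` and
    ``conformity = (3·dice − 2) / dice`` (undefined when dice is 0, reported
    as ``-inf``).
    """
    a = gt_mask.mask
    b = pred_mask.mask
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        raise EmptyTableError("both masks empty: overlap scores undefined")
    inter = int(np.logical_and(a, b).sum())
    union = na + nb - inter
    jaccard = inter / union if union else 0.0
    dice = 2.0 * inter / (na + nb)
    conformity = (3.0 * dice - 2.0) / dice if dice > 0 else CONFORMITY_UNDEFINED
    return jaccard, dice, conformity
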