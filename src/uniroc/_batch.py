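"""Vectorised evaluation of weighted ROC statistics over many weight vectors.

Resampling a dataset with replacement is equivalent to drawing a multinomial
multiplicity vector over its cases, and the unweighted statistic of the
resampled multiset equals the multiplicity-weighted statistic of the base
data (tied copies of a case collapse into the same ROC vertex either way).
The bootstrap routes therefore never materialise resampled datasets: the
base data is sorted and tie-grouped once, and each replicate is a row of a
(replicates x cases) weight matrix evaluated here in vectorised form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roc_core import EvalDataset

__all__ = ["GroupedEval", "group_cases", "batch_weighted_stats"]


@dataclass(frozen=True)
class GroupedEval:
    """A dataset sorted by descending score with tie groups precomputed."""

    order: np.ndarray      # case indices, descending hs, stable
    sp_sorted: np.ndarray  # labels in sorted order
    group_end: np.ndarray  # inclusive end index of each threshold group
    thresholds: np.ndarray


def group_cases(data: EvalDataset) -> GroupedEval:
    order = np.argsort(-data.hs, kind="stable")
    hs_sorted = data.hs[order]
    changes = hs_sorted[1:] != hs_sorted[:-1]
    group_end = np.flatnonzero(np.append(changes, True))
    return GroupedEval(
        order=order,
        sp_sorted=data.sp[order].astype(float),
        group_end=group_end,
        thresholds=hs_sorted[group_end],
    )


def batch_weighted_stats(
    grouped: GroupedEval,
    weights: np.ndarray,
    chunk_size: int = 512,
) -> dict[str, np.ndarray]:
    """Weighted AUC and Se* for each row of a (reps x cases) weight matrix.

    ``weights`` is indexed by *original* case order; rows may contain zeros
    (cases absent from a replicate).  Rows in which either class carries no
    weight are returned as NaN in both statistics and flagged invalid.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    n_reps = weights.shape[0]
    auc = np.empty(n_reps)
    se_star = np.empty(n_reps)
    valid = np.empty(n_reps, dtype=bool)
    for start in range(0, n_reps, chunk_size):
        sl = slice(start, min(start + chunk_size, n_reps))
        _chunk_stats(grouped, weights[sl], auc[sl], se_star[sl], valid[sl])
    return {"auc": auc, "se_star": se_star, "valid": valid}


def _chunk_stats(g: GroupedEval, w: np.ndarray, auc_out, se_out, valid_out) -> None:
    ws = w[:, g.order]
    pres = ws * g.sp_sorted
    absn = ws - pres
    cum_p = np.cumsum(pres, axis=1)[:, g.group_end]
    cum_a = np.cumsum(absn, axis=1)[:, g.group_end]
    tot_p = cum_p[:, -1]
    tot_a = cum_a[:, -1]
    valid = (tot_p > 0.0) & (tot_a > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = cum_p / tot_p[:, None]
        fpr = cum_a / tot_a[:, None]
    zeros = np.zeros((w.shape[0], 1))
    tpr = np.concatenate([zeros, tpr], axis=1)
    fpr = np.concatenate([zeros, fpr], axis=1)

    auc = (np.diff(fpr, axis=1) * (tpr[:, 1:] + tpr[:, :-1]) / 2.0).sum(axis=1)

    spec = 1.0 - fpr
    diff = np.abs(tpr - spec)
    mean = (tpr + spec) / 2.0
    dmin = diff.min(axis=1, keepdims=True) if diff.size else diff
    se_star = np.where(diff == dmin, mean, -np.inf).max(axis=1)

    auc[~valid] = np.nan
    se_star[~valid] = np.nan
    auc_out[:] = auc
    se_out[:] = se_star
    valid_out[:] = valid
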