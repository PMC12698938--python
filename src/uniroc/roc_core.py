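"""Empirical (weighted) ROC curves and threshold statistics.

The empirical ROC curve of a presence-absence evaluation dataset is built by
scanning the unique habitat-suitability scores in decreasing order and
accumulating, at each threshold, the presences and absences scoring at that
value.  With per-case weights the counts are replaced by weight sums, which
yields the weighted true/false positive rates ``tp.w``/``fp.w`` and, via the
trapezoidal rule, the weighted AUC (wAUC).  Tied scores (presences and
absences sharing a value) collapse into a single vertex, so mixed-class ties
produce diagonal curve segments; the trapezoidal rule handles both shapes
uniformly.

Only the relative weights *within* each class matter: multiplying all
presence weights (or all absence weights, or the whole vector) by a positive
constant leaves every statistic unchanged, because the cumulative weight sums
are normalised by the class totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "EvalDataset",
    "RocCurve",
    "MetricResult",
    "build_roc",
    "trapezoidal_auc",
    "mann_whitney_auc",
    "weighted_auc",
    "sensitivity_star",
]


class InvalidDatasetError(ValueError):
    """Raised when an evaluation table violates the dataset contract."""


@dataclass(frozen=True)
class EvalDataset:
    """A presence-absence evaluation table.

    Parameters
    ----------
    hs : array-like of float
        Habitat suitability score per case, each in [0, 1].
    sp : array-like of int
        Observed state per case: 1 = presence, 0 = absence.
    w : array-like of float, optional
        Strictly positive case weight.  Defaults to unit weights.  Weights
        are accepted on any positive scale; no normalisation is applied.
    """

    hs: np.ndarray
    sp: np.ndarray
    w: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        hs = np.asarray(self.hs, dtype=float)
        sp = np.asarray(self.sp)
        w = np.ones_like(hs) if self.w is None else np.asarray(self.w, dtype=float)
        if hs.ndim != 1 or sp.shape != hs.shape or w.shape != hs.shape:
            raise InvalidDatasetError(
                "hs, sp and w must be one-dimensional vectors of equal length"
            )
        if hs.size < 2:
            raise InvalidDatasetError("at least two cases are required")
        if not np.all(np.isfinite(hs)) or hs.min() < 0.0 or hs.max() > 1.0:
            raise InvalidDatasetError("all suitability scores must be finite and in [0, 1]")
        if not np.isin(sp, (0, 1)).all():
            raise InvalidDatasetError("sp must contain only 0 (absence) and 1 (presence)")
        sp = sp.astype(np.int8)
        if not (sp == 1).any() or not (sp == 0).any():
            raise InvalidDatasetError(
                "dataset must contain at least one presence and one absence"
            )
        if not np.all(np.isfinite(w)) or w.min() <= 0.0:
            raise InvalidDatasetError("all case weights must be finite and > 0")
        object.__setattr__(self, "hs", hs)
        object.__setattr__(self, "sp", sp)
        object.__setattr__(self, "w", w)

    def __len__(self) -> int:
        return self.hs.size

    @property
    def n_presences(self) -> int:
        return int((self.sp == 1).sum())

    @property
    def n_absences(self) -> int:
        return int((self.sp == 0).sum())

    def with_weights(self, w: np.ndarray) -> "EvalDataset":
        """Return a copy of the dataset carrying a new weight vector."""
        return EvalDataset(self.hs, self.sp, np.asarray(w, dtype=float))


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC vertices, one per unique score plus the (0, 0) origin.

    ``thresholds[k]`` is the unique suitability value generating vertex
    ``k``; the origin carries a ``+inf`` sentinel (no case is called
    present).  ``fpr`` and ``tpr`` are non-decreasing, start at (0, 0) and
    end at (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __len__(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class MetricResult:
    """A named discrimination statistic with optional CI and threshold."""

    name: str
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    threshold: Optional[float] = None
    method: str = "trapezoidal"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "threshold": self.threshold,
            "method": self.method,
        }


def _grouped_rates(data: EvalDataset, weights: np.ndarray):
    """Unique descending thresholds and cumulative weighted rates.

    Scores equal under exact float comparison share a threshold: scores are
    data, not computed quantities, so no tolerance is applied.
    """
    order = np.argsort(-data.hs, kind="stable")
    hs, sp, w = data.hs[order], data.sp[order], weights[order]
    uniq_desc, inverse = np.unique(-hs, return_inverse=True)
    thresholds = -uniq_desc
    k = thresholds.size
    tp = np.zeros(k)
    fp = np.zeros(k)
    np.add.at(tp, inverse, w * sp)
    np.add.at(fp, inverse, w * (1 - sp))
    tot_p = tp.sum()
    tot_a = fp.sum()
    if tot_p <= 0.0 or tot_a <= 0.0:
        raise InvalidDatasetError("both classes must carry positive total weight")
    tpr = np.cumsum(tp) / tot_p
    fpr = np.cumsum(fp) / tot_a
    return thresholds, fpr, tpr


def build_roc(data: EvalDataset, weighted: bool = False) -> RocCurve:
    """Build the empirical ROC curve of ``data``.

    With ``weighted=True`` the cumulative true/false positive rates sum the
    case weights instead of counting cases.  One vertex is emitted per unique
    suitability value, preceded by the (0, 0) origin (threshold sentinel
    ``+inf``); mixed-class ties therefore appear as diagonal segments.
    """
    weights = data.w if weighted else np.ones_like(data.w)
    thresholds, fpr, tpr = _grouped_rates(data, weights)
    return RocCurve(
        thresholds=np.concatenate([[np.inf], thresholds]),
        fpr=np.concatenate([[0.0], fpr]),
        tpr=np.concatenate([[0.0], tpr]),
    )


def trapezoidal_auc(curve: RocCurve) -> MetricResult:
    """Area under an empirical ROC curve by the trapezoidal rule.

    Sums, over consecutive vertices, ``diff(fpr) * (tpr_k + tpr_{k+1}) / 2``
    — rectangle areas on a tie-free staircase, trapezoids across diagonal
    (tied) segments.  The same formula serves weighted and unweighted curves.
    """
    auc = float(np.trapezoid(curve.tpr, curve.fpr))
    return MetricResult(name="AUC", estimate=auc, method="trapezoidal")


def mann_whitney_auc(data: EvalDataset) -> MetricResult:
    """AUC via the Mann-Whitney U statistic (unit weights).

    ``U / (n_presences * n_absences)``, i.e. the proportion of
    presence-absence pairs ranked concordantly, ties counting one half.
    Equals the trapezoidal estimate on the same data, ties included.
    """
    pres = data.hs[data.sp == 1]
    abs_ = data.hs[data.sp == 0]
    u = stats.mannwhitneyu(pres, abs_, alternative="two-sided").statistic
    return MetricResult(
        name="AUC", estimate=float(u / (pres.size * abs_.size)), method="mann-whitney"
    )


def weighted_auc(data: EvalDataset) -> MetricResult:
    """Weighted AUC (wAUC): trapezoidal rule on the weighted ROC curve."""
    res = trapezoidal_auc(build_roc(data, weighted=True))
    return MetricResult(name="wAUC", estimate=res.estimate, method="trapezoidal")


def _se_star_from_rates(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray):
    """Vertex scan for Se*: minimise |Se - Sp|, then prefer the higher
    (Se + Sp)/2, then the higher threshold."""
    se = tpr
    sp_rate = 1.0 - fpr
    diff = np.abs(se - sp_rate)
    mean = (se + sp_rate) / 2.0
    candidates = np.flatnonzero(diff == diff.min())
    best = candidates[np.argmax(mean[candidates])]  # argmax ties -> first,
    # and thresholds are descending, so the first is the highest threshold
    return float(mean[best]), float(thresholds[best])


def sensitivity_star(data: EvalDataset, weighted: bool = False) -> MetricResult:
    """Sensitivity-star: mean of Se and Sp at the vertex where they are
    closest.

    All ROC vertices compete, including the origin (Se = 0, Sp = 1).  The
    weighted variant scans the weighted curve.  Ties on |Se - Sp| are broken
    toward the higher (Se + Sp)/2, then the higher threshold.
    """
    curve = build_roc(data, weighted=weighted)
    value, threshold = _se_star_from_rates(curve.fpr, curve.tpr, curve.thresholds)
    return MetricResult(
        name="wSe*" if weighted else "Se*",
        estimate=value,
        threshold=threshold,
        method="trapezoidal",
    )
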