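"""Uniform discrimination statistics: uAUC and uSe*.

The uniform statistics are the weighted statistics of :mod:`uniroc.roc_core`
with a particular weight choice that removes the representativeness effect:
the suitability axis [0, 1] is cut into equal-width bins and every case is
weighted by the inverse of its bin's occupancy, so the weighted score
distribution is uniform over the occupied bins and discrimination scores
become comparable across datasets with different suitability distributions.

Two computation routes are provided:

* the **direct** route plugs the inverse-occupancy weights straight into the
  weighted trapezoidal estimator (deterministic, no resampling);
* the **legacy bootstrap** route resamples cases with replacement with
  selection probability proportional to the weights, computes the unweighted
  statistic on each replicate, and averages.

Percentile bootstrap confidence intervals for the direct statistics resample
cases with *equal* probability and recompute the bin weights on every
replicate, so the interval reflects the sampling variability of the weights
as well as of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._batch import GroupedEval, batch_weighted_stats, group_cases
from .roc_core import EvalDataset, MetricResult, sensitivity_star, weighted_auc

__all__ = [
    "BinWeighting",
    "BootstrapSpec",
    "uniform_weights",
    "uauc_direct",
    "use_star_direct",
    "uniform_bootstrap",
    "uauc_bootstrap",
    "use_star_bootstrap",
    "percentile_ci",
]

DEFAULT_N_BINS = 10
_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class BinWeighting:
    """Inverse-occupancy bin weights over the suitability axis."""

    n_bins: int
    edges: np.ndarray
    bin_counts: np.ndarray
    case_weights: np.ndarray


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling settings for the bootstrap routes."""

    n_reps: int = 1000
    seed: Optional[int] = None
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _bin_edges(n_bins: int) -> np.ndarray:
    # arange/n keeps edges like 3/10 on the same double as the literal 0.3,
    # so printed two-decimal scores land in the expected bin
    return np.arange(n_bins + 1) / n_bins


def bin_index(hs: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin of each score: half-open [lo, hi) bins, last bin closed at 1."""
    edges = _bin_edges(n_bins)
    idx = np.digitize(hs, edges) - 1
    return np.minimum(idx, n_bins - 1)


def uniform_weights(data: EvalDataset, n_bins: int = DEFAULT_N_BINS) -> BinWeighting:
    """Weight each case by the inverse of its suitability bin's occupancy.

    Bins are equal-width over the fixed support [0, 1] (not the data range),
    half-open on the right except the last, which includes 1.0.  Empty bins
    contribute no cases and are skipped; occupancy counts both classes.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    idx = bin_index(data.hs, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return BinWeighting(
        n_bins=n_bins,
        edges=_bin_edges(n_bins),
        bin_counts=counts,
        case_weights=1.0 / counts[idx],
    )


def uauc_direct(data: EvalDataset, n_bins: int = DEFAULT_N_BINS) -> MetricResult:
    """uAUC by the direct weighted trapezoidal estimator (no resampling)."""
    weighting = uniform_weights(data, n_bins)
    res = weighted_auc(data.with_weights(weighting.case_weights))
    return MetricResult(name="uAUC", estimate=res.estimate, method="direct-weighted")


def use_star_direct(data: EvalDataset, n_bins: int = DEFAULT_N_BINS) -> MetricResult:
    """uSe* by the direct weighted estimator: Se* on the uniform-weighted curve."""
    weighting = uniform_weights(data, n_bins)
    res = sensitivity_star(data.with_weights(weighting.case_weights), weighted=True)
    return MetricResult(
        name="uSe*", estimate=res.estimate, threshold=res.threshold,
        method="direct-weighted",
    )


def _redraw_multinomial(
    rng: np.random.Generator,
    pvals: np.ndarray,
    n_draw: int,
    n_reps: int,
    grouped: GroupedEval,
    weight_fn,
) -> dict[str, np.ndarray]:
    """Draw multiplicity vectors, redrawing replicates where a class vanishes.

    Each replicate gets at most ``_MAX_REDRAW_ROUNDS`` redraws before a
    RuntimeError; silently discarding degenerate draws would bias small-n
    results.
    """
    counts = rng.multinomial(n_draw, pvals, size=n_reps)
    stats = batch_weighted_stats(grouped, weight_fn(counts))
    rounds = 0
    while not stats["valid"].all():
        if rounds >= _MAX_REDRAW_ROUNDS:
            raise RuntimeError(
                "could not draw a replicate containing both classes "
                f"after {_MAX_REDRAW_ROUNDS} redraws"
            )
        bad = np.flatnonzero(~stats["valid"])
        counts[bad] = rng.multinomial(n_draw, pvals, size=bad.size)
        redone = batch_weighted_stats(grouped, weight_fn(counts[bad]))
        for key in ("auc", "se_star", "valid"):
            stats[key][bad] = redone[key]
        rounds += 1
    return stats


def _stratified_replicates(
    data: EvalDataset,
    n_bins: int,
    spec: BootstrapSpec,
    rng: Optional[np.random.Generator],
) -> dict[str, np.ndarray]:
    """Replicate statistics of the legacy stratified bootstrap.

    Cases are resampled with replacement with selection probability
    proportional to their inverse-occupancy weight and the *unweighted*
    statistics are computed on each replicate; both statistics share the
    same draws.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    weighting = uniform_weights(data, n_bins)
    pvals = weighting.case_weights / weighting.case_weights.sum()
    if not spec.stratified:
        pvals = np.full(len(data), 1.0 / len(data))
    grouped = group_cases(data)
    return _redraw_multinomial(
        rng, pvals, len(data), spec.n_reps, grouped, lambda c: c.astype(float)
    )


def uniform_bootstrap(
    data: EvalDataset,
    statistic: str = "auc",
    n_bins: int = DEFAULT_N_BINS,
    spec: BootstrapSpec = BootstrapSpec(),
    rng: Optional[np.random.Generator] = None,
) -> MetricResult:
    """Legacy stratified-bootstrap route for the uniform statistics.

    Cases are resampled with replacement with selection probability
    proportional to their inverse-occupancy weight; the *unweighted*
    statistic is computed on each replicate and the replicate mean is
    returned.  Replicates in which a class vanishes are redrawn.
    """
    if statistic not in ("auc", "se_star"):
        raise ValueError("statistic must be 'auc' or 'se_star'")
    reps = _stratified_replicates(data, n_bins, spec, rng)[statistic]
    return MetricResult(
        name="uAUC" if statistic == "auc" else "uSe*",
        estimate=float(reps.mean()),
        method="bootstrap",
    )


def uauc_bootstrap(
    data: EvalDataset,
    n_bins: int = DEFAULT_N_BINS,
    spec: BootstrapSpec = BootstrapSpec(),
    rng: Optional[np.random.Generator] = None,
) -> MetricResult:
    return uniform_bootstrap(data, "auc", n_bins, spec, rng)


def use_star_bootstrap(
    data: EvalDataset,
    n_bins: int = DEFAULT_N_BINS,
    spec: BootstrapSpec = BootstrapSpec(),
    rng: Optional[np.random.Generator] = None,
) -> MetricResult:
    return uniform_bootstrap(data, "se_star", n_bins, spec, rng)


def _direct_replicates(
    data: EvalDataset,
    n_bins: int,
    spec: BootstrapSpec,
    rng: Optional[np.random.Generator],
) -> dict[str, np.ndarray]:
    """Ordinary bootstrap replicates of the direct statistics.

    Cases are resampled with equal probability; the inverse-occupancy bin
    weights are recomputed on every replicate before the weighted statistic
    is evaluated (weights are part of the estimator, so their sampling
    variability belongs in the interval).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = len(data)
    idx = bin_index(data.hs, n_bins)
    grouped = group_cases(data)

    def reweight(counts: np.ndarray) -> np.ndarray:
        occ = np.zeros((counts.shape[0], n_bins))
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                occ[:, b] = counts[:, sel].sum(axis=1)
        occ[occ == 0.0] = 1.0  # bins absent from the replicate: no cases to weight
        return counts / occ[:, idx]

    pvals = np.full(n, 1.0 / n)
    return _redraw_multinomial(rng, pvals, n, spec.n_reps, grouped, reweight)


def percentile_ci(
    data: EvalDataset,
    statistic: str = "auc",
    n_bins: int = DEFAULT_N_BINS,
    spec: BootstrapSpec = BootstrapSpec(),
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> MetricResult:
    """Percentile bootstrap CI for a direct-route uniform statistic.

    The point estimate is the direct statistic on the full data; the bounds
    are the alpha/2 and 1 - alpha/2 empirical percentiles of the replicate
    distribution.
    """
    if statistic not in ("auc", "se_star"):
        raise ValueError("statistic must be 'auc' or 'se_star'")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    reps = _direct_replicates(data, n_bins, spec, rng)[statistic]
    lo, hi = np.quantile(reps, [(1 - level) / 2, 1 - (1 - level) / 2])
    point = (
        uauc_direct(data, n_bins) if statistic == "auc" else use_star_direct(data, n_bins)
    )
    return MetricResult(
        name=point.name,
        estimate=point.estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        threshold=point.threshold,
        method="direct-weighted",
    )
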