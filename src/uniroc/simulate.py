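"""Simulation study: bias, precision, and CI coverage of the uniform statistics.

Suitability scores are drawn from four scenario distributions on [0, 1]
(mixtures of truncated normals and a uniform component) chosen to span
qualitatively different representativeness situations: extreme bimodal (A),
monotically decreasing (B), mid-peaked (C) and low-skewed with a uniform
half (D).  Labels are generated from a perfectly calibrated model — each
case is a presence with probability equal to its suitability score — so the
population values of the uniform statistics are known (0.83 for uAUC, 0.75
for uSe*) and bias, interquartile range and CI coverage can be measured
directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roc_core import EvalDataset, mann_whitney_auc, sensitivity_star
from .uniform import (
    DEFAULT_N_BINS,
    BootstrapSpec,
    _direct_replicates,
    _stratified_replicates,
    uauc_direct,
    use_star_direct,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "ExperimentReport",
    "REFERENCE_VALUES",
    "draw_suitability",
    "generate_species",
    "simulate_dataset",
    "run_bias_experiment",
    "run_coverage_experiment",
]

#: Population values of the uniform statistics under a perfectly calibrated
#: model.  With uniform suitability, presences have density 2x and absences
#: 2(1-x) on [0, 1]: the probability a presence outscores an absence is 5/6
#: and sensitivity at the Se = Sp threshold (t = 1/2) is 3/4; both are used
#: at the two-decimal precision conventional in this literature.
REFERENCE_VALUES = {"uAUC": 0.83, "uSe*": 0.75}

#: Sample sizes of the full replication grid.
DEFAULT_N_GRID = (30, 50, 74, 100, 150, 200, 250, 500, 1000, 10_000)


@dataclass(frozen=True)
class Scenario:
    """A mixture distribution for suitability scores on [0, 1].

    ``components`` is a sequence of (family, mu, sigma, fraction) tuples
    where family is ``"truncnorm"`` (normal truncated to [0, 1]) or
    ``"uniform"`` (mu/sigma ignored); fractions must sum to 1.
    """

    label: str
    components: tuple

    def __post_init__(self) -> None:
        fracs = [c[3] for c in self.components]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        for family, _, sigma, _ in self.components:
            if family == "truncnorm" and sigma <= 0:
                raise ValueError("truncnorm components need sigma > 0")
            if family not in ("truncnorm", "uniform"):
                raise ValueError(f"unknown component family {family!r}")


SCENARIOS = {
    "A": Scenario("A", (("truncnorm", 0.0, 0.25, 0.5), ("truncnorm", 1.0, 0.25, 0.5))),
    "B": Scenario("B", (("truncnorm", 0.0, 0.6, 1.0),)),
    "C": Scenario("C", (("truncnorm", 0.5, 0.3, 1.0),)),
    "D": Scenario("D", (("truncnorm", 0.0, 0.05, 0.5), ("uniform", None, None, 0.5))),
}


def _as_scenario(scenario) -> Scenario:
    if isinstance(scenario, Scenario):
        return scenario
    try:
        return SCENARIOS[str(scenario).upper()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_suitability(scenario, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` suitability scores from a scenario mixture.

    Component sample sizes follow the stated fractions (cumulative rounding,
    so they sum to ``n`` exactly).  Truncated-normal components are sampled
    exactly on [0, 1] (scipy's truncnorm, not clipping).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    scenario = _as_scenario(scenario)
    rng = _as_rng(seed)
    fracs = np.array([c[3] for c in scenario.components])
    sizes = np.diff(np.round(np.cumsum(fracs) * n).astype(int), prepend=0)
    parts = []
    for (family, mu, sigma, _), size in zip(scenario.components, sizes):
        if size == 0:
            continue
        if family == "uniform":
            parts.append(rng.uniform(0.0, 1.0, size))
        else:
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            parts.append(
                sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
            )
    return np.concatenate(parts)


def generate_species(hs: np.ndarray, seed=None) -> np.ndarray:
    """Perfectly calibrated labels: presence iff an independent uniform draw
    falls below the case's suitability score."""
    hs = np.asarray(hs, dtype=float)
    rng = _as_rng(seed)
    return (rng.uniform(size=hs.size) < hs).astype(np.int8)


def simulate_dataset(
    scenario, n: int, seed=None, max_redraws: int = 1000
) -> tuple[EvalDataset, int]:
    """Simulate one calibrated dataset, redrawing if a class is absent.

    Single-class draws are possible at small n under extreme scenarios; the
    whole iteration is redrawn (scores and labels) and the redraw count
    returned so experiment reports can surface it.
    """
    rng = _as_rng(seed)
    for redraws in range(max_redraws + 1):
        hs = draw_suitability(scenario, n, rng)
        sp = generate_species(hs, rng)
        if 0 < sp.sum() < n:
            return EvalDataset(hs, sp), redraws
    raise RuntimeError(f"no two-class dataset after {max_redraws} redraws")


@dataclass(frozen=True)
class ExperimentReport:
    """Tidy summary of a simulation experiment.

    ``rows`` holds one record per (statistic, method) with the summaries the
    study design calls for: median, bias (median minus the reference value,
    uniform statistics only), IQR, mean — or, for coverage runs, the CI
    containment proportion.
    """

    kind: str
    scenario: str
    n: int
    n_bins: int
    seed: Optional[int]
    n_redraws: int
    params: dict
    rows: tuple

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows))
        df.insert(0, "scenario", self.scenario)
        df.insert(1, "n", self.n)
        return df

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), **kw)


def _child_rngs(seed, n: int) -> list[np.random.Generator]:
    # one child stream per iteration: results do not depend on how the
    # iteration loop is chunked or parallelised
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def run_bias_experiment(
    scenario,
    n: int,
    n_iterations: int = 10_000,
    n_bins: int = DEFAULT_N_BINS,
    methods: Sequence[str] = ("direct", "bootstrap"),
    n_reps: int = 1000,
    seed=None,
) -> ExperimentReport:
    """Measure bias and precision of AUC, Se*, uAUC and uSe*.

    Per iteration a calibrated dataset is simulated and the plain statistics
    (Mann-Whitney AUC, Se*) plus the uniform statistics by each requested
    route are computed.  Bias is the median minus the reference value; the
    IQR measures precision.
    """
    scenario = _as_scenario(scenario)
    unknown = set(methods) - {"direct", "bootstrap"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    values: dict[tuple[str, str], list] = {
        ("AUC", "mann-whitney"): [],
        ("Se*", "trapezoidal"): [],
    }
    for m in methods:
        values[("uAUC", m)] = []
        values[("uSe*", m)] = []
    total_redraws = 0
    for rng in _child_rngs(seed, n_iterations):
        data, redraws = simulate_dataset(scenario, n, rng)
        total_redraws += redraws
        values[("AUC", "mann-whitney")].append(mann_whitney_auc(data).estimate)
        values[("Se*", "trapezoidal")].append(sensitivity_star(data).estimate)
        if "direct" in methods:
            values[("uAUC", "direct")].append(uauc_direct(data, n_bins).estimate)
            values[("uSe*", "direct")].append(use_star_direct(data, n_bins).estimate)
        if "bootstrap" in methods:
            reps = _stratified_replicates(data, n_bins, BootstrapSpec(n_reps=n_reps), rng)
            values[("uAUC", "bootstrap")].append(float(reps["auc"].mean()))
            values[("uSe*", "bootstrap")].append(float(reps["se_star"].mean()))
    rows = []
    for (name, method), vals in values.items():
        arr = np.asarray(vals)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        ref = REFERENCE_VALUES.get(name)
        rows.append(
            {
                "statistic": name,
                "method": method,
                "reference": ref,
                "median": float(med),
                "bias": float(med - ref) if ref is not None else None,
                "iqr": float(q3 - q1),
                "mean": float(arr.mean()),
                "n_iterations": n_iterations,
            }
        )
    return ExperimentReport(
        kind="bias",
        scenario=scenario.label,
        n=n,
        n_bins=n_bins,
        seed=seed if isinstance(seed, int) else None,
        n_redraws=total_redraws,
        params={"methods": list(methods), "n_reps": n_reps},
        rows=tuple(rows),
    )


def run_coverage_experiment(
    scenario,
    n: int,
    n_outer: int = 100,
    n_reps: int = 1000,
    n_bins: int = DEFAULT_N_BINS,
    level: float = 0.95,
    seed=None,
) -> ExperimentReport:
    """Coverage of percentile bootstrap CIs for the direct uniform statistics.

    Per outer iteration: simulate a calibrated dataset, bootstrap the direct
    uAUC and uSe* (bin weights recomputed on every replicate), take the
    percentile interval, and record whether it contains the reference value.
    Both statistics share the same resampling draws.
    """
    scenario = _as_scenario(scenario)
    hits = {"uAUC": 0, "uSe*": 0}
    total_redraws = 0
    alpha = 1.0 - level
    for rng in _child_rngs(seed, n_outer):
        data, redraws = simulate_dataset(scenario, n, rng)
        total_redraws += redraws
        reps = _direct_replicates(data, n_bins, BootstrapSpec(n_reps=n_reps), rng)
        for name, key in (("uAUC", "auc"), ("uSe*", "se_star")):
            lo, hi = np.quantile(reps[key], [alpha / 2, 1 - alpha / 2])
            if lo <= REFERENCE_VALUES[name] <= hi:
                hits[name] += 1
    rows = tuple(
        {
            "statistic": name,
            "method": "direct",
            "reference": REFERENCE_VALUES[name],
            "coverage": hits[name] / n_outer,
            "n_outer": n_outer,
            "n_reps": n_reps,
            "level": level,
        }
        for name in ("uAUC", "uSe*")
    )
    return ExperimentReport(
        kind="coverage",
        scenario=scenario.label,
        n=n,
        n_bins=n_bins,
        seed=seed if isinstance(seed, int) else None,
        n_redraws=total_redraws,
        params={"n_outer": n_outer, "n_reps": n_reps, "level": level},
        rows=rows,
    )
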