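"""The bundled 20-case worked example and fixture export.

A small presence-absence table with suitability scores on a regular 0.05
grid, together with six weighting vectors (``w.a`` … ``w.f``) illustrating
how down-weighting individual cases moves the weighted AUC: constant
per-class weights leave it unchanged, down-weighting a low-scored absence
lowers it, down-weighting a high-scored absence raises it, and rescaling the
whole vector changes nothing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .roc_core import EvalDataset

__all__ = ["table1", "table1_weights", "table1_tied", "make_fixtures"]

_HS = np.array([
    1.00, 0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55,
    0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05,
])
_SP = np.array([0, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0])

_WEIGHTS = {
    # constant within each class: identical curve and wAUC
    "w.a": np.where(_SP == 0, 0.2, 1.0),
    # case 20, the lowest-scored absence, down-weighted
    "w.b": np.where(np.arange(20) == 19, 0.2, 1.0),
    # case 1, the highest-scored absence, down-weighted
    "w.c": np.where(np.arange(20) == 0, 0.2, 1.0),
    # case 12, a mid-ranked absence, down-weighted
    "w.d": np.where(np.arange(20) == 11, 0.2, 1.0),
    # case 2, a high-scored presence, down-weighted
    "w.e": np.where(np.arange(20) == 1, 0.2, 1.0),
    # w.e rescaled (x0.2 on the presences): same relative weights
    "w.f": np.where(np.arange(20) == 1, 0.04, np.where(_SP == 1, 0.2, 1.0)),
}


def table1() -> EvalDataset:
    """The 20-case worked example (11 presences, 9 absences; AUC 0.667)."""
    return EvalDataset(_HS.copy(), _SP.copy())


def table1_weights() -> dict[str, np.ndarray]:
    """The six weighting vectors of the worked example, keyed w.a … w.f."""
    return {k: v.copy() for k, v in _WEIGHTS.items()}


def table1_tied() -> EvalDataset:
    """The tied variant: cases 11-15 all score 0.3, so the ROC curve has a
    diagonal segment at that threshold (2 presences, 3 absences tied)."""
    hs = _HS.copy()
    hs[10:15] = 0.3
    return EvalDataset(hs, _SP.copy())


def make_fixtures(out_dir) -> list[Path]:
    """Write the worked-example fixtures as CSV files.

    Emits ``table1.csv`` (case, hs, sp), ``table1_weights.csv`` (case plus
    the six weight columns) and ``table1_tied.csv`` (the tied variant).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case = np.arange(1, 21)
    paths = []

    df = pd.DataFrame({"case": case, "hs": _HS, "sp": _SP})
    paths.append(out_dir / "table1.csv")
    df.to_csv(paths[-1], index=False)

    wdf = pd.DataFrame({"case": case, **_WEIGHTS})
    paths.append(out_dir / "table1_weights.csv")
    wdf.to_csv(paths[-1], index=False)

    tied = table1_tied()
    tdf = pd.DataFrame({"case": case, "hs": tied.hs, "sp": tied.sp})
    paths.append(out_dir / "table1_tied.csv")
    tdf.to_csv(paths[-1], index=False)
    return paths
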