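"""Reading evaluation tables and writing results.

Input is a plain delimited table of (score, label, optional weight) — one
row per evaluated case.  Georeferencing, rasters and model fitting are
upstream concerns; this package only consumes model outputs.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .roc_core import EvalDataset, InvalidDatasetError, MetricResult, RocCurve

__all__ = ["read_eval_table", "write_results", "write_curve", "read_curve"]


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_eval_table(
    path,
    hs_col: str = "hs",
    sp_col: str = "sp",
    w_col: str = "w",
    sep: Optional[str] = None,
) -> EvalDataset:
    """Read a CSV/TSV evaluation table into an :class:`EvalDataset`.

    The delimiter is inferred from the extension (``.tsv``/``.tab`` means
    tab) unless given.  A missing weight column means unit weights.  Rows
    with missing score or label are reported by row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    for col in (hs_col, sp_col):
        if col not in df.columns:
            raise InvalidDatasetError(
                f"{path.name}: required column {col!r} not found "
                f"(columns: {', '.join(df.columns)})"
            )
    bad = df.index[df[hs_col].isna() | df[sp_col].isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header and 1-basing
        raise InvalidDatasetError(f"{path.name}: missing hs or sp in rows {rows}")
    w = df[w_col].to_numpy(dtype=float) if w_col in df.columns else None
    return EvalDataset(df[hs_col].to_numpy(dtype=float), df[sp_col].to_numpy(), w)


def _finite_or_none(x: Optional[float]) -> Optional[float]:
    if x is None or not math.isfinite(x):
        return None
    return x


def result_record(result: MetricResult) -> dict:
    """JSON-safe record of a metric result (non-finite thresholds -> null)."""
    rec = result.to_dict()
    rec["threshold"] = _finite_or_none(rec["threshold"])
    return rec


def write_results(
    results: Union[MetricResult, Iterable[MetricResult]],
    path=None,
    fmt: str = "json",
) -> str:
    """Serialise metric results as JSON (default) or CSV.

    Returns the rendered text; additionally writes it to ``path`` if given
    (``"-"`` and None both mean: return only).
    """
    if isinstance(results, MetricResult):
        results = [results]
    records = [result_record(r) for r in results]
    if fmt == "json":
        text = json.dumps(records, indent=2) + "\n"
    elif fmt == "csv":
        text = pd.DataFrame(records).to_csv(index=False)
    else:
        raise ValueError("fmt must be 'json' or 'csv'")
    if path not in (None, "-"):
        Path(path).write_text(text)
    return text


def write_curve(curve: RocCurve, path) -> None:
    """Export ROC vertices as CSV with columns threshold, fpr, tpr.

    Values are written with full precision (repr round-trip), so reading the
    file back reproduces the vertices exactly; the origin's sentinel
    threshold appears as ``inf``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for t, x, y in zip(curve.thresholds, curve.fpr, curve.tpr):
            writer.writerow([repr(float(t)), repr(float(x)), repr(float(y))])


def read_curve(path) -> RocCurve:
    """Read back a curve written by :func:`write_curve`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return RocCurve(
        thresholds=df["threshold"].to_numpy(dtype=float),
        fpr=df["fpr"].to_numpy(dtype=float),
        tpr=df["tpr"].to_numpy(dtype=float),
    )
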