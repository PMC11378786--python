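"""Delimited-text I/O for meta-analysis summary tables and results.

All interchange is plain text.  A first-order summary table has one row per
meta-analysis with columns ``id``, ``mean``, ``se``; synthesis results are
emitted as one-row tables with the method, estimate, CI and category.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .meta_core import MAResult
from .synthesis import SynthesisOutcome

__all__ = ["read_ma_table", "results_from_table", "outcomes_to_frame", "write_outcomes"]

_REQUIRED = ("id", "mean", "se")


def read_ma_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a table of first-order MA summaries (columns id, mean, se).

    ``sep=None`` sniffs the delimiter (comma, tab or whitespace).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"summary table {path!s} lacks required columns: {missing}")
    if not (df["se"] > 0).all():
        raise ValueError("all standard errors in the summary table must be positive")
    return df[list(_REQUIRED)]


def results_from_table(df: pd.DataFrame) -> list[MAResult]:
    """Turn summary rows into MAResult records (CI rebuilt as mean +- 1.96 se)."""
    return [MAResult.from_summary(float(r["mean"]), float(r["se"])) for _, r in df.iterrows()]


def outcomes_to_frame(outcomes: Sequence[SynthesisOutcome]) -> pd.DataFrame:
    """One row per synthesis outcome (method, estimate, CI, category, detail)."""
    rows = []
    for o in outcomes:
        rows.append({
            "method": o.method,
            "mean": o.mean,
            "se": o.se,
            "ci_low": o.ci_low,
            "ci_high": o.ci_high,
            "category": o.category.value,
            "detail": ";".join(f"{k}={v}" for k, v in o.detail.items()),
        })
    return pd.DataFrame(rows)


def write_outcomes(outcomes: Sequence[SynthesisOutcome], path: str | Path, sep: str = ",") -> None:
    outcomes_to_frame(outcomes).to_csv(path, sep=sep, index=False)
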