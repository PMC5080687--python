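"""Rendering of balance results as text tables, CSV or JSON.

The balance engine returns full-precision numbers; all rounding happens
here, at display time, controlled by a :class:`ReportSpec`. An undefined
butanol/isopropanol ratio (zero isopropanol titer) renders as ``—`` in text
tables, an empty cell in CSV and ``null`` in JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .balance import BalanceResult
from .errors import ValidationError

__all__ = ["ReportSpec", "results_frame", "render_results", "fold_changes", "render_folds"]

#: Metrics included in fold-change comparisons (ratios condition/baseline).
FOLD_METRICS = (
    "y_b", "y_ib", "p_b", "p_ib", "bi_ratio",
    "nadph_c", "cr_butanol_pct", "cr_ib_pct",
)

_UNDEFINED_TEXT = "—"


@dataclass
class ReportSpec:
    """Display options for a report."""

    fmt: str = "table"
    decimals: int = 2
    baseline: str | None = None
    metrics: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fmt not in ("table", "csv", "json"):
            raise ValidationError(f"unknown format {self.fmt!r}")
        if self.decimals < 0:
            raise ValidationError("decimals must be >= 0")


def results_frame(results: list[BalanceResult]) -> pd.DataFrame:
    """Full-precision DataFrame, one row per condition."""
    return pd.DataFrame([r.to_dict() for r in results]).set_index("label")


def _rounded(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    return df.round(decimals)


def render_results(results: list[BalanceResult], spec: ReportSpec | None = None) -> str:
    """Render results in the requested format; rounding at display only."""
    spec = spec or ReportSpec()
    df = results_frame(results)
    if spec.metrics:
        missing = [m for m in spec.metrics if m not in df.columns]
        if missing:
            raise ValidationError(f"unknown metrics: {missing}")
        df = df[list(spec.metrics)]
    df = _rounded(df, spec.decimals)
    if spec.fmt == "json":
        # pandas maps NaN (undefined B/I) to JSON null
        return json.dumps(json.loads(df.reset_index().to_json(orient="records")), indent=2)
    if spec.fmt == "csv":
        return df.to_csv()
    return df.fillna(_UNDEFINED_TEXT).to_string()


def fold_changes(results: list[BalanceResult], baseline: str) -> pd.DataFrame:
    """Per-metric ratios condition/baseline at full precision.

    Raises
    ------
    ValidationError
        If the baseline label is absent (the message lists available labels).
    """
    df = results_frame(results)
    if baseline not in df.index:
        raise ValidationError(
            f"baseline {baseline!r} not found; available labels: "
            + ", ".join(map(str, df.index))
        )
    base = df.loc[baseline]
    folds = pd.DataFrame(index=df.index)
    for metric in FOLD_METRICS:
        if metric not in df.columns:
            continue
        denom = base[metric]
        if denom is None or pd.isna(denom) or denom == 0:
            folds[metric] = float("nan")
        else:
            folds[metric] = df[metric].astype(float) / float(denom)
    return folds


def render_folds(folds: pd.DataFrame, spec: ReportSpec | None = None) -> str:
    """Fold-change report; folds displayed at 1 decimal by convention."""
    spec = spec or ReportSpec()
    df = folds.round(1)
    if spec.fmt == "json":
        return json.dumps(json.loads(df.reset_index().to_json(orient="records")), indent=2)
    if spec.fmt == "csv":
        return df.to_csv()
    return df.fillna(_UNDEFINED_TEXT).to_string()
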