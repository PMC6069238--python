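"""Result tables: percentile reports, route comparisons, display conventions.

The rendered tables follow the conventions of published %ADI percentile
tables: values below 0.001% print as ``<0.001%``; values below 10% print
with three decimals (``8.313%``); values at or above 10% print with two
(``16.89%``).  Confidence bounds render in parentheses with the same rule.
Ratios are always computed from unrounded values and rounded exactly once,
at render time, to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, EmptyComparisonError
from .mc import PercentileReport

__all__ = [
    "ExternalPercentiles",
    "RouteComparison",
    "format_percent",
    "parse_percent",
    "percentile_label",
    "build_comparison",
    "render_percentile_table",
    "plot_pct_adi_density",
]

DISPLAY_FLOOR = 0.001  # percent; below this a cell prints "<0.001%"


@dataclass(frozen=True)
class ExternalPercentiles:
    """Percentile estimates taken from an external source (a published table).

    Missing entries (``NA`` cells) are NaN.  Shape: ``percentiles`` strictly
    increasing; ``point``/``lower``/``upper`` aligned, NaN allowed.
    """

    percentiles: np.ndarray
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def from_csv(cls, path) -> "ExternalPercentiles":
        """Read a (percentile, point, ci_lower, ci_upper) CSV; blank = NA."""
        df = pd.read_csv(path)
        required = {"percentile", "point"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: need columns {sorted(required)}")
        probs = df["percentile"].to_numpy(dtype=float)
        if np.any(np.diff(probs) <= 0):
            raise DataError(f"{path}: percentiles must be strictly increasing")
        point = df["point"].to_numpy(dtype=float)
        lower = df.get("ci_lower", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
        upper = df.get("ci_upper", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
        return cls(percentiles=probs, point=point, lower=lower, upper=upper)

    def __len__(self) -> int:
        return len(self.percentiles)


def _as_external(report) -> ExternalPercentiles:
    if isinstance(report, ExternalPercentiles):
        return report
    if isinstance(report, PercentileReport):
        return ExternalPercentiles(
            percentiles=np.asarray(report.percentiles, dtype=float),
            point=np.asarray(report.point, dtype=float),
            lower=np.asarray(report.lower, dtype=float),
            upper=np.asarray(report.upper, dtype=float),
        )
    raise DataError(f"cannot interpret {type(report).__name__} as a percentile table")


@dataclass
class RouteComparison:
    """Non-dietary vs dietary %ADI aligned on a shared percentile grid.

    ``ratio`` holds dietary/non-dietary point ratios, unrounded; NaN where
    either side is missing or the non-dietary point is zero.
    """

    table: pd.DataFrame  # columns: percentile, nondiet_*, diet_*, ratio

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    def render(self) -> str:
        lines = [f"{'Percentile':<12}{'Non-dietary':<28}{'Dietary':<28}{'Ratio':<8}"]
        for row in self.table.itertuples(index=False):
            nd = _render_cell(row.nondiet_point, row.nondiet_lower, row.nondiet_upper)
            di = _render_cell(row.diet_point, row.diet_lower, row.diet_upper)
            ratio = "NA" if not math.isfinite(row.ratio) else f"{row.ratio:.2f}"
            lines.append(
                f"{percentile_label(row.percentile):<12}{nd:<28}{di:<28}{ratio:<8}"
            )
        return "\n".join(lines)

    def ratio_at(self, p: float) -> float:
        idx = np.argmin(np.abs(self.table["percentile"].to_numpy() - p))
        if not np.isclose(self.table["percentile"].iloc[idx], p):
            raise DataError(f"percentile {p} not in comparison grid")
        return float(self.table["ratio"].iloc[idx])


def format_percent(value: float) -> str:
    """Apply the display floor and the 3-decimal / 2-decimal precision switch."""
    if not math.isfinite(value):
        return "NA"
    if value < DISPLAY_FLOOR:
        return "<0.001%"
    if value < 10.0:
        return f"{value:.3f}%"
    return f"{value:.2f}%"


def parse_percent(text: str) -> float:
    """Inverse of :func:`format_percent` up to the printed precision.

    ``"<0.001%"`` parses as 0.0 (the value is only known to be below the
    floor); ``"NA"`` parses as NaN.
    """
    text = text.strip()
    if text == "NA":
        return math.nan
    if text.startswith("<"):
        return 0.0
    if not text.endswith("%"):
        raise DataError(f"not a rendered percent cell: {text!r}")
    return float(text[:-1])


def percentile_label(p: float) -> str:
    """0.975 -> 'P97.5'."""
    return f"P{100.0 * p:g}"


def _render_cell(point: float, lower: float, upper: float) -> str:
    if not math.isfinite(point):
        return "NA"
    if math.isfinite(lower) and math.isfinite(upper):
        return f"{format_percent(point)} ({format_percent(lower)}, {format_percent(upper)})"
    return format_percent(point)


def build_comparison(nondietary, dietary) -> RouteComparison:
    """Align a non-dietary report with external dietary percentiles.

    Accepts a :class:`~dustintake.mc.PercentileReport` or
    :class:`ExternalPercentiles` on either side.  Rows align on percentiles
    shared by both grids; dietary cells missing at a shared percentile render
    as NA and produce no ratio.
    """
    nd = _as_external(nondietary)
    di = _as_external(dietary)
    rows = []
    for i, p in enumerate(nd.percentiles):
        j = np.flatnonzero(np.isclose(di.percentiles, p))
        if j.size == 0:
            continue
        j = int(j[0])
        nd_pt = float(nd.point[i])
        di_pt = float(di.point[j])
        ratio = (
            di_pt / nd_pt
            if math.isfinite(di_pt) and math.isfinite(nd_pt) and nd_pt > 0
            else math.nan
        )
        rows.append(
            {
                "percentile": float(p),
                "nondiet_point": nd_pt,
                "nondiet_lower": float(nd.lower[i]),
                "nondiet_upper": float(nd.upper[i]),
                "diet_point": di_pt,
                "diet_lower": float(di.lower[j]),
                "diet_upper": float(di.upper[j]),
                "ratio": ratio,
            }
        )
    if not rows:
        raise EmptyComparisonError("no overlapping percentiles between the two tables")
    return RouteComparison(table=pd.DataFrame(rows))


def render_percentile_table(report, title: str = "") -> str:
    """Plain-text percentile table with CI cells, one row per percentile."""
    ext = _as_external(report)
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Percentile':<12}{'% of ADI (95% CI)':<32}")
    for p, pt, lo, hi in zip(ext.percentiles, ext.point, ext.lower, ext.upper):
        lines.append(f"{percentile_label(p):<12}{_render_cell(pt, lo, hi):<32}")
    return "\n".join(lines)


def plot_pct_adi_density(draws, path, label: str = "% of ADI") -> None:
    """Log-scale density plot of simulated %ADI draws (matplotlib, Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(draws, dtype=float)
    x = x[x > 0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.log10(x), bins=200, density=True, color="#4477aa")
    ax.set_xlabel(f"log10({label})")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
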