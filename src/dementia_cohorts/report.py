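"""Descriptive and inferential output tables.

All percentages are rounded half-away-from-zero to one decimal and
coefficients to two decimals — the printing convention used consistently
in the summary, prevalence, and coefficient tables.  Tables are plain
:class:`pandas.DataFrame` objects and export to delimited text, so a
re-read table equals the in-memory one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (2.45 → 2.5, −2.45 → −2.5) at ndigits."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, half-away-from-zero to one decimal.

    Exact rational arithmetic, so printed-count percentages recompute
    reproducibly (e.g. 58 883 of 99 420 → 59.2).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    ratio = (Decimal(100) * Decimal(numerator)) / Decimal(denominator)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# prevalence by age group × cohort
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceTable:
    """Dementia prevalence per (age group, cohort) cell with margins."""

    cells: pd.DataFrame  # age_group, cohort, n, n_dementia, prevalence_pct
    by_age_group: pd.DataFrame
    by_cohort: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PrevalenceTable":
        cells = pd.read_csv(path)
        return cls(
            cells=cells,
            by_age_group=_margin(cells, "age_group"),
            by_cohort=_margin(cells, "cohort"),
        )

    def pivot(self) -> pd.DataFrame:
        """Age groups × cohorts matrix of prevalence percentages."""
        return self.cells.pivot(
            index="age_group", columns="cohort", values="prevalence_pct"
        )


def _margin(cells: pd.DataFrame, by: str) -> pd.DataFrame:
    g = cells.groupby(by, sort=True)[["n", "n_dementia"]].sum().reset_index()
    g["prevalence_pct"] = [
        percentage(int(d), int(n)) for d, n in zip(g["n_dementia"], g["n"])
    ]
    return g


def prevalence_table(
    records: pd.DataFrame, outcome: str = "dementia_hat"
) -> PrevalenceTable:
    """Per-cell dementia prevalence; empty cells are absent, never zero."""
    needed = {"age_group", "cohort", outcome}
    if not records.empty and not needed.issubset(records.columns):
        raise KeyError(f"records need columns {sorted(needed)}")
    if records.empty:
        empty = pd.DataFrame(
            columns=["age_group", "cohort", "n", "n_dementia", "prevalence_pct"]
        )
        return PrevalenceTable(empty, empty.copy(), empty.copy())
    valid = records.dropna(subset=[outcome])
    g = (
        valid.groupby(["age_group", "cohort"], observed=True)[outcome]
        .agg(n="size", n_dementia="sum")
        .reset_index()
    )
    g["prevalence_pct"] = [
        percentage(int(d), int(n)) for d, n in zip(g["n_dementia"], g["n"])
    ]
    return PrevalenceTable(
        cells=g, by_age_group=_margin(g, "age_group"), by_cohort=_margin(g, "cohort")
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summary_table(records: pd.DataFrame, dialect=None) -> pd.DataFrame:
    """Counts and column percentages by gender, age group, and birth cohort.

    One row per variable level: (block, level, count, pct); within each
    block the counts sum to the number of person-wave observations.
    """
    total = len(records)
    rows: list[tuple[str, str, int, float]] = []

    def block(name: str, series: pd.Series, order=None) -> None:
        counts = series.value_counts(dropna=True)
        levels = order if order is not None else sorted(counts.index)
        for level in levels:
            c = int(counts.get(level, 0))
            rows.append((name, str(level), c, percentage(c, total) if total else 0.0))

    if total:
        block("gender", records["gender"], ["female", "male"])
        age_order = sorted(records["age_group"].dropna().unique())
        block("age_group", records["age_group"], age_order)
        if dialect is not None:
            cohort_order = [c for c in dialect.cohort_labels
                            if c in set(records["cohort"].dropna())]
        else:
            cohort_order = sorted(records["cohort"].dropna().unique())
        block("cohort", records["cohort"], cohort_order)
    table = pd.DataFrame(rows, columns=["block", "level", "count", "pct"])
    for name, sub in table.groupby("block"):
        if int(sub["count"].sum()) != total:
            logger.warning("block %s counts do not sum to total (missing values?)", name)
    return table


# ---------------------------------------------------------------------------
# coefficient tables
# ---------------------------------------------------------------------------

def significance_mark(p_value: float) -> str:
    """Two-sided significance mark: 'b' for P<.01, 'c' for P<.05, else ''."""
    if p_value < 0.01:
        return "b"
    if p_value < 0.05:
        return "c"
    return ""


def format_estimate(estimate: float, low: float, high: float) -> str:
    """'-0.18 (-0.25 to -0.10)' — two decimals, half away from zero."""
    fmt = lambda v: f"{round_half_away(v, 2):.2f}"
    return f"{fmt(estimate)} ({fmt(low)} to {fmt(high)})"


def coefficient_table(fits: Mapping[str, object], columns: str = "cohort") -> pd.DataFrame:
    """Side-by-side formatted cohort coefficients for several fits.

    ``fits`` maps a region/stratum name to an APC fit exposing
    ``coefficients``, ``ci95``, ``p_values`` and ``n_obs``.  Unfitted
    (``None``) entries are omitted with a warning.
    """
    table: dict[str, dict[str, str]] = {}
    n_row: dict[str, str] = {}
    for region, fit in fits.items():
        if fit is None or not getattr(fit, "converged", True):
            logger.warning("region %s has no converged fit; omitted", region)
            continue
        col: dict[str, str] = {}
        for name, est in fit.coefficients.items():
            if columns and not name.startswith(f"{columns}:"):
                continue
            lo, hi = fit.ci95[name]
            mark = significance_mark(fit.p_values[name])
            label = name.split(":", 1)[1] if ":" in name else name
            col[label] = format_estimate(est, lo, hi) + (f" [{mark}]" if mark else "")
        table[region] = col
        n_row[region] = str(fit.n_obs)
    out = pd.DataFrame(table)
    if not out.empty:
        out.loc["No. of observations"] = pd.Series(n_row)
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_prevalence(table: PrevalenceTable, path: str | Path) -> None:
    """Line plot of prevalence by age group, one line per birth cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    piv = table.pivot()
    for cohort in piv.columns:
        ax.plot(piv.index, piv[cohort], marker="o", label=str(cohort))
    ax.set_xlabel("Age group")
    ax.set_ylabel("Dementia prevalence (%)")
    ax.legend(title="Birth cohort", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cohort_coefficients(fits: Mapping[str, object], path: str | Path) -> None:
    """Cohort point estimates with 95% CI bars per region/stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    offset = 0.0
    for region, fit in fits.items():
        if fit is None:
            continue
        names = [k for k in fit.coefficients if k.startswith("cohort:")]
        xs = np.arange(len(names)) + offset
        est = [fit.coefficients[k] for k in names]
        err = [
            (fit.coefficients[k] - fit.ci95[k][0], fit.ci95[k][1] - fit.coefficients[k])
            for k in names
        ]
        ax.errorbar(
            xs, est, yerr=np.array(err).T, fmt="o", capsize=3, label=str(region)
        )
        ax.set_xticks(np.arange(len(names)))
        ax.set_xticklabels([k.split(":", 1)[1] for k in names], rotation=45, ha="right")
        offset += 0.12
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("Cohort coefficient (latent scale)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
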