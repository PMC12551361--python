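"""Reading, validation, and harmonization of multi-wave aging panels.

Panels are held in memory as :class:`pandas.DataFrame` objects with one row
per person-wave and a fixed column schema (:data:`PANEL_COLUMNS`).  On disk
they are comma-separated UTF-8 text with a header row; missing values are
written as the explicit sentinel ``NA`` (never an empty string).

The module also implements the age/cohort arithmetic shared by every
downstream stage: exact calendar-year age (age = interview year − birth
year), the six 5-year age groups starting at 71–75, and survey-specific
birth-cohort bins.  Surveys differ only in their cohort binning — the US
panel opens with a wide 1890–1913 reference cohort (8 bins in total) while
the European and English panels open with 1901–1918 and 1908–1918
respectively (7 bins) — so each is described by a small
:class:`SurveyDialect` that can also be loaded from a YAML descriptor,
allowing new surveys to be added without code changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sentinel written to / read from delimited files for missing values.
MISSING = "NA"

#: Cognitive test score columns and their valid closed ranges.
SCORE_RANGES: Mapping[str, tuple[float, float]] = {
    "word_recall": (0, 20),  # immediate + delayed 10-word recall
    "serial7": (0, 5),  # serial-sevens subtraction, correct steps
    "orientation": (0, 4),  # date orientation items
}

SCORE_COLUMNS: tuple[str, ...] = tuple(SCORE_RANGES)

#: Fixed panel schema (order used when writing files).
PANEL_COLUMNS: tuple[str, ...] = (
    "person_id",
    "country",
    "birth_year",
    "gender",
    "education_years",
    "wave",
    "interview_year",
    "proxy",
    *SCORE_COLUMNS,
    "adl_count",
    "iadl_count",
    "informant_score",
)

#: The six age groups: 71–75, 76–80, 81–85, 86–90, 91–95, 96+.
AGE_GROUP_BOUNDS: tuple[tuple[int, float], ...] = (
    (71, 75),
    (76, 80),
    (81, 85),
    (86, 90),
    (91, 95),
    (96, math.inf),
)

AGE_GROUP_LABELS: tuple[str, ...] = ("71-75", "76-80", "81-85", "86-90", "91-95", "96+")

#: Minimum eligible age: respondents older than 70 at interview.
MIN_AGE = 71


class PanelValidationError(ValueError):
    """Raised when a panel file cannot be accepted as a whole."""


class CoverageError(KeyError):
    """Raised when the GDP series does not cover a (country, year) pair."""


@dataclass(frozen=True)
class SurveyDialect:
    """Cohort-binning conventions of one survey family.

    ``cohort_bins`` are closed birth-year intervals, ordered and disjoint;
    the first bin is the reference cohort of every regression.
    """

    name: str
    cohort_bins: tuple[tuple[int, int], ...]
    min_age: int = MIN_AGE
    age_groups: tuple[tuple[int, float], ...] = AGE_GROUP_BOUNDS

    def __post_init__(self) -> None:
        bins = self.cohort_bins
        if not bins:
            raise ValueError("dialect needs at least one cohort bin")
        for lo, hi in bins:
            if lo > hi:
                raise ValueError(f"cohort bin {lo}-{hi} is inverted")
        for (_, hi), (lo2, _) in zip(bins, bins[1:]):
            if lo2 <= hi:
                raise ValueError("cohort bins must be disjoint and ordered")

    @property
    def cohort_labels(self) -> tuple[str, ...]:
        return tuple(f"{lo}-{hi}" for lo, hi in self.cohort_bins)

    @property
    def reference_cohort(self) -> str:
        return self.cohort_labels[0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyDialect":
        """Load a dialect descriptor (``name`` + list of ``[lo, hi]`` bins)."""
        spec = yaml.safe_load(Path(path).read_text())
        bins = tuple((int(lo), int(hi)) for lo, hi in spec["cohort_bins"])
        return cls(name=str(spec["name"]), cohort_bins=bins)


def _five_year_bins(first: int = 1919, last: int = 1948) -> tuple[tuple[int, int], ...]:
    return tuple((lo, lo + 4) for lo in range(first, last - 3, 5))


#: US survey: wide 1890–1913 reference cohort, then 5-year bins → 8 bins.
HRS = SurveyDialect("HRS", ((1890, 1913), (1914, 1918)) + _five_year_bins())
#: European survey: 1901–1918 reference, then 5-year bins → 7 bins.
SHARE = SurveyDialect("SHARE", ((1901, 1918),) + _five_year_bins())
#: English survey: 1908–1918 reference, then 5-year bins → 7 bins.
ELSA = SurveyDialect("ELSA", ((1908, 1918),) + _five_year_bins())

DIALECTS: Mapping[str, SurveyDialect] = {"HRS": HRS, "SHARE": SHARE, "ELSA": ELSA}


# ---------------------------------------------------------------------------
# age / cohort arithmetic
# ---------------------------------------------------------------------------

def compute_age(interview_year: int, birth_year: int) -> int:
    """Exact calendar-year age: interview year minus birth year."""
    age = int(interview_year) - int(birth_year)
    if age < 0:
        raise ValueError(
            f"interview year {interview_year} precedes birth year {birth_year}"
        )
    return age


def bin_age_group(age: int) -> int | None:
    """Map an integer age to age group 1..6, or ``None`` if younger than 71."""
    if isinstance(age, bool) or not float(age).is_integer():
        raise ValueError(f"age must be an integer, got {age!r}")
    age = int(age)
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age < MIN_AGE:
        return None
    for group, (lo, hi) in enumerate(AGE_GROUP_BOUNDS, start=1):
        if lo <= age <= hi:
            return group
    raise AssertionError("unreachable: groups tile [71, inf)")


def bin_cohort(birth_year: int, dialect: SurveyDialect) -> str | None:
    """Return the dialect's cohort label containing ``birth_year``, else ``None``."""
    for (lo, hi), label in zip(dialect.cohort_bins, dialect.cohort_labels):
        if lo <= int(birth_year) <= hi:
            return label
    return None


# ---------------------------------------------------------------------------
# GDP series
# ---------------------------------------------------------------------------

@dataclass
class GDPSeries:
    """Annual real GDP growth rates (percent) by country and calendar year."""

    frame: pd.DataFrame  # columns: country, year, growth_pct

    def __post_init__(self) -> None:
        required = {"country", "year", "growth_pct"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"GDP frame needs columns {sorted(required)}")
        if self.frame.duplicated(["country", "year"]).any():
            raise ValueError("duplicate (country, year) entries in GDP series")

    def get(self, country: str, year: int) -> float:
        sel = self.frame[
            (self.frame["country"] == country) & (self.frame["year"] == int(year))
        ]
        if sel.empty:
            raise CoverageError(f"no GDP growth for ({country}, {year})")
        return float(sel["growth_pct"].iloc[0])

    def covers(self, country: str, year: int) -> bool:
        return bool(
            ((self.frame["country"] == country) & (self.frame["year"] == int(year))).any()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GDPSeries":
        return cls(pd.read_csv(path, na_values=[MISSING], keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# panel reading & validation
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    """Machine-readable record of rows dropped during validation."""

    rejections: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, reason: str) -> None:
        self.rejections.append((row, reason))

    def __len__(self) -> int:
        return len(self.rejections)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejections, columns=["row", "reason"])


def _row_problems(row: pd.Series) -> list[str]:
    problems: list[str] = []
    if pd.isna(row["person_id"]) or pd.isna(row["birth_year"]) or pd.isna(row["interview_year"]):
        problems.append("missing identifier or year")
        return problems
    if int(row["interview_year"]) < int(row["birth_year"]):
        problems.append("interview year precedes birth year")
    gender = row.get("gender")
    if not pd.isna(gender) and gender not in ("female", "male"):
        problems.append(f"unknown gender {gender!r}")
    edu = row.get("education_years")
    if not pd.isna(edu) and float(edu) < 0:
        problems.append("negative education years")
    proxy = bool(row["proxy"])
    informant = row.get("informant_score")
    if proxy and pd.isna(informant):
        problems.append("proxy respondent without informant score")
    if not proxy and not pd.isna(informant):
        problems.append("informant score on self-respondent")
    if not pd.isna(informant) and not (1.0 <= float(informant) <= 5.0):
        problems.append("informant score outside 1-5")
    for col, (lo, hi) in SCORE_RANGES.items():
        val = row.get(col)
        if not pd.isna(val) and not (lo <= float(val) <= hi):
            problems.append(f"{col} outside {lo}-{hi}")
    for col in ("adl_count", "iadl_count"):
        val = row.get(col)
        if not pd.isna(val) and not (0 <= float(val) <= 5):
            problems.append(f"{col} outside 0-5")
    return problems


def read_panel(
    path: str | Path,
    dialect: SurveyDialect | str,
    *,
    max_reject_fraction: float = 0.5,
) -> tuple[pd.DataFrame, RejectionReport]:
    """Read a delimited panel file, validating each row.

    Rows violating record invariants are dropped and collected in a
    :class:`RejectionReport` (1-based data row numbers with reasons).  More
    than ``max_reject_fraction`` rejected rows, an unknown dialect, or a
    missing required column is a hard error.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise PanelValidationError(f"unknown survey dialect {dialect!r}") from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, na_values=[MISSING], keep_default_na=False)
    missing_cols = set(PANEL_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise PanelValidationError(f"panel file lacks columns {sorted(missing_cols)}")
    raw = raw.copy()
    raw["proxy"] = raw["proxy"].map(
        lambda v: v if pd.isna(v) else str(v).strip().lower() in ("1", "true", "yes")
    )

    report = RejectionReport()
    keep = np.ones(len(raw), dtype=bool)
    for i, (_, row) in enumerate(raw.iterrows()):
        problems = _row_problems(row)
        if problems:
            keep[i] = False
            report.add(i + 1, "; ".join(problems))
    if len(raw) and (~keep).sum() / len(raw) > max_reject_fraction:
        raise PanelValidationError(
            f"{(~keep).sum()} of {len(raw)} rows rejected — file unusable"
        )
    records = raw[keep].reset_index(drop=True)
    records.attrs["dialect"] = dialect.name
    return records, report


def write_panel(records: pd.DataFrame, path: str | Path) -> None:
    """Write a panel in the canonical dialect (``NA`` sentinel, fixed order)."""
    cols = [c for c in PANEL_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    out = records[cols].copy()
    if "proxy" in out:
        out["proxy"] = out["proxy"].astype(int)
    out.to_csv(path, index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# derived columns, eligibility, GDP join
# ---------------------------------------------------------------------------

def add_derived_columns(records: pd.DataFrame, dialect: SurveyDialect) -> pd.DataFrame:
    """Attach ``age``, ``age_group`` (1..6 or <NA>) and ``cohort`` columns."""
    out = records.copy()
    out["age"] = out["interview_year"].astype(int) - out["birth_year"].astype(int)
    if (out["age"] < 0).any():
        raise ValueError("negative age encountered (interview before birth)")
    out["age_group"] = pd.array(
        [bin_age_group(a) for a in out["age"]], dtype="Int64"
    )
    out["cohort"] = [bin_cohort(b, dialect) for b in out["birth_year"]]
    return out


def filter_eligible(
    records: pd.DataFrame, dialect: SurveyDialect | None = None
) -> pd.DataFrame:
    """Keep person-waves aged ≥ 71 with an in-range birth cohort.

    Exclusion counts by reason are logged; the result carries ``age``,
    ``age_group`` and ``cohort`` columns.
    """
    if dialect is None:
        dialect = DIALECTS[records.attrs.get("dialect", "HRS")]
    out = add_derived_columns(records, dialect)
    under_age = out["age_group"].isna()
    out_of_cohort = pd.Series([c is None for c in out["cohort"]], index=out.index)
    logger.info(
        "eligibility filter: %d under age 71, %d outside cohort bins, %d kept",
        int(under_age.sum()),
        int((out_of_cohort & ~under_age).sum()),
        int((~under_age & ~out_of_cohort).sum()),
    )
    kept = out[~under_age & ~out_of_cohort].reset_index(drop=True)
    kept.attrs["dialect"] = dialect.name
    return kept


def attach_gdp(records: pd.DataFrame, gdp: GDPSeries) -> pd.DataFrame:
    """Join each record with its own country's growth rate in its interview year.

    Pooled multi-country fits use the per-country value, never an average.
    Missing coverage for any (country, year) pair present is a hard error.
    """
    pairs = records[["country", "interview_year"]].drop_duplicates()
    uncovered = [
        (c, int(y))
        for c, y in pairs.itertuples(index=False)
        if not gdp.covers(c, int(y))
    ]
    if uncovered:
        raise CoverageError(f"GDP series does not cover {sorted(uncovered)}")
    merged = records.merge(
        gdp.frame.rename(columns={"year": "interview_year", "growth_pct": "gdp_growth"}),
        on=["country", "interview_year"],
        how="left",
    )
    merged.attrs.update(records.attrs)
    return merged
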