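"""Synthetic multi-wave aging panels with known age, cohort, and period effects.

The generator mirrors the data-generating process assumed by the downstream
age-period-cohort models.  Latent cognition of person *i* at wave *t* is

    c_it = age_effect(agegroup_it) + cohort_effect(cohort_i)
           + period_coupling · gdp_growth(country_i, t) + u_i + eps_it,

with a person-level random intercept u_i ~ N(0, individual_sd²) and
occasion noise eps_it ~ N(0, noise_sd²).  Lower latent cognition is worse;
two ordered cutpoints κ1 < κ2 partition the scale into the three clinical
classes (c < κ1 → dementia, κ1 ≤ c < κ2 → cognitively impaired not
demented, c ≥ κ2 → normal).  Observable survey data (test scores, ADL/IADL
limitation counts, proxy interviews with an informant questionnaire) are
noisy, truncated views of the latent scale, and a small random subsample of
persons receives a gold-standard clinical adjudication at one wave,
emulating a one-time in-home assessment substudy.

Because the true effects are known, classification and APC estimation can
be tested by parameter recovery.  All randomness flows from a single root
seed through named substreams, so every stage is individually reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from dementia_cohorts.panel import (
    HRS,
    DIALECTS,
    GDPSeries,
    SCORE_RANGES,
    SurveyDialect,
    bin_cohort,
)

logger = logging.getLogger(__name__)

#: Ordered class codes on the latent scale (lowest cognition first).
DEMENTIA, CIND, NORMAL = 0, 1, 2
CLASS_NAMES = {DEMENTIA: "dementia", CIND: "cind", NORMAL: "normal"}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default latent age-group effects (lower = worse cognition with age).
DEFAULT_AGE_EFFECT: Mapping[int, float] = {
    1: 0.0,
    2: -0.30,
    3: -0.60,
    4: -0.95,
    5: -1.30,
    6: -1.60,
}

#: Default latent cohort effects: later-born cohorts have better cognition,
#: with a gradient whose probit-scale magnitude matches what large US panels
#: report (reference 1890–1913 bin at zero, up to ~+0.55 for 1944–1948).
DEFAULT_COHORT_EFFECT: Mapping[str, float] = {
    "1890-1913": 0.0,
    "1914-1918": 0.10,
    "1919-1923": 0.18,
    "1924-1928": 0.27,
    "1929-1933": 0.32,
    "1934-1938": 0.31,
    "1939-1943": 0.46,
    "1944-1948": 0.55,
}

#: Observation models for cognitive scores: score = round(clip(a + b·c + N(0, s))).
DEFAULT_SCORE_MODELS: Mapping[str, tuple[float, float, float]] = {
    "word_recall": (9.5, 3.5, 2.5),
    "serial7": (3.3, 1.1, 1.1),
    "orientation": (3.6, 0.8, 0.7),
}

#: Informant questionnaire (IQCODE-like, 1–5, higher = more decline).
DEFAULT_INFORMANT_MODEL: tuple[float, float, float] = (3.1, -0.75, 0.45)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults encode the study regime the package is tested under: 10 000
    persons observed over six biennial waves, ages above 70, roughly 10%
    proxy interviews, 10% gold-standard adjudication, and age/cohort
    gradients of realistic probit-scale magnitude.
    """

    n_individuals: int = 10_000
    survey_years: tuple[int, ...] = (2004, 2006, 2008, 2010, 2012, 2014)
    birth_year_range: tuple[int, int] = (1909, 1943)
    cohort_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_EFFECT)
    )
    age_effect: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_EFFECT)
    )
    period_coupling: float = 0.03
    individual_sd: float = 0.5
    noise_sd: float = 1.0
    diagnosis_cutpoints: tuple[float, float] = (-1.7, -0.8)
    #: p(proxy | latent c) = 1 / (1 + exp(intercept + slope·c)); slope > 0
    #: makes proxy interviews more likely as cognition falls.
    proxy_prob_given_latent: tuple[float, float] = (3.0, 1.5)
    gold_fraction: float = 0.1
    attrition_rate_per_wave: float = 0.10
    #: Optional cognition-linked attrition: exit probability becomes
    #: rate · (1 + slope · max(0, −c)), capped at 1, to exercise the
    #: worry that the cognitively impaired die between waves.
    attrition_cognition_slope: float = 0.0
    female_fraction: float = 0.58
    #: Optional additional latent cohort shift applied to women only
    #: (e.g. a stronger improvement gradient for recent female cohorts).
    cohort_effect_female: Mapping[str, float] | None = None
    score_models: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MODELS)
    )
    informant_model: tuple[float, float, float] = DEFAULT_INFORMANT_MODEL
    dialect: SurveyDialect = HRS
    seed: int = 0

    def __post_init__(self) -> None:
        k1, k2 = self.diagnosis_cutpoints
        if not k1 < k2:
            raise ValueError(f"cutpoints must satisfy κ1 < κ2, got {k1} ≥ {k2}")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if list(self.survey_years) != sorted(set(self.survey_years)):
            raise ValueError("survey_years must be strictly increasing")
        if not 0 < self.gold_fraction <= 1:
            raise ValueError("gold_fraction must be in (0, 1]")
        if not 0 <= self.attrition_rate_per_wave < 1:
            raise ValueError("attrition_rate_per_wave must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be non-negative")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError("birth_year_range inverted")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(open(path))
        if "dialect" in raw and isinstance(raw["dialect"], str):
            raw["dialect"] = DIALECTS[raw["dialect"]]
        for key in ("survey_years", "birth_year_range", "diagnosis_cutpoints",
                    "proxy_prob_given_latent", "informant_model"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "age_effect" in raw:
            raw["age_effect"] = {int(k): float(v) for k, v in raw["age_effect"].items()}
        if "score_models" in raw:
            raw["score_models"] = {k: tuple(v) for k, v in raw["score_models"].items()}
        return cls(**raw)


@dataclass
class TruePanel:
    """Simulated person-waves with both truth and identifiers.

    ``records`` has one row per eligible person-wave and carries, besides
    the identifier/demographic columns, the latent cognition draw, the
    3-class truth and the binary dementia indicator.
    """

    records: pd.DataFrame
    config: SimulationConfig
    n_excluded: int = 0

    @property
    def latent_cognition(self) -> np.ndarray:
        return self.records["latent_cognition"].to_numpy()

    @property
    def true_class(self) -> np.ndarray:
        return self.records["true_class"].to_numpy()

    @property
    def true_dementia(self) -> np.ndarray:
        return self.records["true_dementia"].to_numpy()


# ---------------------------------------------------------------------------
# GDP series
# ---------------------------------------------------------------------------

def simulate_gdp_series(
    years: Sequence[int],
    countries: Sequence[str],
    mean_growth: float = 2.0,
    ar_coefficient: float = 0.5,
    innovation_sd: float = 1.0,
    seed: int = 0,
) -> GDPSeries:
    """Stationary AR(1) annual GDP growth (percent) per country.

    The first year is drawn from the stationary distribution, so the series
    has mean ``mean_growth`` and lag-1 autocorrelation ``ar_coefficient``
    marginally at every year.
    """
    years = list(years)
    countries = list(countries)
    if not years or not countries:
        raise ValueError("years and countries must be non-empty")
    if innovation_sd < 0:
        raise ValueError("innovation_sd must be non-negative")
    if not -1 < ar_coefficient < 1:
        raise ValueError("ar_coefficient must lie in (-1, 1) for stationarity")
    rng = substream(seed, "gdp")
    rows = []
    stat_sd = innovation_sd / np.sqrt(1.0 - ar_coefficient**2)
    for country in countries:
        x = mean_growth + stat_sd * rng.standard_normal()
        for i, year in enumerate(years):
            if i > 0:
                x = mean_growth + ar_coefficient * (x - mean_growth) + (
                    innovation_sd * rng.standard_normal()
                )
            rows.append((country, int(year), float(x)))
    return GDPSeries(pd.DataFrame(rows, columns=["country", "year", "growth_pct"]))


# ---------------------------------------------------------------------------
# latent panel
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig, gdp: GDPSeries) -> TruePanel:
    """Draw the latent panel: eligibility, attrition, latent cognition, truth.

    Persons appear only at waves where their exact calendar-year age is at
    least 71 and they have not yet attrited; persons never eligible at any
    wave (or born outside every cohort bin) are excluded with a logged
    count, not an error.
    """
    n = config.n_individuals
    dialect = config.dialect
    years = np.asarray(config.survey_years)
    n_waves = len(years)
    countries = sorted(gdp.frame["country"].unique())
    if not countries:
        raise ValueError("GDP series contains no countries")

    rng_people = substream(config.seed, "people")
    birth = rng_people.integers(
        config.birth_year_range[0], config.birth_year_range[1] + 1, size=n
    )
    female = rng_people.random(n) < config.female_fraction
    education = np.clip(np.round(rng_people.normal(12.0, 3.0, size=n)), 0, 20)
    country = np.asarray(countries)[rng_people.integers(0, len(countries), size=n)]
    u = substream(config.seed, "intercepts").standard_normal(n) * config.individual_sd

    cohorts = np.array([bin_cohort(b, dialect) for b in birth], dtype=object)
    coh_eff = np.array(
        [config.cohort_effect.get(c, 0.0) if c is not None else np.nan for c in cohorts]
    )
    if config.cohort_effect_female is not None:
        extra = np.array(
            [config.cohort_effect_female.get(c, 0.0) if c is not None else 0.0 for c in cohorts]
        )
        coh_eff = coh_eff + np.where(female, extra, 0.0)

    ages = years[None, :] - birth[:, None]  # (n, n_waves)
    groups = np.zeros(ages.shape, dtype=int)
    for idx, (lo, hi) in enumerate(dialect.age_groups, start=1):
        groups[(ages >= lo) & (ages <= hi)] = idx
    age_eff = np.zeros(ages.shape)
    for gnum, val in config.age_effect.items():
        age_eff[groups == gnum] = val

    gmap = {(r.country, int(r.year)): float(r.growth_pct)
            for r in gdp.frame.itertuples(index=False)}
    per_country = {c: np.array([gmap[(c, int(y))] for y in years]) for c in countries}
    growth = np.stack([per_country[c] for c in country])

    eps = substream(config.seed, "noise").standard_normal(ages.shape) * config.noise_sd
    latent = age_eff + coh_eff[:, None] + config.period_coupling * growth + u[:, None] + eps

    # permanent exit before each wave > 1; hazard optionally scaled by the
    # previous wave's latent deficit (worse cognition -> likelier exit)
    attr = substream(config.seed, "attrition").random((n, n_waves))
    gone = np.zeros(n, dtype=bool)
    exited = np.zeros((n, n_waves), dtype=bool)
    base = config.attrition_rate_per_wave
    for w in range(1, n_waves):
        rate = np.full(n, base)
        if config.attrition_cognition_slope:
            deficit = np.maximum(0.0, -latent[:, w - 1])
            rate = np.minimum(1.0, base * (1.0 + config.attrition_cognition_slope * deficit))
        gone |= attr[:, w] < rate
        exited[:, w] = gone

    in_cohort = np.array([c is not None for c in cohorts])
    present = (groups > 0) & ~exited & in_cohort[:, None]
    n_excluded = int((~((groups > 0).any(axis=1) & in_cohort)).sum())
    if n_excluded:
        logger.info("simulate_panel: excluded %d persons never eligible", n_excluded)

    ii, ww = np.nonzero(present)
    k1, k2 = config.diagnosis_cutpoints
    lat = latent[ii, ww]
    true_class = np.where(lat < k1, DEMENTIA, np.where(lat < k2, CIND, NORMAL))
    records = pd.DataFrame(
        {
            "person_id": np.char.add("P", np.char.zfill(ii.astype(str), 6)),
            "country": country[ii],
            "birth_year": birth[ii],
            "gender": np.where(female[ii], "female", "male"),
            "education_years": education[ii],
            "wave": ww + 1,
            "interview_year": years[ww],
            "gdp_growth": growth[ii, ww],
            "latent_cognition": lat,
            "true_class": true_class,
            "true_dementia": (true_class == DEMENTIA).astype(int),
            "age": ages[ii, ww],
            "age_group": pd.array(groups[ii, ww], dtype="Int64"),
            "cohort": cohorts[ii],
        }
    )
    records.attrs["dialect"] = dialect.name
    return TruePanel(records=records, config=config, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def degrade_to_observables(
    panel: TruePanel, config: SimulationConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Project the latent panel onto what a survey actually records.

    Cognitive test scores are affine-in-latent plus independent noise,
    rounded and truncated to their declared ranges; ADL/IADL limitation
    counts are binomial with rates decreasing in latent cognition; a proxy
    interview is drawn with probability increasing as cognition falls, in
    which case self-test scores are missing and an informant score (1–5,
    higher = more decline) is recorded instead.
    """
    config = config or panel.config
    seed = config.seed if seed is None else seed
    rec = panel.records
    latent = rec["latent_cognition"].to_numpy(dtype=float)
    m = len(rec)

    out = rec[
        [
            "person_id",
            "country",
            "birth_year",
            "gender",
            "education_years",
            "wave",
            "interview_year",
        ]
    ].copy()

    a0, b0 = config.proxy_prob_given_latent
    p_proxy = 1.0 / (1.0 + np.exp(a0 + b0 * latent))
    proxy = substream(seed, "proxy").random(m) < p_proxy
    out["proxy"] = proxy

    rng_scores = substream(seed, "scores")
    for name, (a, b, s) in config.score_models.items():
        lo, hi = SCORE_RANGES[name]
        raw = a + b * latent + rng_scores.standard_normal(m) * s
        score = np.clip(np.round(raw), lo, hi)
        out[name] = np.where(proxy, np.nan, score)

    rng_fn = substream(seed, "functional")
    # limitation probability per item rises as cognition falls
    p_adl = 1.0 / (1.0 + np.exp(2.6 + 1.3 * latent))
    p_iadl = 1.0 / (1.0 + np.exp(2.0 + 1.4 * latent))
    out["adl_count"] = rng_fn.binomial(5, p_adl).astype(float)
    out["iadl_count"] = rng_fn.binomial(5, p_iadl).astype(float)

    ai, bi, si = config.informant_model
    informant = np.clip(ai + bi * latent + substream(seed, "informant").standard_normal(m) * si, 1.0, 5.0)
    out["informant_score"] = np.where(proxy, np.round(informant, 2), np.nan)

    out.attrs["dialect"] = rec.attrs.get("dialect", config.dialect.name)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gold standard
# ---------------------------------------------------------------------------

@dataclass
class GoldStandard:
    """Clinically adjudicated 3-class labels on a person subsample.

    One label per sampled person, taken at one randomly chosen observed
    wave (the adjudication substudy was a one-time assessment).  Persons
    are pre-split 50/50 into disjoint calibration and validation halves.
    """

    labels: pd.DataFrame  # person_id, wave, true_class
    train_persons: tuple[str, ...]
    validation_persons: tuple[str, ...]

    def split(self, which: str) -> pd.DataFrame:
        persons = self.train_persons if which == "train" else self.validation_persons
        return self.labels[self.labels["person_id"].isin(persons)]

    def to_csv(self, path) -> None:
        out = self.labels.copy()
        out["split"] = np.where(
            out["person_id"].isin(self.train_persons), "train", "validation"
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GoldStandard":
        raw = pd.read_csv(path)
        return cls(
            labels=raw[["person_id", "wave", "true_class"]],
            train_persons=tuple(raw.loc[raw["split"] == "train", "person_id"]),
            validation_persons=tuple(raw.loc[raw["split"] == "validation", "person_id"]),
        )


def assign_gold_standard(
    panel: TruePanel, gold_fraction: float | None = None, seed: int | None = None
) -> GoldStandard:
    """Simple random person subsample with truth labels at one wave each."""
    config = panel.config
    gold_fraction = config.gold_fraction if gold_fraction is None else gold_fraction
    if not 0 < gold_fraction <= 1:
        raise ValueError("gold_fraction must be in (0, 1]")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "gold")

    persons = panel.records["person_id"].unique()
    n_gold = max(1, int(round(gold_fraction * len(persons))))
    if n_gold < 50:
        logger.warning(
            "gold subsample has only %d persons; calibration may be unstable", n_gold
        )
    sampled = rng.choice(persons, size=n_gold, replace=False)

    by_person = panel.records.groupby("person_id")
    rows = []
    for pid in sampled:
        grp = by_person.get_group(pid)
        pick = grp.iloc[rng.integers(0, len(grp))]
        rows.append((pid, int(pick["wave"]), int(pick["true_class"])))
    labels = pd.DataFrame(rows, columns=["person_id", "wave", "true_class"])

    perm = rng.permutation(n_gold)
    half = n_gold // 2
    train = tuple(labels["person_id"].iloc[perm[:half]])
    val = tuple(labels["person_id"].iloc[perm[half:]])
    return GoldStandard(labels=labels, train_persons=train, validation_persons=val)
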