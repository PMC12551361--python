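"""Synthetic-cohort generator: closed-form oracles and structural invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dementia_cohorts.simulate import (
    DEMENTIA,
    SimulationConfig,
    assign_gold_standard,
    degrade_to_observables,
    simulate_gdp_series,
    simulate_panel,
)

ZERO_EFFECTS = dict(
    cohort_effect={c: 0.0 for c in SimulationConfig().cohort_effect},
    age_effect={g: 0.0 for g in range(1, 7)},
    period_coupling=0.0,
)


# ---------------------------------------------------------------------------
# GDP series
# ---------------------------------------------------------------------------


def test_gdp_degenerate_noise_is_exactly_the_mean():
    gdp = simulate_gdp_series([2000, 2001, 2002], ["US", "DE"], 2.0, 0.0, 0.0, seed=1)
    assert (gdp.frame["growth_pct"] == 2.0).all()
    assert len(gdp.frame) == 6


def test_gdp_same_seed_same_series():
    a = simulate_gdp_series(range(2000, 2020), ["US"], seed=5)
    b = simulate_gdp_series(range(2000, 2020), ["US"], seed=5)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    c = simulate_gdp_series(range(2000, 2020), ["US"], seed=6)
    assert not c.frame["growth_pct"].equals(a.frame["growth_pct"])


def test_gdp_ar1_moments_match_closed_form():
    """Long AR(1): sample mean within 3 SEs of 2.0, lag-1 autocorr within 0.05."""
    mean, ar, sd = 2.0, 0.5, 1.0
    gdp = simulate_gdp_series(range(1, 10_001), ["US"], mean, ar, sd, seed=3)
    x = gdp.frame["growth_pct"].to_numpy()
    stat_var = sd**2 / (1 - ar**2)
    # SE of the mean of an AR(1): sqrt(var/n * (1+ar)/(1-ar))
    se_mean = np.sqrt(stat_var / x.size * (1 + ar) / (1 - ar))
    assert abs(x.mean() - mean) < 3 * se_mean
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert abs(r1 - ar) < 0.05


def test_gdp_invalid_inputs():
    with pytest.raises(ValueError):
        simulate_gdp_series([], ["US"])
    with pytest.raises(ValueError):
        simulate_gdp_series([2000], [])
    with pytest.raises(ValueError):
        simulate_gdp_series([2000], ["US"], ar_coefficient=1.0)


# ---------------------------------------------------------------------------
# latent panel
# ---------------------------------------------------------------------------


def test_cutpoint_below_support_gives_zero_prevalence(default_gdp):
    cfg = SimulationConfig(
        n_individuals=2_000,
        **ZERO_EFFECTS,
        individual_sd=0.0,
        noise_sd=1.0,
        diagnosis_cutpoints=(-30.0, -0.5),
        seed=2,
    )
    panel = simulate_panel(cfg, default_gdp)
    assert panel.records["true_dementia"].sum() == 0


def test_zero_cohort_effects_equalize_prevalence_across_cohorts(default_gdp):
    """With no cohort effect, per-age-group prevalence is cohort-invariant
    up to binomial sampling error at n=20,000."""
    cfg = SimulationConfig(
        n_individuals=20_000,
        cohort_effect={c: 0.0 for c in SimulationConfig().cohort_effect},
        seed=3,
    )
    rec = simulate_panel(cfg, default_gdp).records
    for _, grp in rec.groupby("age_group"):
        pooled = grp["true_dementia"].mean()
        for _, sub in grp.groupby("cohort"):
            if len(sub) < 300:
                continue
            se = np.sqrt(pooled * (1 - pooled) / len(sub))
            assert abs(sub["true_dementia"].mean() - pooled) < 4 * se + 1e-12


def test_prevalence_matches_normal_cdf_oracle(default_gdp):
    """All effects zero, total latent SD 1, κ1=0 → P(dementia)=Φ(0)=0.5."""
    cfg = SimulationConfig(
        n_individuals=20_000,
        **ZERO_EFFECTS,
        individual_sd=0.6,
        noise_sd=0.8,
        diagnosis_cutpoints=(0.0, 0.5),
        seed=4,
    )
    rec = simulate_panel(cfg, default_gdp).records
    # u and eps are independent normals: total SD sqrt(0.36+0.64)=1
    prev = rec["true_dementia"].mean()
    # repeated measures per person: conservative 4-sigma band on persons
    n_persons = rec["person_id"].nunique()
    assert abs(prev - norm.cdf(0.0)) < 4 * np.sqrt(0.25 / n_persons) * 2


def test_simulate_panel_deterministic_under_seed(default_gdp, small_config, small_truth):
    again = simulate_panel(small_config, default_gdp)
    pd.testing.assert_frame_equal(again.records, small_truth.records)


def test_all_person_waves_are_eligible(small_truth):
    rec = small_truth.records
    assert (rec["age"] >= 71).all()
    assert rec["cohort"].notna().all()
    assert rec["true_dementia"].isin([0, 1]).all()
    # class/dementia consistency
    assert (rec["true_dementia"] == (rec["true_class"] == DEMENTIA)).all()


def test_attrition_is_permanent(small_truth):
    waves = small_truth.records.groupby("person_id")["wave"].agg(["min", "max", "size"])
    # a person eligible from first presence onward has contiguous waves:
    # absence after exit is permanent, so waves form one run
    assert (waves["max"] - waves["min"] + 1 == waves["size"]).all()


def test_monotone_age_effect_gives_monotone_prevalence(default_gdp):
    """Prevalence rises with age group in every well-populated cohort."""
    cfg = SimulationConfig(n_individuals=20_000, seed=5)
    rec = simulate_panel(cfg, default_gdp).records
    for cohort, grp in rec.groupby("cohort"):
        by_age = grp.groupby("age_group", observed=True)["true_dementia"].agg(["mean", "size"])
        by_age = by_age[by_age["size"] >= 500]
        diffs = np.diff(by_age["mean"].to_numpy())
        assert (diffs > -0.02).all(), (cohort, by_age)


def test_zero_period_coupling_makes_panel_gdp_invariant():
    gdp_a = simulate_gdp_series(range(2004, 2015), ["US"], 2.0, 0.5, 1.0, seed=21)
    gdp_b = simulate_gdp_series(range(2004, 2015), ["US"], -1.0, 0.2, 3.0, seed=22)
    cfg = SimulationConfig(n_individuals=500, period_coupling=0.0, seed=6)
    rec_a = simulate_panel(cfg, gdp_a).records.drop(columns="gdp_growth")
    rec_b = simulate_panel(cfg, gdp_b).records.drop(columns="gdp_growth")
    pd.testing.assert_frame_equal(rec_a, rec_b)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(diagnosis_cutpoints=(1.0, -1.0))
    with pytest.raises(ValueError):
        SimulationConfig(survey_years=(2004, 2002))
    with pytest.raises(ValueError):
        SimulationConfig(gold_fraction=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(attrition_rate_per_wave=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(noise_sd=0.0)


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text(
        "n_individuals: 100\nseed: 9\ndialect: SHARE\n"
        "survey_years: [2004, 2006]\nbirth_year_range: [1910, 1930]\n"
        "age_effect: {1: 0.0, 2: -0.2, 3: -0.4, 4: -0.6, 5: -0.9, 6: -1.2}\n"
    )
    cfg = SimulationConfig.from_yaml(path)
    assert cfg.n_individuals == 100
    assert cfg.dialect.name == "SHARE"
    assert cfg.age_effect[3] == -0.4


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def test_noiseless_scores_are_deterministic_truncated_affine(default_gdp):
    cfg = SimulationConfig(
        n_individuals=500,
        score_models={"word_recall": (10.0, 2.0, 0.0), "serial7": (3.0, 1.0, 0.0),
                      "orientation": (3.5, 0.8, 0.0)},
        proxy_prob_given_latent=(50.0, 0.0),  # essentially no proxies
        seed=8,
    )
    panel = simulate_panel(cfg, default_gdp)
    obs = degrade_to_observables(panel)
    latent = panel.records["latent_cognition"].to_numpy()
    expected = np.clip(np.round(10.0 + 2.0 * latent), 0, 20)
    got = obs["word_recall"].to_numpy()
    assert np.array_equal(got[~np.isnan(got)], expected[~np.isnan(got)])


def test_observable_ranges_respected(small_observed):
    bounds = {
        "word_recall": (0, 20),
        "serial7": (0, 5),
        "orientation": (0, 4),
        "adl_count": (0, 5),
        "iadl_count": (0, 5),
        "informant_score": (1, 5),
    }
    for col, (lo, hi) in bounds.items():
        vals = small_observed[col].dropna()
        assert vals.between(lo, hi).all(), col


def test_score_latent_correlation_matches_bivariate_normal(default_gdp):
    """At mild truncation, corr(score, latent) ≈ bσ/sqrt(b²σ² + s²)."""
    cfg = SimulationConfig(
        n_individuals=20_000,
        **ZERO_EFFECTS,  # latent centered: negligible truncation
        individual_sd=0.6,
        noise_sd=0.8,
        score_models={"word_recall": (10.0, 3.0, 2.0), "serial7": (2.5, 0.5, 1.0),
                      "orientation": (2.0, 0.4, 0.7)},
        proxy_prob_given_latent=(50.0, 0.0),
        seed=9,
    )
    panel = simulate_panel(cfg, default_gdp)
    obs = degrade_to_observables(panel)
    mask = obs["word_recall"].notna()
    got = np.corrcoef(
        obs.loc[mask, "word_recall"], panel.records.loc[mask.to_numpy(), "latent_cognition"]
    )[0, 1]
    sigma = 1.0  # total latent SD
    expected = 3.0 * sigma / np.sqrt(3.0**2 * sigma**2 + 2.0**2)
    assert abs(got - expected) < 0.05


def test_proxy_interviews_concentrate_among_impaired(small_truth, small_observed):
    latent = small_truth.records["latent_cognition"]
    proxies = small_observed["proxy"].to_numpy()
    assert latent[proxies].mean() < latent[~proxies].mean() - 0.5
    # proxies carry informant scores; self-respondents never do
    assert small_observed.loc[proxies, "informant_score"].notna().all()
    assert small_observed.loc[~proxies, "informant_score"].isna().all()
    assert small_observed.loc[proxies, "word_recall"].isna().all()


# ---------------------------------------------------------------------------
# gold standard
# ---------------------------------------------------------------------------


def test_gold_fraction_one_labels_every_person(small_truth):
    gold = assign_gold_standard(small_truth, gold_fraction=1.0, seed=1)
    assert len(gold.labels) == small_truth.records["person_id"].nunique()
    assert set(gold.train_persons).isdisjoint(gold.validation_persons)


def test_gold_same_seed_same_subsample(small_truth):
    a = assign_gold_standard(small_truth, seed=3)
    b = assign_gold_standard(small_truth, seed=3)
    pd.testing.assert_frame_equal(a.labels, b.labels)
    assert a.train_persons == b.train_persons


def test_gold_labels_equal_truth_at_sampled_wave(small_truth):
    gold = assign_gold_standard(small_truth, seed=4)
    merged = gold.labels.merge(
        small_truth.records[["person_id", "wave", "true_class"]],
        on=["person_id", "wave"],
        suffixes=("_gold", "_panel"),
    )
    assert len(merged) == len(gold.labels)
    assert (merged["true_class_gold"] == merged["true_class_panel"]).all()


def test_gold_label_distribution_matches_population(default_gdp):
    cfg = SimulationConfig(n_individuals=10_000, seed=10)
    panel = simulate_panel(cfg, default_gdp)
    gold = assign_gold_standard(panel, gold_fraction=0.5, seed=10)
    # person-level one-wave class shares vs the sampled labels
    pop = panel.records.groupby("person_id")["true_class"].first()
    n = len(gold.labels)
    for cls in (0, 1, 2):
        share = (gold.labels["true_class"] == cls).mean()
        # loose multinomial 4-sigma band around the per-person wave-1 share
        p = (pop == cls).mean()
        assert abs(share - p) < 4 * np.sqrt(p * (1 - p) / n) + 0.05


def test_gold_round_trip(tmp_path, small_gold):
    path = tmp_path / "gold.csv"
    small_gold.to_csv(path)
    from dementia_cohorts.simulate import GoldStandard

    back = GoldStandard.from_csv(path)
    pd.testing.assert_frame_equal(
        back.labels.reset_index(drop=True), small_gold.labels.reset_index(drop=True)
    )
    assert set(back.train_persons) == set(small_gold.train_persons)
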