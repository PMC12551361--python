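"""Estimate birth-cohort effects on dementia with a GDP period proxy.

Simulates a panel whose true cohort effects on the dementia probit scale
are (0, −0.2, −0.3, −0.5), then fits the random-intercept probit GLMM in
GDP mode and prints the recovered gradient with cluster-robust 95% CIs.
"""

from dementia_cohorts import SimulationConfig, simulate_gdp_series, simulate_panel
from dementia_cohorts.apc import build_design, fit_glmm
from dementia_cohorts.report import coefficient_table

config = SimulationConfig(
    n_individuals=6_000,
    birth_year_range=(1914, 1933),
    cohort_effect={"1914-1918": 0.0, "1919-1923": 0.2,
                   "1924-1928": 0.3, "1929-1933": 0.5},
    period_coupling=0.05,
    seed=19,
)
gdp = simulate_gdp_series(range(2004, 2015), ["US"], innovation_sd=2.0, seed=19)
panel = simulate_panel(config, gdp)

design = build_design(panel.records, config.dialect, mode="gdp",
                      outcome="true_dementia")
fit = fit_glmm(design, link="probit", re="individual_intercept")

print(f"observations: {fit.n_obs}   persons: {fit.n_persons}")
print(f"random-intercept SD: {fit.random_intercept_sd:.3f} (true 0.5)")
print(f"GDP growth coefficient: {fit.coefficients['gdp_growth']:.4f} (true -0.05)")
print("\ncohort coefficients vs reference 1914-1918 "
      "(true: -0.20, -0.30, -0.50; [b] marks P<.01):")
print(coefficient_table({"synthetic": fit}).to_string())
# Negative estimates mean later-born cohorts are less likely to have
# dementia at the same age — the generational improvement the model is
# designed to measure — and each CI should bracket its true value.
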