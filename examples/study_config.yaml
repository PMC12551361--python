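# Example study configuration for the CLI:
#   dementia-cohorts run-all --config examples/study_config.yaml --out-dir study/
# Any SimulationConfig field may appear here; omitted fields keep their
# defaults (see docs/methods.md for the full table).
n_individuals: 5000
seed: 42
dialect: HRS
survey_years: [2004, 2006, 2008, 2010, 2012, 2014]
birth_year_range: [1909, 1943]
gold_fraction: 0.1
attrition_rate_per_wave: 0.1
period_coupling: 0.03
individual_sd: 0.5
noise_sd: 1.0
diagnosis_cutpoints: [-1.7, -0.8]
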