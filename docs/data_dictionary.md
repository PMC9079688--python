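# Data dictionary

All tabular interfaces are plain CSV. The synthetic generator writes these
files; the same readers (`no2burden.io`) accept real data in the same
layout. Categorical labels: `age_group` ∈ {0-0.5, 0.5-1, 1-2, 3-6, 7-11,
12-17} (years), `sex` ∈ {boy, girl}, `household` ∈ {smoking, non-smoking}.

## exposure.csv — one row per city × age_group × sex × household

| column | units | meaning |
|---|---|---|
| city, province | — | labels; every province must appear in context_province.csv |
| latitude | °N | city latitude (generator covariate; optional in real data) |
| age_group, sex, household | — | stratum labels |
| cooking_mean, cooking_sd | µg/m³ | exposure to cooking-source NO₂: mean and SD of the intra-population variability distribution |
| ambient_mean, ambient_sd | µg/m³ | exposure to outdoor-source NO₂ |
| indoor_smoking_mean, indoor_smoking_sd | µg/m³ | total indoor-source exposure in smoking households (empty for non-smoking rows); the SHS component is derived as indoor_smoking − cooking, clamped at 0 |

## population_incidence.csv — one row per city × age_group × sex

| column | units | meaning |
|---|---|---|
| city, province, age_group, sex | — | group key |
| N | children | group population |
| IR | 1/year | asthma incidence per child per year, in (0, 1) |

## context_province.csv — one row per province

| column | units | meaning |
|---|---|---|
| province | — | label |
| f_exp | — | exposure factor in (0, 1]: ratio of population exposure to ambient concentration (ventilation, indoor removal, time-activity, respiration) |
| p_shs | — | proportion of the population exposed to second-hand smoke, in [0, 1] |

## context_cost.csv — one row per city × age_group × sex

| column | units | meaning |
|---|---|---|
| city, age_group, sex | — | key |
| cost_direct | RMB/case | direct treatment cost (varies by age/sex) |
| treatment_days | days/case | treatment and hospitalization days (varies by age/sex) |
| gdp_daily | RMB/day | city's daily per-capita GDP (indirect-cost price) |

## generator_config.json

Sidecar written next to a synthetic bundle: the full `SyntheticConfig`
including the seed, sufficient to regenerate the bundle bit-for-bit.

## Outputs

`national_burden.csv`: columns `kind` (source | scenario), `label`
(ambient/cooking/shs/total or SB/EC/IT1/IT2/IT3/AQG), `metric`
(cases | cost_rmb), `mean`, `ui_low`, `ui_high` (95% interval).

`per_city_burden.csv`: per-city attributable cases (mean and 95% UI),
indoor share of the attributable burden, and mean case reduction per
scenario.

`run_manifest.json`: seed, draw counts, distribution families, C-R
parameters and scenario list of the run.
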