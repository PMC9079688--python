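"""Statistical structure and reproducibility of the synthetic generator."""

import numpy as np
import pytest

from no2burden import (
    AGE_GROUPS,
    ConfigurationError,
    SyntheticConfig,
    assemble,
    generate_bundle,
    generate_context_tables,
    generate_exposure_table,
    generate_population_incidence,
    deterministic_burden,
)
from no2burden.io import read_bundle
from no2burden.synthetic import write_bundle


def test_seeded_runs_are_byte_identical(tmp_path, tiny_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_bundle(generate_bundle(tiny_config), d1)
    write_bundle(generate_bundle(tiny_config), d2)
    for name in ("exposure.csv", "population_incidence.csv",
                 "context_province.csv", "context_cost.csv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_different_seed_changes_output(tiny_config):
    other = tiny_config.model_copy(update={"seed": tiny_config.seed + 1})
    a = generate_exposure_table(tiny_config)
    b = generate_exposure_table(other)
    assert not np.allclose(a["cooking_mean"], b["cooking_mean"])


def test_stratum_grid_is_complete():
    cfg = SyntheticConfig(n_cities=3, n_provinces=2, seed=1)
    df = generate_exposure_table(cfg)
    assert len(df) == 3 * 6 * 2 * 2
    assert not df.duplicated(["city", "age_group", "sex", "household"]).any()
    smoking = df["household"] == "smoking"
    assert df.loc[smoking, "indoor_smoking_mean"].notna().all()
    assert (
        df.loc[smoking, "indoor_smoking_mean"]
        > df.loc[smoking, "cooking_mean"]
    ).all()


def test_zero_cooking_share_target_gives_zero_cooking():
    cfg = SyntheticConfig(n_cities=4, n_provinces=2, seed=2,
                          cooking_share_target=0.0)
    df = generate_exposure_table(cfg)
    assert (df["cooking_mean"] == 0).all()


def test_cooking_share_recovered_from_emitted_table():
    cfg = SyntheticConfig(seed=3)  # default 330 cities
    df = generate_exposure_table(cfg)
    share = (df["cooking_mean"] / (df["cooking_mean"] + df["ambient_mean"])).mean()
    assert abs(share - cfg.cooking_share_target) < 0.05


def test_indoor_share_increases_with_latitude():
    cfg = SyntheticConfig(seed=4)
    df = generate_exposure_table(cfg)
    per_city = df.groupby("city").agg(
        lat=("latitude", "first"),
        cook=("cooking_mean", "mean"),
        amb=("ambient_mean", "mean"),
    )
    slope = np.polyfit(per_city["lat"], per_city["cook"] / (per_city["cook"] + per_city["amb"]), 1)[0]
    assert slope > 0


def test_population_total_conserved():
    cfg = SyntheticConfig(n_cities=10, n_provinces=5, seed=5,
                          population_total=1_000_000)
    pop = generate_population_incidence(cfg)
    assert abs(pop["N"].sum() - 1_000_000) <= len(pop)


def test_incidence_echoes_configured_rates():
    cfg = SyntheticConfig(n_cities=4, n_provinces=2, seed=6)
    pop = generate_population_incidence(cfg)
    for sex, rates in cfg.incidence_by_age_sex.items():
        for age, rate in zip(AGE_GROUPS, rates):
            sel = (pop["sex"] == sex) & (pop["age_group"] == age)
            assert (pop.loc[sel, "IR"] == rate).all()


def test_province_modifiers_scale_incidence_ratio():
    cfg = SyntheticConfig(
        n_cities=4, n_provinces=2, seed=7,
        province_ir_modifiers={"P01": 1.2, "P02": 0.8},
    )
    pop = generate_population_incidence(cfg)
    a = pop[pop["province"] == "P01"].set_index(["age_group", "sex"])["IR"]
    b = pop[pop["province"] == "P02"].set_index(["age_group", "sex"])["IR"]
    ratio = (a / b.reindex(a.index)).dropna()
    assert np.allclose(ratio, 1.5)


def test_context_values_inside_configured_ranges():
    cfg = SyntheticConfig(n_cities=12, n_provinces=4, seed=8)
    province, cost = generate_context_tables(cfg)
    assert province["f_exp"].between(*cfg.fexp_range).all()
    assert province["p_shs"].between(*cfg.pshs_range).all()
    assert cost["cost_direct"].between(*cfg.cost_direct_range).all()
    assert cost["treatment_days"].between(*cfg.treatment_days_range).all()
    assert (cost["gdp_daily"] > 0).all()


def test_degenerate_fexp_interval():
    cfg = SyntheticConfig(n_cities=6, n_provinces=3, seed=9,
                          fexp_range=(0.7, 0.7))
    province, _ = generate_context_tables(cfg)
    assert (province["f_exp"] == 0.7).all()


def test_zero_pshs_kills_downstream_shs_burden():
    cfg = SyntheticConfig(n_cities=4, n_provinces=2, seed=10,
                          pshs_range=(0.0, 0.0))
    bundle = generate_bundle(cfg)
    det = deterministic_burden(bundle)
    assert det["AN_shs"] == 0.0
    assert det["Cost_shs"] == 0.0


def test_emitted_tables_round_trip_through_readers(tmp_path, tiny_bundle):
    write_bundle(tiny_bundle, tmp_path)
    loaded = read_bundle(tmp_path)
    assert len(loaded.exposure) == len(tiny_bundle.exposure)
    # the round-tripped bundle assembles without validation errors
    assembled = assemble(loaded.exposure, loaded.province)
    assert (assembled["shs_mean"] >= 0).all()


@pytest.mark.parametrize(
    "bad",
    [
        dict(ambient_mean_range=(-1.0, 5.0)),
        dict(fexp_range=(0.0, 0.5)),
        dict(pshs_range=(0.2, 1.5)),
        dict(incidence_by_age_sex={
            "boy": (0.004, 0.005, 0.006, 0.007, 0.008, 0.009),  # increasing
            "girl": (0.003, 0.003, 0.003, 0.003, 0.003, 0.003),
        }),
        dict(incidence_by_age_sex={
            "boy": (0.005, 0.004, 0.003, 0.002, 0.002, 0.002),
            "girl": (0.006, 0.005, 0.004, 0.003, 0.003, 0.003),  # girls above
        }),
        dict(population_total=0),
        dict(n_provinces=99, n_cities=10),
    ],
)
def test_invalid_configurations_rejected(bad):
    with pytest.raises((ConfigurationError, ValueError)):
        SyntheticConfig(**bad)
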