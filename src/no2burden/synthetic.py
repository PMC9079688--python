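"""Synthetic study-population generator.

Produces the four input tables the pipeline consumes — stratified exposure
concentrations, population and incidence, province context (exposure factor,
second-hand-smoke proportion), and cost parameters — with the statistical
structure of the real source-apportioned exposure study: 330 cities in 31
provinces, positive right-skewed concentrations, a north–south gradient in
the indoor share of exposure, and asthma incidence that declines with age
and is higher in boys.

Everything is driven by a :class:`~no2burden.config.SyntheticConfig` and a
single seed; each table is generated from an independent child stream of
that seed, so the tables are reproducible individually or as a bundle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AGE_GROUP_WIDTHS,
    AGE_GROUPS,
    HOUSEHOLDS,
    SEXES,
    ConfigurationError,
    SyntheticConfig,
)

__all__ = [
    "InputBundle",
    "generate_exposure_table",
    "generate_population_incidence",
    "generate_context_tables",
    "generate_bundle",
    "write_bundle",
]

# Child-stream indices; one per generated table so tables are independent.
_STREAM_CITY = 0
_STREAM_EXPOSURE = 1
_STREAM_POPULATION = 2
_STREAM_CONTEXT = 3


@dataclasses.dataclass
class InputBundle:
    """The four input tables, plus the config that produced them."""

    exposure: pd.DataFrame
    population: pd.DataFrame
    province: pd.DataFrame
    cost: pd.DataFrame
    config: SyntheticConfig | None = None


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _city_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Per-city attributes shared by all tables.

    Cities are assigned to provinces round-robin; each city gets a latitude
    (degrees N, 18–50 covering the urban extent of China), a mean
    outdoor-source exposure, a heavy-tailed population weight and a daily
    per-capita GDP mildly correlated with city size.
    """
    rng = _rng(config, _STREAM_CITY)
    n = config.n_cities
    cities = [f"C{i + 1:03d}" for i in range(n)]
    if len(set(cities)) != len(cities):  # pragma: no cover - defensive
        raise ConfigurationError("duplicate city labels")
    provinces = [f"P{(i % config.n_provinces) + 1:02d}" for i in range(n)]
    latitude = rng.uniform(18.0, 50.0, n)
    lo, hi = config.ambient_mean_range
    ambient_mean = rng.uniform(lo, hi, n)
    size_weight = rng.lognormal(0.0, config.city_size_sigma, n)
    size_weight = size_weight / size_weight.sum()
    glo, ghi = config.gdp_daily_range
    # GDP rank-correlated with size: big cities tend to be richer.
    gdp_base = rng.uniform(glo, ghi, n)
    rank = size_weight.argsort().argsort() / max(n - 1, 1)
    gdp_daily = 0.7 * gdp_base + 0.3 * (glo + rank * (ghi - glo))
    slo, shi = config.shs_mean_range
    shs_increment = rng.uniform(slo, shi, n)
    return pd.DataFrame(
        {
            "city": cities,
            "province": provinces,
            "latitude": latitude,
            "ambient_mean_city": ambient_mean,
            "size_weight": size_weight,
            "gdp_daily": gdp_daily,
            "shs_increment": shs_increment,
        }
    )


def _cooking_share(config: SyntheticConfig, latitude: np.ndarray) -> np.ndarray:
    """Expected cooking share of (cooking + ambient) exposure per city.

    Linear in latitude so the national mean equals ``cooking_share_target``
    while northern cities (less window opening, more time indoors) sit above
    it — the gradient the source study reports.
    """
    lat_std = (latitude - 34.0) / 16.0  # ~[-1, 1] over 18–50 °N
    share = config.cooking_share_target * (1.0 + config.share_gradient * lat_std)
    return np.clip(share, 0.0, 0.95)


def _stratum_index(city_df: pd.DataFrame) -> pd.DataFrame:
    """Cartesian product city × age × sex × household, city-major order."""
    idx = pd.MultiIndex.from_product(
        [city_df["city"], AGE_GROUPS, SEXES, HOUSEHOLDS],
        names=["city", "age_group", "sex", "household"],
    )
    df = idx.to_frame(index=False)
    return df.merge(city_df, on="city", how="left")


def generate_exposure_table(config: SyntheticConfig) -> pd.DataFrame:
    """One row per city × age group × sex × household type, with the mean and
    SD of exposure to cooking-source and outdoor-source NO₂ (µg/m³) and, for
    smoking households, of total indoor-source exposure.

    The smoking-household indoor mean is constructed as the cooking mean plus
    a city-level second-hand-smoke increment, so the derived SHS
    concentration is non-negative by construction.
    """
    rng = _rng(config, _STREAM_EXPOSURE)
    city_df = _city_frame(config)
    df = _stratum_index(city_df)
    n = len(df)

    share = _cooking_share(config, df["latitude"].to_numpy())
    ambient_city = df["ambient_mean_city"].to_numpy()
    # Mild age/sex variation in exposure (time-activity differences), mean ~1.
    jitter_cook = rng.lognormal(0.0, 0.10, n)
    jitter_amb = rng.lognormal(0.0, 0.08, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        cooking_mean = np.where(
            share >= 1.0, 0.0, ambient_city * share / (1.0 - share)
        ) * jitter_cook
    ambient_mean = ambient_city * jitter_amb
    cv = config.cv_within_group
    indoor_smoking_mean = cooking_mean + df["shs_increment"].to_numpy()

    out = df[["city", "province", "latitude", "age_group", "sex", "household"]].copy()
    out["cooking_mean"] = cooking_mean
    out["cooking_sd"] = cv * cooking_mean
    out["ambient_mean"] = ambient_mean
    out["ambient_sd"] = cv * ambient_mean
    smoking = (out["household"] == "smoking").to_numpy()
    out["indoor_smoking_mean"] = np.where(smoking, indoor_smoking_mean, np.nan)
    out["indoor_smoking_sd"] = np.where(smoking, cv * indoor_smoking_mean, np.nan)
    return out


def generate_population_incidence(config: SyntheticConfig) -> pd.DataFrame:
    """Per city × age × sex: child population N and asthma incidence IR.

    City sizes are heavy-tailed (lognormal) and normalized so ΣN equals
    ``population_total`` up to integer rounding; within a city, population is
    split across age groups proportionally to their year-width and between
    sexes by ``boy_fraction``.  Incidence echoes the configured age/sex rates
    times any province modifier.
    """
    city_df = _city_frame(config)
    idx = pd.MultiIndex.from_product(
        [city_df["city"], AGE_GROUPS, SEXES], names=["city", "age_group", "sex"]
    )
    df = idx.to_frame(index=False).merge(
        city_df[["city", "province", "size_weight"]], on="city", how="left"
    )
    widths = np.asarray(AGE_GROUP_WIDTHS)
    age_frac = dict(zip(AGE_GROUPS, widths / widths.sum()))
    sex_frac = {"boy": config.boy_fraction, "girl": 1.0 - config.boy_fraction}
    frac = (
        df["size_weight"].to_numpy()
        * df["age_group"].map(age_frac).to_numpy()
        * df["sex"].map(sex_frac).to_numpy()
    )
    df["N"] = np.rint(config.population_total * frac).astype(np.int64)

    rates = {
        (sex, age): r
        for sex, sex_rates in config.incidence_by_age_sex.items()
        for age, r in zip(AGE_GROUPS, sex_rates)
    }
    ir = np.array([rates[(s, a)] for s, a in zip(df["sex"], df["age_group"])])
    modifier = (
        df["province"].map(config.province_ir_modifiers).fillna(1.0).to_numpy()
    )
    df["IR"] = ir * modifier
    return df[["city", "province", "age_group", "sex", "N", "IR"]]


def generate_context_tables(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Province context (f_exp, P_SHS) and per-stratum cost parameters.

    Returns ``(province, cost)``: the province table maps each province to
    its exposure factor and second-hand-smoke exposure proportion; the cost
    table has one row per city × age × sex with the age/sex direct cost and
    treatment days and the city's daily per-capita GDP.
    """
    rng = _rng(config, _STREAM_CONTEXT)
    city_df = _city_frame(config)
    provinces = sorted(city_df["province"].unique())
    flo, fhi = config.fexp_range
    plo, phi = config.pshs_range
    province = pd.DataFrame(
        {
            "province": provinces,
            "f_exp": rng.uniform(flo, fhi, len(provinces)),
            "p_shs": rng.uniform(plo, phi, len(provinces)),
        }
    )

    clo, chi = config.cost_direct_range
    tlo, thi = config.treatment_days_range
    cost_as = pd.MultiIndex.from_product(
        [AGE_GROUPS, SEXES], names=["age_group", "sex"]
    ).to_frame(index=False)
    cost_as["cost_direct"] = rng.uniform(clo, chi, len(cost_as))
    cost_as["treatment_days"] = rng.uniform(tlo, thi, len(cost_as))
    cost = (
        pd.MultiIndex.from_product(
            [city_df["city"], AGE_GROUPS, SEXES], names=["city", "age_group", "sex"]
        )
        .to_frame(index=False)
        .merge(cost_as, on=["age_group", "sex"], how="left")
        .merge(city_df[["city", "gdp_daily"]], on="city", how="left")
    )
    return province, cost


def generate_bundle(config: SyntheticConfig) -> InputBundle:
    """Generate all four tables as one internally consistent bundle."""
    province, cost = generate_context_tables(config)
    return InputBundle(
        exposure=generate_exposure_table(config),
        population=generate_population_incidence(config),
        province=province,
        cost=cost,
        config=config,
    )


def write_bundle(bundle: InputBundle, outdir: str | Path) -> list[Path]:
    """Write the four CSVs plus a JSON sidecar recording config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in [
        ("exposure", bundle.exposure),
        ("population_incidence", bundle.population),
        ("context_province", bundle.province),
        ("context_cost", bundle.cost),
    ]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    sidecar = outdir / "generator_config.json"
    payload = bundle.config.model_dump() if bundle.config is not None else {}
    sidecar.write_text(json.dumps(payload, indent=2, default=list) + "\n")
    paths.append(sidecar)
    return paths
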