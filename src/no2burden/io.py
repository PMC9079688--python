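"""CSV readers and writers for the pipeline's tabular interfaces.

The column layout is documented in ``docs/data_dictionary.md``; the same
readers serve synthetic and real data.  Readers validate column presence,
dtypes and value ranges up front so schema problems surface as one itemized
error instead of NaN-propagation downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGE_GROUPS, HOUSEHOLDS, SEXES, SchemaError
from .synthetic import InputBundle

__all__ = ["read_bundle", "read_exposure", "read_population",
           "read_province", "read_cost", "write_results"]


def _require(df: pd.DataFrame, cols: list[str], table: str) -> list[str]:
    problems = [f"{table}: missing column {c!r}" for c in cols if c not in df.columns]
    return problems


def _check_range(df, col, lo, hi, table, problems, *, lo_open=False):
    if col not in df.columns:
        return
    x = pd.to_numeric(df[col], errors="coerce")
    bad = x.isna() | (x < lo) | (x > hi) | ((x == lo) if lo_open else False)
    if bad.any():
        problems.append(f"{table}: {int(bad.sum())} invalid values in {col!r}")


def read_exposure(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require(
        df,
        ["city", "province", "age_group", "sex", "household",
         "cooking_mean", "cooking_sd", "ambient_mean", "ambient_sd",
         "indoor_smoking_mean", "indoor_smoking_sd"],
        "exposure",
    )
    if not problems:
        bad_age = ~df["age_group"].isin(AGE_GROUPS)
        bad_sex = ~df["sex"].isin(SEXES)
        bad_hh = ~df["household"].isin(HOUSEHOLDS)
        for name, bad in [("age_group", bad_age), ("sex", bad_sex),
                          ("household", bad_hh)]:
            if bad.any():
                problems.append(f"exposure: unknown {name} labels "
                                f"{sorted(df.loc[bad, name].unique())}")
        for col in ("cooking_mean", "cooking_sd", "ambient_mean", "ambient_sd"):
            _check_range(df, col, 0, np.inf, "exposure", problems)
        smoking = df["household"] == "smoking"
        if df.loc[smoking, "indoor_smoking_mean"].isna().any():
            problems.append("exposure: smoking rows lack indoor_smoking_mean")
        dup = df.duplicated(["city", "age_group", "sex", "household"])
        if dup.any():
            problems.append(f"exposure: {int(dup.sum())} duplicate stratum rows")
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require(df, ["city", "province", "age_group", "sex", "N", "IR"],
                        "population")
    if not problems:
        _check_range(df, "N", 0, np.inf, "population", problems)
        _check_range(df, "IR", 0, 1, "population", problems, lo_open=True)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_province(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require(df, ["province", "f_exp", "p_shs"], "province")
    if not problems:
        _check_range(df, "f_exp", 0, 1, "province", problems, lo_open=True)
        _check_range(df, "p_shs", 0, 1, "province", problems)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_cost(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require(
        df, ["city", "age_group", "sex", "cost_direct", "treatment_days",
             "gdp_daily"], "cost",
    )
    if not problems:
        for col in ("cost_direct", "treatment_days", "gdp_daily"):
            _check_range(df, col, 0, np.inf, "cost", problems)
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_bundle(directory: str | Path) -> InputBundle:
    """Load the four-table input bundle written by the generator or CLI."""
    directory = Path(directory)
    return InputBundle(
        exposure=read_exposure(directory / "exposure.csv"),
        population=read_population(directory / "population_incidence.csv"),
        province=read_province(directory / "context_province.csv"),
        cost=read_cost(directory / "context_cost.csv"),
    )


def write_results(results, outdir: str | Path) -> list[Path]:
    """Write national and per-city result CSVs plus the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "national_burden.csv", outdir / "per_city_burden.csv",
             outdir / "run_manifest.json"]
    results.national.to_csv(paths[0], index=False)
    results.per_city.to_csv(paths[1], index=False)
    paths[2].write_text(json.dumps(results.manifest, indent=2) + "\n")
    return paths
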