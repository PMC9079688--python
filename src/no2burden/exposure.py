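"""Source-specific NO₂ exposure assembly and counterfactual scenarios.

Exposure to NO₂ is apportioned into three sources: outdoor air infiltrating
indoors plus time spent outdoors ("ambient"), gas combustion during cooking
("cooking"), and tobacco combustion in smoking households ("shs").  The
second-hand-smoke concentration is not tabulated directly; it is the excess
of a smoking household's total indoor-source exposure over its cooking
exposure.  Total exposure is the sum of the sources present in a household.

Restriction scenarios transform the assembled table: a smoking ban zeroes
the smoking-household proportion, electric cooking zeroes the cooking
source, and the WHO interim-target / guideline scenarios cap the *outdoor*
concentration — recovered from outdoor-source exposure via the province
exposure factor — at the target.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import (
    BASELINE,
    DegenerateInputError,
    MissingContextError,
    No2BurdenError,
    Scenario,
)

__all__ = [
    "derive_shs",
    "total_exposure",
    "source_proportions",
    "assemble",
    "apply_scenario",
]


def derive_shs(c_indoor_smoking_mean, c_cooking_mean):
    """Second-hand-smoke exposure: indoor-smoking-household total minus the
    cooking component, clamped at zero.

    A negative difference is physically meaningless (it can arise from
    measurement noise in the upstream exposure model), so it is clamped with
    a warning rather than propagated.
    """
    ind = np.asarray(c_indoor_smoking_mean, dtype=float)
    cook = np.asarray(c_cooking_mean, dtype=float)
    if np.any(ind < 0) or np.any(cook < 0):
        raise No2BurdenError("concentrations must be non-negative")
    diff = ind - cook
    if np.any(diff < 0):
        warnings.warn(
            "indoor smoking-household mean below cooking mean; "
            "clamping SHS concentration at 0",
            stacklevel=2,
        )
        diff = np.maximum(diff, 0.0)
    if np.isscalar(c_indoor_smoking_mean) and np.isscalar(c_cooking_mean):
        return float(diff)
    return diff


def total_exposure(
    c_cooking, c_ambient, c_shs=0.0, *, smoking: bool | np.ndarray = False
):
    """Total exposure C_exp: cooking + ambient, plus SHS in smoking households."""
    c_cooking = np.asarray(c_cooking, dtype=float)
    c_ambient = np.asarray(c_ambient, dtype=float)
    c_shs = np.asarray(c_shs, dtype=float)
    total = c_cooking + c_ambient + np.where(smoking, c_shs, 0.0)
    return float(total) if total.ndim == 0 else total


def source_proportions(c_cooking_mean, c_ambient_mean, c_shs_mean, p_shs):
    """Contribution proportions (PS_ambient, PS_cooking, PS_SHS).

    All three shares have the common denominator
    ``C̄_cooking + C̄_ambient + P_SHS·C̄_SHS``; the SHS term is weighted by
    the proportion of the population exposed to second-hand smoke, so the
    shares describe the population of a stratum, not a single household.
    """
    cook = np.asarray(c_cooking_mean, dtype=float)
    amb = np.asarray(c_ambient_mean, dtype=float)
    shs = np.asarray(c_shs_mean, dtype=float)
    p = np.asarray(p_shs, dtype=float)
    if np.any(cook < 0) or np.any(amb < 0) or np.any(shs < 0):
        raise No2BurdenError("concentration means must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise No2BurdenError("p_shs must lie in [0, 1]")
    denom = cook + amb + p * shs
    if np.any(denom <= 0):
        raise DegenerateInputError("all sources zero: proportions undefined")
    out = (amb / denom, cook / denom, p * shs / denom)
    if np.ndim(denom) == 0:
        return tuple(float(x) for x in out)
    return out


_REQUIRED_EXPOSURE_COLS = [
    "city", "province", "age_group", "sex", "household",
    "cooking_mean", "cooking_sd", "ambient_mean", "ambient_sd",
]


def assemble(exposure: pd.DataFrame, province: pd.DataFrame) -> pd.DataFrame:
    """Join the raw exposure table with province context and derive SHS.

    Returns a working table with, per stratum row: mean/SD of the three
    sources (SHS zero for non-smoking households), the province exposure
    factor ``f_exp`` and SHS-exposure proportion ``p_shs``, and the total
    exposure mean ``c_exp_mean``.
    """
    missing = [c for c in _REQUIRED_EXPOSURE_COLS if c not in exposure.columns]
    if missing:
        raise No2BurdenError(f"exposure table missing columns: {missing}")
    df = exposure.copy()
    smoking = (df["household"] == "smoking").to_numpy()

    shs_mean = np.zeros(len(df))
    shs_sd = np.zeros(len(df))
    if smoking.any():
        ind_mean = df.loc[smoking, "indoor_smoking_mean"].to_numpy(dtype=float)
        ind_sd = df.loc[smoking, "indoor_smoking_sd"].to_numpy(dtype=float)
        cook_mean = df.loc[smoking, "cooking_mean"].to_numpy(dtype=float)
        cook_sd = df.loc[smoking, "cooking_sd"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ind_mean)):
            raise No2BurdenError("smoking rows need indoor_smoking_mean")
        shs_mean[smoking] = derive_shs(ind_mean, cook_mean)
        # SD of the SHS component: independent-source quadrature difference,
        # floored at zero (the upstream model reports per-source SDs).
        shs_sd[smoking] = np.sqrt(np.maximum(ind_sd**2 - cook_sd**2, 0.0))
    df["shs_mean"] = shs_mean
    df["shs_sd"] = shs_sd

    ctx = province.set_index("province")
    for col in ("f_exp", "p_shs"):
        if col not in ctx.columns:
            raise No2BurdenError(f"province table missing column {col!r}")
    unknown = sorted(set(df["province"]) - set(ctx.index))
    if unknown:
        raise MissingContextError(f"provinces without context entries: {unknown}")
    df["f_exp"] = df["province"].map(ctx["f_exp"]).to_numpy()
    df["p_shs"] = df["province"].map(ctx["p_shs"]).to_numpy()
    if np.any((df["f_exp"] <= 0) | (df["f_exp"] > 1)):
        raise No2BurdenError("f_exp must lie in (0, 1]")

    df["c_exp_mean"] = total_exposure(
        df["cooking_mean"].to_numpy(),
        df["ambient_mean"].to_numpy(),
        df["shs_mean"].to_numpy(),
        smoking=smoking,
    )
    return df


def apply_scenario(assembled: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Transform an assembled exposure table under a restriction scenario.

    * ``BASELINE2019``: identity.
    * ``SB``: concentrations unchanged; ``p_shs`` set to 0 (nobody is exposed
      to second-hand smoke, so the smoking-household branch gets zero weight).
    * ``EC``: cooking mean and SD set to 0 everywhere.
    * ``IT1``–``IT3``, ``AQG``: the 2019 outdoor concentration is recovered
      as ``ambient_mean / f_exp``; where it exceeds the target, ambient
      exposure is replaced by ``target × f_exp`` with the SD rescaled by the
      same ratio (constant CV); otherwise it is left unchanged.

    Idempotent for every scenario.
    """
    df = assembled.copy()
    name = scenario.name
    if name == BASELINE.name:
        pass
    elif name == "SB":
        df["p_shs"] = 0.0
    elif name == "EC":
        df["cooking_mean"] = 0.0
        df["cooking_sd"] = 0.0
    elif scenario.outdoor_target is not None:
        f_exp = df["f_exp"].to_numpy(dtype=float)
        if np.any(f_exp <= 0):
            raise MissingContextError("f_exp must be positive for outdoor scenarios")
        amb = df["ambient_mean"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            outdoor_2019 = np.where(amb > 0, amb / f_exp, 0.0)
        capped = outdoor_2019 > scenario.outdoor_target
        ratio = np.ones(len(df))
        ratio[capped] = scenario.outdoor_target * f_exp[capped] / amb[capped]
        df["ambient_mean"] = amb * ratio
        df["ambient_sd"] = df["ambient_sd"].to_numpy(dtype=float) * ratio
    else:  # pragma: no cover - registry prevents this
        raise No2BurdenError(f"scenario {name!r} has no transformation rule")

    smoking = (df["household"] == "smoking").to_numpy()
    df["c_exp_mean"] = total_exposure(
        df["cooking_mean"].to_numpy(),
        df["ambient_mean"].to_numpy(),
        df["shs_mean"].to_numpy(),
        smoking=smoking,
    )
    df["scenario"] = name
    return df
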