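"""Cost-of-illness valuation of attributable asthma cases.

Each case costs the direct medical expenditure for that age/sex group plus
an indirect productivity loss: a caregiver's forgone income, priced at the
city's daily per-capita GDP times the treatment-and-hospitalization days.
Costs are computed at stratum level — so the city GDP and age/sex cost
parameters bind to the right cases — and only then aggregated.  All values
are nominal 2019 RMB; no discounting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import No2BurdenError

__all__ = ["cost_per_case", "cost_of_cases", "attach_cost_params"]


def cost_per_case(cost_direct, gdp_daily, treatment_days):
    """Per-case cost: ``Cost_d + GDP_p × T`` (RMB)."""
    cd = np.asarray(cost_direct, dtype=float)
    gdp = np.asarray(gdp_daily, dtype=float)
    t = np.asarray(treatment_days, dtype=float)
    if np.any(cd < 0) or np.any(gdp < 0) or np.any(t < 0):
        raise No2BurdenError("cost parameters must be non-negative")
    out = cd + gdp * t
    return float(out) if out.ndim == 0 else out


def cost_of_cases(cases, cost_direct, gdp_daily, treatment_days):
    """Total cost ``(Cost_d + GDP_p × T) × cases``, elementwise (RMB/year).

    ``cases`` may be an attributable count (AN) or a scenario reduction
    (RAN); the formula is linear in cases, so source costs sum to the total
    cost exactly.
    """
    n = np.asarray(cases, dtype=float)
    if np.any(n < 0):
        raise No2BurdenError("case counts must be non-negative")
    out = n * cost_per_case(cost_direct, gdp_daily, treatment_days)
    return float(out) if out.ndim == 0 else out


def attach_cost_params(groups: pd.DataFrame, cost: pd.DataFrame) -> pd.DataFrame:
    """Join per-group cost parameters onto a (city, age_group, sex) table.

    Raises if any group lacks a cost row — silent NaNs here would corrupt
    every downstream aggregate.
    """
    keys = ["city", "age_group", "sex"]
    for col in keys:
        if col not in groups.columns or col not in cost.columns:
            raise No2BurdenError(f"both tables need key column {col!r}")
    needed = ["cost_direct", "treatment_days", "gdp_daily"]
    missing = [c for c in needed if c not in cost.columns]
    if missing:
        raise No2BurdenError(f"cost table missing columns: {missing}")
    merged = groups.merge(cost[keys + needed], on=keys, how="left", validate="m:1")
    bad = merged[needed].isna().any(axis=1)
    if bad.any():
        examples = merged.loc[bad, keys].head(5).to_dict("records")
        raise No2BurdenError(f"groups without cost parameters, e.g. {examples}")
    return merged
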