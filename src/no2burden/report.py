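"""Presentation helpers: rounding conventions and summary tables.

Rounding follows the presentation precision of burden-of-disease reporting:
case counts to the nearest thousand, shares and percent reductions to the
nearest integer percent (halves up), costs to the nearest million RMB.
"""

from __future__ import annotations

import math

import pandas as pd

from .config import No2BurdenError

__all__ = [
    "round_half_up",
    "thousands",
    "millions",
    "percent_share",
    "source_table",
    "scenario_table",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (not banker's rounding)."""
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)


def thousands(cases: float) -> int:
    """Cases rounded to the nearest thousand (returned in thousands)."""
    return int(round_half_up(cases / 1e3))


def millions(rmb: float) -> int:
    """RMB rounded to the nearest million (returned in millions)."""
    return int(round_half_up(rmb / 1e6))


def percent_share(part: float, total: float) -> int:
    """``part / total`` as an integer percent (halves up)."""
    if total == 0:
        raise No2BurdenError("share of a zero total is undefined")
    return int(round_half_up(100.0 * part / total))


def source_table(national: pd.DataFrame) -> pd.DataFrame:
    """Attributable cases and costs by source with integer percent shares."""
    src = national[national["kind"] == "source"].set_index(["label", "metric"])
    total_cases = src.loc[("total", "cases"), "mean"]
    rows = []
    for label in ("ambient", "cooking", "shs", "total"):
        cases = src.loc[(label, "cases")]
        cost = src.loc[(label, "cost_rmb")]
        rows.append(
            {
                "source": label,
                "cases_thousand": thousands(cases["mean"]),
                "cases_ui": f"{thousands(cases['ui_low'])}-{thousands(cases['ui_high'])}",
                "share_pct": percent_share(cases["mean"], total_cases),
                "cost_million_rmb": millions(cost["mean"]),
                "cost_ui": f"{millions(cost['ui_low'])}-{millions(cost['ui_high'])}",
            }
        )
    return pd.DataFrame(rows)


def scenario_table(national: pd.DataFrame) -> pd.DataFrame:
    """Case and cost reductions per scenario, with percent of the 2019 total."""
    src = national[national["kind"] == "source"].set_index(["label", "metric"])
    total_cases = src.loc[("total", "cases"), "mean"]
    scen = national[national["kind"] == "scenario"].set_index(["label", "metric"])
    rows = []
    for label in scen.index.get_level_values("label").unique():
        ran = scen.loc[(label, "cases")]
        cost = scen.loc[(label, "cost_rmb")]
        rows.append(
            {
                "scenario": label,
                "reduction_thousand": thousands(ran["mean"]),
                "reduction_ui": f"{thousands(ran['ui_low'])}-{thousands(ran['ui_high'])}",
                "reduction_pct": percent_share(ran["mean"], total_cases),
                "cost_reduction_million_rmb": millions(cost["mean"]),
                "cost_reduction_ui": f"{millions(cost['ui_low'])}-{millions(cost['ui_high'])}",
            }
        )
    return pd.DataFrame(rows)
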