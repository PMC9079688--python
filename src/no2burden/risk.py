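"""Concentration-response, attributable fractions and case counts.

The concentration-response function is log-linear in the equivalent ambient
concentration: relative risk ``RR = rr0 ** ((C − LC) / ΔC0)`` above the
low-concentration threshold ``LC`` and 1 below it.  Because the risk
coefficient comes from cohort studies of *ambient* NO₂ while the pipeline
works with *exposure* concentrations, exposure is first divided by the
province exposure factor and converted from µg/m³ to ppb.

Burden follows the comparative-risk-assessment scheme used by the Global
Burden of Disease study: the population attributable fraction
``PAF = (R̄R − 1) / R̄R`` of baseline incidence, apportioned to sources by
their contribution proportions; scenario benefits use the potential impact
fraction ``PIF = (R̄R − R̄R') / R̄R``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CRFunction, DegenerateInputError, No2BurdenError

__all__ = [
    "equivalent_ambient_ppb",
    "rr_from_exposure",
    "mean_rr_group",
    "paf",
    "pif",
    "attributable_cases",
    "reduction_cases",
]

_TOL = 1e-9


def equivalent_ambient_ppb(c_exp, f_exp, crf: CRFunction):
    """Equivalent ambient concentration in ppb: ``(C_exp / f_exp) × 0.487``."""
    c_exp = np.asarray(c_exp, dtype=float)
    f_exp = np.asarray(f_exp, dtype=float)
    if np.any(c_exp < 0):
        raise No2BurdenError("exposure concentration must be non-negative")
    if np.any(f_exp <= 0) or np.any(f_exp > 1):
        raise DegenerateInputError("f_exp must lie in (0, 1]")
    out = c_exp / f_exp * crf.ugm3_to_ppb
    return float(out) if out.ndim == 0 else out


def rr_from_exposure(c_exp, f_exp, crf: CRFunction, *, rr0=None, lc=None):
    """Relative risk of asthma onset at exposure ``c_exp`` (µg/m³).

    ``rr0`` and ``lc`` may override the central parameters (scalar or
    broadcastable arrays), which is how uncertainty draws enter.  The
    exponentiation is done in log space, ``exp(k·ln RR0)``, so large
    exponents lose no precision.
    """
    rr0 = crf.rr0 if rr0 is None else np.asarray(rr0, dtype=float)
    lc = crf.lc if lc is None else np.asarray(lc, dtype=float)
    if np.any(np.asarray(rr0) <= 0):
        raise No2BurdenError("rr0 must be positive")
    if np.any(np.asarray(lc) < 0):
        raise No2BurdenError("LC must be non-negative")
    ppb = equivalent_ambient_ppb(c_exp, f_exp, crf)
    excess = np.maximum(np.asarray(ppb) - lc, 0.0)
    out = np.exp(np.log(rr0) * excess / crf.delta_c0)
    return float(out) if out.ndim == 0 else out


def mean_rr_group(rr_nonsmoking, rr_smoking, p_shs):
    """Population-average RR: household-type mixture weighted by P_SHS."""
    rr_ns = np.asarray(rr_nonsmoking, dtype=float)
    rr_s = np.asarray(rr_smoking, dtype=float)
    p = np.asarray(p_shs, dtype=float)
    if np.any(rr_ns < 1.0 - _TOL) or np.any(rr_s < 1.0 - _TOL):
        raise No2BurdenError("average RR below 1 is outside the model's domain")
    if np.any((p < 0) | (p > 1)):
        raise No2BurdenError("p_shs must lie in [0, 1]")
    out = (1.0 - p) * rr_ns + p * rr_s
    return float(out) if out.ndim == 0 else out


def paf(rr_bar, *, floor: bool = False):
    """Population attributable fraction ``(R̄R − 1) / R̄R``.

    The concentration-response function never yields RR < 1, so values below
    1 signal a corrupt user-supplied RR table and raise; ``floor=True``
    clips them to 0 instead (for exploratory use).
    """
    rr = np.asarray(rr_bar, dtype=float)
    if np.any(rr < 1.0 - _TOL):
        if not floor:
            raise DegenerateInputError("PAF requires average RR >= 1")
        rr = np.maximum(rr, 1.0)
    out = (rr - 1.0) / rr
    out = np.maximum(out, 0.0)  # kill -0.0 / rounding below 1
    return float(out) if out.ndim == 0 else out


def pif(rr_bar, rr_bar_counterfactual):
    """Potential impact fraction ``(R̄R − R̄R') / R̄R``.

    Positive when the counterfactual lowers exposure; reduces to the PAF
    when the counterfactual removes all excess risk (R̄R' = 1).
    """
    rr = np.asarray(rr_bar, dtype=float)
    rr_po = np.asarray(rr_bar_counterfactual, dtype=float)
    if np.any(rr <= 0):
        raise DegenerateInputError("baseline average RR must be positive")
    if np.any(rr < 1.0 - _TOL) or np.any(rr_po < 1.0 - _TOL):
        raise No2BurdenError("average RR below 1 is outside the model's domain")
    out = (rr - rr_po) / rr
    return float(out) if out.ndim == 0 else out


def _aligned(groups: pd.DataFrame, values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != len(groups):
        raise No2BurdenError(
            f"{name} has length {arr.shape[-1]}, expected {len(groups)} groups"
        )
    return arr


def attributable_cases(
    groups: pd.DataFrame, paf_g, ps_g, *, per_stratum: bool = False
):
    """Attributable new cases for one source: ``Σ_g PS·PAF·IR·N``.

    ``groups`` needs columns ``N`` and ``IR``; ``paf_g`` and ``ps_g`` are
    aligned per-group arrays (``ps_g`` may be a scalar, e.g. 1 for the total
    over all sources).  With ``per_stratum=True`` the per-group terms are
    returned instead of their sum.
    """
    for col in ("N", "IR"):
        if col not in groups.columns:
            raise No2BurdenError(f"groups table missing column {col!r}")
    paf_arr = _aligned(groups, paf_g, "paf_g")
    ps_arr = np.asarray(ps_g, dtype=float)
    if ps_arr.ndim > 0:
        ps_arr = _aligned(groups, ps_g, "ps_g")
    if np.any(paf_arr < 0) or np.any(paf_arr > 1):
        raise No2BurdenError("PAF values must lie in [0, 1]")
    if np.any(ps_arr < 0) or np.any(ps_arr > 1):
        raise No2BurdenError("source proportions must lie in [0, 1]")
    terms = (
        ps_arr
        * paf_arr
        * groups["IR"].to_numpy(dtype=float)
        * groups["N"].to_numpy(dtype=float)
    )
    return terms if per_stratum else float(terms.sum())


def reduction_cases(groups: pd.DataFrame, pif_g, *, per_stratum: bool = False):
    """Scenario case reduction: ``Σ_g PIF·IR·N`` (per stratum on request)."""
    for col in ("N", "IR"):
        if col not in groups.columns:
            raise No2BurdenError(f"groups table missing column {col!r}")
    pif_arr = _aligned(groups, pif_g, "pif_g")
    terms = (
        pif_arr
        * groups["IR"].to_numpy(dtype=float)
        * groups["N"].to_numpy(dtype=float)
    )
    return terms if per_stratum else float(terms.sum())
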