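"""Two-stage Monte Carlo engine and robustness check.

The two stages separate what varies between children from what is unknown
to the analyst:

* **variability stage** (inner, default 2000 draws) — individual exposure
  is resampled around each stratum's mean/SD (lognormal by default); the
  relative risk is averaged over these draws to give the population-level
  average RR per stratum;
* **uncertainty stage** (outer, default 1000 draws) — the concentration-
  response parameters (RR0, LC) and national multiplicative factors for
  baseline incidence, direct cost and treatment days are resampled; each
  draw yields one complete set of PAF/PIF, case counts and costs.

Reported statistics are the mean and the 2.5th–97.5th percentile interval
over uncertainty draws (linear interpolation between order statistics, so
intervals are bit-reproducible given a seed).

Variability draws are *shared* between the baseline and every scenario
within an uncertainty draw (common random numbers): a scenario transforms
the same sampled children, so impact fractions are contrasts, not noise.
Strata are processed in city-aligned chunks; the working set stays
proportional to ``chunk × n_variability`` and no strata × variability ×
uncertainty array is ever materialized.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    BASELINE,
    SOURCES,
    CRFunction,
    MCConfig,
    No2BurdenError,
    Scenario,
)
from .economics import attach_cost_params
from .exposure import apply_scenario, assemble, source_proportions
from .risk import mean_rr_group, paf as paf_fn, pif as pif_fn, rr_from_exposure

__all__ = [
    "BurdenResults",
    "RobustnessResult",
    "summarize",
    "sample_uncertainty",
    "run_two_stage",
    "deterministic_burden",
    "robustness_check",
]

_GROUP_KEYS = ["city", "age_group", "sex"]


# ---------------------------------------------------------------------------
# Summaries


def summarize(draws: np.ndarray, level: float = 95.0) -> tuple[float, float, float]:
    """Mean and central ``level``% percentile interval of a 1-D draw vector."""
    draws = np.asarray(draws, dtype=float)
    if not np.all(np.isfinite(draws)):
        raise No2BurdenError("non-finite values in Monte Carlo draws")
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(draws, [half, 100.0 - half])
    return float(draws.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Uncertainty-stage sampling


def _lognormal_sigma_from_ui(lo: float, hi: float) -> float:
    return (np.log(hi) - np.log(lo)) / (2.0 * stats.norm.ppf(0.975))


def sample_uncertainty(
    rng: np.random.Generator, mc: MCConfig, crf: CRFunction
) -> dict[str, np.ndarray]:
    """Draw the outer-stage parameter vectors (length ``n_uncertainty``).

    RR0 is lognormal with median at the central estimate and scale matched
    to the printed 95% UI; LC is triangular (or uniform) over its stated
    range; the incidence/cost/treatment-day factors are normals with mean 1
    truncated at 0.
    """
    n = mc.n_uncertainty
    if mc.rr0_dist == "degenerate":
        rr0 = np.full(n, crf.rr0)
    else:
        sigma = _lognormal_sigma_from_ui(*crf.rr0_ui)
        rr0 = rng.lognormal(np.log(crf.rr0), sigma, n)
    if mc.lc_dist == "degenerate":
        lc = np.full(n, crf.lc)
    elif mc.lc_dist == "uniform":
        lc = rng.uniform(crf.lc_range[0], crf.lc_range[1], n)
    else:
        lo, hi = crf.lc_range
        lc = (
            np.full(n, float(lo))
            if hi == lo
            else rng.triangular(lo, crf.lc, hi, n)
        )

    def factor(cv: float) -> np.ndarray:
        if cv == 0:
            return np.ones(n)
        a = (0.0 - 1.0) / cv
        return stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=cv, size=n,
                                   random_state=rng)

    return {
        "rr0": rr0,
        "lc": lc,
        "ir_factor": factor(mc.ir_cv),
        "cost_factor": factor(mc.cost_cv),
        "tdays_factor": factor(mc.tdays_cv),
    }


# ---------------------------------------------------------------------------
# Variability-stage sampling

_SOURCE_COLS = {"cooking": "cooking", "ambient": "ambient", "shs": "shs"}


def _sample_exposure(
    mean: np.ndarray, sd: np.ndarray, z: np.ndarray, family: str
) -> np.ndarray:
    """Sample per-child exposure draws from standard-normal innovations ``z``.

    Lognormal is moment-matched to (mean, SD); the truncated-normal
    alternative maps the same innovations through the inverse CDF, so both
    families share common random numbers.  Zero SD collapses to the mean
    and zero mean to zero.
    """
    mean = mean[:, None]
    sd = sd[:, None]
    out = np.broadcast_to(mean, z.shape).copy()
    active = (mean > 0) & (sd > 0)
    rows = active[:, 0]
    if not rows.any():
        return out
    m, s = mean[rows], sd[rows]
    if family == "lognormal":
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        out[rows] = np.exp(mu + np.sqrt(sigma2) * z[rows])
    else:  # truncnorm
        a = (0.0 - m) / s
        u = stats.norm.cdf(z[rows])
        out[rows] = stats.truncnorm.ppf(u, a, np.inf, loc=m, scale=s)
    return out


# ---------------------------------------------------------------------------
# Input preparation


@dataclasses.dataclass
class _Prepared:
    groups: pd.DataFrame  # city-major, with N, IR, cost params
    city_labels: np.ndarray
    city_index: np.ndarray  # per group -> city position
    p_shs: np.ndarray  # per group
    f_exp: dict[str, np.ndarray]  # household -> per group
    means: dict[tuple[str, str], np.ndarray]  # (household, source) -> mean
    sds: dict[tuple[str, str], np.ndarray]
    ps: dict[str, np.ndarray]  # source -> per-group contribution proportion


def _prepare(bundle, crf: CRFunction) -> _Prepared:
    assembled = assemble(bundle.exposure, bundle.province)
    groups = bundle.population.sort_values(_GROUP_KEYS, kind="mergesort")
    groups = attach_cost_params(groups, bundle.cost).reset_index(drop=True)

    city_labels, city_index = np.unique(groups["city"], return_inverse=True)
    # np.unique sorts, matching the mergesort order above; city blocks are
    # therefore contiguous and city_index is non-decreasing.

    means: dict[tuple[str, str], np.ndarray] = {}
    sds: dict[tuple[str, str], np.ndarray] = {}
    f_exp: dict[str, np.ndarray] = {}
    p_shs = None
    for household in ("non-smoking", "smoking"):
        sub = assembled[assembled["household"] == household]
        sub = groups[_GROUP_KEYS].merge(sub, on=_GROUP_KEYS, how="left",
                                        validate="1:1")
        if sub["cooking_mean"].isna().any():
            raise No2BurdenError(
                f"exposure table lacks {household} rows for some groups"
            )
        for source in SOURCES:
            means[(household, source)] = sub[f"{_SOURCE_COLS[source]}_mean"].to_numpy(float)
            sds[(household, source)] = sub[f"{_SOURCE_COLS[source]}_sd"].to_numpy(float)
        f_exp[household] = sub["f_exp"].to_numpy(float)
        if p_shs is None:
            p_shs = sub["p_shs"].to_numpy(float)

    p = p_shs
    cook_bar = (1 - p) * means[("non-smoking", "cooking")] + p * means[("smoking", "cooking")]
    amb_bar = (1 - p) * means[("non-smoking", "ambient")] + p * means[("smoking", "ambient")]
    shs_bar = means[("smoking", "shs")]
    ps_amb, ps_cook, ps_shs = source_proportions(cook_bar, amb_bar, shs_bar, p)
    return _Prepared(
        groups=groups,
        city_labels=city_labels,
        city_index=city_index,
        p_shs=p,
        f_exp=f_exp,
        means=means,
        sds=sds,
        ps={"ambient": ps_amb, "cooking": ps_cook, "shs": ps_shs},
    )


def _scenario_transform(
    sc: Scenario, prep: _Prepared, household: str, sl: slice
) -> tuple[float, np.ndarray, bool]:
    """(cooking multiplier, per-group ambient ratio, p_shs zeroed?) for a
    scenario on one household's chunk slice."""
    if sc.name == BASELINE.name:
        return 1.0, np.ones(sl.stop - sl.start), False
    if sc.name == "SB":
        return 1.0, np.ones(sl.stop - sl.start), True
    if sc.name == "EC":
        return 0.0, np.ones(sl.stop - sl.start), False
    if sc.outdoor_target is None:  # pragma: no cover
        raise No2BurdenError(f"scenario {sc.name!r} has no transformation rule")
    amb = prep.means[(household, "ambient")][sl]
    f = prep.f_exp[household][sl]
    ratio = np.ones_like(amb)
    with np.errstate(divide="ignore", invalid="ignore"):
        outdoor = np.where(amb > 0, amb / f, 0.0)
    capped = outdoor > sc.outdoor_target
    ratio[capped] = sc.outdoor_target * f[capped] / amb[capped]
    return 1.0, ratio, False


# ---------------------------------------------------------------------------
# Results containers


@dataclasses.dataclass
class BurdenResults:
    """National and per-city burden summaries plus the raw uncertainty draws."""

    national: pd.DataFrame
    per_city: pd.DataFrame
    draws: dict[str, np.ndarray]
    manifest: dict


@dataclasses.dataclass
class RobustnessResult:
    estimates: np.ndarray
    grand_mean: float
    max_rel_error: float
    sd_rel_error: float


# ---------------------------------------------------------------------------
# The engine


def run_two_stage(
    bundle,
    *,
    crf: CRFunction | None = None,
    mc: MCConfig | None = None,
    scenarios: Sequence[Scenario] = (),
    seed: int = 0,
    collect_city: bool = True,
) -> BurdenResults:
    """Run the full two-stage simulation.

    Returns attributable cases and costs by source (plus the all-source
    total), and case/cost reductions for each requested scenario, each with
    mean and 95% UI over the uncertainty draws.
    """
    crf = crf or CRFunction()
    mc = mc or MCConfig()
    prep = _prepare(bundle, crf)
    scen_list = list(scenarios)
    n_groups = len(prep.groups)
    n_u, n_v = mc.n_uncertainty, mc.n_variability
    n_cities = len(prep.city_labels)

    ss = np.random.SeedSequence([int(seed), 0x6E6F32])
    rng_u, rng_v = [np.random.default_rng(s) for s in ss.spawn(2)]
    unc = sample_uncertainty(rng_u, mc, crf)
    c_u = np.log(unc["rr0"]) / crf.delta_c0
    lc_u = unc["lc"]

    w = prep.groups["IR"].to_numpy(float) * prep.groups["N"].to_numpy(float)
    cd = prep.groups["cost_direct"].to_numpy(float)
    indir = (
        prep.groups["gdp_daily"].to_numpy(float)
        * prep.groups["treatment_days"].to_numpy(float)
    )

    labels = list(SOURCES) + ["total"]
    ps_full = dict(prep.ps, total=np.ones(n_groups))
    cases_acc = {s: np.zeros(n_u) for s in labels}
    costd_acc = {s: np.zeros(n_u) for s in labels}
    indir_acc = {s: np.zeros(n_u) for s in labels}
    ran_acc = {sc.name: np.zeros(n_u) for sc in scen_list}
    ran_costd_acc = {sc.name: np.zeros(n_u) for sc in scen_list}
    ran_indir_acc = {sc.name: np.zeros(n_u) for sc in scen_list}
    city_cases = np.zeros((n_u, n_cities)) if collect_city else None
    city_indoor = np.zeros((n_u, n_cities)) if collect_city else None
    city_ran = (
        {sc.name: np.zeros((n_u, n_cities)) for sc in scen_list}
        if collect_city
        else None
    )

    # chunk over whole cities so per-city reduceat boundaries stay aligned
    groups_per_city = n_groups // n_cities
    chunk_cities = max(1, mc.chunk_groups // max(groups_per_city, 1))
    city_starts = np.searchsorted(prep.city_index, np.arange(n_cities))

    households = ("non-smoking", "smoking")
    # exposure sets that need their own RR evaluation (SB reuses baseline)
    eval_scens = [BASELINE] + [sc for sc in scen_list if sc.name != "SB"]

    for c0 in range(0, n_cities, chunk_cities):
        c1 = min(c0 + chunk_cities, n_cities)
        g0, g1 = int(city_starts[c0]), (
            int(city_starts[c1]) if c1 < n_cities else n_groups
        )
        sl = slice(g0, g1)
        gc = g1 - g0

        # innovations, shared across scenarios (and both families)
        z = {
            (h, src): rng_v.standard_normal((gc, n_v))
            for h in households
            for src in SOURCES
        }
        draws = {
            (h, src): _sample_exposure(
                prep.means[(h, src)][sl], prep.sds[(h, src)][sl],
                z[(h, src)], mc.exposure_family,
            )
            for h in households
            for src in SOURCES
        }

        rrbar: dict[tuple[str, str], np.ndarray] = {}
        buf = np.empty((2 * gc, n_v), dtype=np.float64)
        for sc in eval_scens:
            ppb_rows = []
            for h in households:
                cook_mult, amb_ratio, _ = _scenario_transform(sc, prep, h, sl)
                total = (
                    cook_mult * draws[(h, "cooking")]
                    + amb_ratio[:, None] * draws[(h, "ambient")]
                )
                if h == "smoking":
                    total = total + draws[(h, "shs")]
                ppb_rows.append(
                    (total / prep.f_exp[h][sl][:, None] * crf.ugm3_to_ppb)
                )
            ppb = np.vstack(ppb_rows)
            out_ns = np.empty((n_u, gc), dtype=np.float64)
            out_s = np.empty((n_u, gc), dtype=np.float64)
            for u in range(n_u):
                np.subtract(ppb, lc_u[u], out=buf)
                np.maximum(buf, 0.0, out=buf)
                np.multiply(buf, c_u[u], out=buf)
                np.exp(buf, out=buf)
                m = buf.mean(axis=1)
                out_ns[u] = m[:gc]
                out_s[u] = m[gc:]
            rrbar[(sc.name, "non-smoking")] = out_ns
            rrbar[(sc.name, "smoking")] = out_s

        p = prep.p_shs[sl]
        rrb_base = (
            (1 - p) * rrbar[(BASELINE.name, "non-smoking")]
            + p * rrbar[(BASELINE.name, "smoking")]
        )
        paf_mat = (rrb_base - 1.0) / rrb_base

        for s in labels:
            wt = w[sl] * ps_full[s][sl]
            cases_acc[s] += paf_mat @ wt
            costd_acc[s] += paf_mat @ (wt * cd[sl])
            indir_acc[s] += paf_mat @ (wt * indir[sl])

        if collect_city:
            starts = city_starts[c0:c1] - g0
            city_cases[:, c0:c1] += np.add.reduceat(
                paf_mat * w[sl], starts, axis=1
            )
            wt_in = w[sl] * (ps_full["cooking"][sl] + ps_full["shs"][sl])
            city_indoor[:, c0:c1] += np.add.reduceat(
                paf_mat * wt_in, starts, axis=1
            )

        for sc in scen_list:
            if sc.name == "SB":
                rrb_po = rrbar[(BASELINE.name, "non-smoking")]
            else:
                rrb_po = (
                    (1 - p) * rrbar[(sc.name, "non-smoking")]
                    + p * rrbar[(sc.name, "smoking")]
                )
            pif_mat = (rrb_base - rrb_po) / rrb_base
            ran_acc[sc.name] += pif_mat @ w[sl]
            ran_costd_acc[sc.name] += pif_mat @ (w[sl] * cd[sl])
            ran_indir_acc[sc.name] += pif_mat @ (w[sl] * indir[sl])
            if collect_city:
                city_ran[sc.name][:, c0:c1] += np.add.reduceat(
                    pif_mat * w[sl], starts, axis=1
                )

    irf, cdf, tdf = unc["ir_factor"], unc["cost_factor"], unc["tdays_factor"]
    draws_out: dict[str, np.ndarray] = {}
    rows = []
    for s in labels:
        an = irf * cases_acc[s]
        cost = irf * (cdf * costd_acc[s] + tdf * indir_acc[s])
        draws_out[f"AN_{s}"] = an
        draws_out[f"Cost_{s}"] = cost
        rows.append(("source", s, "cases", *summarize(an)))
        rows.append(("source", s, "cost_rmb", *summarize(cost)))
    for sc in scen_list:
        ran = irf * ran_acc[sc.name]
        cost = irf * (cdf * ran_costd_acc[sc.name] + tdf * ran_indir_acc[sc.name])
        draws_out[f"RAN_{sc.name}"] = ran
        draws_out[f"CostRed_{sc.name}"] = cost
        rows.append(("scenario", sc.name, "cases", *summarize(ran)))
        rows.append(("scenario", sc.name, "cost_rmb", *summarize(cost)))
    national = pd.DataFrame(
        rows, columns=["kind", "label", "metric", "mean", "ui_low", "ui_high"]
    )

    if collect_city:
        an_city = irf[:, None] * city_cases
        lo, hi = np.percentile(an_city, [2.5, 97.5], axis=0)
        per_city = pd.DataFrame(
            {
                "city": prep.city_labels,
                "cases_mean": an_city.mean(axis=0),
                "cases_ui_low": lo,
                "cases_ui_high": hi,
                "indoor_share": (
                    (irf[:, None] * city_indoor).mean(axis=0)
                    / np.maximum(an_city.mean(axis=0), 1e-300)
                ),
            }
        )
        for sc in scen_list:
            per_city[f"ran_{sc.name}_mean"] = (
                irf[:, None] * city_ran[sc.name]
            ).mean(axis=0)
    else:
        per_city = pd.DataFrame({"city": prep.city_labels})

    manifest = {
        "seed": int(seed),
        "n_variability": n_v,
        "n_uncertainty": n_u,
        "exposure_family": mc.exposure_family,
        "rr0_dist": mc.rr0_dist,
        "lc_dist": mc.lc_dist,
        "ir_cv": mc.ir_cv,
        "cost_cv": mc.cost_cv,
        "tdays_cv": mc.tdays_cv,
        "chunk_groups": mc.chunk_groups,
        "crf": crf.model_dump(),
        "scenarios": [sc.name for sc in scen_list],
        "n_groups": n_groups,
        "n_cities": n_cities,
    }
    return BurdenResults(national=national, per_city=per_city,
                         draws=draws_out, manifest=manifest)


# ---------------------------------------------------------------------------
# Deterministic single-pass pipeline (no sampling)


def deterministic_burden(
    bundle,
    *,
    crf: CRFunction | None = None,
    scenarios: Sequence[Scenario] = (),
) -> dict[str, float]:
    """Point-estimate pipeline evaluated at the exposure means and central
    parameters (no variability or uncertainty sampling).

    Coincides with the Monte Carlo mean exactly when all exposure SDs are
    zero and all uncertainty distributions are degenerate — the convergence
    anchor the test suite uses.
    """
    crf = crf or CRFunction()
    prep = _prepare(bundle, crf)
    assembled = assemble(bundle.exposure, bundle.province)
    w = prep.groups["IR"].to_numpy(float) * prep.groups["N"].to_numpy(float)
    cd = prep.groups["cost_direct"].to_numpy(float)
    indir = (
        prep.groups["gdp_daily"].to_numpy(float)
        * prep.groups["treatment_days"].to_numpy(float)
    )

    def rr_bar_of(table: pd.DataFrame) -> np.ndarray:
        rr = {}
        for h in ("non-smoking", "smoking"):
            sub = prep.groups[_GROUP_KEYS].merge(
                table[table["household"] == h], on=_GROUP_KEYS, validate="1:1"
            )
            rr[h] = rr_from_exposure(
                sub["c_exp_mean"].to_numpy(float),
                sub["f_exp"].to_numpy(float),
                crf,
            )
        return mean_rr_group(rr["non-smoking"], rr["smoking"], prep.p_shs)

    rrb = rr_bar_of(assembled)
    paf_g = paf_fn(rrb)
    out: dict[str, float] = {}
    for s in SOURCES:
        out[f"AN_{s}"] = float((prep.ps[s] * paf_g * w).sum())
        out[f"Cost_{s}"] = float((prep.ps[s] * paf_g * w * (cd + indir)).sum())
    out["AN_total"] = float((paf_g * w).sum())
    out["Cost_total"] = float((paf_g * w * (cd + indir)).sum())
    for sc in scenarios:
        counter = apply_scenario(assembled, sc)
        rrb_po = (
            rr_bar_of(counter)
            if sc.name != "SB"
            else rr_bar_of(assembled.assign(p_shs=0.0))
        )
        if sc.name == "SB":
            sub = prep.groups[_GROUP_KEYS].merge(
                assembled[assembled["household"] == "non-smoking"],
                on=_GROUP_KEYS, validate="1:1",
            )
            rrb_po = rr_from_exposure(
                sub["c_exp_mean"].to_numpy(float), sub["f_exp"].to_numpy(float), crf
            )
        pif_g = pif_fn(rrb, rrb_po)
        out[f"RAN_{sc.name}"] = float((pif_g * w).sum())
        out[f"CostRed_{sc.name}"] = float((pif_g * w * (cd + indir)).sum())
    return out


# ---------------------------------------------------------------------------
# Robustness


def robustness_check(
    bundle,
    *,
    crf: CRFunction | None = None,
    mc: MCConfig | None = None,
    seed: int = 0,
    scenarios: Sequence[Scenario] = (),
    n_repeats: int | None = None,
) -> RobustnessResult:
    """Repeat the full two-stage simulation with distinct sub-seeds and
    measure the spread of the headline estimate (total attributable cases).

    Returns the maximum relative deviation from the grand mean across
    repeats — the stability metric the draw counts must keep small — along
    with its standard deviation.
    """
    mc = mc or MCConfig()
    n_rep = n_repeats or mc.n_robustness_repeats
    ss = np.random.SeedSequence([int(seed), 0x726F62])
    estimates = np.empty(n_rep)
    for r, child in enumerate(ss.spawn(n_rep)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = run_two_stage(
            bundle, crf=crf, mc=mc, scenarios=scenarios,
            seed=sub_seed, collect_city=False,
        )
        estimates[r] = res.draws["AN_total"].mean()
    grand = float(estimates.mean())
    if grand == 0:
        rel = np.zeros_like(estimates)
    else:
        rel = np.abs(estimates - grand) / grand
    return RobustnessResult(
        estimates=estimates,
        grand_mean=grand,
        max_rel_error=float(rel.max()),
        sd_rel_error=float(rel.std(ddof=1)) if n_rep > 1 else 0.0,
    )
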