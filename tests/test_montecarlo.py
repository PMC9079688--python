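"""Two-stage Monte Carlo engine: collapse, determinism, stability."""

import math

import numpy as np
import pytest

from no2burden import (
    CRFunction,
    MCConfig,
    SCENARIOS,
    deterministic_burden,
    robustness_check,
    run_two_stage,
    summarize,
)
from no2burden.montecarlo import sample_uncertainty

ALL_SCENARIOS = list(SCENARIOS.values())


def hand_oracle() -> dict[str, float]:
    """Closed-form burden for the two-group fixture, computed from first
    principles with plain ``math`` — independent of the package's code path."""

    def rr(c_exp, f=0.7, rr0=1.26, lc=2.0):
        ppb = c_exp / f * 0.487
        return 1.0 if ppb <= lc else math.exp(math.log(rr0) * (ppb - lc) / 10.0)

    out = {k: 0.0 for k in
           ["AN_ambient", "AN_cooking", "AN_shs", "AN_total",
            "Cost_total", "RAN_SB", "RAN_EC", "RAN_AQG"]}
    p = 0.4
    groups = [
        # cook, amb, shs, IR, N, per-case cost
        dict(cook=10.0, amb=30.0, shs=5.0, ir=0.008, n=100_000,
             percase=1000.0 + 300.0 * 3.0),
        dict(cook=8.0, amb=25.0, shs=4.0, ir=0.006, n=90_000,
             percase=1100.0 + 300.0 * 2.0),
    ]
    for g in groups:
        rr_ns = rr(g["cook"] + g["amb"])
        rr_s = rr(g["cook"] + g["amb"] + g["shs"])
        rr_bar = (1 - p) * rr_ns + p * rr_s
        paf = (rr_bar - 1) / rr_bar
        denom = g["cook"] + g["amb"] + p * g["shs"]
        w = g["ir"] * g["n"]
        out["AN_ambient"] += g["amb"] / denom * paf * w
        out["AN_cooking"] += g["cook"] / denom * paf * w
        out["AN_shs"] += p * g["shs"] / denom * paf * w
        out["AN_total"] += paf * w
        out["Cost_total"] += paf * w * g["percase"]
        # smoking ban: mixture weight of the smoking branch goes to zero
        out["RAN_SB"] += (rr_bar - rr_ns) / rr_bar * w
        # electric cooking: cooking removed in both households
        rr_bar_ec = (1 - p) * rr(g["amb"]) + p * rr(g["amb"] + g["shs"])
        out["RAN_EC"] += (rr_bar - rr_bar_ec) / rr_bar * w
        # AQG: outdoor (amb / 0.7) exceeds 10 in both groups -> amb = 7.0
        rr_bar_aqg = (1 - p) * rr(g["cook"] + 7.0) + p * rr(g["cook"] + 7.0 + g["shs"])
        out["RAN_AQG"] += (rr_bar - rr_bar_aqg) / rr_bar * w
    return out


class TestOracleEquivalence:
    def test_deterministic_pipeline_matches_hand_computation(self, oracle_bundle):
        expected = hand_oracle()
        got = deterministic_burden(
            oracle_bundle,
            scenarios=[SCENARIOS["SB"], SCENARIOS["EC"], SCENARIOS["AQG"]],
        )
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, rel=1e-12), key

    def test_degenerate_mc_collapses_to_closed_form(self, oracle_bundle):
        """Zero exposure SDs + point parameters: every uncertainty draw is
        identical, the UI has zero width, and the mean equals the
        deterministic pipeline."""
        mc = MCConfig(n_variability=16, n_uncertainty=16).degenerate()
        res = run_two_stage(
            oracle_bundle, mc=mc, seed=5,
            scenarios=[SCENARIOS["SB"], SCENARIOS["EC"], SCENARIOS["AQG"]],
        )
        expected = hand_oracle()
        nat = res.national.set_index(["kind", "label", "metric"])
        for (kind, label, key) in [
            ("source", "ambient", "AN_ambient"),
            ("source", "cooking", "AN_cooking"),
            ("source", "shs", "AN_shs"),
            ("source", "total", "AN_total"),
            ("scenario", "SB", "RAN_SB"),
            ("scenario", "EC", "RAN_EC"),
            ("scenario", "AQG", "RAN_AQG"),
        ]:
            row = nat.loc[(kind, label, "cases")]
            assert row["mean"] == pytest.approx(expected[key], rel=1e-12), key
            assert row["ui_high"] - row["ui_low"] == 0.0
        cost = nat.loc[("source", "total", "cost_rmb")]
        assert cost["mean"] == pytest.approx(expected["Cost_total"], rel=1e-12)


class TestDeterminismAndSummaries:
    def test_same_seed_same_output(self, tiny_bundle):
        mc = MCConfig(n_variability=50, n_uncertainty=40)
        a = run_two_stage(tiny_bundle, mc=mc, seed=9, scenarios=ALL_SCENARIOS)
        b = run_two_stage(tiny_bundle, mc=mc, seed=9, scenarios=ALL_SCENARIOS)
        assert a.national.equals(b.national)
        assert a.per_city.equals(b.per_city)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])
        c = run_two_stage(tiny_bundle, mc=mc, seed=10, scenarios=ALL_SCENARIOS)
        assert not np.array_equal(a.draws["AN_total"], c.draws["AN_total"])

    def test_percentile_summary_against_normal_quantiles(self):
        draws = np.random.default_rng(42).standard_normal(1000)
        mean, lo, hi = summarize(draws)
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)
        assert abs(mean) < 0.15

    def test_ui_brackets_mean_in_every_row(self, tiny_bundle):
        mc = MCConfig(n_variability=50, n_uncertainty=60)
        res = run_two_stage(tiny_bundle, mc=mc, seed=2, scenarios=ALL_SCENARIOS)
        nat = res.national
        assert (nat["ui_low"] <= nat["mean"] + 1e-9).all()
        assert (nat["mean"] <= nat["ui_high"] + 1e-9).all()


class TestScenarioOrdering:
    def test_outdoor_reductions_monotone_per_draw_and_in_mean(self, tiny_bundle):
        mc = MCConfig(n_variability=40, n_uncertainty=50)
        res = run_two_stage(tiny_bundle, mc=mc, seed=4, scenarios=ALL_SCENARIOS)
        it1, it2 = res.draws["RAN_IT1"], res.draws["RAN_IT2"]
        it3, aqg = res.draws["RAN_IT3"], res.draws["RAN_AQG"]
        # common variability draws make the ordering exact draw by draw
        assert (it1 <= it2 + 1e-9).all()
        assert (it2 <= it3 + 1e-9).all()
        assert (it3 <= aqg + 1e-9).all()
        assert it1.mean() <= it2.mean() <= it3.mean() <= aqg.mean()


class TestStability:
    def test_variability_averaging_is_stable(self, tiny_bundle):
        """Halving the variability draws moves the point estimate by <1%.

        The outer stage is held at its central parameters so the comparison
        isolates the inner (variability) averaging."""
        base = run_two_stage(
            tiny_bundle,
            mc=MCConfig(n_variability=1000, n_uncertainty=20).degenerate(),
            seed=21,
        ).draws["AN_total"].mean()
        halved = run_two_stage(
            tiny_bundle,
            mc=MCConfig(n_variability=500, n_uncertainty=20).degenerate(),
            seed=22,
        ).draws["AN_total"].mean()
        assert abs(halved - base) / base < 0.01

    def test_degenerate_robustness_error_is_zero(self, oracle_bundle):
        mc = MCConfig(n_variability=8, n_uncertainty=8).degenerate()
        res = robustness_check(oracle_bundle, mc=mc, seed=1, n_repeats=5)
        assert res.max_rel_error == 0.0
        assert res.sd_rel_error == 0.0

    def test_uncertainty_draw_families(self):
        crf = CRFunction()
        rng = np.random.default_rng(0)
        mc = MCConfig(n_uncertainty=4000)
        draws = sample_uncertainty(rng, mc, crf)
        # lognormal RR0: median at the central estimate
        assert np.median(draws["rr0"]) == pytest.approx(crf.rr0, rel=0.02)
        # triangular LC stays inside its stated range, mode near 2
        assert draws["lc"].min() >= crf.lc_range[0]
        assert draws["lc"].max() <= crf.lc_range[1]
        assert draws["lc"].mean() == pytest.approx((0 + 2 + 5) / 3, abs=0.1)
        # truncated-normal factors are positive with mean ~1
        for key in ("ir_factor", "cost_factor", "tdays_factor"):
            assert (draws[key] > 0).all()
            assert draws[key].mean() == pytest.approx(1.0, abs=0.02)
        degenerate = sample_uncertainty(
            np.random.default_rng(0), mc.degenerate(), crf
        )
        assert (degenerate["rr0"] == crf.rr0).all()
        assert (degenerate["lc"] == crf.lc).all()
        assert (degenerate["ir_factor"] == 1.0).all()
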