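"""ICER comparison, break-even search, tornado and PSA machinery."""

import math

import numpy as np
import pytest

from btccea.config import Bounded, base_case_config, with_value
from btccea.economics import (
    ArmResult,
    breakeven_price,
    build_psa_distributions,
    compare,
    evaluate,
    one_way_sa,
    run_psa,
)


@pytest.fixture
def cfg():
    return base_case_config()


def arm(cost, qaly, name="combo"):
    return ArmResult(name, cost, qaly)


class TestCompare:
    def test_simple_icer(self):
        c = compare(arm(100.0, 2.0), arm(0.0, 0.0, "chemo"), wtp=50.0)
        assert c.icer == pytest.approx(50.0)
        assert c.incremental_cost == 100.0 and c.incremental_qaly == 2.0
        assert c.dominance == "tradeoff"

    def test_dominant_when_cheaper_and_better(self):
        c = compare(arm(-10.0, 0.1), arm(0.0, 0.0, "chemo"), wtp=50.0)
        assert c.dominance == "dominant"

    def test_dominated_when_dearer_and_worse(self):
        c = compare(arm(10.0, -0.1), arm(0.0, 0.0, "chemo"), wtp=50.0)
        assert c.dominance == "dominated"

    def test_zero_qaly_difference_undefined(self):
        c = compare(arm(10.0, 1.0), arm(0.0, 1.0, "chemo"), wtp=50.0)
        assert c.dominance == "undefined"
        assert math.isnan(c.icer)

    def test_published_icers_imply_common_delta_qaly(self):
        """The two published ICER/incremental-cost pairs back-divide to the
        same unrounded incremental QALY (~0.11623) to 4 significant figures;
        the comparison layer reproduces both ICERs from that shared value."""
        dq_no = 80961.10 / 696571.11
        dq_char = 18555.19 / 159644.70
        assert dq_no == pytest.approx(dq_char, rel=1e-4)
        dq = dq_no
        no = compare(arm(97628.84, 1.0 + dq), arm(16667.75, 1.0, "chemo"), wtp=37663.26)
        char = compare(arm(35222.94, 1.0 + dq), arm(16667.75, 1.0, "chemo"), wtp=37663.26)
        assert no.icer == pytest.approx(696571.11, rel=1e-4)
        assert char.icer == pytest.approx(159644.70, rel=1e-4)


class TestBreakeven:
    def test_linear_oracle(self, cfg):
        """Total cost is affine in the durvalumab unit price, so the break-even
        price solves a linear equation; bisection must agree."""
        icer0 = evaluate(with_value(cfg, "costs.durvalumab_per_mg", 1.0)).icer
        icer1 = evaluate(with_value(cfg, "costs.durvalumab_per_mg", 2.0)).icer
        slope = icer1 - icer0
        analytic = 1.0 + (cfg.wtp_per_qaly - icer0) / slope
        res = breakeven_price(cfg)
        assert res["price_per_mg"] == pytest.approx(analytic, rel=1e-3)
        assert res["icer"] == pytest.approx(cfg.wtp_per_qaly, rel=1e-4)
        assert res["reduction_pct"] == pytest.approx(
            100 * (1 - analytic / 5.61), abs=0.1
        )

    def test_fixed_point_at_wtp_equal_base_icer(self, cfg):
        base_icer = evaluate(cfg).icer
        cfg_fp = base_case_config()
        cfg_fp.wtp_per_qaly = base_icer
        res = breakeven_price(cfg_fp)
        assert res["price_per_mg"] == pytest.approx(5.61, rel=0.01)

    def test_unbracketed_wtp_reports_endpoint_icers(self, cfg):
        cfg.wtp_per_qaly = 1e9
        with pytest.raises(ValueError, match="not bracketed"):
            breakeven_price(cfg, price_bounds=(0.0, 10.0))

    def test_icer_monotone_in_price(self, cfg):
        icers = [
            evaluate(with_value(cfg, "costs.durvalumab_per_mg", p)).icer
            for p in (1.0, 3.0, 5.61, 8.0)
        ]
        assert all(a < b for a, b in zip(icers, icers[1:]))


class TestOneWaySA:
    def test_degenerate_range_gives_zero_spread(self, cfg):
        cfg.costs.paclitaxel_per_100mg = Bounded(
            base=108.22, lower=108.22, upper=108.22, distribution="gamma"
        )
        entries = one_way_sa(cfg, parameters=["costs.paclitaxel_per_100mg"])
        assert entries[0].spread == 0.0

    def test_base_icer_bracketed_by_monotone_parameter(self, cfg):
        base = evaluate(cfg).icer
        (entry,) = one_way_sa(cfg, parameters=["costs.durvalumab_per_mg"])
        lo, hi = sorted([entry.icer_at_lower, entry.icer_at_upper])
        assert lo <= base <= hi

    def test_durvalumab_price_dominates_tornado(self, cfg):
        entries = one_way_sa(cfg)
        assert entries[0].parameter == "costs.durvalumab_per_mg"

    def test_discount_rate_endpoints_finite(self, cfg):
        (entry,) = one_way_sa(cfg, parameters=["discount"])
        base = evaluate(cfg).icer
        assert np.isfinite(entry.icer_at_lower) and np.isfinite(entry.icer_at_upper)
        lo, hi = sorted([entry.icer_at_lower, entry.icer_at_upper])
        assert lo <= base <= hi


class TestPSADistributions:
    def test_gamma_moment_matching(self, cfg):
        cfg.costs.paclitaxel_per_100mg = Bounded(
            base=100.0, lower=75.0, upper=125.0, distribution="gamma"
        )
        samplers = build_psa_distributions(cfg)
        rng = np.random.default_rng(0)
        draws = samplers["costs.paclitaxel_per_100mg"](rng, 100_000)
        assert draws.mean() == pytest.approx(100.0, rel=0.01)
        assert draws.std() == pytest.approx(25.0 / 1.96, rel=0.02)
        assert np.all(draws > 0)

    def test_beta_utilities_stay_in_unit_interval(self, cfg):
        samplers = build_psa_distributions(cfg)
        rng = np.random.default_rng(1)
        for name in ("utilities.pfs", "utilities.pd"):
            draws = samplers[name](rng, 50_000)
            assert np.all((draws > 0) & (draws < 1))
        pd_draws = samplers["utilities.pd"](np.random.default_rng(2), 100_000)
        assert pd_draws.mean() == pytest.approx(0.4, rel=0.01)

    def test_pfs_upper_bound_truncated_before_matching(self, cfg):
        # published range 0.675-1.125; sampling must treat the upper as 1.0
        samplers = build_psa_distributions(cfg)
        draws = samplers["utilities.pfs"](np.random.default_rng(3), 100_000)
        assert draws.max() < 1.0
        assert draws.mean() == pytest.approx(0.9, rel=0.01)

    def test_zero_width_range_is_point_mass(self, cfg):
        cfg.costs.terminal = Bounded(
            base=4517.85, lower=4517.85, upper=4517.85, distribution="gamma"
        )
        samplers = build_psa_distributions(cfg)
        draws = samplers["costs.terminal"](np.random.default_rng(4), 100)
        assert np.all(draws == 4517.85)


class TestRunPSA:
    def degenerate_config(self):
        cfg = base_case_config()
        for holder, field in [(cfg.costs, f) for f in type(cfg.costs).model_fields] + [
            (cfg.utilities, "pfs"), (cfg.utilities, "pd"), (cfg, "discount")
        ]:
            b = getattr(holder, field)
            setattr(holder, field, Bounded(base=b.base, lower=b.base, upper=b.base,
                                           distribution=b.distribution))
        return cfg

    def test_point_mass_psa_reproduces_base_case(self):
        cfg = self.degenerate_config()
        base = evaluate(cfg)
        psa = run_psa(cfg, n=3, seed=0)
        np.testing.assert_allclose(psa.delta_cost, base.incremental_cost, rtol=1e-12)
        np.testing.assert_allclose(psa.delta_qaly, base.incremental_qaly, rtol=1e-12)

    def test_ceac_at_zero_wtp_counts_cost_savings(self, cfg):
        psa = run_psa(cfg, n=60, seed=5)
        assert psa.ceac.probability[0] == pytest.approx(
            np.mean(psa.delta_cost <= 0)
        )

    def test_ceac_monotone_when_all_draws_gain_qalys(self, cfg):
        psa = run_psa(cfg, n=60, seed=6)
        assert np.all(psa.delta_qaly > 0)
        assert np.all(np.diff(psa.ceac.probability) >= 0)

    def test_ceac_grid_contains_threshold(self, cfg):
        psa = run_psa(cfg, n=10, seed=7)
        assert np.any(np.isclose(psa.ceac.wtp, 37663.26))
        assert psa.ceac.at(37663.26) == psa.acceptability(37663.26)

    def test_same_seed_bit_identical(self, cfg):
        a = run_psa(cfg, n=40, seed=11)
        b = run_psa(cfg, n=40, seed=11)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.ceac.probability, b.ceac.probability)

    def test_invalid_draw_count_rejected(self, cfg):
        with pytest.raises(ValueError):
            run_psa(cfg, n=0)
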