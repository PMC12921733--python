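"""Tornado, scenarios, PSA, CEAC and the price-threshold search."""

import numpy as np
import pytest

from bchicea import (
    apply_overrides,
    ceac,
    compare,
    evaluate,
    one_way_sa,
    price_threshold,
    psa,
    run_scenarios,
)
from bchicea.parameters import apply_settings_overrides
from bchicea.uncertainty import (
    ParameterRef,
    ScenarioSpec,
    _draw,
    bundled_scenarios,
    parameter_catalog,
)


class TestTornado:
    def test_zero_se_parameters_have_zero_range_and_rank_last(
        self, sentio, osia, settings, life_table
    ):
        params = [
            ParameterRef("cmp", "transitions.explantation", "probability", 0.0085, 0.0039),
            ParameterRef("ref", "transitions.revision", "probability", 0.0, 0.0),
        ]
        entries = one_way_sa(sentio, osia, settings, life_table, params)
        assert entries[-1].parameter == "ref:transitions.revision"
        assert entries[-1].range == 0.0
        assert entries[0].range > 0.0

    def test_cost_parameter_bounds_match_independent_reruns(
        self, sentio, osia, settings, life_table
    ):
        pref = ParameterRef("cmp", "costs.battery_per_cycle", "cost", 28.64, 2.864)
        entry = one_way_sa(sentio, osia, settings, life_table, [pref])[0]
        for bound, nmb in ((entry.low_input, entry.nmb_low), (entry.high_input, entry.nmb_high)):
            varied = apply_overrides(osia, {"costs.battery_per_cycle": bound})
            inc = compare(
                evaluate(sentio, settings, life_table),
                evaluate(varied, settings, life_table),
                settings.wtp_threshold,
            )
            assert nmb == pytest.approx(inc.nmb, rel=1e-12)

    def test_shared_on_state_utility_is_among_top_drivers(
        self, sentio, osia, settings, life_table
    ):
        entries = one_way_sa(sentio, osia, settings, life_table)
        top = [e.parameter for e in entries[:3]]
        assert "shared:utilities.on_bchi" in top

    def test_empty_parameter_list_rejected(self, sentio, osia, settings, life_table):
        with pytest.raises(ValueError, match="empty"):
            one_way_sa(sentio, osia, settings, life_table, [])

    def test_bounds_clamped_into_valid_domain(self, sentio, osia, settings, life_table):
        pref = ParameterRef("ref", "transitions.pain", "probability", 0.0088, 0.0060)
        entry = one_way_sa(sentio, osia, settings, life_table, [pref])[0]
        assert entry.low_input == 0.0  # 0.0088 - 1.96*0.006 < 0, clamped


class TestScenarios:
    def test_empty_scenario_changes_nothing(self, sentio, osia, settings, life_table):
        res = run_scenarios([ScenarioSpec("noop")], sentio, osia, settings, life_table)[0]
        assert res.pct_change_cost == 0.0
        assert res.pct_change_qalys == 0.0

    def test_five_year_horizon_equals_direct_rerun(self, sentio, osia, settings, life_table):
        res = run_scenarios(
            [ScenarioSpec("h5", {"horizon": 5.0})], sentio, osia, settings, life_table
        )[0]
        short = apply_settings_overrides(settings, {"horizon": 5.0})
        inc = compare(
            evaluate(sentio, short, life_table),
            evaluate(osia, short, life_table),
            short.wtp_threshold,
        )
        assert res.incremental.delta_qalys == pytest.approx(inc.delta_qalys, rel=1e-12)

    def test_removing_discounting_raises_incremental_qalys(
        self, sentio, osia, settings, life_table
    ):
        base = compare(
            evaluate(sentio, settings, life_table),
            evaluate(osia, settings, life_table),
            settings.wtp_threshold,
        )
        res = run_scenarios(
            [ScenarioSpec("r0", {"discount_rate_costs": 0.0, "discount_rate_qalys": 0.0})],
            sentio, osia, settings, life_table,
        )[0]
        assert res.incremental.delta_qalys > base.delta_qalys

    def test_bundled_catalog_resolves_end_to_end(self, sentio, osia, settings, life_table):
        catalog = bundled_scenarios()
        results = run_scenarios(catalog, sentio, osia, settings, life_table)
        assert len(results) == len(catalog)
        assert len({r.name for r in results}) == len(results)

    def test_unresolvable_override_names_the_scenario(
        self, sentio, osia, settings, life_table
    ):
        bad = ScenarioSpec("broken", ref_overrides={"costs.nope": 1.0})
        with pytest.raises(ValueError, match="broken"):
            run_scenarios([bad], sentio, osia, settings, life_table)


class TestDraws:
    def test_beta_draws_recover_probability_moments(self):
        pref = ParameterRef("cmp", "transitions.soft_tissue", "probability", 0.0638, 0.024)
        x = _draw(pref, 40_000, seed=5, warnings=[])
        assert x.mean() == pytest.approx(0.0638, abs=3 * 0.024 / np.sqrt(40_000))
        assert x.std() == pytest.approx(0.024, rel=0.05)
        assert np.all((x >= 0) & (x <= 1))

    def test_gamma_draws_recover_cost_moments(self):
        pref = ParameterRef("ref", "costs.hospitalisation", "cost", 5588.26, 558.826)
        x = _draw(pref, 40_000, seed=5, warnings=[])
        assert x.mean() == pytest.approx(5588.26, abs=3 * 558.826 / np.sqrt(40_000))
        assert x.std() == pytest.approx(558.826, rel=0.05)
        assert np.all(x >= 0)

    def test_decrement_draws_stay_negative(self):
        pref = ParameterRef("shared", "utilities.soft_tissue_decrement", "decrement",
                            -0.030, 0.006)
        x = _draw(pref, 10_000, seed=5, warnings=[])
        assert np.all(x <= 0)
        assert x.mean() == pytest.approx(-0.030, abs=3 * 0.006 / np.sqrt(10_000))

    def test_oversized_se_falls_back_with_warning(self):
        warnings = []
        pref = ParameterRef("ref", "transitions.pain", "probability", 0.0044, 0.5)
        x = _draw(pref, 1_000, seed=5, warnings=warnings)
        assert np.all((x >= 0) & (x <= 1))
        assert any("variance clamped" in w for w in warnings)


class TestPSA:
    def test_same_seed_is_bit_identical(self, sentio, osia, settings, life_table):
        a = psa(sentio, osia, settings, life_table, n_iterations=200, seed=11)
        b = psa(sentio, osia, settings, life_table, n_iterations=200, seed=11)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)
        assert a.quadrant_shares == b.quadrant_shares

    def test_zero_observed_events_stay_fixed(self, sentio, osia, settings, life_table):
        out = psa(sentio, osia, settings, life_table, n_iterations=50, seed=1)
        varied = out.metadata["varied_parameters"]
        assert "ref:transitions.explantation" not in varied  # zero in the base case
        assert "ref:transitions.revision" not in varied
        assert "cmp:transitions.explantation" in varied

    def test_zero_ses_collapse_to_the_deterministic_base_case(
        self, sentio, osia, settings, life_table
    ):
        frozen = [
            ParameterRef(p.arm, p.path, p.kind, p.mean, 0.0)
            for p in parameter_catalog(sentio, osia, include_timing=False)
        ]
        out = psa(sentio, osia, settings, life_table, n_iterations=20, seed=3,
                  parameters=frozen)
        base = compare(
            evaluate(sentio, settings, life_table),
            evaluate(osia, settings, life_table),
            settings.wtp_threshold,
        )
        assert np.allclose(out.delta_cost, base.delta_cost)
        assert np.allclose(out.delta_qalys, base.delta_qalys)

    def test_quadrant_shares_partition_the_iterations(
        self, sentio, osia, settings, life_table
    ):
        out = psa(sentio, osia, settings, life_table, n_iterations=300, seed=9)
        assert sum(out.quadrant_shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_adding_a_parameter_leaves_other_draws_unchanged(
        self, sentio, osia, settings, life_table
    ):
        # counter-based substreams: draws are keyed by parameter, not position
        base = [ParameterRef("cmp", "transitions.explantation", "probability", 0.0085, 0.0039)]
        extra = base + [ParameterRef("shared", "utilities.on_bchi", "utility", 0.76, 0.038)]
        w = []
        assert np.array_equal(_draw(base[0], 100, 17, w), _draw(extra[0], 100, 17, w))


class TestCEAC:
    def test_zero_wtp_counts_cost_saving_iterations(self, sentio, osia, settings, life_table):
        out = psa(sentio, osia, settings, life_table, n_iterations=400, seed=2)
        assert ceac(out, [0.0])[0] == pytest.approx(np.mean(out.delta_cost <= 0))

    def test_matches_per_iteration_nmb_scan(self, sentio, osia, settings, life_table):
        out = psa(sentio, osia, settings, life_table, n_iterations=400, seed=2)
        grid = [0.0, 10_000.0, 50_000.0, 100_000.0]
        brute = [
            np.mean([l * q - c >= 0 for q, c in zip(out.delta_qalys, out.delta_cost)])
            for l in grid
        ]
        assert np.array_equal(ceac(out, grid), brute)

    def test_nondecreasing_when_every_iteration_gains_qalys(
        self, sentio, osia, settings, life_table
    ):
        out = psa(sentio, osia, settings, life_table, n_iterations=400, seed=2)
        keep = out.delta_qalys > 0
        out.delta_qalys, out.delta_cost = out.delta_qalys[keep], out.delta_cost[keep]
        curve = ceac(out, np.arange(0, 100_001, 5_000, dtype=float))
        assert np.all(np.diff(curve) >= 0)

    def test_empty_grid_rejected(self, sentio, osia, settings, life_table):
        out = psa(sentio, osia, settings, life_table, n_iterations=10, seed=2)
        with pytest.raises(ValueError, match="empty"):
            ceac(out, [])


class TestPriceThreshold:
    def test_fixed_point_returns_the_current_price(self, sentio, osia, settings, life_table):
        # put the reference arm in the trade-off quadrant first
        pricey = apply_overrides(sentio, {"costs.device_acquisition": 30_000.0})
        inc = compare(
            evaluate(pricey, settings, life_table),
            evaluate(osia, settings, life_table),
            settings.wtp_threshold,
        )
        assert inc.icer is not None and inc.icer > 0
        found = price_threshold(pricey, osia, settings, life_table, inc.icer)
        assert found == pytest.approx(30_000.0, abs=1.0)

    def test_threshold_verified_by_rerun_and_monotone_in_target(
        self, sentio, osia, settings, life_table
    ):
        p50 = price_threshold(sentio, osia, settings, life_table, 50_000.0)
        p80 = price_threshold(sentio, osia, settings, life_table, 80_000.0)
        assert p80 > p50
        at = apply_overrides(sentio, {"costs.device_acquisition": p50})
        inc = compare(
            evaluate(at, settings, life_table),
            evaluate(osia, settings, life_table),
            settings.wtp_threshold,
        )
        assert inc.icer == pytest.approx(50_000.0, abs=0.5)

    def test_unreachable_target_rejected(self, sentio, osia, settings, life_table):
        with pytest.raises(ValueError, match="not reachable"):
            price_threshold(sentio, osia, settings, life_table, 50_000.0,
                            price_bounds=(14_000.0, 15_000.0))
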