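"""Tests of the beef supply-chain construction and allocation wiring."""

import numpy as np
import pytest

import beeflca as b
from beeflca.chain import (
    FeedTrial,
    HarvestSplit,
    RationItem,
    augment_indirect_n2o,
    build_chain_system,
    build_gate_to_gate_system,
    carcass_mass,
    cow_calf_process,
    economic_allocation,
    make_stage_process,
    scenario_boundaries,
    truncate_backgrounding,
)
from beeflca.lci import characterize, contribution_analysis, solve_inventory


@pytest.fixture
def unl_like_trial():
    """60 head gaining 293 -> 590 kg with a single-ingredient ration."""
    return FeedTrial(
        treatment="EFC",
        n_head=60,
        days_on_feed=154,
        start_weight=293.0,
        end_weight=590.0,
        ration=[RationItem("corn grain", 10.0, 9.0, 12.0)],
        emissions={"enteric_ch4": 12.0, "manure_ch4": 4.0, "manure_n2o": 0.5, "nh3": 20.0},
    )


class TestIndirectN2O:
    def test_zero_ammonia_gives_zero(self):
        assert augment_indirect_n2o(0.0, 0.01) == 0.0

    def test_hand_computed_value(self):
        # 100 * (14/17) * 0.01 * (44/28) = 1.2941 kg N2O
        assert augment_indirect_n2o(100.0, 0.01) == pytest.approx(1.2941, abs=1e-4)

    def test_linearity(self):
        one = augment_indirect_n2o(50.0, 0.01)
        assert augment_indirect_n2o(100.0, 0.01) == pytest.approx(2 * one, rel=1e-12)

    def test_emission_factor_sanity_bound(self):
        with pytest.raises(ValueError):
            augment_indirect_n2o(10.0, 0.2)
        with pytest.raises(ValueError):
            augment_indirect_n2o(10.0, -0.01)

    def test_include_flag_off(self):
        assert augment_indirect_n2o(100.0, 0.01, include=False) == 0.0


class TestStageProcess:
    def test_emissions_per_1000kg_lwg(self, unl_like_trial, bundle):
        proc = make_stage_process("fy", unl_like_trial, bundle.params, basis="lwg")
        ch4 = next(
            e for e in proc.exchanges if e.flow.id == "ch4_enteric"
        )
        # 1000 * (60 * 12.0) / (60 * 297)
        assert ch4.amount == pytest.approx(1000.0 * 60 * 12.0 / (60 * 297.0))

    def test_total_feed_input_matches_herd_total(self, unl_like_trial, bundle):
        proc = make_stage_process("fy", unl_like_trial, bundle.params, basis="lwg")
        grain = next(e for e in proc.exchanges if e.flow.id == "corn_grain")
        herd_total = 60 * 154 * 10.0
        assert grain.amount * unl_like_trial.total_lwg / 1000.0 == pytest.approx(
            herd_total
        )

    def test_cow_calf_process_is_treatment_independent(self, bundle):
        p1 = cow_calf_process(bundle.params)
        p2 = cow_calf_process(bundle.params)
        assert p1.id == p2.id == "cow_calf"
        assert [(e.flow.id, e.amount) for e in p1.exchanges] == [
            (e.flow.id, e.amount) for e in p2.exchanges
        ]

    def test_zero_gain_rejected(self, bundle):
        with pytest.raises(ValueError):
            FeedTrial(
                treatment="CNV",
                n_head=10,
                days_on_feed=10,
                start_weight=300.0,
                end_weight=300.0,
                ration=[RationItem("corn grain", 5.0, 9.0)],
                emissions={},
            )

    def test_chain_basis_conserves_live_weight(self, unl_like_trial, bundle):
        proc = make_stage_process("fy", unl_like_trial, bundle.params, basis="chain")
        feeder = next(e for e in proc.exchanges if e.flow.id.startswith("feeder_lw"))
        assert feeder.amount == pytest.approx(293.0 / 590.0)


class TestTruncation:
    def test_identity_at_full_end_weight(self, bundle):
        full = bundle.trials["bg_full"]["CNV"]
        same = truncate_backgrounding(full, full.end_weight)
        assert same.days_on_feed == full.days_on_feed
        assert same.total_feed_dm == pytest.approx(full.total_feed_dm)

    def test_midpoint_halves_cumulative_quantities(self, bundle):
        full = bundle.trials["bg_full"]["CNV"]
        mid = 0.5 * (full.start_weight + full.end_weight)
        half = truncate_backgrounding(full, mid)
        assert half.days_on_feed == full.days_on_feed // 2
        assert half.total_feed_dm == pytest.approx(0.5 * full.total_feed_dm)
        for gas, v in full.emissions.items():
            assert half.emissions[gas] == pytest.approx(0.5 * v)

    def test_ksu_like_truncation_to_unl_start(self):
        full = FeedTrial(
            treatment="CNV",
            n_head=60,
            days_on_feed=92,
            start_weight=244.5,
            end_weight=380.0,
            ration=[RationItem("corn grain", 8.0, 9.0)],
            emissions={"enteric_ch4": 10.0},
        )
        trunc = truncate_backgrounding(full, 293.0)
        frac = (293.0 - 244.5) / (380.0 - 244.5)
        assert trunc.days_on_feed == round(92 * frac)  # 33 days
        assert trunc.total_feed_dm == pytest.approx(frac * full.total_feed_dm)
        assert trunc.end_weight == 293.0

    def test_target_outside_range_rejected(self, bundle):
        full = bundle.trials["bg_full"]["CNV"]
        with pytest.raises(ValueError):
            truncate_backgrounding(full, full.start_weight - 1)
        with pytest.raises(ValueError):
            truncate_backgrounding(full, full.end_weight + 1)


class TestCarcassAndAllocation:
    @pytest.mark.parametrize(
        "cull, finished, expected",
        [(0.0, 1000.0, 630.0), (1000.0, 0.0, 500.0), (600.0, 590.0, 671.7)],
    )
    def test_carcass_mass(self, cull, finished, expected):
        assert carcass_mass(cull, finished, HarvestSplit()) == pytest.approx(expected)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            carcass_mass(-1.0, 0.0, HarvestSplit())

    def test_revenue_allocation_factors(self):
        f = economic_allocation({"cuts": 90.0, "hide": 5.0, "rendering": 5.0})
        assert f["cuts"] == pytest.approx(0.90)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_single_coproduct_gets_factor_one(self):
        assert economic_allocation({"cuts": 42.0}) == {"cuts": 1.0}

    def test_unequal_revenues_hand_shares(self):
        f = economic_allocation({"a": 7.0, "b": 2.0, "c": 1.0})
        assert f == pytest.approx({"a": 0.7, "b": 0.2, "c": 0.1})

    def test_all_zero_revenues_rejected(self):
        with pytest.raises(ValueError):
            economic_allocation({"a": 0.0, "b": 0.0})


class TestBypassEquivalence:
    def _chain_trials(self, bundle, treatment):
        fy = bundle.trials["fy_full"][treatment]
        bg = truncate_backgrounding(bundle.trials["bg_full"][treatment], fy.start_weight)
        return {"bg": bg, "fy": fy}

    @pytest.mark.parametrize("alpha", [0.25, 0.8])
    def test_bypass_equals_allocate_then_recombine(self, bundle, alpha):
        """Assigning all cow/calf burden to calves and recombining cull cows
        burden-free at harvest equals explicit allocation at any factor."""
        tr = self._chain_trials(bundle, "CNV")
        by = build_chain_system(tr, bundle.params, bundle.background, wiring="bypass")
        al = build_chain_system(
            tr, bundle.params, bundle.background, wiring="allocated", calf_alloc=alpha
        )
        r_by = characterize(solve_inventory(by), bundle.method).totals
        r_al = characterize(solve_inventory(al), bundle.method).totals
        for cat in r_by:
            assert r_al[cat] == pytest.approx(r_by[cat], rel=1e-9)

    def test_allocation_factor_does_not_leak_into_results(self, bundle):
        tr = self._chain_trials(bundle, "CNV")
        res = [
            characterize(
                solve_inventory(
                    build_chain_system(
                        tr, bundle.params, bundle.background,
                        wiring="allocated", calf_alloc=a,
                    )
                ),
                bundle.method,
            ).totals
            for a in (0.3, 0.95)
        ]
        for cat in res[0]:
            assert res[0][cat] == pytest.approx(res[1][cat], rel=1e-9)


class TestScenarios:
    def test_scenario_1_is_fy_only(self, bundle):
        cfg = scenario_boundaries(1)[0]
        cnv, _ = b.build_scenario(cfg, bundle.trials, bundle.params, bundle.background)
        stage_ids = [p.id for p in cnv.processes if ":" in p.id]
        assert stage_ids == ["fy:CNV"]

    def test_scenario_5_weights_identical_across_treatments(self, bundle):
        for tset in ("bg_s5", "fy_s5"):
            cnv = bundle.trials[tset]["CNV"]
            efc = bundle.trials[tset]["EFC"]
            assert cnv.start_weight == efc.start_weight
            assert cnv.end_weight == efc.end_weight
        assert bundle.trials["fy_s5"]["CNV"].end_weight == 662.0

    def test_scenario_4_mass_balance(self, bundle):
        """Total LWG of the matched system equals (UNL start - wean) plus
        the feed-yard gain."""
        fy = bundle.trials["fy_full"]["CNV"]
        bg = truncate_backgrounding(bundle.trials["bg_full"]["CNV"], fy.start_weight)
        total = bg.lwg_per_head + fy.lwg_per_head
        expected = (fy.start_weight - 244.5) + (fy.end_weight - fy.start_weight)
        assert total == pytest.approx(expected)

    def test_chain_live_weight_is_conserved_between_stages(self, bundle):
        cfg = [s for s in scenario_boundaries(4) if s.boundary == "cradle_to_harvest"][0]
        cnv, _ = b.build_scenario(cfg, bundle.trials, bundle.params, bundle.background)
        by_id = {p.id: p for p in cnv.processes}
        bg = by_id["bg_chain:CNV"]
        fy = by_id["fy_chain:CNV"]
        fy_start = next(e for e in fy.exchanges if e.flow.id == "feeder_lw_CNV")
        bg_trial = truncate_backgrounding(
            bundle.trials["bg_full"]["CNV"], bundle.trials["fy_full"]["CNV"].start_weight
        )
        assert fy_start.amount == pytest.approx(
            bg_trial.end_weight / bundle.trials["fy_full"]["CNV"].end_weight
        )

    def test_treatment_isolation_null_generator(self, null_bundle):
        """With identical trial pairs every scenario gives exactly 0 %."""
        res = b.ComparativeLCA(null_bundle).fit()
        assert np.allclose(res.impacts.percent_decrease, 0.0, atol=1e-9)

    def test_dilution_cradle_smaller_than_gate_to_gate(self, results):
        """Adding treatment-independent cow/calf and harvesting stages
        dilutes the percent decrease in every category."""
        gtg = results.impacts.query("scenario_id == 4 and boundary == 'BG_plus_FY'")
        cradle = results.impacts.query(
            "scenario_id == 4 and boundary == 'cradle_to_harvest'"
        )
        for cat in gtg.category:
            g = gtg[gtg.category == cat].percent_decrease.iloc[0]
            c = cradle[cradle.category == cat].percent_decrease.iloc[0]
            assert 0 < c < g

    def test_herd_scale_and_intensity_scale_agree(self, bundle):
        """Impacts per 1000 kg LWG are identical whether computed from the
        per-1000-kg process or rescaled from a herd-total demand."""
        trial = bundle.trials["fy_full"]["CNV"]
        tr = {"fy": trial}
        per_fu = build_gate_to_gate_system(
            tr, bundle.params, bundle.background, "gate_to_gate_FY", demand_kg=1000.0
        )
        herd = build_gate_to_gate_system(
            tr, bundle.params, bundle.background, "gate_to_gate_FY",
            demand_kg=trial.total_lwg,
        )
        r_fu = characterize(solve_inventory(per_fu), bundle.method).totals
        r_herd = characterize(solve_inventory(herd), bundle.method).totals
        scale = trial.total_lwg / 1000.0
        for cat in r_fu:
            assert r_herd[cat] == pytest.approx(scale * r_fu[cat], rel=1e-12)

    def test_all_scenarios_solve_for_both_treatments(self, bundle):
        for sid in range(1, 7):
            for cfg in scenario_boundaries(sid):
                cnv, efc = b.build_scenario(
                    cfg, bundle.trials, bundle.params, bundle.background
                )
                for sys in (cnv, efc):
                    g = solve_inventory(sys)
                    assert all(np.isfinite(v) for v in g.values())

    def test_nonnegative_impacts_on_acyclic_chain(self, results):
        assert (results.impacts[["CNV", "EFC"]] >= 0).all().all()
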