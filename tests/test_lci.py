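"""Unit tests of the matrix LCI engine."""

import numpy as np
import pytest

from beeflca.lci import (
    AmbiguousSupplyError,
    Exchange,
    Flow,
    ImpactMethod,
    InfeasibleSystemError,
    ProductSystem,
    UnitProcess,
    UnitMismatchError,
    UnlinkedFlowError,
    build_matrices,
    characterize,
    contribution_analysis,
    percent_decrease,
    read_impact_method,
    read_process_database,
    solve_inventory,
    write_impact_method,
    write_process_database,
)


def product(fid, unit="kg"):
    return Flow(fid, fid, "product", unit)


def elementary(fid, unit="kg"):
    return Flow(fid, fid, "elementary", unit)


def make_method(**climate):
    factors = {
        "climate change": climate or {"co2": 1.0},
        "land use": {},
        "water use": {},
        "fossil energy": {},
    }
    return ImpactMethod(factors=factors)


class TestBuildMatrices:
    def test_single_process_identity(self):
        beef = product("beef")
        proc = UnitProcess("p", "p", (beef, 1.0), [])
        sys = ProductSystem([proc], {beef: 5.0})
        mats = build_matrices(sys)
        assert mats.A.tolist() == [[1.0]]
        assert mats.f.tolist() == [5.0]

    def test_two_process_chain_declaration_order(self):
        p, q = product("P"), product("Q")
        proc_p = UnitProcess("p", "p", (p, 1.0), [Exchange(q, 0.5, "input")])
        proc_q = UnitProcess("q", "q", (q, 1.0), [])
        mats = build_matrices(ProductSystem([proc_p, proc_q], {p: 1.0}))
        assert mats.A.tolist() == [[1.0, 0.0], [-0.5, 1.0]]

    def test_three_process_with_self_loop_matches_hand_matrix(self):
        # hand-constructed: a supplies itself 0.1 per unit, b needs 0.2 a,
        # c needs 0.4 b and 0.3 a
        a, bf, c = product("a"), product("b"), product("c")
        procs = [
            UnitProcess("pa", "pa", (a, 1.0), [Exchange(a, 0.1, "input")]),
            UnitProcess("pb", "pb", (bf, 2.0), [Exchange(a, 0.2, "input")]),
            UnitProcess(
                "pc", "pc", (c, 1.0),
                [Exchange(bf, 0.4, "input"), Exchange(a, 0.3, "input")],
            ),
        ]
        mats = build_matrices(ProductSystem(procs, {c: 1.0}))
        expected = [[0.9, -0.2, -0.3], [0.0, 2.0, -0.4], [0.0, 0.0, 1.0]]
        np.testing.assert_allclose(mats.A, expected)

    def test_unlinked_flow_is_named(self):
        p, q = product("P"), product("mystery")
        proc = UnitProcess("p", "p", (p, 1.0), [Exchange(q, 0.5, "input")])
        with pytest.raises(UnlinkedFlowError, match="mystery"):
            build_matrices(ProductSystem([proc], {p: 1.0}))

    def test_ambiguous_supply_rejected(self):
        p = product("P")
        procs = [
            UnitProcess("p1", "p1", (p, 1.0), []),
            UnitProcess("p2", "p2", (p, 1.0), []),
        ]
        with pytest.raises(AmbiguousSupplyError, match="P"):
            build_matrices(ProductSystem(procs, {p: 1.0}))

    def test_unit_mismatch_at_link_time(self):
        p = product("P")
        q_kg = product("Q", "kg")
        q_mj = product("Q", "MJ")
        procs = [
            UnitProcess("p", "p", (p, 1.0), [Exchange(q_mj, 1.0, "input")]),
            UnitProcess("q", "q", (q_kg, 1.0), []),
        ]
        with pytest.raises(UnitMismatchError):
            build_matrices(ProductSystem(procs, {p: 1.0}))

    def test_coproduction_rejected_at_construction(self):
        p, q = product("P"), product("Q")
        with pytest.raises(ValueError, match="allocated"):
            UnitProcess("p", "p", (p, 1.0), [Exchange(q, 1.0, "output")])


class TestSolveInventory:
    def test_direct_emission_scales_with_demand(self):
        beef, co2 = product("beef"), elementary("co2")
        proc = UnitProcess("p", "p", (beef, 1.0), [Exchange(co2, 2.0, "output")])
        g = solve_inventory(ProductSystem([proc], {beef: 1000.0}))
        assert g["co2"] == pytest.approx(2000.0)

    def test_upstream_emission_through_chain(self):
        p, q, ch4 = product("P"), product("Q"), elementary("ch4")
        procs = [
            UnitProcess("p", "p", (p, 1.0), [Exchange(q, 0.5, "input")]),
            UnitProcess("q", "q", (q, 1.0), [Exchange(ch4, 1.0, "output")]),
        ]
        g = solve_inventory(ProductSystem(procs, {p: 10.0}))
        assert g["ch4"] == pytest.approx(5.0)

    def test_singular_matrix_is_infeasible(self):
        p, q = product("P"), product("Q")
        procs = [
            # p consumes 1 q per unit and q consumes 1 p per unit at amount 1:
            # A = [[1,-1],[-1,1]] is singular
            UnitProcess("p", "p", (p, 1.0), [Exchange(q, 1.0, "input")]),
            UnitProcess("q", "q", (q, 1.0), [Exchange(p, 1.0, "input")]),
        ]
        with pytest.raises(InfeasibleSystemError):
            solve_inventory(ProductSystem(procs, {p: 1.0}))

    def test_self_loop_matches_neumann_series(self):
        p, co2 = product("P"), elementary("co2")
        proc = UnitProcess(
            "p", "p", (p, 1.0),
            [Exchange(p, 0.1, "input"), Exchange(co2, 1.0, "output")],
        )
        g = solve_inventory(ProductSystem([proc], {p: 1.0}))
        # scaling = sum over k of 0.1^k
        expected = sum(0.1**k for k in range(40))
        assert g["co2"] == pytest.approx(expected, rel=1e-10)

    def test_linearity_in_demand(self, bundle):
        from beeflca.chain import build_gate_to_gate_system

        tr = {"fy": bundle.trials["fy_full"]["CNV"]}
        s1 = build_gate_to_gate_system(
            tr, bundle.params, bundle.background, "gate_to_gate_FY", demand_kg=1000.0
        )
        s2 = build_gate_to_gate_system(
            tr, bundle.params, bundle.background, "gate_to_gate_FY", demand_kg=2000.0
        )
        g1, g2 = solve_inventory(s1), solve_inventory(s2)
        for fid, v in g1.items():
            assert g2[fid] == pytest.approx(2.0 * v, rel=1e-12)


def _random_system(rng, n_max=8):
    """Random small solvable system with dominant diagonal (spectral
    radius of I - D^-1 A below 1)."""
    n = rng.integers(1, n_max + 1)
    flows = [product(f"f{i}") for i in range(n)]
    em = [elementary(f"e{i}") for i in range(3)]
    procs = []
    for j in range(n):
        ref_amount = rng.uniform(0.5, 2.0)
        exchanges = []
        for i in range(n):
            if rng.random() < 0.4:
                amount = rng.uniform(0.0, 0.6) * ref_amount / n
                if i == j and amount >= 0.9 * ref_amount:
                    continue
                exchanges.append(Exchange(flows[i], amount, "input"))
        for e in em:
            if rng.random() < 0.7:
                exchanges.append(Exchange(e, rng.uniform(0, 5), "output"))
        procs.append(UnitProcess(f"p{j}", f"p{j}", (flows[j], ref_amount), exchanges))
    demand = {flows[int(rng.integers(0, n))]: rng.uniform(1, 100)}
    return ProductSystem(procs, demand)


def _neumann_inventory(system, tol=1e-12, max_terms=10_000):
    """Brute-force power-series oracle: s = sum_k M^k y with M = I - D^-1 A."""
    mats = build_matrices(system)
    D = np.diag(np.diag(mats.A))
    Dinv = np.diag(1.0 / np.diag(mats.A))
    M = np.eye(len(mats.f)) - Dinv @ mats.A
    y = Dinv @ mats.f
    s = y.copy()
    term = y.copy()
    for _ in range(max_terms):
        term = M @ term
        s += term
        if np.linalg.norm(term) < tol * max(np.linalg.norm(s), 1.0):
            break
    g = mats.B @ s
    return {fl.id: g[i] for i, fl in enumerate(mats.elementary_flows)}


def test_neumann_series_oracle_on_random_systems():
    """solve_inventory agrees with the truncated power-series expansion on
    many random small systems."""
    rng = np.random.default_rng(20240917)
    checked = 0
    for _ in range(60):
        sys = _random_system(rng)
        mats = build_matrices(sys)
        M = np.eye(len(mats.f)) - np.diag(1.0 / np.diag(mats.A)) @ mats.A
        if np.max(np.abs(np.linalg.eigvals(M))) >= 0.95:
            continue
        expected = _neumann_inventory(sys)
        got = solve_inventory(sys)
        checked += 1
        for fid, v in expected.items():
            assert got[fid] == pytest.approx(v, rel=1e-8, abs=1e-10)
    assert checked >= 50


class TestCharacterize:
    def test_single_flow(self):
        method = make_method(ch4=28.0)
        res = characterize({"ch4": 5.0}, method)
        assert res.totals["climate change"] == pytest.approx(140.0)

    def test_empty_inventory_all_zero(self):
        res = characterize({}, make_method())
        assert all(v == 0.0 for v in res.totals.values())

    def test_three_flow_dot_product(self):
        method = make_method(co2=1.0, ch4=28.0, n2o=265.0)
        g = {"co2": 100.0, "ch4": 2.5, "n2o": 0.4}
        res = characterize(g, method)
        # hand spreadsheet: 100*1 + 2.5*28 + 0.4*265 = 276
        assert res.totals["climate change"] == pytest.approx(100 + 70 + 106)

    def test_missing_factor_contributes_zero_and_warns(self, caplog):
        import logging

        method = make_method(co2=1.0)
        with caplog.at_level(logging.WARNING, logger="beeflca.lci"):
            res = characterize({"co2": 1.0, "orphan": 99.0}, method)
        assert res.totals["climate change"] == pytest.approx(1.0)
        assert any("orphan" in r.message for r in caplog.records)


class TestContributions:
    def test_single_process_gets_everything(self):
        beef, co2 = product("beef"), elementary("co2")
        proc = UnitProcess("p", "p", (beef, 1.0), [Exchange(co2, 2.0, "output")])
        res = contribution_analysis(
            ProductSystem([proc], {beef: 1.0}), make_method(co2=1.0)
        )
        assert res.contributions["climate change"]["p"] == pytest.approx(
            res.totals["climate change"]
        )

    def test_equal_emitters_split_evenly(self):
        a, bf, co2 = product("a"), product("b"), elementary("co2")
        top = product("top")
        procs = [
            UnitProcess("pa", "pa", (a, 1.0), [Exchange(co2, 3.0, "output")]),
            UnitProcess("pb", "pb", (bf, 1.0), [Exchange(co2, 3.0, "output")]),
            UnitProcess(
                "pt", "pt", (top, 1.0),
                [Exchange(a, 1.0, "input"), Exchange(bf, 1.0, "input")],
            ),
        ]
        res = contribution_analysis(
            ProductSystem(procs, {top: 1.0}), make_method(co2=1.0)
        )
        c = res.contributions["climate change"]
        assert c["pa"] == pytest.approx(c["pb"])
        assert c["pa"] == pytest.approx(0.5 * res.totals["climate change"])

    def test_contributions_sum_to_total_on_beef_chain(self, bundle, results):
        for (sid, boundary) in [(1, "gate_to_gate_FY"), (4, "cradle_to_harvest")]:
            shares = results.contributions(sid, boundary)
            for cat, grp in shares.groupby("category"):
                total = results.impacts.query(
                    "scenario_id == @sid and boundary == @boundary"
                    " and category == @cat"
                ).CNV.iloc[0]
                assert grp.contribution.sum() == pytest.approx(total, rel=1e-9)
                assert grp.share.sum() == pytest.approx(1.0, rel=1e-9)


class TestPercentDecrease:
    @pytest.mark.parametrize(
        "cnv, efc, expected",
        [(8608.0, 8109.0, 5.80), (3365.0, 3191.0, 5.17), (7.0, 7.0, 0.0)],
    )
    def test_examples(self, cnv, efc, expected):
        assert round(percent_decrease(cnv, efc), 2) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)
        with pytest.raises(ValueError):
            percent_decrease(-5.0, 1.0)


def test_process_database_roundtrip(tmp_path, bundle):
    path = tmp_path / "db.csv"
    write_process_database(bundle.background, path)
    back = read_process_database(path)
    assert [p.id for p in back] == [p.id for p in bundle.background]
    for orig, loaded in zip(bundle.background, back):
        assert loaded.reference_product[0] == orig.reference_product[0]
        assert len(loaded.exchanges) == len(orig.exchanges)
        for eo, el in zip(orig.exchanges, loaded.exchanges):
            assert el.flow.id == eo.flow.id
            assert el.amount == pytest.approx(eo.amount, rel=1e-12)
            assert (el.uncertainty is None) == (eo.uncertainty is None)


def test_impact_method_roundtrip(tmp_path, method):
    path = tmp_path / "factors.csv"
    write_impact_method(method, path)
    back = read_impact_method(path)
    assert back.factors == method.factors
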