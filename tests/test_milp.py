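import dataclasses

import numpy as np
import pytest

from minnet import fixtures, milp
from minnet.milp import (BuildError, InfeasibleScenarioError, build_minnw,
                         build_minnw0, build_minnw_rep, encode, solve)
from minnet.model_io import (LinearFunctionality, ReductionScenario,
                             ValidationError)
from minnet.preprocess import partial_coupling_classes

from conftest import network_from_dict


def geq(rid, value):
    return ({rid: 1.0}, ">=", value)


# ---------------------------------------------------------------------------
# Builders: structure
# ---------------------------------------------------------------------------

class TestBuilders:
    def test_minnw0_counts(self, linear_chain):
        scen = ReductionScenario(protected_reactions={"ex"})
        prob = build_minnw0(linear_chain, scen)
        assert prob.formulation == "minnw0"
        assert prob.copies == 1
        # one binary per irreversible reaction, no abar
        assert prob.n_binary() == 3
        assert set(prob.objective) == {f"a[{r}]@0" for r in
                                       linear_chain.reaction_ids}

    def test_minnw0_reversible_gets_two_binaries(self):
        net = network_from_dict(
            ["A"], {"r": ({"A": 1}, -10, 10), "ex": ({"A": -1}, 0, 10)})
        prob = build_minnw0(net, ReductionScenario(protected_reactions={"ex"}))
        assert "a[r]@0" in prob.variables
        assert "an[r]@0" in prob.variables
        assert any(row.name.startswith("eq6[r]") for row in prob.rows)

    def test_minnw_copy_count(self):
        net, scen = fixtures.make_dual_condition_toy()
        prob = build_minnw(net, scen)
        assert prob.copies == 3  # protected copy + 2 functionalities
        # aggregated binaries exist for every reaction
        assert set(prob.aggregated) == set(net.reaction_ids)
        # 3 copies * 8 reactions + 8 aggregated (all irreversible)
        assert prob.n_binary() == 3 * 8 + 8

    def test_minnw_objective_is_aggregated(self):
        net, scen = fixtures.make_dual_condition_toy()
        prob = build_minnw(net, scen)
        assert set(prob.objective) == {f"A[{r}]" for r in net.reaction_ids}
        assert all(c == 1.0 for c in prob.objective.values())

    def test_minnw_rep_objective_weights_are_class_sizes(self):
        net, scen = fixtures.make_dual_condition_toy()
        part = partial_coupling_classes(net)
        prob = build_minnw_rep(net, scen, part)
        assert prob.binary_space == "class"
        weights = sorted(prob.objective.values())
        assert weights == sorted(len(c) for c in part.classes)

    def test_minnw_rep_requires_partition(self):
        net, scen = fixtures.make_dual_condition_toy()
        with pytest.raises(BuildError):
            build_minnw_rep(net, scen, None)

    def test_unresolved_scenario_rejected(self, linear_chain):
        from minnet.model_io import FractionOfOptimum
        f = LinearFunctionality("g", (), FractionOfOptimum("ex", 0.5))
        scen = ReductionScenario(functionalities=[f],
                                 protected_reactions={"ex"})
        with pytest.raises(BuildError, match="unresolved"):
            build_minnw(linear_chain, scen)

    def test_unknown_protected_rejected(self, linear_chain):
        scen = ReductionScenario(protected_reactions={"ghost"})
        with pytest.raises(ValidationError):
            build_minnw(linear_chain, scen)

    def test_protected_metabolite_row_skips_covered(self):
        # protected metabolite touched by a protected reaction needs no
        # eq3-style row of its own
        net = network_from_dict(
            ["A"], {"up": ({"A": 1}, 0, 10), "ex": ({"A": -1}, 0, 10)})
        scen = ReductionScenario(protected_metabolites={"A"},
                                 protected_reactions={"ex"})
        prob = build_minnw(net, scen)
        assert not any("pmet" in r.name or "eq3" in r.name
                       for r in prob.rows if "[A]" in r.name)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class TestEncoding:
    def test_modes_differ_in_constants(self, linear_chain):
        scen = ReductionScenario(protected_reactions={"ex"})
        prob = build_minnw(linear_chain, scen)
        rows_ind = {r.name: r for r in encode(prob, "indicator").rows}
        rows_big = {r.name: r for r in encode(prob, "bigM").rows}
        name = "eq4hi[v[ex]@0]"
        assert rows_ind[name].coeffs["a[ex]@0"] == -10.0   # model bound
        assert rows_big[name].coeffs["a[ex]@0"] == -1000.0  # global M

    def test_unknown_mode_rejected(self, linear_chain):
        prob = build_minnw(linear_chain,
                           ReductionScenario(protected_reactions={"ex"}))
        with pytest.raises(BuildError):
            encode(prob, "magic")

    def test_delta_ge_bigm_rejected(self, linear_chain):
        scen = ReductionScenario(protected_reactions={"ex"}, delta=1e-4,
                                 big_M=5e-5)
        with pytest.raises(ValidationError):
            build_minnw(linear_chain, scen)

    def test_infinite_bounds_capped_in_encoding_only(self):
        net = network_from_dict(
            ["A"], {"up": ({"A": 1}, 0, np.inf), "ex": ({"A": -1}, 0, 10)})
        scen = ReductionScenario(protected_reactions={"ex"})
        prob = build_minnw(net, scen)
        enc = encode(prob, "indicator")
        assert enc.variables["v[up]@0"].ub == 1000.0
        # the problem itself keeps the infinite bound
        assert prob.variables["v[up]@0"].ub == np.inf


# ---------------------------------------------------------------------------
# Solving toys
# ---------------------------------------------------------------------------

class TestSolve:
    @pytest.mark.parametrize("mode", ["indicator", "bigM"])
    def test_branch_toy_minimum(self, mode):
        net, scen = fixtures.make_branch_toy()
        sol = solve(build_minnw(net, scen), mode=mode)
        assert sol.n_active == 3
        assert sol.active == frozenset({"uptake", "r1", "export"})

    def test_witnesses_satisfy_delta(self):
        net, scen = fixtures.make_branch_toy()
        sol = solve(build_minnw(net, scen))
        w = sol.witness(0)
        for rid in sol.active:
            assert abs(w[rid]) >= scen.delta - 1e-9
        for rid in set(net.reaction_ids) - sol.active:
            assert abs(w[rid]) <= 1e-6

    def test_dual_toy_joint_minimum(self):
        net, scen = fixtures.make_dual_condition_toy()
        sol = solve(build_minnw(net, scen))
        assert sol.n_active == 6
        assert sol.active == frozenset(
            {"EX_o2", "uptake", "conv1", "conv2", "ox_alt", "EX_bio"})
        # each functionality copy satisfies its own rows
        assert sol.witness(1)["EX_bio"] >= 1.0 - 1e-6
        assert sol.witness(1)["EX_o2"] >= 0.1 - 1e-6
        assert sol.witness(2)["EX_bio"] >= 1.0 - 1e-6
        assert abs(sol.witness(2)["EX_o2"]) <= 1e-6

    def test_minnw0_infeasible_on_conflicting_conditions(self):
        net, scen = fixtures.make_dual_condition_toy()
        with pytest.raises(InfeasibleScenarioError):
            solve(build_minnw0(net, scen))

    def test_minnw0_matches_minnw_single_condition(self):
        net, scen = fixtures.make_dual_condition_toy()
        one = dataclasses.replace(scen,
                                  functionalities=[scen.functionalities[0]])
        s0 = solve(build_minnw0(net, one))
        s1 = solve(build_minnw(net, one))
        assert s0.n_active == s1.n_active == 4

    def test_minnw_rep_matches_minnw(self):
        net, scen = fixtures.make_dual_condition_toy()
        part = partial_coupling_classes(net)
        s_rep = solve(build_minnw_rep(net, scen, part))
        s_full = solve(build_minnw(net, scen))
        assert s_rep.n_active == s_full.n_active
        assert s_rep.active == s_full.active
        # class-space solution activates whole classes only
        for cls in part.as_sets():
            assert cls <= s_rep.active or not (cls & s_rep.active)

    def test_protected_reaction_always_active(self):
        net, _ = fixtures.make_symmetric_toy(3)
        scen = ReductionScenario(protected_reactions={"p2"})
        sol = solve(build_minnw(net, scen))
        assert "p2" in sol.active
        assert sol.active == frozenset({"uptake", "p2", "export"})

    def test_protected_metabolite_needs_one_touching_reaction(self):
        net, _ = fixtures.make_symmetric_toy(2)
        scen = ReductionScenario(protected_metabolites={"B"})
        sol = solve(build_minnw(net, scen))
        touching = set(net.reactions_of_metabolite("B"))
        assert sol.active & touching

    def test_infeasible_bounds_detected(self):
        net = network_from_dict(
            ["A"], {"up": ({"A": 1}, 0, 1), "ex": ({"A": -1}, 0, 10)})
        scen = ReductionScenario(functionalities=[
            LinearFunctionality.from_rows("f", [geq("ex", 5.0)])])
        with pytest.raises(InfeasibleScenarioError):
            solve(build_minnw(net, scen))

    def test_monotonicity_adding_functionality(self):
        # adding a functionality can only grow the minimum size
        net, scen = fixtures.make_dual_condition_toy()
        base = dataclasses.replace(scen, functionalities=[])
        one = dataclasses.replace(scen,
                                  functionalities=[scen.functionalities[0]])
        sizes = [solve(build_minnw(net, s)).n_active
                 for s in (base, one, scen)]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_reversible_activity_with_negative_flux(self):
        # reaction must run backwards to satisfy the functionality
        net = network_from_dict(
            ["A"],
            {"r": ({"A": 1}, -10, 10), "ex": ({"A": -1}, -10, 10)})
        scen = ReductionScenario(functionalities=[
            LinearFunctionality.from_rows("back", [({"r": 1.0}, "<=", -1.0)])])
        sol = solve(build_minnw(net, scen))
        assert "r" in sol.active
        assert sol.witness(1)["r"] <= -1.0 + 1e-6

    def test_delta_scales_minimum_threshold(self):
        # a tight bound can make delta-activity infeasible for large delta
        net = network_from_dict(
            ["A"], {"up": ({"A": 1}, 0, 1e-5), "ex": ({"A": -1}, 0, 10)})
        with pytest.warns(UserWarning):
            scen = ReductionScenario(protected_reactions={"ex"}, delta=1e-3)
        with pytest.raises(InfeasibleScenarioError):
            solve(build_minnw(net, scen))
        scen2 = ReductionScenario(protected_reactions={"ex"}, delta=1e-6)
        assert solve(build_minnw(net, scen2)).n_active == 2


# ---------------------------------------------------------------------------
# LP export
# ---------------------------------------------------------------------------

class TestDump:
    def test_dump_lp_contains_equation_tags(self, tmp_path, linear_chain):
        prob = build_minnw(linear_chain,
                           ReductionScenario(protected_reactions={"ex"}))
        out = tmp_path / "model.lp"
        milp.dump_lp(prob, out)
        text = out.read_text()
        assert "eq4lo" in text
        assert "ss_" in text or "ss[" in text
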