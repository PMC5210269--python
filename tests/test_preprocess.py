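import itertools

import numpy as np
import pytest

from minnet import _lp, fixtures
from minnet.model_io import (LinearFunctionality, ReductionScenario,
                             ValidationError)
from minnet.preprocess import (CouplingPartition, dead_end_reduction,
                               find_blocked_reactions,
                               find_dead_end_metabolites,
                               partial_coupling_classes, preprocess_network,
                               project_scenario, remove_reactions)

from conftest import network_from_dict


# ---------------------------------------------------------------------------
# Dead ends
# ---------------------------------------------------------------------------

class TestDeadEnds:
    def test_no_dead_ends_in_chain(self, linear_chain):
        assert find_dead_end_metabolites(linear_chain) == set()

    def test_produced_only_metabolite(self):
        net = network_from_dict(
            ["A", "X"],
            {"up": ({"A": 1}, 0, 10),
             "side": ({"A": -1, "X": 1}, 0, 10),   # X never consumed
             "ex": ({"A": -1}, 0, 10)})
        assert find_dead_end_metabolites(net) == {"X"}
        red, dead, removed = dead_end_reduction(net)
        assert dead == {"X"}
        assert removed == {"side"}
        assert red.reaction_ids == ["up", "ex"]

    def test_cascade(self):
        # removing r2 (only consumer of X) makes Y produced-only too
        net = network_from_dict(
            ["A", "X", "Y"],
            {"up": ({"A": 1}, 0, 10),
             "r1": ({"A": -1, "X": 1}, 0, 10),
             "r2": ({"X": -1, "Y": 1}, 0, 10),     # Y never consumed
             "ex": ({"A": -1}, 0, 10)})
        red, dead, removed = dead_end_reduction(net)
        assert dead == {"X", "Y"}
        assert removed == {"r1", "r2"}
        assert red.reaction_ids == ["up", "ex"]

    def test_reversible_counts_both_ways(self):
        # A <-> X via reversible r: X has both a producer and a consumer
        # (the same reversible reaction), so the structural dead-end scan
        # keeps it -- the LP-based blocked-reaction test catches r instead
        net = network_from_dict(
            ["A", "X"],
            {"up": ({"A": 1}, 0, 10),
             "r": ({"A": -1, "X": 1}, -10, 10),
             "ex": ({"A": -1}, 0, 10)})
        assert find_dead_end_metabolites(net) == set()
        assert find_blocked_reactions(net) == {"r"}

    def test_total_collapse_returns_none(self):
        net = network_from_dict(["A"], {"r": ({"A": 1}, 0, 10)})
        red, dead, removed = dead_end_reduction(net)
        assert red is None
        assert dead == {"A"}
        assert removed == {"r"}


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------

class TestBlocked:
    def test_chain_is_unblocked(self, linear_chain):
        assert find_blocked_reactions(linear_chain) == set()

    def test_internal_cycle_without_exchange_is_blocked(self):
        net = network_from_dict(
            ["A", "B", "C"],
            {"up": ({"A": 1}, 0, 10),
             "ex": ({"A": -1}, 0, 10),
             "c1": ({"B": -1, "C": 1}, 0, 10),    # B/C have no source
             "c2": ({"C": -1, "B": 1}, 0, 10)})
        blocked = find_blocked_reactions(net)
        # c1/c2 form an internal loop; over the cone they can cycle, so
        # they are NOT blocked -- the classic thermodynamic loop caveat
        assert blocked == set()

    def test_one_way_dead_branch_is_blocked(self):
        net = network_from_dict(
            ["A", "B"],
            {"up": ({"A": 1}, 0, 10),
             "branch": ({"A": -1, "B": 1}, 0, 10),  # B has no consumer
             "ex": ({"A": -1}, 0, 10)})
        assert find_blocked_reactions(net) == {"branch"}

    def test_bounds_do_not_affect_blockedness(self):
        # blockedness is defined over the cone C0: a zero upper bound does
        # not make a reaction blocked
        net = network_from_dict(
            ["A"],
            {"up": ({"A": 1}, 0, 0), "ex": ({"A": -1}, 0, 0)})
        assert find_blocked_reactions(net) == set()

    def test_idempotent_after_removal(self):
        net = fixtures.random_feasible_network(8, 12, seed=3)
        blocked = find_blocked_reactions(net)
        if blocked:
            net2 = remove_reactions(net, blocked)
            assert find_blocked_reactions(net2) == set()

    def test_remove_unknown_reaction_rejected(self, linear_chain):
        with pytest.raises(ValidationError):
            remove_reactions(linear_chain, ["ghost"])


# ---------------------------------------------------------------------------
# Partial coupling
# ---------------------------------------------------------------------------

def oracle_partition(network, tol=1e-9):
    """Definitional pairwise partial-coupling test: r ~ s iff v_r = 0
    forces v_s = 0 over C0 and vice versa (4 LPs per pair via range_of)."""
    def forced_zero(r, s):
        lo, hi = _lp.range_of(network, r, cone_box=1.0, fixed_zero=[s])
        return hi <= tol and lo >= -tol

    rids = network.reaction_ids
    classes = []
    for r in rids:
        for cls in classes:
            s = cls[0]
            if forced_zero(r, s) and forced_zero(s, r):
                cls.append(r)
                break
        else:
            classes.append([r])
    return {frozenset(c) for c in classes}


class TestCoupling:
    def test_chain_is_one_class(self, linear_chain):
        part = partial_coupling_classes(linear_chain)
        assert part.as_sets() == {frozenset({"up", "conv", "ex"})}

    def test_parallel_paths_are_separate(self):
        net, _ = fixtures.make_symmetric_toy(2)
        part = partial_coupling_classes(net)
        # uptake and export are partially coupled (sole source and sink);
        # the interchangeable parallel steps are not coupled to anything
        assert part.as_sets() == {
            frozenset({"uptake", "export"}), frozenset({"p1"}),
            frozenset({"p2"})}

    def test_dual_toy_classes(self):
        net, _ = fixtures.make_dual_condition_toy()
        part = partial_coupling_classes(net)
        assert part.as_sets() == {
            frozenset({"EX_o2"}), frozenset({"ox_path1", "ox_path2"}),
            frozenset({"uptake", "conv1"}), frozenset({"conv2"}),
            frozenset({"ox_alt"}), frozenset({"EX_bio"})}

    def test_representative_prefers_irreversible(self):
        # A -> B chain where the middle step is reversible: the class mixes
        # reversibilities and the representative must be irreversible
        net = network_from_dict(
            ["A", "B"],
            {"up": ({"A": 1}, 0, 10),
             "conv": ({"A": -1, "B": 1}, -10, 10),
             "ex": ({"B": -1}, 0, 10)})
        part = partial_coupling_classes(net)
        (cls,) = part.as_sets()
        assert cls == frozenset({"up", "conv", "ex"})
        rep = part.representative[part.class_of["conv"]]
        assert net.irreversible[net.rxn_index(rep)]

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_matches_definitional_oracle(self, seed):
        net = fixtures.random_feasible_network(6, 10, rev_fraction=0.3,
                                               seed=seed)
        blocked = find_blocked_reactions(net)
        if blocked:
            net = remove_reactions(net, blocked)
        assert partial_coupling_classes(net).as_sets() == \
            oracle_partition(net)

    def test_column_order_invariance(self):
        net = fixtures.random_feasible_network(6, 10, rev_fraction=0.3,
                                               seed=5)
        blocked = find_blocked_reactions(net)
        if blocked:
            net = remove_reactions(net, blocked)
        base = partial_coupling_classes(net).as_sets()
        rng = np.random.default_rng(0)
        perm = rng.permutation(net.n_reactions)
        from minnet.model_io import MetabolicNetwork
        shuffled = MetabolicNetwork(
            net.metabolite_ids,
            [net.reaction_ids[j] for j in perm],
            net.S[:, perm], net.l[perm], net.u[perm],
            net.irreversible[perm])
        assert partial_coupling_classes(shuffled).as_sets() == base

    def test_blocked_network_rejected(self):
        net = network_from_dict(
            ["A", "B"],
            {"up": ({"A": 1}, 0, 10),
             "branch": ({"A": -1, "B": 1}, 0, 10),
             "ex": ({"A": -1}, 0, 10)})
        with pytest.raises(ValidationError, match="[Bb]locked"):
            partial_coupling_classes(net)

    def test_partition_invariants(self):
        net, _ = fixtures.make_dual_condition_toy()
        part = partial_coupling_classes(net)
        all_members = [r for c in part.classes for r in c]
        assert sorted(all_members) == sorted(net.reaction_ids)
        for k, rep in part.representative.items():
            assert rep in part.classes[k]
        for rid, k in part.class_of.items():
            assert rid in part.classes[k]


# ---------------------------------------------------------------------------
# preprocess_network and project_scenario
# ---------------------------------------------------------------------------

class TestPreprocessPipeline:
    def test_report_statuses(self):
        net = network_from_dict(
            ["A", "B", "X"],
            {"up": ({"A": 1}, 0, 10),
             "branch": ({"A": -1, "B": 1}, 0, 10),   # blocked (B dead end)
             "lone": ({"X": 1}, 0, 10),              # X produced only
             "ex": ({"A": -1}, 0, 10)})
        report = preprocess_network(net)
        status = report.reaction_status(net)
        assert status["up"] == status["ex"] == "unblocked"
        assert status["lone"] == "dead_end_removed"
        assert status["branch"] in ("blocked", "dead_end_removed")
        assert sorted(report.network.reaction_ids) == ["ex", "up"]

    def test_tsv_output(self, tmp_path, linear_chain):
        report = preprocess_network(linear_chain)
        out = tmp_path / "report.tsv"
        report.write_tsv(out, linear_chain)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("reaction_id\tstatus")
        assert len(lines) == 1 + linear_chain.n_reactions

    def test_determinism(self):
        net = fixtures.random_feasible_network(8, 12, seed=7)
        a = preprocess_network(net)
        b = preprocess_network(net)
        assert a.partition.as_sets() == b.partition.as_sets()
        assert a.blocked_reactions == b.blocked_reactions

    def test_project_scenario_drops_blocked_terms(self):
        net = network_from_dict(
            ["A", "B"],
            {"up": ({"A": 1}, 0, 10),
             "branch": ({"A": -1, "B": 1}, 0, 10),
             "ex": ({"A": -1}, 0, 10)})
        report = preprocess_network(net)
        f = LinearFunctionality.from_rows(
            "f", [({"ex": 1.0, "branch": 2.0}, ">=", 1.0)])
        scen = ReductionScenario(protected_reactions={"ex"},
                                 functionalities=[f])
        proj = project_scenario(scen, report.network)
        (rows,) = [g.rows for g in proj.functionalities]
        assert rows == (((("ex", -1.0),), -1.0),)

    def test_project_scenario_rejects_blocked_protected(self):
        net = network_from_dict(
            ["A", "B"],
            {"up": ({"A": 1}, 0, 10),
             "branch": ({"A": -1, "B": 1}, 0, 10),
             "ex": ({"A": -1}, 0, 10)})
        report = preprocess_network(net)
        scen = ReductionScenario(protected_reactions={"branch"})
        with pytest.raises(ValidationError, match="branch"):
            project_scenario(scen, report.network)
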