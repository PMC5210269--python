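"""Deterministic toy networks, random fixtures, and a brute-force oracle.

The toys reproduce the two classical failure modes of greedy / per-condition
network reduction:

* :func:`make_branch_toy` -- a branch point where pruning reactions in an
  unlucky order yields a 4-reaction subnetwork although a 3-reaction one
  exists (greedy-vs-optimal trap).
* :func:`make_dual_condition_toy` -- an 8-reaction network with aerobic and
  anaerobic growth functionalities whose joint minimum subnetwork (6
  reactions) is strictly smaller than the union of the two per-condition
  minima (7 reactions), because the joint optimum reuses a dual-purpose
  route that neither per-condition optimum touches.

:func:`brute_force_minimum_subnetworks` is the independent oracle: it
enumerates reaction subsets explicitly and decides feasibility with plain
LPs, mirroring the delta-threshold activity semantics of the MILP without
sharing any code path with it.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np

from . import _lp
from .model_io import (LinearFunctionality, MetabolicNetwork,
                       ReductionScenario, resolve_scenario)

__all__ = [
    "make_branch_toy", "make_dual_condition_toy", "make_symmetric_toy",
    "make_dof_toy", "random_feasible_network", "random_scenario",
    "brute_force_minimum_subnetworks",
]


def _network(mets, reactions):
    """Build a network from {rid: (stoich dict, lb, ub)}."""
    rids = list(reactions)
    S = np.zeros((len(mets), len(rids)))
    l = np.zeros(len(rids))
    u = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        stoich, lo, hi = reactions[rid]
        for m, coef in stoich.items():
            S[mets.index(m), j] = coef
        l[j], u[j] = lo, hi
    return MetabolicNetwork(mets, rids, S, l, u)


def _geq(rid, value):
    return ({rid: 1.0}, ">=", value)


# ---------------------------------------------------------------------------
# Toys
# ---------------------------------------------------------------------------

def make_branch_toy() -> tuple[MetabolicNetwork, ReductionScenario]:
    """Uptake -> {direct r1 | two-step r2,r3} -> protected export.

    The unique minimum subnetwork is {uptake, r1, export} (3 reactions); a
    greedy pruning that zeroes r1 first is stuck with the 4-reaction
    alternative {uptake, r2, r3, export}.
    """
    net = _network(
        ["A", "I", "B"],
        {
            "uptake": ({"A": 1}, 0, 10),
            "r1": ({"A": -1, "B": 1}, 0, 10),
            "r2": ({"A": -1, "I": 1}, 0, 10),
            "r3": ({"I": -1, "B": 1}, 0, 10),
            "export": ({"B": -1}, 0, 10),
        })
    scenario = ReductionScenario(protected_reactions={"export"})
    return net, scenario


def make_dual_condition_toy() -> tuple[MetabolicNetwork, ReductionScenario]:
    """Aerobic/anaerobic dual-functionality toy (8 reactions).

    Routes to biomass B: a dedicated 2-step oxygen route
    (ox_path1: O -> D, ox_path2: D -> B), and a 3-step oxygen-free route
    (uptake -> C, conv1: C -> C2, conv2: C2 -> B) with a 1-step
    oxygen-consuming exit (ox_alt: C2 + O -> B).

    Functionalities: biomass export >= 1 with oxygen uptake >= 0.1
    (aerobic), and biomass export >= 1 with oxygen uptake = 0 (anaerobic).
    The per-condition minima are {EX_o2, ox_path1, ox_path2, EX_bio} and
    {uptake, conv1, conv2, EX_bio} (union: 7 reactions); the joint minimum
    replaces the dedicated oxygen route by ox_alt on top of the oxygen-free
    route (6 reactions).  Both conditions on one flux vector are
    contradictory (v_o2 >= 0.1 and v_o2 = 0).
    """
    net = _network(
        ["O", "C", "C2", "D", "B"],
        {
            "EX_o2": ({"O": 1}, 0, 10),
            "ox_path1": ({"O": -1, "D": 1}, 0, 10),
            "ox_path2": ({"D": -1, "B": 1}, 0, 10),
            "uptake": ({"C": 1}, 0, 10),
            "conv1": ({"C": -1, "C2": 1}, 0, 10),
            "conv2": ({"C2": -1, "B": 1}, 0, 10),
            "ox_alt": ({"C2": -1, "O": -1, "B": 1}, 0, 10),
            "EX_bio": ({"B": -1}, 0, 10),
        })
    aerobic = LinearFunctionality.from_rows(
        "aerobic", [_geq("EX_bio", 1.0), _geq("EX_o2", 0.1)])
    anaerobic = LinearFunctionality.from_rows(
        "anaerobic", [_geq("EX_bio", 1.0), ({"EX_o2": 1.0}, "=", 0.0)])
    scenario = ReductionScenario(protected_reactions={"EX_bio"},
                                 functionalities=[aerobic, anaerobic])
    return net, scenario


def make_symmetric_toy(n_paths: int = 3
                       ) -> tuple[MetabolicNetwork, ReductionScenario]:
    """``n_paths`` interchangeable routes A -> B; enumeration must find one
    minimum subnetwork per route."""
    reactions = {"uptake": ({"A": 1}, 0, 10)}
    for k in range(1, n_paths + 1):
        reactions[f"p{k}"] = ({"A": -1, "B": 1}, 0, 10)
    reactions["export"] = ({"B": -1}, 0, 10)
    net = _network(["A", "B"], reactions)
    return net, ReductionScenario(protected_reactions={"export"})


def make_dof_toy() -> tuple[MetabolicNetwork, ReductionScenario]:
    """Two parallel uptakes feeding one protected export.

    With dof_min = 1 the unique minimum is {up1, export} (dof 1); the
    returned scenario demands dof_min = 2, which forces the strictly larger
    {up1, up2, export} (dof 2).
    """
    net = _network(
        ["A"],
        {
            "up1": ({"A": 1}, 0, 10),
            "up2": ({"A": 1}, 0, 10),
            "export": ({"A": -1}, 0, 10),
        })
    scenario = ReductionScenario(protected_reactions={"up1", "export"},
                                 dof_min=2)
    return net, scenario


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

def _components(network: MetabolicNetwork) -> list[set[int]]:
    """Connected components of the metabolite graph induced by reactions."""
    parent = list(range(network.n_metabolites))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(network.n_reactions):
        touched = np.nonzero(network.S[:, j])[0]
        for m in touched[1:]:
            parent[find(m)] = find(touched[0])
    groups: dict[int, set[int]] = {}
    for m in range(network.n_metabolites):
        if np.any(network.S[m] != 0):
            groups.setdefault(find(m), set()).add(m)
    return list(groups.values())


def random_feasible_network(n_met: int, n_rxn: int,
                            rev_fraction: float = 0.25,
                            seed: int = 0) -> MetabolicNetwork:
    """Random sparse integer-stoichiometry network with a guaranteed
    unblocked pathway.

    The first reactions form a deterministic uptake -> chain -> export
    spine (always unblocked); the rest are random conversions or
    exchanges.  Every connected metabolite component ends up with at least
    one exchange.  Bounds are 0/±10; a reaction is reversible with
    probability ``rev_fraction``.
    """
    if not (1 <= n_met <= n_rxn):
        raise ValueError("need n_rxn >= n_met >= 1")
    rng = np.random.default_rng(seed)
    k = min(n_met, 3)
    n_spine = k + 1
    if n_rxn < n_spine:
        raise ValueError(f"need at least {n_spine} reactions for the spine")

    S = np.zeros((n_met, n_rxn))
    S[0, 0] = 1.0                                   # uptake -> M0
    for i in range(1, k):
        S[i - 1, i], S[i, i] = -1.0, 1.0            # chain M(i-1) -> Mi
    S[k - 1, k] = -1.0                              # export M(k-1) ->

    for j in range(n_spine, n_rxn):
        if rng.random() < 0.25:
            S[rng.integers(n_met), j] = rng.choice([-1.0, 1.0])
            continue
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        mets = rng.choice(n_met, size=min(n_sub + n_prod, n_met),
                          replace=False)
        for m in mets[:n_sub]:
            S[m, j] = -float(rng.integers(1, 3))
        for m in mets[n_sub:]:
            S[m, j] = float(rng.integers(1, 3))

    # give every connected component an exchange (single-entry column)
    for _ in range(10):
        exch_mets = {int(np.nonzero(S[:, j])[0][0])
                     for j in range(n_rxn)
                     if np.count_nonzero(S[:, j]) == 1}
        net_tmp = MetabolicNetwork([f"M{i}" for i in range(n_met)],
                                   [f"R{j}" for j in range(n_rxn)],
                                   S, np.zeros(n_rxn), np.full(n_rxn, 10.0))
        missing = [comp for comp in _components(net_tmp)
                   if not (comp & exch_mets)]
        if not missing:
            break
        for comp in missing:
            candidates = [j for j in range(n_spine, n_rxn)
                          if np.count_nonzero(S[:, j]) > 1
                          and set(np.nonzero(S[:, j])[0]) <= comp]
            m = int(rng.choice(sorted(comp)))
            j = int(rng.choice(candidates)) if candidates \
                else int(rng.integers(n_spine, n_rxn))
            S[:, j] = 0.0
            S[m, j] = -1.0

    rev = rng.random(n_rxn) < rev_fraction
    l = np.where(rev, -10.0, 0.0)
    u = np.full(n_rxn, 10.0)
    return MetabolicNetwork([f"M{i}" for i in range(n_met)],
                            [f"R{j}" for j in range(n_rxn)], S, l, u)


def random_scenario(network: MetabolicNetwork, seed: int = 0,
                    n_functionalities: int = 2,
                    delta: float = 1e-04) -> ReductionScenario:
    """Random feasible reduction scenario for a generated network.

    Functionality targets are drawn from reactions whose maximal forward
    flux is at least 1; thresholds at half that maximum (capped at 1) keep
    each functionality LP-feasible.  The second functionality may pin an
    unrelated reaction to zero when that remains feasible.  One target is
    protected; with probability 1/2 one of its metabolites is protected too.
    """
    rng = np.random.default_rng(seed)
    maxima = {}
    for rid in network.reaction_ids:
        res = _lp.flux_lp(network, objective={rid: 1.0}, sense="max")
        if res.ok and res.objective >= 1.0:
            maxima[rid] = res.objective
    if not maxima:
        raise ValueError("network has no reaction with forward flux >= 1")
    targets = sorted(maxima)

    funcs = []
    used = []
    for fi in range(n_functionalities):
        rid = targets[int(rng.integers(len(targets)))]
        threshold = min(1.0, 0.5 * maxima[rid])
        rows = [_geq(rid, threshold)]
        if fi > 0 and rng.random() < 0.5:
            for _ in range(5):
                q = network.reaction_ids[int(rng.integers(network.n_reactions))]
                if q == rid:
                    continue
                trial = rows + [({q: 1.0}, "=", 0.0)]
                canon = LinearFunctionality.from_rows("trial", trial)
                if _lp.flux_lp(network, leq_rows=canon.rows).ok:
                    rows = trial
                    break
        funcs.append(LinearFunctionality.from_rows(f"f{fi + 1}", rows))
        used.append(rid)

    protected_rxn = used[0]
    protected_mets: set[str] = set()
    if rng.random() < 0.5:
        touched = [m for m in network.metabolite_ids
                   if network.S[network.met_index(m),
                                network.rxn_index(protected_rxn)] != 0]
        if touched:
            protected_mets.add(touched[int(rng.integers(len(touched)))])
    return ReductionScenario(
        protected_metabolites=protected_mets,
        protected_reactions={protected_rxn},
        functionalities=funcs, delta=delta)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _copy_rows(scenario, j):
    """Canonical <= rows of copy j (empty for the protected copy 0)."""
    return scenario.functionalities[j - 1].rows if j >= 1 else ()


def _protected_requirements(network, scenario, active):
    """Per-reaction activity demands of copy 0: list of (rid, signs).

    Protected reactions must carry |v| >= delta; each uncovered protected
    metabolite needs at least one touching reaction doing so.  Returns
    ``None`` when a demand cannot be met within ``active``.
    """
    demands = []
    for rid in sorted(scenario.protected_reactions):
        if rid not in active:
            return None
        signs = [+1] if network.irreversible[network.rxn_index(rid)] \
            else [+1, -1]
        demands.append([(rid, s) for s in signs])
    for m in sorted(scenario.protected_metabolites):
        touching = set(network.reactions_of_metabolite(m))
        if touching & scenario.protected_reactions:
            continue
        options = []
        for rid in sorted(touching & active):
            signs = [+1] if network.irreversible[network.rxn_index(rid)] \
                else [+1, -1]
            options.extend((rid, s) for s in signs)
        if not options:
            return None
        demands.append(options)
    return demands


def _witness(network, rows, zeros, forced, delta):
    """LP feasibility with sign-directed activity demands ``(rid, sign)``."""
    bounds = {}
    for rid, sign in forced:
        lo, hi = bounds.get(rid, (-math.inf, math.inf))
        if sign > 0:
            bounds[rid] = (max(lo, delta), hi)
        else:
            bounds[rid] = (lo, min(hi, -delta))
    return _lp.flux_lp(network, leq_rows=rows, fixed_zero=zeros,
                       extra_bounds=bounds)


def _copy0_witness(network, scenario, active, zeros, delta):
    """A copy-0 witness meeting all protected demands, or ``None``."""
    demands = _protected_requirements(network, scenario, active)
    if demands is None:
        return None
    for combo in itertools.product(*demands) if demands else [()]:
        res = _witness(network, (), zeros, combo, delta)
        if res.ok:
            return res.x, combo
    return None


class _CopyState:
    """Achievability bookkeeping for one flux copy within one active set."""

    def __init__(self, network, rows, zeros, base_x, base_forced, delta):
        self.network = network
        self.rows = rows
        self.zeros = zeros
        self.delta = delta
        self.forced = list(base_forced)  # demands that must always hold
        self.sign: dict[str, int] = {}
        self.required: list = []
        tol = delta * (1 - 1e-9)
        for j, rid in enumerate(network.reaction_ids):
            if abs(base_x[j]) >= tol:
                self.sign[rid] = 1 if base_x[j] > 0 else -1

    def achievable(self, rid) -> bool:
        if rid in self.sign:
            return True
        tol = self.delta * (1 - 1e-9)
        res = _lp.flux_lp(self.network, objective={rid: 1.0}, sense="max",
                          leq_rows=self.rows, fixed_zero=self.zeros)
        if res.ok and res.objective >= tol:
            self._absorb(res.x)
            self.sign.setdefault(rid, 1)
            return True
        if not self.network.irreversible[self.network.rxn_index(rid)]:
            res = _lp.flux_lp(self.network, objective={rid: 1.0}, sense="min",
                              leq_rows=self.rows, fixed_zero=self.zeros)
            if res.ok and res.objective <= -tol:
                self._absorb(res.x)
                self.sign.setdefault(rid, -1)
                return True
        return False

    def _absorb(self, x) -> None:
        tol = self.delta * (1 - 1e-9)
        for j, rid in enumerate(self.network.reaction_ids):
            if rid not in self.sign and abs(x[j]) >= tol:
                self.sign[rid] = 1 if x[j] > 0 else -1

    def joint_ok(self, extra=()) -> bool:
        demands = list(self.forced)
        demands += [(rid, self.sign[rid]) for rid in self.required]
        demands += list(extra)
        return _witness(self.network, self.rows, self.zeros, demands,
                        self.delta).ok


def _feasible_active_set(network, scenario, active, delta) -> bool:
    """Does ``active`` support witnesses for copy 0 and every functionality,
    with every member delta-active on at least one copy?"""
    zeros = [rid for rid in network.reaction_ids if rid not in active]

    base = _copy0_witness(network, scenario, active, zeros, delta)
    if base is None:
        return False
    x0, combo0 = base
    copies = [_CopyState(network, (), zeros, x0, combo0, delta)]
    for j in range(1, len(scenario.functionalities) + 1):
        rows = _copy_rows(scenario, j)
        res = _lp.flux_lp(network, leq_rows=rows, fixed_zero=zeros)
        if not res.ok:
            return False
        copies.append(_CopyState(network, rows, zeros, res.x, (), delta))

    cover: dict[str, list[int]] = {}
    for rid in sorted(active):
        cover[rid] = [k for k, st in enumerate(copies) if st.achievable(rid)]
        if not cover[rid]:
            return False

    # joint confirmation: maximal assignment first, then exclusive demands
    # plus greedy completion
    for k, st in enumerate(copies):
        st.required = [rid for rid in sorted(active) if k in cover[rid]]
    if all(st.joint_ok() for st in copies):
        return True
    for k, st in enumerate(copies):
        st.required = [rid for rid in sorted(active) if cover[rid] == [k]]
        if not st.joint_ok():
            return False
    for rid in sorted(active):
        if len(cover[rid]) == 1:
            continue
        placed = False
        for k in cover[rid]:
            st = copies[k]
            if st.joint_ok(extra=[(rid, st.sign[rid])]):
                st.required.append(rid)
                placed = True
                break
        if not placed:
            return False
    return True


def _necessary_reactions(network, scenario, candidates, delta):
    """Reactions whose removal alone breaks some copy: subset of every
    feasible active set."""
    necessary = set(scenario.protected_reactions)
    for rid in sorted(candidates - necessary):
        for j in range(1, len(scenario.functionalities) + 1):
            if not _lp.flux_lp(network, leq_rows=_copy_rows(scenario, j),
                               fixed_zero=[rid]).ok:
                necessary.add(rid)
                break
        else:
            if scenario.protected_metabolites or scenario.protected_reactions:
                if _copy0_witness(network, scenario,
                                  set(network.reaction_ids) - {rid},
                                  [rid], delta) is None:
                    necessary.add(rid)
    return necessary


def brute_force_minimum_subnetworks(network: MetabolicNetwork,
                                    scenario: ReductionScenario,
                                    dof_min: Optional[int] = None,
                                    ) -> list[frozenset]:
    """All minimum feasible active sets, by explicit subset enumeration.

    A subset is feasible when copy-0 (protected sets) and every
    functionality copy admit an LP witness vanishing outside the subset,
    and every member reaction can carry ``|v| >= delta`` on some copy
    (confirmed by joint witnesses).  Subsets whose stoichiometric degrees
    of freedom fall below ``dof_min`` (default: the scenario's) are skipped
    and the search continues at larger sizes, mirroring the dof-filtered
    enumeration semantics.  Returns ``[]`` for an infeasible scenario
    (distinguishable from a feasible scenario whose minimum is the whole
    network).
    """
    if network.n_reactions > 16:
        raise ValueError("brute force is guarded to networks of <= 16 reactions")
    scenario = resolve_scenario(network, scenario)
    if dof_min is None:
        dof_min = scenario.dof_min
    delta = scenario.delta

    # candidates: reactions delta-achievable on at least one copy of the
    # full network (achievability only shrinks as reactions are removed)
    candidates = set()
    for j in range(len(scenario.functionalities) + 1):
        rows = _copy_rows(scenario, j)
        res = _lp.flux_lp(network, leq_rows=rows)
        if not res.ok:
            return []
        state = _CopyState(network, rows, [], res.x, (), delta)
        for rid in network.reaction_ids:
            if state.achievable(rid):
                candidates.add(rid)
    if not scenario.protected_reactions <= candidates:
        return []

    necessary = _necessary_reactions(network, scenario, candidates, delta)
    if not necessary <= candidates:
        return []
    free = sorted(candidates - necessary)

    from .enumeration import degrees_of_freedom

    for extra in range(len(free) + 1):
        k = len(necessary) + extra
        if k == 0:
            continue
        found = []
        for combo in itertools.combinations(free, extra):
            active = frozenset(necessary) | frozenset(combo)
            if _feasible_active_set(network, scenario, active, delta):
                found.append(active)
        if dof_min and found:
            found = [a for a in found
                     if degrees_of_freedom(network, a) >= dof_min]
        if found:
            return sorted(found, key=sorted)
    return []
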