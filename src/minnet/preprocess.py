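"""Network preprocessing: dead ends, blocked reactions, coupling classes.

Blockedness and partial coupling are defined over the sign-constrained cone

    C0 = { v | S v = 0,  v_i >= 0 for irreversible i },

*not* over the bounded flux space: the finite bounds ``l, u`` enter only the
MILP.  A reaction ``r`` is blocked iff ``v_r = 0`` for all ``v in C0``; two
unblocked reactions are partially coupled (``r <=> s``) iff
``v_r = 0 <=> v_s = 0`` for all ``v in C0``.  Partial coupling is an
equivalence relation; its classes behave like all-or-nothing reaction groups
(compare enzyme subsets) and let the MILP use one binary variable per class
instead of one per reaction.

Because ``C0`` is a cone, all LP tests here box it into ``[-1, 1]`` without
changing which fluxes can be nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.linalg import null_space

from . import _lp
from .model_io import MetabolicNetwork, ValidationError

__all__ = [
    "CouplingPartition",
    "find_dead_end_metabolites",
    "dead_end_reduction",
    "find_blocked_reactions",
    "remove_reactions",
    "partial_coupling_classes",
    "preprocess_network",
    "project_scenario",
    "PreprocessReport",
]

LP_TOL = 1e-09


# ---------------------------------------------------------------------------
# Dead-end metabolites
# ---------------------------------------------------------------------------

def _dead_end_pass(S: np.ndarray, irrev: np.ndarray,
                   mets: np.ndarray, rxns: np.ndarray) -> np.ndarray:
    """Metabolite indices (within ``mets``) lacking a producer or a consumer."""
    sub = S[np.ix_(mets, rxns)]
    rev = ~irrev[rxns]
    producers = (sub > 0) | ((sub != 0) & rev)
    consumers = (sub < 0) | ((sub != 0) & rev)
    return np.nonzero(~(producers.any(axis=1) & consumers.any(axis=1)))[0]


def find_dead_end_metabolites(network: MetabolicNetwork) -> set[str]:
    """Metabolites that can only ever be produced or only ever consumed.

    A reversible reaction counts as both producer and consumer.  The
    computation iterates to a fixed point: a dead-end metabolite and every
    reaction touching it are removed, which may create new dead ends.
    """
    return dead_end_reduction(network)[1]


def dead_end_reduction(network: MetabolicNetwork
                       ) -> tuple[Optional[MetabolicNetwork], set[str], set[str]]:
    """Fixed-point removal of dead-end metabolites and their reactions.

    Returns ``(reduced_network, dead_metabolites, removed_reactions)``;
    ``reduced_network`` is ``None`` when the cascade removes every reaction.
    """
    mets = np.arange(network.n_metabolites)
    rxns = np.arange(network.n_reactions)
    dead_mets: list[int] = []
    while mets.size:
        local = _dead_end_pass(network.S, network.irreversible, mets, rxns)
        if local.size == 0:
            break
        # metabolites with no reaction at all are orphans, not dead ends
        touched = np.any(network.S[np.ix_(mets[local], rxns)] != 0, axis=1)
        dead = mets[local[touched]]
        if dead.size == 0:
            mets = np.delete(mets, local)
            continue
        dead_mets.extend(dead.tolist())
        gone = np.any(network.S[np.ix_(dead, rxns)] != 0, axis=0)
        rxns = rxns[~gone]
        mets = np.setdiff1d(mets, dead)
    dead_ids = {network.metabolite_ids[i] for i in dead_mets}
    removed = set(network.reaction_ids) - {network.reaction_ids[j] for j in rxns}
    if removed == set(network.reaction_ids):
        return None, dead_ids, removed  # every reaction cascades away
    reduced = remove_reactions(network, removed) if removed else network.copy()
    return reduced, dead_ids, removed


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------

def find_blocked_reactions(network: MetabolicNetwork,
                           tol: float = LP_TOL) -> set[str]:
    """Reactions with ``v_r = 0`` for every ``v`` in the cone ``C0``.

    Tests ``max v_r <= tol`` and ``min v_r >= -tol`` over ``C0`` boxed into
    ``[-1, 1]``; every LP solution encountered on the way serves as a
    nonzero-flux witness for all reactions it activates.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    unblocked = np.zeros(network.n_reactions, dtype=bool)
    blocked: set[str] = set()
    for j, rid in enumerate(network.reaction_ids):
        if unblocked[j]:
            continue
        res = _lp.flux_lp(network, objective={rid: 1.0}, sense="max",
                          cone_box=1.0)
        if not res.ok:
            raise RuntimeError(
                f"LP failure while testing blockedness of {rid!r}: {res.status}")
        unblocked |= np.abs(res.x) > tol
        if res.objective > tol:
            continue
        res = _lp.flux_lp(network, objective={rid: 1.0}, sense="min",
                          cone_box=1.0)
        if not res.ok:
            raise RuntimeError(
                f"LP failure while testing blockedness of {rid!r}: {res.status}")
        unblocked |= np.abs(res.x) > tol
        if res.objective < -tol:
            continue
        blocked.add(rid)
    return blocked


def remove_reactions(network: MetabolicNetwork,
                     rxns: Iterable[str]) -> MetabolicNetwork:
    """Drop the given reaction columns; all-zero metabolite rows go too."""
    rxns = set(rxns)
    unknown = rxns - set(network.reaction_ids)
    if unknown:
        raise ValidationError(f"unknown reactions: {sorted(unknown)}")
    keep = [r for r in network.reaction_ids if r not in rxns]
    if not keep:
        raise ValidationError("removing all reactions leaves an empty network")
    if not rxns:
        return network.copy()
    return network.subnetwork(keep)


# ---------------------------------------------------------------------------
# Partial coupling
# ---------------------------------------------------------------------------

@dataclass
class CouplingPartition:
    """Partition of the (unblocked) reactions into partial-coupling classes.

    ``representative`` maps each class index to one member; when a class
    mixes reversibilities the representative is chosen irreversible, so the
    class gets sign-split binaries in the MILP only if even its most
    constrained member is reversible.
    """

    classes: list[frozenset[str]]
    representative: dict[int, str]
    class_size: dict[int, int]
    class_of: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for k, cls in enumerate(self.classes):
            if self.representative[k] not in cls:
                raise ValidationError(
                    f"representative {self.representative[k]!r} not in class {k}")
            if self.class_size[k] != len(cls):
                raise ValidationError(f"class_size mismatch for class {k}")
            if seen & cls:
                raise ValidationError("classes are not disjoint")
            seen |= cls
        for rid, k in self.class_of.items():
            if rid not in self.classes[k]:
                raise ValidationError(f"class_of[{rid!r}] inconsistent")
        if len(self.class_of) != len(seen):
            raise ValidationError("class_of does not cover the partition")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.classes)

    @classmethod
    def singletons(cls, network: MetabolicNetwork) -> "CouplingPartition":
        ids = list(network.reaction_ids)
        return cls([frozenset([r]) for r in ids],
                   {k: r for k, r in enumerate(ids)},
                   {k: 1 for k in range(len(ids))},
                   {r: k for k, r in enumerate(ids)})


def _nullspace_seed(network: MetabolicNetwork, tol: float) -> list[list[int]]:
    """Group reactions whose nullspace-basis rows are proportional.

    If the kernel rows of two reactions are proportional with nonzero ratio,
    then ``v_r = lambda v_s`` on the whole nullspace, hence on ``C0``; such
    reactions are partially coupled and can be merged without any LP.
    """
    N = null_space(network.S)
    if N.size == 0:
        # rank-complete S: every reaction blocked; precondition excludes this
        return [[j] for j in range(network.n_reactions)]
    groups: dict[tuple, list[int]] = {}
    for j in range(network.n_reactions):
        row = N[j]
        norm = np.linalg.norm(row)
        if norm <= tol:
            groups[("zero", j)] = [j]  # C0-blocked; caller rejects earlier
            continue
        d = row / norm
        lead = np.nonzero(np.abs(d) > 1e-08)[0][0]
        if d[lead] < 0:
            d = -d
        key = tuple(np.round(d, 8))
        groups.setdefault(key, []).append(j)
    return list(groups.values())


def _forced_zero_given(network: MetabolicNetwork, r: str, s: str,
                       tol: float) -> bool:
    """True iff ``v_s = 0`` forces ``v_r = 0`` over C0."""
    lo, hi = _lp.range_of(network, r, cone_box=1.0, fixed_zero=[s])
    return hi <= tol and lo >= -tol


def partial_coupling_classes(network: MetabolicNetwork,
                             tol: float = LP_TOL) -> CouplingPartition:
    """Partition the reactions of a blocked-free network by partial coupling.

    Strategy: proportional rows of a nullspace basis of ``S`` seed classes
    (sound merges, no LPs); remaining class pairs are tested definitionally
    with LPs over ``C0`` (``v_r`` forced to zero by ``v_s = 0`` and vice
    versa), with transitivity pruning through a union-find.
    """
    blocked = find_blocked_reactions(network, tol=max(tol, LP_TOL))
    if blocked:
        raise ValidationError(
            f"network contains blocked reactions (e.g. {sorted(blocked)[:3]}); "
            f"remove them before computing coupling classes")

    seeds = _nullspace_seed(network, tol)
    parent = list(range(len(seeds)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rids = network.reaction_ids
    for i in range(len(seeds)):
        for k in range(i + 1, len(seeds)):
            if find(i) == find(k):
                continue
            r, s = rids[seeds[i][0]], rids[seeds[k][0]]
            if _forced_zero_given(network, r, s, tol) and \
               _forced_zero_given(network, s, r, tol):
                parent[find(k)] = find(i)

    merged: dict[int, list[int]] = {}
    for i, seed in enumerate(seeds):
        merged.setdefault(find(i), []).extend(seed)

    classes, representative, class_size, class_of = [], {}, {}, {}
    for members in sorted(merged.values(), key=min):
        k = len(classes)
        member_ids = [rids[j] for j in sorted(members)]
        irrev = [rid for rid in member_ids
                 if network.irreversible[network.rxn_index(rid)]]
        representative[k] = irrev[0] if irrev else member_ids[0]
        classes.append(frozenset(member_ids))
        class_size[k] = len(member_ids)
        for rid in member_ids:
            class_of[rid] = k
    return CouplingPartition(classes, representative, class_size, class_of)


# ---------------------------------------------------------------------------
# One-shot preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessReport:
    network: MetabolicNetwork
    dead_end_metabolites: set[str]
    dead_end_reactions: set[str]
    blocked_reactions: set[str]
    partition: Optional[CouplingPartition]

    def reaction_status(self, original: MetabolicNetwork) -> dict[str, str]:
        out = {}
        for rid in original.reaction_ids:
            if rid in self.dead_end_reactions:
                out[rid] = "dead_end_removed"
            elif rid in self.blocked_reactions:
                out[rid] = "blocked"
            else:
                out[rid] = "unblocked"
        return out

    def write_tsv(self, path, original: MetabolicNetwork) -> None:
        status = self.reaction_status(original)
        lines = ["reaction_id\tstatus\tclass_index\tis_representative"]
        for rid in original.reaction_ids:
            if self.partition is not None and rid in self.partition.class_of:
                k = self.partition.class_of[rid]
                rep = int(self.partition.representative[k] == rid)
                lines.append(f"{rid}\t{status[rid]}\t{k}\t{rep}")
            else:
                lines.append(f"{rid}\t{status[rid]}\t\t")
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


def preprocess_network(network: MetabolicNetwork, tol: float = LP_TOL,
                       with_partition: bool = True) -> PreprocessReport:
    """Remove dead ends and blocked reactions, optionally compute classes.

    Dead-end removal runs first purely as a speed heuristic; the final
    unblocked set is identical with or without it, since reactions touching
    a dead-end metabolite are blocked in ``C0``.
    """
    reduced, dead_mets, dead_rxns = dead_end_reduction(network)
    if reduced is None:
        raise ValidationError(
            "dead-end removal eliminates every reaction; the network "
            "supports no steady-state flux")
    blocked = find_blocked_reactions(reduced, tol=tol)
    if blocked:
        reduced = remove_reactions(reduced, blocked)
    partition = partial_coupling_classes(reduced, tol=tol) \
        if with_partition else None
    return PreprocessReport(reduced, dead_mets, dead_rxns, blocked, partition)


def project_scenario(scenario, network: MetabolicNetwork):
    """Restrict a scenario to a preprocessed (reduced) network.

    Reactions removed by preprocessing are blocked, i.e. carry zero flux in
    every steady state of the original network, so dropping their terms
    from functionality rows changes nothing.  A protected reaction or
    metabolite that was removed is unsatisfiable and raises
    :class:`~minnet.model_io.ValidationError`.
    """
    import dataclasses

    kept_rxns = set(network.reaction_ids)
    kept_mets = set(network.metabolite_ids)
    missing = scenario.protected_reactions - kept_rxns
    if missing:
        raise ValidationError(
            f"protected reactions are blocked or removed: {sorted(missing)}")
    missing = scenario.protected_metabolites - kept_mets
    if missing:
        raise ValidationError(
            f"protected metabolites have only blocked reactions: "
            f"{sorted(missing)}")
    funcs = []
    for f in scenario.functionalities:
        if not f.resolved:
            raise ValidationError(
                f"functionality {f.label!r} must be resolved (on the "
                f"original network) before projection")
        rows = []
        for coeffs, rhs in f.rows:
            kept = tuple((rid, c) for rid, c in coeffs if rid in kept_rxns)
            if kept:
                rows.append((kept, rhs))
            elif rhs < 0:
                raise ValidationError(
                    f"functionality {f.label!r} demands flux through "
                    f"blocked reactions only")
        if rows:  # a functionality with only vacuous rows imposes nothing
            funcs.append(dataclasses.replace(f, rows=tuple(rows)))
    return dataclasses.replace(scenario, functionalities=funcs)
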