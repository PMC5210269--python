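"""Supporting analyses: FVA, objective maxima, essential reactions, and
comparison statistics across enumerated minimum subnetworks.

A reaction is *essential* for an objective (typically biomass) when fixing
its flux to zero drops the maximal objective below p% of the unconstrained
optimum (p = 20 by default).  Every reaction essential at level p belongs
to every minimum subnetwork whose scenario demands at least p% of the
optimum -- a useful sanity check on enumeration results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import _lp
from .enumeration import EnumerationResult
from .model_io import MetabolicNetwork

__all__ = ["fva", "max_objective", "essential_reactions",
           "compare_subnetworks", "ComparisonReport"]

_TOL = 1e-06


def fva(network: MetabolicNetwork, extra_constraints: _lp.Rows = (),
        reactions: Optional[Sequence[str]] = None) -> dict:
    """Flux variability analysis: per-reaction (min, max) over the flux
    space intersected with ``extra_constraints`` (canonical <= rows)."""
    probe = _lp.flux_lp(network, leq_rows=extra_constraints)
    if not probe.ok:
        raise RuntimeError(f"FVA base LP is {probe.status}")
    out = {}
    for rid in (reactions if reactions is not None else network.reaction_ids):
        out[rid] = _lp.range_of(network, rid, leq_rows=extra_constraints)
    return out


def max_objective(network: MetabolicNetwork, objective_reaction: str,
                  fixing_rows: _lp.Rows = ()) -> float:
    """LP maximum of ``v_obj`` over the flux space plus fixing rows."""
    res = _lp.flux_lp(network, objective={objective_reaction: 1.0},
                      sense="max", leq_rows=fixing_rows)
    if res.status == "unbounded":
        raise RuntimeError(f"max v_{objective_reaction} is unbounded")
    if not res.ok:
        raise RuntimeError(f"max v_{objective_reaction} LP is {res.status}")
    return res.objective


def essential_reactions(network: MetabolicNetwork, objective_reaction: str,
                        p: float = 20.0, fixing_rows: _lp.Rows = ()) -> set:
    """Reactions whose knockout drops the objective below p% of optimum.

    Knockout is modelled as ``v_i = 0`` (equivalent to deleting the column,
    but cheaper).  A knockout that makes the LP infeasible is essential.
    """
    opt = max_objective(network, objective_reaction, fixing_rows)
    if opt <= _TOL:
        raise ValueError(
            f"maximal {objective_reaction} flux is {opt:g}; essentiality "
            f"is undefined for a zero optimum")
    threshold = (p / 100.0) * opt
    essential = set()
    for rid in network.reaction_ids:
        res = _lp.flux_lp(network, objective={objective_reaction: 1.0},
                          sense="max", leq_rows=fixing_rows, fixed_zero=[rid])
        if (not res.ok) or res.objective < threshold - _TOL:
            essential.add(rid)
    return essential


@dataclass
class ComparisonReport:
    """Distribution of reactions across enumerated minimum subnetworks."""

    n_solutions: int
    core: frozenset
    union: frozenset
    occurrence_counts: dict            # rid -> number of subnetworks
    membership: dict                   # rid -> tuple of 0/1 per solution
    mutually_exclusive_pairs: list = field(default_factory=list)
    always_together_pairs: list = field(default_factory=list)

    def write_tsv(self, path) -> None:
        cols = "\t".join(f"snw_{k + 1}" for k in range(self.n_solutions))
        lines = [f"reaction_id\toccurrence_count\tis_core\t{cols}"]
        for rid in sorted(self.union):
            row = "\t".join(str(b) for b in self.membership[rid])
            lines.append(f"{rid}\t{self.occurrence_counts[rid]}"
                         f"\t{int(rid in self.core)}\t{row}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_pairs_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "mutually_exclusive": [sorted(p) for p in
                                   self.mutually_exclusive_pairs],
            "always_together": [sorted(p) for p in
                                self.always_together_pairs],
        }, indent=2) + "\n")


def compare_subnetworks(result: EnumerationResult) -> ComparisonReport:
    """Core/union sets, occurrence counts and co-occurrence pair patterns.

    Mutually exclusive pairs never share a subnetwork (disjoint occurrence
    sets); always-together pairs have identical occurrence sets.  Both are
    reported for non-core reactions only, by exact occurrence-set
    comparison -- no statistical association measure is involved.
    """
    if not result.solutions:
        raise ValueError("comparison needs at least one solution")
    sets = [s.active for s in result.solutions]
    union = result.union_reactions
    core = result.core_reactions
    occ_sets = {rid: frozenset(k for k, s in enumerate(sets) if rid in s)
                for rid in union}
    counts = {rid: len(occ_sets[rid]) for rid in union}
    membership = {rid: tuple(int(rid in s) for s in sets) for rid in union}

    variable = sorted(union - core)
    exclusive, together = [], []
    for i, r in enumerate(variable):
        for s in variable[i + 1:]:
            if not occ_sets[r] & occ_sets[s]:
                exclusive.append((r, s))
            elif occ_sets[r] == occ_sets[s]:
                together.append((r, s))
    return ComparisonReport(len(sets), core, union, counts, membership,
                            exclusive, together)
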