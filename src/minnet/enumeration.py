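"""Minimum subnetworks: dof filtering and exhaustive enumeration.

A single MILP solve yields one minimum subnetwork satisfying the protected
sets and functionalities.  Two loops are layered on top of it, both driven
by integer cuts (exclusion constraints): re-solving until the subnetwork
meets the minimum degrees-of-freedom requirement, and enumerating *all*
minimum subnetworks.  A cut forbids exactly one 0/1 activity pattern

    sum_{i: Z_i = 0} a_i  +  sum_{i: Z_i = 1} (1 - a_i)  >=  1,

i.e. at least one previously inactive reaction becomes active or one
previously active reaction becomes inactive.  Cuts act in whatever binary
space the problem uses (reactions for minNW, coupling classes for
minNW_rep); since active sets are unions of coupling classes, class-level
cuts separate exactly the same solution families.

Enumeration stops, with ``exhausted=True``, as soon as the post-cut optimum
strictly exceeds the minimum size or the problem becomes infeasible: cuts
only remove already-found patterns, so a larger optimum proves completeness.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import milp
from .backends import get_backend
from .milp import (InfeasibleScenarioError, LinearRow, MilpProblem,
                   SubnetworkSolution)
from .model_io import MetabolicNetwork, ReductionScenario
from .preprocess import CouplingPartition, partial_coupling_classes

__all__ = [
    "EnumerationResult", "DofUnsatisfiableError",
    "degrees_of_freedom", "exclusion_constraint",
    "minimum_subnetwork", "enumerate_all",
]


class DofUnsatisfiableError(RuntimeError):
    """No subnetwork satisfies the degrees-of-freedom requirement."""

    def __init__(self, message: str, rejected: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.rejected = rejected


# ---------------------------------------------------------------------------
# Degrees of freedom
# ---------------------------------------------------------------------------

def degrees_of_freedom(network: MetabolicNetwork,
                       active: Iterable[str]) -> int:
    """Nullspace dimension of S restricted to the active reactions.

    dof = |active| - rank(S[:, active]); rows of untouched metabolites are
    zero and do not affect the rank.
    """
    active = list(active)
    if not active:
        raise ValueError("dof of an empty reaction set is undefined")
    sub = network.submatrix(active)
    return len(active) - int(np.linalg.matrix_rank(sub))


# ---------------------------------------------------------------------------
# Integer cuts
# ---------------------------------------------------------------------------

def exclusion_constraint(problem: MilpProblem,
                         solution: SubnetworkSolution) -> LinearRow:
    """Append a cut forbidding the solution's activity pattern; return it."""
    if solution.binary_space != problem.binary_space:
        raise ValueError(
            f"cannot cut a {solution.binary_space}-space solution in a "
            f"{problem.binary_space}-space problem")
    if not problem.aggregated:
        raise ValueError(
            "exclusion cuts need aggregated activity binaries "
            "(minNW / minNW_rep formulations)")
    unknown = solution.active_pattern - set(problem.binary_keys)
    if unknown:
        raise ValueError(f"pattern keys outside problem: {sorted(unknown)[:3]}")
    coeffs, lb = {}, 1.0
    for key in problem.binary_keys:
        if key in solution.active_pattern:
            coeffs[problem.aggregated[key]] = -1.0
            lb -= 1.0
        else:
            coeffs[problem.aggregated[key]] = 1.0
    row = LinearRow(f"cut[{len(problem.rows)}]", coeffs, lb=lb)
    problem.rows.append(row)
    return row


# ---------------------------------------------------------------------------
# Solve sessions
# ---------------------------------------------------------------------------

class _Session:
    """One encoded problem on one backend, supporting incremental cuts."""

    def __init__(self, network, scenario, use_representatives,
                 backend, partition):
        self.network = network
        self.scenario = scenario
        if use_representatives:
            if partition is None:
                partition = partial_coupling_classes(network)
            self.problem = milp.build_minnw_rep(network, scenario, partition)
        else:
            self.problem = milp.build_minnw(network, scenario)
        self.backend = get_backend(backend)
        self.backend.load(milp.encode(self.problem))

    def solve(self, time_limit=None) -> SubnetworkSolution:
        status = self.backend.solve(time_limit)
        if status == "infeasible":
            raise InfeasibleScenarioError(
                "no subnetwork satisfies the remaining requirements")
        if status in ("timeout", "failed"):
            from .backends import SolverError
            raise SolverError(f"solver status {status!r}")
        sol = milp._extract(self.problem, self.backend.values(), status)
        sol.dof = degrees_of_freedom(self.network, sol.active) \
            if sol.active else 0
        return sol

    def exclude(self, solution: SubnetworkSolution) -> None:
        row = exclusion_constraint(self.problem, solution)
        self.backend.add_row(row)


# ---------------------------------------------------------------------------
# Public drivers
# ---------------------------------------------------------------------------

def minimum_subnetwork(network: MetabolicNetwork,
                       scenario: ReductionScenario,
                       use_representatives: bool = False,
                       backend="glpk", time_limit: Optional[float] = None,
                       partition: Optional[CouplingPartition] = None,
                       ) -> SubnetworkSolution:
    """Smallest subnetwork meeting all requirements, dof included.

    Solves the MILP, checks ``dof >= dof_min``, and on failure excludes the
    subnetwork with a cut and re-solves; the returned solution may therefore
    be larger than the unfiltered optimum.
    """
    session = _Session(network, scenario, use_representatives, backend,
                       partition)
    deadline = time.monotonic() + time_limit if time_limit else None
    rejected = []
    while True:
        remaining = deadline - time.monotonic() if deadline else None
        try:
            sol = session.solve(remaining)
        except InfeasibleScenarioError:
            if not rejected:
                raise
            raise DofUnsatisfiableError(
                f"no subnetwork reaches dof >= {scenario.dof_min} "
                f"({len(rejected)} smaller subnetworks rejected)",
                tuple(rejected)) from None
        if sol.dof >= scenario.dof_min:
            return sol
        rejected.append(sol)
        session.exclude(sol)


@dataclass
class EnumerationResult:
    """All minimum subnetworks found, with completeness certificate."""

    solutions: list[SubnetworkSolution]
    minimum_size: int
    exhausted: bool
    core_reactions: frozenset = field(init=False)
    union_reactions: frozenset = field(init=False)

    def __post_init__(self) -> None:
        sets = [s.active for s in self.solutions]
        if len({frozenset(s) for s in sets}) != len(sets):
            raise ValueError("duplicate active sets in enumeration result")
        self.core_reactions = frozenset.intersection(*sets) if sets \
            else frozenset()
        self.union_reactions = frozenset.union(*sets) if sets else frozenset()

    def __len__(self) -> int:
        return len(self.solutions)

    def active_sets(self) -> set[frozenset]:
        return {s.active for s in self.solutions}

    def to_json_dict(self, provenance: Optional[dict] = None) -> dict:
        out = {
            "minimum_size": self.minimum_size,
            "exhausted": self.exhausted,
            "n_solutions": len(self.solutions),
            "core_reactions": sorted(self.core_reactions),
            "union_reactions": sorted(self.union_reactions),
            "solutions": [
                {
                    "active": sorted(s.active),
                    "dof": s.dof,
                    "witness_fluxes": {str(j): w
                                       for j, w in s.witness_fluxes.items()},
                }
                for s in self.solutions
            ],
        }
        if provenance:
            out["provenance"] = provenance
        return out


def enumerate_all(network: MetabolicNetwork, scenario: ReductionScenario,
                  use_representatives: bool = False,
                  max_solutions: Optional[int] = None,
                  time_limit: Optional[float] = None,
                  backend="glpk",
                  partition: Optional[CouplingPartition] = None,
                  ) -> EnumerationResult:
    """Enumerate every minimum subnetwork via iterated integer cuts.

    Solutions failing the dof requirement are excluded but not counted; the
    minimum size is the smallest active count among dof-passing solutions.
    Results are canonicalized (sorted by active set) so output order does
    not depend on the backend's tie-breaking.
    """
    session = _Session(network, scenario, use_representatives, backend,
                       partition)
    deadline = time.monotonic() + time_limit if time_limit else None
    solutions: list[SubnetworkSolution] = []
    rejected_dof: list[SubnetworkSolution] = []
    minimum_size: Optional[int] = None
    exhausted = False
    while True:
        if max_solutions is not None and len(solutions) >= max_solutions:
            break
        remaining = deadline - time.monotonic() if deadline else None
        if remaining is not None and remaining <= 0:
            break
        try:
            sol = session.solve(remaining)
        except InfeasibleScenarioError:
            if minimum_size is None:
                if rejected_dof:
                    raise DofUnsatisfiableError(
                        f"no subnetwork reaches dof >= {scenario.dof_min} "
                        f"({len(rejected_dof)} subnetworks rejected)",
                        tuple(rejected_dof)) from None
                raise
            exhausted = True
            break
        if minimum_size is not None and sol.n_active > minimum_size:
            exhausted = True
            break
        session.exclude(sol)
        if sol.dof < scenario.dof_min:
            rejected_dof.append(sol)
            continue  # excluded but not counted
        if minimum_size is None:
            minimum_size = sol.n_active
        solutions.append(sol)
    if minimum_size is None:
        raise DofUnsatisfiableError(
            f"no subnetwork reaches dof >= {scenario.dof_min} within the "
            f"enumeration limits")
    solutions.sort(key=lambda s: tuple(sorted(s.active)))
    return EnumerationResult(solutions, minimum_size, exhausted)
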