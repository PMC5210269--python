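"""MILP formulations for minimum functional subnetworks.

Three formulations are built as solver-agnostic constraint systems:

MinNW-0
    One flux copy ``v``; binary activity indicators ``a_i`` (and ``abar_i``
    for the backward direction of reversible reactions) linked to the flux
    by big-M / indicator rows; all functionalities ``D_f v <= d_f`` imposed
    on that single copy; objective ``min sum a_i + sum abar_k``.  Suitable
    only when the functionalities are mutually compatible within one flux
    vector.

minNW
    One flux copy per functionality plus a copy 0 for the protected sets,
    with per-copy indicators ``a_i^j`` and aggregated indicators ``a_i``
    (active on some copy); objective ``min sum a_i``.  This is the general
    formulation: conflicting functionalities (e.g. aerobic and anaerobic
    growth) each get their own witness flux vector, while the objective
    counts a reaction once no matter how many copies use it.

minNW_rep
    As minNW, but with one set of binaries per partial-coupling class
    instead of per reaction, and objective weights equal to the class sizes
    -- the optimum still counts *reactions*, not representatives.

Activity coupling comes in two encodings.  ``bigM`` emits the textbook rows
``delta*a <= v <= M*a`` (and the sign-split variant for reversible
reactions) with one global constant ``M``; infinite model bounds are capped
at ``M`` inside the encoding only.  ``indicator`` expresses the implications
``a=0 => v=0``, ``a=1 => v >= delta`` (``abar=1 => v <= -delta``); since no
available backend branches on indicators natively, the encoder compiles them
to rows using each reaction's own finite bounds as tight constants, which
avoids the numerical pitfalls of one large global M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import backends
from .model_io import (MetabolicNetwork, ReductionScenario, ValidationError)
from .preprocess import CouplingPartition

__all__ = [
    "BuildError", "InfeasibleScenarioError", "ConsistencyError",
    "Variable", "LinearRow", "ActivityLink", "MilpProblem", "EncodedProblem",
    "SubnetworkSolution",
    "build_minnw0", "build_minnw", "build_minnw_rep",
    "encode", "solve", "dump_lp",
]

WITNESS_TOL = 1e-06


class BuildError(ValueError):
    """The MILP could not be assembled from the given inputs."""


class InfeasibleScenarioError(RuntimeError):
    """The requirements admit no feasible subnetwork (proved by the solver)."""

    def __init__(self, message: str, rejected: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.rejected = rejected


class ConsistencyError(RuntimeError):
    """Solver binaries and witness fluxes disagree beyond tolerance."""


# ---------------------------------------------------------------------------
# Problem containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # 'continuous' | 'binary'
    lb: float = -math.inf
    ub: float = math.inf


@dataclass(frozen=True)
class LinearRow:
    name: str
    coeffs: dict  # var name -> coefficient
    lb: float = -math.inf
    ub: float = math.inf


@dataclass(frozen=True)
class ActivityLink:
    """Couples one flux variable to the binaries of its reaction/class.

    ``kind='full'`` demands ``|v| >= delta`` when active; ``kind='zero'``
    only forces ``v = 0`` when inactive (used for class members whose
    nonzeroness already follows from partial coupling, where a shared sign
    constraint could be unsound).
    """

    flux: str
    pos: str
    neg: Optional[str]
    model_lb: float
    model_ub: float
    kind: str = "full"
    tag: str = "eq1"


@dataclass
class MilpProblem:
    """Solver-agnostic MILP: variables, structural rows, activity links."""

    formulation: str              # 'minnw0' | 'minnw' | 'minnw_rep'
    variables: dict = field(default_factory=dict)
    rows: list = field(default_factory=list)
    activity_links: list = field(default_factory=list)
    objective: dict = field(default_factory=dict)
    binary_space: str = "reaction"          # 'reaction' | 'class'
    binary_keys: list = field(default_factory=list)
    members: dict = field(default_factory=dict)   # key -> tuple of rids
    aggregated: dict = field(default_factory=dict)  # key -> A-var name
    copies: int = 1
    delta: float = 1e-4
    big_M: float = 1000.0
    encoding: str = "indicator"
    network: Optional[MetabolicNetwork] = None
    scenario: Optional[ReductionScenario] = None

    def add_var(self, name, kind, lb=-math.inf, ub=math.inf) -> str:
        self.variables[name] = Variable(name, kind, lb, ub)
        return name

    def add_row(self, name, coeffs, lb=-math.inf, ub=math.inf) -> None:
        self.rows.append(LinearRow(name, dict(coeffs), lb, ub))

    def n_binary(self) -> int:
        return sum(1 for v in self.variables.values() if v.kind == "binary")


@dataclass
class EncodedProblem:
    """A MilpProblem with every activity link materialized as linear rows."""

    variables: dict
    rows: list
    objective: dict
    mode: str
    source: MilpProblem


@dataclass
class SubnetworkSolution:
    """One minimum subnetwork: active reactions plus per-copy flux witnesses.

    ``witness_fluxes[0]`` realizes the protected sets; ``witness_fluxes[j]``
    (j >= 1) realizes functionality j.  ``active_pattern`` holds the 0/1
    activity pattern in the problem's binary space (reaction ids or class
    representative ids) and is what integer cuts act on.
    """

    active: frozenset
    witness_fluxes: dict
    n_active: int
    active_pattern: frozenset
    binary_space: str
    encoding: str
    delta: float
    solver_status: str
    dof: Optional[int] = None

    def witness(self, copy: int) -> dict:
        return self.witness_fluxes[copy]


# ---------------------------------------------------------------------------
# Naming helpers
# ---------------------------------------------------------------------------

def _v(rid, j):
    return f"v[{rid}]@{j}"


def _a(key, j):
    return f"a[{key}]@{j}"


def _an(key, j):
    return f"an[{key}]@{j}"


def _A(key):
    return f"A[{key}]"


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _check_inputs(network, scenario):
    if not scenario.resolved:
        raise BuildError(
            "scenario has unresolved fraction-of-optimum functionalities; "
            "call model_io.resolve_scenario first")
    scenario.validate(network)


def _p0_metabolites(network, scenario):
    """Protected metabolites not already covered by a protected reaction."""
    out = []
    for m in sorted(scenario.protected_metabolites):
        touching = set(network.reactions_of_metabolite(m))
        if not (touching & scenario.protected_reactions):
            out.append(m)
    return out


def _add_flux_copy(prob, network, j):
    """Flux variables and steady-state rows for copy ``j``."""
    for i, rid in enumerate(network.reaction_ids):
        prob.add_var(_v(rid, j), "continuous", network.l[i], network.u[i])
    for mi, mid in enumerate(network.metabolite_ids):
        cols = np.nonzero(network.S[mi])[0]
        coeffs = {_v(network.reaction_ids[ci], j): network.S[mi, ci]
                  for ci in cols}
        prob.add_row(f"ss[{mid}]@{j}", coeffs, 0.0, 0.0)


def _add_functionality_rows(prob, f, j):
    for k, (coeffs, rhs) in enumerate(f.rows):
        row = {_v(rid, j): coef for rid, coef in coeffs}
        prob.add_row(f"func[{f.label}][{k}]@{j}", row, ub=rhs)


def _protected_rows(prob, network, scenario, key_of, rev_of, copy):
    """Protected-reaction and protected-metabolite rows on ``copy``."""
    for rid in sorted(scenario.protected_reactions):
        key = key_of[rid]
        if rev_of[key]:
            prob.add_row(f"prot[{rid}]@{copy}",
                         {_a(key, copy): 1.0, _an(key, copy): 1.0}, 1.0, 1.0)
        else:
            prob.add_row(f"prot[{rid}]@{copy}", {_a(key, copy): 1.0}, 1.0, 1.0)
    for m in _p0_metabolites(network, scenario):
        keys = sorted({key_of[rid] for rid in network.reactions_of_metabolite(m)})
        if not keys:
            raise BuildError(f"protected metabolite {m!r} touches no reaction")
        coeffs = {}
        for key in keys:
            coeffs[_a(key, copy)] = 1.0
            if rev_of[key]:
                coeffs[_an(key, copy)] = 1.0
        tag = "eq3" if prob.formulation == "minnw0" else "eq7"
        prob.add_row(f"{tag}[{m}]", coeffs, lb=1.0)


def _copy_binaries(prob, keys, rev_of, j):
    """Per-copy binaries plus the a + abar <= 1 rows (eq6)."""
    for key in keys:
        prob.add_var(_a(key, j), "binary", 0.0, 1.0)
        if rev_of[key]:
            prob.add_var(_an(key, j), "binary", 0.0, 1.0)
            prob.add_row(f"eq6[{key}]@{j}",
                         {_a(key, j): 1.0, _an(key, j): 1.0}, ub=1.0)


def _aggregation_rows(prob, keys, rev_of, n_copies):
    """eq8/eq9: aggregated a_i is 1 iff some copy's indicator is 1."""
    for key in keys:
        prob.add_var(_A(key), "binary", 0.0, 1.0)
        prob.aggregated[key] = _A(key)
        terms = {}
        for j in range(n_copies):
            terms[_a(key, j)] = 1.0
            if rev_of[key]:
                terms[_an(key, j)] = 1.0
        cap = (2 * n_copies) if rev_of[key] else n_copies
        tag = "eq9" if rev_of[key] else "eq8"
        lo = dict(terms); lo[_A(key)] = -1.0
        prob.add_row(f"{tag}lo[{key}]", lo, lb=0.0)
        hi = dict(terms); hi[_A(key)] = -float(cap)
        prob.add_row(f"{tag}hi[{key}]", hi, ub=0.0)


def build_minnw0(network: MetabolicNetwork,
                 scenario: ReductionScenario) -> MilpProblem:
    """Single-flux-copy formulation (MinNW-0).

    All functionality rows bind the one flux copy, so mutually conflicting
    functionalities make this problem infeasible -- that is exactly the
    situation the multi-copy minNW formulation exists for.
    """
    _check_inputs(network, scenario)
    prob = MilpProblem("minnw0", delta=scenario.delta,
                       big_M=scenario.resolved_big_M(network),
                       encoding=scenario.encoding,
                       network=network, scenario=scenario, copies=1)
    keys = list(network.reaction_ids)
    prob.binary_keys = keys
    prob.members = {rid: (rid,) for rid in keys}
    rev_of = {rid: bool(network.reversible[i])
              for i, rid in enumerate(network.reaction_ids)}
    key_of = {rid: rid for rid in keys}

    _add_flux_copy(prob, network, 0)
    _copy_binaries(prob, keys, rev_of, 0)
    for i, rid in enumerate(network.reaction_ids):
        prob.activity_links.append(ActivityLink(
            _v(rid, 0), _a(rid, 0), _an(rid, 0) if rev_of[rid] else None,
            network.l[i], network.u[i],
            tag="eq2" if rev_of[rid] else "eq1"))
    for f in scenario.functionalities:
        _add_functionality_rows(prob, f, 0)
    _protected_rows(prob, network, scenario, key_of, rev_of, 0)

    for rid in keys:
        prob.objective[_a(rid, 0)] = 1.0
        if rev_of[rid]:
            prob.objective[_an(rid, 0)] = 1.0
    prob.aggregated = {}  # objective counts a + abar directly
    return prob


def _build_multicopy(network, scenario, partition):
    """Shared construction of minNW (partition None) and minNW_rep."""
    _check_inputs(network, scenario)
    formulation = "minnw" if partition is None else "minnw_rep"
    prob = MilpProblem(formulation, delta=scenario.delta,
                       big_M=scenario.resolved_big_M(network),
                       encoding=scenario.encoding,
                       network=network, scenario=scenario)
    n_copies = len(scenario.functionalities) + 1
    prob.copies = n_copies

    if partition is None:
        keys = list(network.reaction_ids)
        members = {rid: (rid,) for rid in keys}
        key_of = {rid: rid for rid in keys}
        rev_of = {rid: bool(network.reversible[i])
                  for i, rid in enumerate(network.reaction_ids)}
        prob.binary_space = "reaction"
    else:
        missing = set(network.reaction_ids) - set(partition.class_of)
        extra = set(partition.class_of) - set(network.reaction_ids)
        if missing or extra:
            raise BuildError(
                f"partition does not match network (missing {sorted(missing)[:3]}, "
                f"extra {sorted(extra)[:3]})")
        keys = [partition.representative[k] for k in range(partition.n_classes)]
        members = {partition.representative[k]:
                   tuple(sorted(partition.classes[k]))
                   for k in range(partition.n_classes)}
        key_of = {rid: partition.representative[partition.class_of[rid]]
                  for rid in network.reaction_ids}
        # class reversibility follows its representative (irreversible
        # members are preferred as representatives)
        rev_of = {key: bool(network.reversible[network.rxn_index(key)])
                  for key in keys}
        prob.binary_space = "class"
    prob.binary_keys = keys
    prob.members = members

    for j in range(n_copies):
        _add_flux_copy(prob, network, j)
        _copy_binaries(prob, keys, rev_of, j)
        for i, rid in enumerate(network.reaction_ids):
            key = key_of[rid]
            rev_key = rev_of[key]
            rev_rxn = bool(network.reversible[i])
            # members whose own reversibility disagrees with the class sign
            # convention get zero-linking only; partial coupling over C0
            # already forces them nonzero whenever the class is active
            full = (rid == key) or (rev_rxn == rev_key and not rev_rxn)
            prob.activity_links.append(ActivityLink(
                _v(rid, j), _a(key, j), _an(key, j) if rev_key else None,
                network.l[i], network.u[i],
                kind="full" if full else "zero",
                tag="eq5" if rev_key else "eq4"))
    for j, f in enumerate(scenario.functionalities, start=1):
        _add_functionality_rows(prob, f, j)
    _protected_rows(prob, network, scenario, key_of, rev_of, 0)
    _aggregation_rows(prob, keys, rev_of, n_copies)

    for key in keys:
        prob.objective[_A(key)] = float(len(members[key]))
    return prob


def build_minnw(network: MetabolicNetwork,
                scenario: ReductionScenario) -> MilpProblem:
    """Multi-copy formulation (minNW) with reaction-level binaries.

    With zero functionalities this degenerates to a single protected-set
    copy whose aggregated objective equals the MinNW-0 active-reaction
    count.
    """
    return _build_multicopy(network, scenario, None)


def build_minnw_rep(network: MetabolicNetwork, scenario: ReductionScenario,
                    partition: CouplingPartition) -> MilpProblem:
    """minNW with one binary set per partial-coupling class (minNW_rep).

    Objective weights are the class sizes, so the optimum value is still the
    number of active *reactions*.
    """
    if partition is None:
        raise BuildError("build_minnw_rep requires a CouplingPartition")
    return _build_multicopy(network, scenario, partition)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _clip(x, M):
    return min(max(x, -M), M)


def _activity_rows(link: ActivityLink, delta: float, M: float, mode: str):
    """Materialize one activity link as linear rows.

    bigM mode uses the global constant ``M`` (the literal textbook rows);
    indicator mode uses the reaction's own finite bounds as tight constants,
    which is the standard compilation of ``a=0 => v=0, a=1 => v >= delta``.
    """
    if mode == "bigM":
        U, L = M, -M
    else:
        U = min(link.model_ub, M)
        L = max(link.model_lb, -M)
    v, a, an = link.flux, link.pos, link.neg
    tag = link.tag
    rows = []
    if link.kind == "zero":
        # inactive => v = 0; nonzeroness when active follows from coupling
        acts = {a: 1.0} if an is None else {a: 1.0, an: 1.0}
        lo = {v: 1.0}; lo.update({k: -L for k in acts})
        rows.append(LinearRow(f"{tag}zlo[{v}]", lo, lb=0.0))
        hi = {v: 1.0}; hi.update({k: -U for k in acts})
        rows.append(LinearRow(f"{tag}zhi[{v}]", hi, ub=0.0))
        return rows
    if an is None:
        rows.append(LinearRow(f"{tag}lo[{v}]", {v: 1.0, a: -delta}, lb=0.0))
        rows.append(LinearRow(f"{tag}hi[{v}]", {v: 1.0, a: -U}, ub=0.0))
    else:
        rows.append(LinearRow(f"{tag}lo[{v}]",
                              {v: 1.0, a: -delta, an: -L}, lb=0.0))
        rows.append(LinearRow(f"{tag}hi[{v}]",
                              {v: 1.0, a: -U, an: delta}, ub=0.0))
    return rows


def encode(problem: MilpProblem, mode: Optional[str] = None) -> EncodedProblem:
    """Materialize activity links into backend-ready linear rows."""
    mode = mode or problem.encoding
    if mode not in ("bigM", "indicator"):
        raise BuildError(f"unknown encoding mode {mode!r}")
    if problem.delta >= problem.big_M:
        raise BuildError(
            f"delta={problem.delta:g} must be smaller than big_M={problem.big_M:g}")
    M = problem.big_M
    variables = {}
    for var in problem.variables.values():
        if var.kind == "continuous" and mode == "bigM":
            variables[var.name] = Variable(var.name, var.kind,
                                           _clip(var.lb, M), _clip(var.ub, M))
        elif var.kind == "continuous":
            lb = var.lb if math.isfinite(var.lb) else -M
            ub = var.ub if math.isfinite(var.ub) else M
            variables[var.name] = Variable(var.name, var.kind, lb, ub)
        else:
            variables[var.name] = var
    rows = list(problem.rows)
    for link in problem.activity_links:
        rows.extend(_activity_rows(link, problem.delta, M, mode))
    return EncodedProblem(variables, rows, dict(problem.objective),
                          mode, problem)


def dump_lp(problem: MilpProblem, path, mode: Optional[str] = None) -> None:
    """Export the encoded problem in LP format (constraint names keep their
    equation tags) for debugging."""
    backend = backends.GlpkBackend()
    backend.load(encode(problem, mode))
    backend.write_lp(path)


# ---------------------------------------------------------------------------
# Solving and solution extraction
# ---------------------------------------------------------------------------

def _functionality_violation(problem, values):
    """Largest violation of steady state / functionality rows by witnesses."""
    worst = 0.0
    for row in problem.rows:
        if not (row.name.startswith("ss[") or row.name.startswith("func[")):
            continue
        total = sum(coef * values[name] for name, coef in row.coeffs.items())
        if math.isfinite(row.ub):
            worst = max(worst, total - row.ub)
        if math.isfinite(row.lb):
            worst = max(worst, row.lb - total)
    return worst


def _check_link_semantics(problem: MilpProblem, values: dict) -> None:
    """Verify witness fluxes against the implication semantics of each link.

    inactive (a = abar = 0) => v = 0; a = 1 => v >= delta for full links
    (abar = 1 => v <= -delta); zero-linked class members are only required
    to vanish when inactive -- their nonzeroness when active follows from
    partial coupling.
    """
    delta, tol = problem.delta, WITNESS_TOL
    for link in problem.activity_links:
        v = values[link.flux]
        a = values[link.pos] > 0.5
        an = values[link.neg] > 0.5 if link.neg else False
        if not a and not an and abs(v) > tol:
            raise ConsistencyError(
                f"{link.flux} = {v:g} but its activity flags are 0")
        if link.kind != "full":
            continue
        if a and v < delta - tol:
            raise ConsistencyError(
                f"{link.flux} = {v:g} below delta with {link.pos} = 1")
        if an and v > -delta + tol:
            raise ConsistencyError(
                f"{link.flux} = {v:g} above -delta with {link.neg} = 1")


def _extract(problem: MilpProblem, values: dict, status: str
             ) -> SubnetworkSolution:
    network = problem.network
    delta = problem.delta
    witnesses = {}
    for j in range(problem.copies):
        witnesses[j] = {rid: values[_v(rid, j)] for rid in network.reaction_ids}

    # activity re-derived from the witnesses, cross-checked against binaries
    derived = frozenset(
        rid for rid in network.reaction_ids
        if any(abs(witnesses[j][rid]) > delta / 2 for j in range(problem.copies)))

    if problem.aggregated:
        pattern = frozenset(k for k in problem.binary_keys
                            if values[problem.aggregated[k]] > 0.5)
    else:  # MinNW-0: a reaction/class is active if a or abar is set
        pattern = frozenset(
            k for k in problem.binary_keys
            if values[_a(k, 0)] > 0.5 or values.get(_an(k, 0), 0.0) > 0.5)
    from_binaries = frozenset(
        rid for key in pattern for rid in problem.members[key])

    _check_link_semantics(problem, values)
    if not derived <= from_binaries:
        raise ConsistencyError(
            f"reactions carry flux without being flagged active: "
            f"{sorted(derived - from_binaries)}")
    if problem.binary_space == "reaction" and derived != from_binaries:
        raise ConsistencyError(
            f"activity flags disagree with witness fluxes: "
            f"{sorted(from_binaries ^ derived)} differ (delta={delta:g})")
    violation = _functionality_violation(problem, values)
    if violation > WITNESS_TOL:
        raise ConsistencyError(
            f"witness fluxes violate structural rows by {violation:.2e}")

    return SubnetworkSolution(
        active=from_binaries, witness_fluxes=witnesses,
        n_active=len(from_binaries),
        active_pattern=pattern, binary_space=problem.binary_space,
        encoding=problem.encoding, delta=delta, solver_status=status)


def solve(problem: MilpProblem, backend="glpk",
          time_limit: Optional[float] = None,
          mode: Optional[str] = None) -> SubnetworkSolution:
    """Encode, hand to a backend, and extract a checked solution.

    Raises :class:`InfeasibleScenarioError` when the requirements are
    unsatisfiable (proved infeasible), :class:`backends.SolverError` on
    solver failure or an exhausted time limit without incumbent, and
    :class:`ConsistencyError` when the returned binaries contradict the
    witness fluxes beyond tolerance.
    """
    be = backends.get_backend(backend)
    be.load(encode(problem, mode))
    status = be.solve(time_limit)
    if status == "infeasible":
        raise InfeasibleScenarioError(
            "the protected sets and functionalities admit no feasible "
            "subnetwork under the given bounds")
    if status == "timeout":
        raise backends.SolverError(
            f"time limit of {time_limit}s reached without a feasible incumbent")
    if status == "failed":
        raise backends.SolverError("solver terminated without a usable status")
    return _extract(problem, be.values(), status)
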