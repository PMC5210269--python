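"""Metabolic models, reduction scenarios, and their file formats.

The central object is :class:`MetabolicNetwork`, a plain stoichiometric
description of the steady-state flux space

    C = { v | S v = 0,  l <= v <= u },

where ``S`` is the metabolites x reactions stoichiometric matrix and
``l, u`` are per-reaction flux bounds (lower bound >= 0 for irreversible
reactions).  Boundary/external metabolites are *not* represented: exchange
reactions appear as unbalanced columns, so the steady-state constraint
applies to internal metabolites only.

A :class:`ReductionScenario` collects everything the reduced subnetwork must
preserve: protected metabolites, protected reactions, linear flux
functionalities ``D_f v <= d_f`` (possibly given as fraction-of-optimum
specifications), a minimum number of degrees of freedom, and the numerical
parameters of the MILP encoding (activity threshold ``delta``, big-M
constant, encoding mode).

SBML (Level 3 + FBC, with legacy fallbacks) and BiGG-style JSON are read and
written through cobrapy / libSBML.  Scenario files use this project's own
JSON/YAML schema, documented in :func:`read_scenario`, because SBML has no
standard slot for protected sets or functionalities.
"""

from __future__ import annotations

import difflib
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "ResolutionError",
    "MetabolicNetwork",
    "LinearFunctionality",
    "FractionOfOptimum",
    "ReductionScenario",
    "read_model",
    "read_scenario",
    "resolve_functionality",
    "resolve_scenario",
    "write_subnetwork",
]

_REL_ALIASES = {
    "<=": "<=", "=<": "<=", "le": "<=", "leq": "<=", "≤": "<=",
    ">=": ">=", "=>": ">=", "ge": ">=", "geq": ">=", "≥": ">=",
    "=": "=", "==": "=", "eq": "=",
}


class ValidationError(ValueError):
    """A model or scenario violates a structural invariant."""


class FormatError(ValueError):
    """A file could not be parsed under the named standard."""


class ResolutionError(ValueError):
    """A fraction-of-optimum functionality could not be resolved."""


# ---------------------------------------------------------------------------
# MetabolicNetwork
# ---------------------------------------------------------------------------

@dataclass
class MetabolicNetwork:
    """Stoichiometry, flux bounds and reversibility of a metabolic network.

    Parameters
    ----------
    metabolite_ids : ordered unique identifiers of the internal metabolites.
    reaction_ids : ordered unique identifiers of the reactions.
    S : array of shape ``(n_metabolites, n_reactions)``.
    l, u : per-reaction lower/upper flux bounds; ``+-inf`` allowed.
    irreversible : per-reaction flags; irreversible reactions must have
        ``l >= 0``.  If omitted, inferred as ``l >= 0``.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    l: np.ndarray
    u: np.ndarray
    irreversible: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.metabolite_ids = list(self.metabolite_ids)
        self.reaction_ids = list(self.reaction_ids)
        self.S = np.asarray(self.S, dtype=float)
        self.l = np.asarray(self.l, dtype=float).ravel()
        self.u = np.asarray(self.u, dtype=float).ravel()
        if self.irreversible is None:
            self.irreversible = self.l >= 0
        self.irreversible = np.asarray(self.irreversible, dtype=bool).ravel()
        self._validate()
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    def _validate(self) -> None:
        nm, nr = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.metabolite_ids)) != nm:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != nr:
            raise ValidationError("duplicate reaction ids")
        if self.S.shape != (nm, nr):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({nm}, {nr})")
        for arr, name in ((self.l, "l"), (self.u, "u"),
                          (self.irreversible, "irreversible")):
            if arr.shape != (nr,):
                raise ValidationError(f"{name} has length {arr.shape}, "
                                      f"expected {nr}")
        bad = [self.reaction_ids[i] for i in np.nonzero(self.l > self.u)[0]]
        if bad:
            raise ValidationError(f"l > u for reactions: {bad}")
        bad = [self.reaction_ids[i]
               for i in np.nonzero(self.irreversible & (self.l < 0))[0]]
        if bad:
            raise ValidationError(
                f"irreversible reactions with negative lower bound: {bad}")

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def reversible(self) -> np.ndarray:
        return ~self.irreversible

    def met_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def reactions_of_metabolite(self, met_id: str) -> list[str]:
        """Reactions with a nonzero stoichiometric coefficient for ``met_id``."""
        row = self.S[self.met_index(met_id)]
        return [self.reaction_ids[j] for j in np.nonzero(row)[0]]

    def submatrix(self, rxn_ids: Sequence[str]) -> np.ndarray:
        cols = [self.rxn_index(r) for r in rxn_ids]
        return self.S[:, cols]

    def subnetwork(self, active: Iterable[str]) -> "MetabolicNetwork":
        """Network restricted to ``active``; untouched metabolites dropped."""
        active = list(dict.fromkeys(active))
        if not active:
            raise ValidationError("cannot build an empty subnetwork")
        cols = [self.rxn_index(r) for r in active]
        S = self.S[:, cols]
        keep = np.nonzero(np.any(S != 0, axis=1))[0]
        return MetabolicNetwork(
            [self.metabolite_ids[i] for i in keep],
            active,
            S[keep],
            self.l[cols],
            self.u[cols],
            self.irreversible[cols],
        )

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolite_ids), list(self.reaction_ids),
            self.S.copy(), self.l.copy(), self.u.copy(),
            self.irreversible.copy())


# ---------------------------------------------------------------------------
# Functionalities and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FractionOfOptimum:
    """Require a reaction to carry at least ``fraction`` of its LP optimum.

    ``fixed_rows`` are linear rows (canonical ``coeffs . v <= rhs``) imposed
    both while computing the optimum and in the resolved functionality, e.g.
    an oxygen exchange fixed to zero for an anaerobic condition.
    """

    objective_reaction: str
    fraction: float
    fixed_rows: tuple[tuple[tuple[tuple[str, float], ...], float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValidationError(
                f"fraction-of-optimum gamma must be in (0, 1], "
                f"got {self.fraction}")


def _canonical_rows(rows) -> tuple[tuple[tuple[tuple[str, float], ...], float], ...]:
    """Canonicalize (coeffs, relation, rhs) triples to ``coeffs . v <= rhs``."""
    out = []
    for row in rows:
        if isinstance(row, Mapping):
            coeffs, rel, rhs = row["coeffs"], row.get("relation", "<="), row["rhs"]
        else:
            coeffs, rel, rhs = row
        rel = _REL_ALIASES.get(str(rel).strip())
        if rel is None:
            raise FormatError(f"unknown relation in functionality row: {row!r}")
        items = tuple(sorted((str(k), float(v)) for k, v in dict(coeffs).items()))
        if not items:
            raise FormatError(f"functionality row with no coefficients: {row!r}")
        rhs = float(rhs)
        if rel in ("<=", "="):
            out.append((items, rhs))
        if rel in (">=", "="):
            out.append((tuple((k, -v) for k, v in items), -rhs))
    return tuple(out)


@dataclass(frozen=True)
class LinearFunctionality:
    """A protected flux functionality ``D_f v <= d_f``.

    ``rows`` holds the canonical inequality system: each entry is a pair
    ``(((rxn_id, coef), ...), rhs)`` meaning ``sum coef * v_rxn <= rhs``.
    Relations ``>=`` and ``=`` given to :meth:`from_rows` are canonicalized.
    A :class:`FractionOfOptimum` spec, if present, is turned into explicit
    rows by :func:`resolve_functionality`.
    """

    label: str
    rows: tuple[tuple[tuple[tuple[str, float], ...], float], ...] = ()
    fraction_of_optimum: Optional[FractionOfOptimum] = None

    @classmethod
    def from_rows(cls, label: str, rows,
                  fraction_of_optimum: Optional[FractionOfOptimum] = None
                  ) -> "LinearFunctionality":
        return cls(label, _canonical_rows(rows), fraction_of_optimum)

    @property
    def resolved(self) -> bool:
        return self.fraction_of_optimum is None

    def referenced_reactions(self) -> set[str]:
        refs = {rid for coeffs, _ in self.rows for rid, _ in coeffs}
        if self.fraction_of_optimum is not None:
            refs.add(self.fraction_of_optimum.objective_reaction)
            refs |= {rid for coeffs, _ in self.fraction_of_optimum.fixed_rows
                     for rid, _ in coeffs}
        return refs

    def validate(self, network: MetabolicNetwork) -> None:
        unknown = self.referenced_reactions() - set(network.reaction_ids)
        if unknown:
            raise ValidationError(
                f"functionality {self.label!r} references unknown reactions: "
                f"{sorted(unknown)}")
        if self.resolved and not self.rows:
            raise ValidationError(
                f"functionality {self.label!r} has no rows and no "
                f"fraction-of-optimum spec")


DELTA_RANGE = (1e-06, 1e-04)


@dataclass
class ReductionScenario:
    """User requirements for the reduced subnetwork.

    delta is the activity threshold: a reaction counts as active in a
    subnetwork when it can carry a flux of at least ``delta`` (in absolute
    value) in some witness flux vector.  ``big_M`` is the flux cap used by
    the big-M encoding only; infinite model bounds are never replaced in the
    network itself.
    """

    protected_metabolites: set[str] = field(default_factory=set)
    protected_reactions: set[str] = field(default_factory=set)
    functionalities: list[LinearFunctionality] = field(default_factory=list)
    dof_min: int = 1
    delta: float = 1e-04
    big_M: Optional[float] = None
    encoding: str = "indicator"

    def __post_init__(self) -> None:
        self.protected_metabolites = set(self.protected_metabolites)
        self.protected_reactions = set(self.protected_reactions)
        if self.encoding not in ("bigM", "indicator"):
            raise ValidationError(
                f"encoding must be 'bigM' or 'indicator', got {self.encoding!r}")
        if self.dof_min < 0:
            raise ValidationError("dof_min must be non-negative")
        if self.delta <= 0:
            raise ValidationError("delta must be positive")
        if not (DELTA_RANGE[0] <= self.delta <= DELTA_RANGE[1]):
            warnings.warn(
                f"delta={self.delta:g} is outside the recommended range "
                f"[{DELTA_RANGE[0]:g}, {DELTA_RANGE[1]:g}]",
                UserWarning, stacklevel=2)

    def resolved_big_M(self, network: MetabolicNetwork) -> float:
        """big_M, auto-derived as max(1000, max finite |bound|) if unset."""
        if self.big_M is not None:
            M = float(self.big_M)
        else:
            finite = np.concatenate([
                np.abs(self.finite_values(network.l)),
                np.abs(self.finite_values(network.u))])
            M = max(1000.0, float(finite.max()) if finite.size else 0.0)
        if M <= self.delta:
            raise ValidationError(f"big_M={M:g} must exceed delta={self.delta:g}")
        return M

    @staticmethod
    def finite_values(arr: np.ndarray) -> np.ndarray:
        return arr[np.isfinite(arr)]

    def validate(self, network: MetabolicNetwork) -> None:
        for mid in self.protected_metabolites:
            if mid not in network.metabolite_ids:
                raise ValidationError(
                    f"unknown protected metabolite {mid!r}"
                    f"{_suggest(mid, network.metabolite_ids)}")
        for rid in self.protected_reactions:
            if rid not in network.reaction_ids:
                raise ValidationError(
                    f"unknown protected reaction {rid!r}"
                    f"{_suggest(rid, network.reaction_ids)}")
        for f in self.functionalities:
            f.validate(network)
        self.resolved_big_M(network)

    @property
    def resolved(self) -> bool:
        return all(f.resolved for f in self.functionalities)


def _suggest(name: str, pool: Iterable[str]) -> str:
    close = difflib.get_close_matches(name, list(pool), n=3)
    return f" (did you mean {close}?)" if close else ""


# ---------------------------------------------------------------------------
# Reading models
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "bigg_json"
    head = path.read_text(errors="replace")[:200].lstrip()
    if head.startswith("<"):
        return "sbml"
    if head.startswith("{"):
        return "bigg_json"
    raise FormatError(f"cannot determine model format of {path}")


def _from_cobra(model) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    S = create_stoichiometric_matrix(model, array_type="dense")
    l = np.array([r.lower_bound for r in model.reactions], dtype=float)
    u = np.array([r.upper_bound for r in model.reactions], dtype=float)
    bad = [rxns[i] for i in np.nonzero(l > u)[0]]
    if bad:
        raise ValidationError(f"l > u for reactions: {bad}")
    return MetabolicNetwork(mets, rxns, S, l, u, l >= 0)


def read_model(path, format: str = "auto") -> MetabolicNetwork:
    """Read an SBML or BiGG-JSON model into a :class:`MetabolicNetwork`.

    Reversibility is inferred from the lower bounds (``l < 0`` => reversible).
    Boundary species (SBML ``boundaryCondition=true``; BiGG exchange
    pseudo-metabolites) are excluded, so exchange reactions appear as
    unbalanced columns.
    """
    import logging

    import cobra.io

    logging.getLogger("cobra").setLevel(logging.ERROR)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format if format != "auto" else _sniff_format(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "sbml":
                model = cobra.io.read_sbml_model(str(path))
            elif fmt == "bigg_json":
                model = cobra.io.load_json_model(str(path))
            else:
                raise FormatError(f"unknown model format {fmt!r}")
    except (FormatError, ValidationError):
        raise
    except Exception as exc:  # parse failures from libsbml/cobra
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _from_cobra(model)


# ---------------------------------------------------------------------------
# Reading scenarios
# ---------------------------------------------------------------------------

def _parse_functionality(entry: Mapping, idx: int) -> LinearFunctionality:
    if not isinstance(entry, Mapping):
        raise FormatError(f"functionality #{idx} is not a mapping: {entry!r}")
    label = str(entry.get("label", f"functionality_{idx}"))
    foo = None
    if "fraction_of_optimum" in entry:
        spec = entry["fraction_of_optimum"]
        try:
            foo = FractionOfOptimum(
                objective_reaction=str(spec["reaction"]),
                fraction=float(spec["fraction"]),
                fixed_rows=_canonical_rows(spec.get("fixed", [])),
            )
        except KeyError as exc:
            raise FormatError(
                f"functionality {label!r}: fraction_of_optimum needs "
                f"'reaction' and 'fraction' keys ({exc})") from exc
    try:
        rows = _canonical_rows(entry.get("rows", []))
    except (TypeError, KeyError, ValueError) as exc:
        raise FormatError(
            f"functionality {label!r}: malformed inequality row ({exc})") from exc
    if not rows and foo is None:
        raise FormatError(
            f"functionality {label!r} defines neither rows nor a "
            f"fraction_of_optimum spec")
    return LinearFunctionality(label, rows, foo)


def read_scenario(path, network: MetabolicNetwork) -> ReductionScenario:
    """Read a reduction scenario from a JSON/YAML config file.

    Schema (all keys optional unless noted)::

        protected_metabolites: [met_id, ...]
        protected_reactions:   [rxn_id, ...]
        functionalities:
          - label: aerobic
            rows: [{coeffs: {rxn_id: coef, ...}, relation: ">=", rhs: 1.0}]
          - label: growth
            fraction_of_optimum:
                reaction: BIOMASS
                fraction: 0.999
                fixed: [{coeffs: {EX_o2: 1.0}, relation: "=", rhs: 0.0}]
        dof_min: 1          # default 1
        delta: 1.0e-4       # default 1e-4
        big_M: 1000         # default max(1000, max finite |bound|)
        encoding: indicator # or bigM
    """
    import yaml

    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise FormatError(f"could not parse scenario file {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise FormatError(f"scenario file {path} must contain a mapping")
    known = {"protected_metabolites", "protected_reactions", "functionalities",
             "dof_min", "delta", "big_M", "encoding"}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown scenario keys: {sorted(unknown)}")
    funcs = [_parse_functionality(e, i)
             for i, e in enumerate(data.get("functionalities", []) or [])]
    scenario = ReductionScenario(
        protected_metabolites=set(data.get("protected_metabolites", []) or []),
        protected_reactions=set(data.get("protected_reactions", []) or []),
        functionalities=funcs,
        dof_min=int(data.get("dof_min", 1)),
        delta=float(data.get("delta", 1e-04)),
        big_M=(float(data["big_M"]) if data.get("big_M") is not None else None),
        encoding=str(data.get("encoding", "indicator")),
    )
    scenario.validate(network)
    return scenario


# ---------------------------------------------------------------------------
# Fraction-of-optimum resolution
# ---------------------------------------------------------------------------

def resolve_functionality(network: MetabolicNetwork,
                          f: LinearFunctionality) -> LinearFunctionality:
    """Absorb a fraction-of-optimum spec into explicit linear rows.

    Solves ``max { v_obj | S v = 0, l <= v <= u, fixed rows }`` and appends
    the fixing rows plus ``v_obj >= gamma * opt`` to the functionality.
    Pure-inequality functionalities pass through unchanged.
    """
    if f.fraction_of_optimum is None:
        return f
    from . import _lp

    spec = f.fraction_of_optimum
    j = network.rxn_index(spec.objective_reaction)
    res = _lp.flux_lp(network, objective={spec.objective_reaction: 1.0},
                      sense="max", leq_rows=spec.fixed_rows)
    if res.status == "unbounded":
        raise ResolutionError(
            f"functionality {f.label!r}: LP for max v_{spec.objective_reaction} "
            f"is unbounded")
    if res.status != "optimal":
        raise ResolutionError(
            f"functionality {f.label!r}: LP for max v_{spec.objective_reaction} "
            f"is {res.status}")
    opt = res.objective
    new_rows = f.rows + spec.fixed_rows + (
        (((spec.objective_reaction, -1.0),), -spec.fraction * opt),)
    return LinearFunctionality(f.label, new_rows, None)


def resolve_scenario(network: MetabolicNetwork,
                     scenario: ReductionScenario) -> ReductionScenario:
    """Return a copy of ``scenario`` with every functionality resolved."""
    if scenario.resolved:
        return scenario
    out = replace(scenario)
    out.functionalities = [resolve_functionality(network, f)
                           for f in scenario.functionalities]
    return out


# ---------------------------------------------------------------------------
# Writing subnetworks
# ---------------------------------------------------------------------------

def _to_cobra(network: MetabolicNetwork, active: Sequence[str]):
    import cobra

    model = cobra.Model("subnetwork")
    sub = network.subnetwork(active)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in sub.metabolite_ids}
    reactions = []
    for j, rid in enumerate(sub.reaction_ids):
        rxn = cobra.Reaction(rid)
        # plain floats: numpy scalars leak into libsbml setters otherwise
        rxn.lower_bound = float(sub.l[j])
        rxn.upper_bound = float(sub.u[j])
        reactions.append(rxn)
    model.add_reactions(reactions)
    for j, rid in enumerate(sub.reaction_ids):
        stoich = {mets[m]: sub.S[i, j]
                  for i, m in enumerate(sub.metabolite_ids) if sub.S[i, j] != 0}
        model.reactions.get_by_id(rid).add_metabolites(stoich)
    return model


def write_subnetwork(network: MetabolicNetwork, active: Iterable[str],
                     path, format: str = "sbml") -> None:
    """Write the subnetwork induced by ``active`` to ``path``.

    SBML/BiGG-JSON outputs contain exactly the active reactions and the
    metabolites they touch (an active exchange with no surviving metabolite
    is still written).  The TSV variant lists every reaction of the full
    network with an ``in_subnetwork`` 0/1 flag.
    """
    import logging

    import cobra.io

    logging.getLogger("cobra").setLevel(logging.CRITICAL)
    active = set(active)
    unknown = active - set(network.reaction_ids)
    if unknown:
        raise ValidationError(f"unknown reactions in active set: {sorted(unknown)}")
    if not active:
        raise ValidationError("cannot write an empty subnetwork")
    path = Path(path)
    ordered = [r for r in network.reaction_ids if r in active]
    if format == "tsv":
        lines = ["reaction_id\tin_subnetwork"]
        lines += [f"{r}\t{1 if r in active else 0}" for r in network.reaction_ids]
        path.write_text("\n".join(lines) + "\n")
        return
    model = _to_cobra(network, ordered)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if format == "sbml":
            cobra.io.write_sbml_model(model, str(path))
        elif format == "bigg_json":
            cobra.io.save_json_model(model, str(path))
        else:
            raise FormatError(f"unknown output format {format!r}")
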