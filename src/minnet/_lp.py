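"""Thin LP layer over scipy's HiGHS solver.

All plain linear programs in the package (blocked-reaction tests, coupling
tests, FVA, fraction-of-optimum resolution, the brute-force oracle) go
through :func:`flux_lp`.  This keeps the LP path independent of the MILP
backend, so LP-based oracles genuinely cross-check the MILP results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

Rows = Sequence[tuple[tuple[tuple[str, float], ...], float]]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
           3: "unbounded", 4: "failed"}


@dataclass
class LpResult:
    status: str
    x: Optional[np.ndarray]
    objective: float

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def flux_lp(network, objective: Optional[Mapping[str, float]] = None,
            sense: str = "max", leq_rows: Rows = (),
            fixed_zero: Iterable[str] = (), cone_box: Optional[float] = None,
            extra_bounds: Optional[Mapping[str, tuple[float, float]]] = None,
            ) -> LpResult:
    """Solve an LP over the flux space of ``network``.

    Parameters
    ----------
    objective : sparse coefficients over reaction ids; ``None`` solves a
        pure feasibility problem.
    sense : ``"max"`` or ``"min"``.
    leq_rows : canonical inequality rows ``coeffs . v <= rhs``.
    fixed_zero : reactions whose flux is fixed to zero.
    cone_box : if given, the finite bounds ``l, u`` are *replaced* by the
        sign-constrained cone ``C0`` intersected with the box
        ``[-cone_box, cone_box]`` (lower bound 0 for irreversible
        reactions).  Because ``C0`` is a cone, boxing it changes nothing
        about which fluxes can be nonzero.
    extra_bounds : per-reaction bound overrides intersected with the rest.
    """
    n = network.n_reactions
    if cone_box is not None:
        lo = np.where(network.irreversible, 0.0, -cone_box)
        hi = np.full(n, float(cone_box))
    else:
        lo = network.l.copy()
        hi = network.u.copy()
    if extra_bounds:
        for rid, (a, b) in extra_bounds.items():
            j = network.rxn_index(rid)
            lo[j] = max(lo[j], a)
            hi[j] = min(hi[j], b)
    for rid in fixed_zero:
        j = network.rxn_index(rid)
        lo[j] = max(lo[j], 0.0)
        hi[j] = min(hi[j], 0.0)
    if np.any(lo > hi):
        return LpResult("infeasible", None, np.nan)

    c = np.zeros(n)
    if objective:
        for rid, coef in objective.items():
            c[network.rxn_index(rid)] += coef
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")

    A_ub, b_ub = None, None
    if leq_rows:
        A_ub = np.zeros((len(leq_rows), n))
        b_ub = np.empty(len(leq_rows))
        for i, (coeffs, rhs) in enumerate(leq_rows):
            for rid, coef in coeffs:
                A_ub[i, network.rxn_index(rid)] += coef
            b_ub[i] = rhs

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=network.S,
                  b_eq=np.zeros(network.n_metabolites),
                  bounds=np.column_stack([lo, hi]), method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return LpResult(status, None, np.nan)
    obj = float(res.fun) * (-1.0 if sense == "max" else 1.0)
    return LpResult("optimal", np.asarray(res.x), obj)


def range_of(network, rxn_id: str, **kwargs) -> tuple[float, float]:
    """(min, max) of ``v_rxn`` over the (possibly constrained) flux space."""
    out = []
    for sense in ("min", "max"):
        res = flux_lp(network, objective={rxn_id: 1.0}, sense=sense, **kwargs)
        if res.status == "unbounded":
            out.append(-np.inf if sense == "min" else np.inf)
        elif res.ok:
            out.append(res.objective)
        else:
            raise RuntimeError(
                f"LP for {sense} v_{rxn_id} ended with status {res.status}")
    return out[0], out[1]
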