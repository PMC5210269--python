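"""Pluggable MILP backends.

The adapter contract is intentionally small: load an encoded problem,
append linear rows (used for integer cuts during enumeration), solve with an
optional time limit, and report variable values.  The reference adapter
wraps GLPK through swiglpk; GLPK is deterministic and single-threaded, which
makes enumeration order reproducible.

GLPK has no native indicator-constraint branching, so it advertises
``supports_indicator = False``; the :mod:`minnet.milp` encoder compiles
indicator links into bound-tightened linear rows before the problem reaches
any backend (the same reformulation indicator-capable solvers apply
internally when the relevant constants are small).
"""

from __future__ import annotations

import math
import re
import time
from typing import Optional

import swiglpk as glp

__all__ = ["SolverError", "CapabilityError", "GlpkBackend", "get_backend"]


class SolverError(RuntimeError):
    """The solver failed for reasons unrelated to model feasibility."""


class CapabilityError(RuntimeError):
    """The selected backend lacks a required capability."""


def _sanitize(name: str, taken: set[str]) -> str:
    clean = re.sub(r"[^A-Za-z0-9_]", "_", name)[:250] or "x"
    out, k = clean, 1
    while out in taken:
        out, k = f"{clean}_{k}", k + 1
    taken.add(out)
    return out


class GlpkBackend:
    """GLPK (swiglpk) adapter: big-M / pre-compiled indicator rows only."""

    name = "glpk"
    supports_indicator = False

    def __init__(self) -> None:
        self._lp = None
        self._col_of: dict[str, int] = {}
        self._names: list[str] = []
        self._taken: set[str] = set()

    def __del__(self) -> None:
        if self._lp is not None:
            glp.glp_delete_prob(self._lp)
            self._lp = None

    # -- loading -----------------------------------------------------------

    def load(self, encoded) -> None:
        if self._lp is not None:
            glp.glp_delete_prob(self._lp)
        self._lp = glp.glp_create_prob()
        self._taken = set()
        glp.glp_set_obj_dir(self._lp, glp.GLP_MIN)
        variables = list(encoded.variables.values())
        glp.glp_add_cols(self._lp, len(variables))
        self._col_of = {}
        self._names = []
        for j, var in enumerate(variables, start=1):
            self._col_of[var.name] = j
            self._names.append(var.name)
            glp.glp_set_col_name(self._lp, j, _sanitize(var.name, self._taken))
            self._set_bounds(j, var.lb, var.ub, col=True)
            if var.kind == "binary":
                glp.glp_set_col_kind(self._lp, j, glp.GLP_IV)
                self._set_bounds(j, max(var.lb, 0.0), min(var.ub, 1.0), col=True)
            glp.glp_set_obj_coef(self._lp, j,
                                 encoded.objective.get(var.name, 0.0))
        nnz = sum(len(r.coeffs) for r in encoded.rows)
        glp.glp_add_rows(self._lp, len(encoded.rows))
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        k = 0
        for i, row in enumerate(encoded.rows, start=1):
            glp.glp_set_row_name(self._lp, i, _sanitize(row.name, self._taken))
            self._set_bounds(i, row.lb, row.ub, col=False)
            for var_name, coef in row.coeffs.items():
                k += 1
                ia[k], ja[k], ar[k] = i, self._col_of[var_name], float(coef)
        glp.glp_load_matrix(self._lp, k, ia, ja, ar)

    def _set_bounds(self, idx: int, lb: float, ub: float, col: bool) -> None:
        setter = glp.glp_set_col_bnds if col else glp.glp_set_row_bnds
        lo_inf, up_inf = math.isinf(lb), math.isinf(ub)
        if lo_inf and up_inf:
            setter(self._lp, idx, glp.GLP_FR, 0.0, 0.0)
        elif lo_inf:
            setter(self._lp, idx, glp.GLP_UP, 0.0, ub)
        elif up_inf:
            setter(self._lp, idx, glp.GLP_LO, lb, 0.0)
        elif lb == ub:
            setter(self._lp, idx, glp.GLP_FX, lb, ub)
        else:
            setter(self._lp, idx, glp.GLP_DB, lb, ub)

    def add_row(self, row) -> None:
        i = glp.glp_add_rows(self._lp, 1)
        glp.glp_set_row_name(self._lp, i, _sanitize(row.name, self._taken))
        self._set_bounds(i, row.lb, row.ub, col=False)
        n = len(row.coeffs)
        ind = glp.intArray(n + 1)
        val = glp.doubleArray(n + 1)
        for k, (var_name, coef) in enumerate(row.coeffs.items(), start=1):
            ind[k], val[k] = self._col_of[var_name], float(coef)
        glp.glp_set_mat_row(self._lp, i, n, ind, val)

    # -- solving -----------------------------------------------------------

    _MAX_REPAIR_ROUNDS = 100

    def solve(self, time_limit: Optional[float] = None) -> str:
        """Branch-and-bound with an independent incumbent verification loop.

        delta-scale activity rows sit near GLPK's feasibility tolerances
        (violating ``v >= delta * a`` by delta is a relative error of
        delta/M on a big-M row), so every incumbent is re-checked by a
        cold-started LP with the binaries fixed.  A verified incumbent
        yields clean continuous witnesses; an unverifiable one is removed
        with a no-good cut and the MILP is solved again -- such cuts only
        delete infeasible patterns, so the final optimum is unaffected.
        """
        deadline = time.monotonic() + time_limit if time_limit else None
        for _ in range(self._MAX_REPAIR_ROUNDS):
            remaining = deadline - time.monotonic() if deadline else None
            if remaining is not None and remaining <= 0:
                return "timeout"
            status = self._solve_once(remaining)
            if status not in ("optimal", "feasible"):
                return status
            if self._polish():
                return status
            self._add_nogood_cut()
        raise SolverError(
            f"no verifiable incumbent after {self._MAX_REPAIR_ROUNDS} "
            f"repair rounds; the encoding is numerically unstable here")

    def _solve_once(self, time_limit: Optional[float]) -> str:
        # the MIP presolver silently drops delta-scale activity rows and
        # the default integer tolerance (1e-5) can misround a binary
        # sitting at delta/U; solve the relaxation explicitly (cold start:
        # warm-started bases can mask bound changes) and branch with tight
        # tolerances
        glp.glp_term_out(glp.GLP_OFF)
        glp.glp_std_basis(self._lp)
        smcp = glp.glp_smcp()
        glp.glp_init_smcp(smcp)
        smcp.msg_lev = glp.GLP_MSG_OFF
        if time_limit is not None:
            smcp.tm_lim = max(1, int(time_limit * 1000))
        rc = glp.glp_simplex(self._lp, smcp)
        if rc == glp.GLP_ETMLIM:
            return "timeout"
        if rc != 0:
            raise SolverError(f"GLPK glp_simplex returned code {rc}")
        lp_status = glp.glp_get_status(self._lp)
        if lp_status == glp.GLP_NOFEAS:
            return "infeasible"
        if lp_status != glp.GLP_OPT:
            return "failed"

        parm = glp.glp_iocp()
        glp.glp_init_iocp(parm)
        parm.presolve = glp.GLP_OFF
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.tol_int = 1e-09
        parm.tol_obj = 1e-09
        if time_limit is not None:
            parm.tm_lim = max(1, int(time_limit * 1000))
        rc = glp.glp_intopt(self._lp, parm)
        if rc == glp.GLP_ENOPFS or rc == glp.GLP_ENODFS:
            return "infeasible"
        status = glp.glp_mip_status(self._lp)
        if rc == glp.GLP_ETMLIM:
            return "feasible" if status == glp.GLP_FEAS else "timeout"
        if rc != 0:
            raise SolverError(f"GLPK glp_intopt returned code {rc}")
        return {glp.GLP_OPT: "optimal", glp.GLP_FEAS: "feasible",
                glp.GLP_NOFEAS: "infeasible"}.get(status, "failed")

    def _binary_cols(self):
        return [(name, self._col_of[name]) for name in self._names
                if glp.glp_get_col_kind(self._lp, self._col_of[name])
                != glp.GLP_CV]

    def _polish(self) -> bool:
        """Cold-started LP with binaries fixed at their rounded MIP values.

        Returns True and stores verified values on success; False when the
        incumbent's binary assignment has no feasible flux completion.
        """
        lp = self._lp
        saved = []
        for name, j in self._binary_cols():
            saved.append((j, glp.glp_get_col_type(lp, j),
                          glp.glp_get_col_lb(lp, j), glp.glp_get_col_ub(lp, j)))
            val = round(glp.glp_mip_col_val(lp, j))
            glp.glp_set_col_bnds(lp, j, glp.GLP_FX, val, val)
        self._binary_vals = {name: float(round(glp.glp_mip_col_val(lp, j)))
                             for name, j in self._binary_cols()}
        glp.glp_std_basis(lp)
        smcp = glp.glp_smcp()
        glp.glp_init_smcp(smcp)
        smcp.msg_lev = glp.GLP_MSG_OFF
        rc = glp.glp_simplex(lp, smcp)
        ok = rc == 0 and glp.glp_get_status(lp) == glp.GLP_OPT
        self._polished = ok
        if ok:
            self._cont_vals = {
                name: glp.glp_get_col_prim(lp, self._col_of[name])
                for name in self._names
                if glp.glp_get_col_kind(lp, self._col_of[name]) == glp.GLP_CV}
        for j, ctype, lb, ub in saved:
            if ctype == glp.GLP_FR:
                glp.glp_set_col_bnds(lp, j, glp.GLP_FR, 0.0, 0.0)
            else:
                self._set_bounds(j, lb, ub, col=True)
        return ok

    def _add_nogood_cut(self) -> None:
        """Forbid the current (unverifiable) binary assignment."""
        lp = self._lp
        i = glp.glp_add_rows(lp, 1)
        glp.glp_set_row_name(lp, i, _sanitize("nogood", self._taken))
        cols = self._binary_cols()
        ind = glp.intArray(len(cols) + 1)
        val = glp.doubleArray(len(cols) + 1)
        lb = 1.0
        for k, (name, j) in enumerate(cols, start=1):
            ind[k] = j
            if self._binary_vals[name] > 0.5:
                val[k] = -1.0
                lb -= 1.0
            else:
                val[k] = 1.0
        glp.glp_set_mat_row(lp, i, len(cols), ind, val)
        glp.glp_set_row_bnds(lp, i, glp.GLP_LO, lb, 0.0)

    def values(self) -> dict[str, float]:
        out = {}
        for name in self._names:
            j = self._col_of[name]
            if (getattr(self, "_polished", False)
                    and glp.glp_get_col_kind(self._lp, j) == glp.GLP_CV):
                out[name] = self._cont_vals[name]
            elif name in getattr(self, "_binary_vals", {}):
                out[name] = self._binary_vals[name]
            else:
                out[name] = glp.glp_mip_col_val(self._lp, j)
        return out

    def objective_value(self) -> float:
        return glp.glp_mip_obj_val(self._lp)

    def write_lp(self, path) -> None:
        glp.glp_write_lp(self._lp, None, str(path))


_BACKENDS = {"glpk": GlpkBackend}


def get_backend(name="glpk"):
    """Instantiate a backend by name; an instance passes through unchanged."""
    if not isinstance(name, str):
        return name
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise SolverError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}") from None
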