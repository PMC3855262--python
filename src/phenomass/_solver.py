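"""Thin deterministic wrappers around scipy's HiGHS LP/MILP interfaces.

All optimization in the package goes through these two entry points so that
solver options (tolerances, determinism) are controlled in one place.
Variable order is always supplied pre-sorted by the caller, which together
with HiGHS's deterministic single-threaded default makes repeated solves
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from phenomass.errors import SolverError

#: HiGHS status codes for scipy.optimize.milp / linprog
_STATUS_OPTIMAL = 0
_STATUS_INFEASIBLE = 2


@dataclass
class SolveResult:
    feasible: bool
    objective: Optional[float]
    x: Optional[np.ndarray]


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sp.spmatrix],
    b_eq: Optional[np.ndarray],
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[sp.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    maximize: bool = False,
) -> SolveResult:
    """Solve a linear program; returns objective on the caller's scale."""
    obj = -np.asarray(c, dtype=float) if maximize else np.asarray(c, dtype=float)
    res = linprog(
        obj,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == _STATUS_INFEASIBLE:
        return SolveResult(False, None, None)
    if res.status != _STATUS_OPTIMAL:
        raise SolverError(f"LP solve failed: {res.message}")
    val = -res.fun if maximize else res.fun
    return SolveResult(True, float(val), np.asarray(res.x))


def solve_milp(
    c: np.ndarray,
    constraints: Sequence[LinearConstraint],
    integrality: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    maximize: bool = False,
    mip_rel_gap: float = 0.0,
) -> SolveResult:
    """Solve a mixed-integer linear program to proven optimality
    (absolute gap 0 by default, as the objectives used here are integral)."""
    obj = -np.asarray(c, dtype=float) if maximize else np.asarray(c, dtype=float)
    res = milp(
        obj,
        constraints=list(constraints),
        integrality=np.asarray(integrality),
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": mip_rel_gap},
    )
    if res.status == _STATUS_INFEASIBLE:
        return SolveResult(False, None, None)
    if res.status != _STATUS_OPTIMAL:
        raise SolverError(f"MILP solve failed: {res.message}")
    val = -res.fun if maximize else res.fun
    return SolveResult(True, float(val), np.asarray(res.x))


def coupling_constraints(net, rxn_ids: Sequence[str], n_extra: int = 0):
    """Translate a network's linear coupling constraints into
    ``LinearConstraint`` rows over ``[v, extra]`` variable vectors."""
    if not net.coupling:
        return []
    pos = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids) + n_extra
    out = []
    for cc in net.coupling:
        row = sp.lil_matrix((1, n))
        for rid, coef in cc.coefficients.items():
            row[0, pos[rid]] = coef
        row = row.tocsr()
        if cc.relation == "=":
            out.append(LinearConstraint(row, cc.rhs, cc.rhs))
        elif cc.relation == "<=":
            out.append(LinearConstraint(row, -np.inf, cc.rhs))
        else:
            out.append(LinearConstraint(row, cc.rhs, np.inf))
    return out
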