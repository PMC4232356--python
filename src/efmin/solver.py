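"""Thin LP backend abstraction.

All methods in this package reduce to linear programs of the form
``min c @ x  s.t.  A_eq @ x = b_eq,  A_ub @ x <= b_ub,  l <= x <= u``.
They go through :func:`solve_lp` so the backend (currently scipy's HiGHS)
is interchangeable; HiGHS supports native infinite bounds, so unbounded
fluxes need no big-M surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None
    objective: float | None
    message: str = ""


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    A_ub=None,
    b_ub=None,
    bounds=None,
) -> LPResult:
    """Solve an LP with HiGHS; statuses collapse to optimal/infeasible/unbounded."""
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    if status == OPTIMAL:
        return LPResult(OPTIMAL, np.asarray(res.x), float(res.fun), res.message)
    return LPResult(status, None, None, res.message)


def vstack(blocks):
    """Sparse vertical stack, tolerant of empty block lists."""
    blocks = [b for b in blocks if b is not None and b.shape[0] > 0]
    if not blocks:
        return None
    return sparse.vstack(blocks, format="csr")
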