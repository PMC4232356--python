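"""Independent brute-force oracle for weighted absolute-flux minimization.

Enumerates the basic feasible solutions (vertices) of the polytope
{S r = 0, lb <= r <= ub, r_biomass >= epsilon} by activating every choice of
n - m candidate constraints (finite bounds plus the biomass floor) and
solving the resulting square linear system.  The minimum of sum w_i |r_i|
over feasible vertices equals the LP optimum for any non-negative weights,
because the objective is concave-free (piecewise linear convex) and the
polytope is pointed on the fixtures used (all lower bounds finite).

Deliberately naive: no LP machinery shared with the package.
"""

import itertools
import math

import numpy as np


def brute_force_min(model, weights, epsilon, tol=1e-9):
    """Return (best objective, best flux vector) over enumerated vertices."""
    S = model.stoichiometric_matrix()
    m, n = S.shape
    ids = model.reaction_ids
    bio = ids.index(model.biomass_reaction_id)
    w = np.array([weights[rid] for rid in ids])
    bounds = model.bounds()

    candidates = []
    for j, (lb, ub) in enumerate(bounds):
        if math.isfinite(lb):
            candidates.append((j, lb))
        if math.isfinite(ub):
            candidates.append((j, ub))
    candidates.append((bio, epsilon))

    best_obj, best_r = math.inf, None
    for combo in itertools.combinations(candidates, n - m):
        A = np.zeros((n, n))
        b = np.zeros(n)
        A[:m] = S
        for k, (j, val) in enumerate(combo):
            A[m + k, j] = 1.0
            b[m + k] = val
        try:
            r = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.abs(S @ r) <= tol):
            continue
        feasible = all(
            lb - tol <= r[j] <= ub + tol for j, (lb, ub) in enumerate(bounds)
        ) and r[bio] >= epsilon - tol
        if not feasible:
            continue
        obj = float(w @ np.abs(r))
        if obj < best_obj:
            best_obj, best_r = obj, r
    return best_obj, best_r
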