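"""The E-Fmin linear program, solution normalization, and FVA.

E-Fmin predicts a steady-state flux distribution by minimizing the weighted
sum of flux magnitudes

    min  sum_i w_i * |r_i|
    s.t. S @ r = 0
         r_L <= r <= r_U
         r_B >= epsilon

where ``w_i = 1 - g_i`` comes from normalized expression and ``r_B`` is the
biomass flux.  ``epsilon`` is an arbitrary small positive flux: because the
feasible set and objective are positively homogeneous, the optimal flux
pattern scales linearly with epsilon, so solutions normalized to a common
reference flux are invariant to its choice.

The absolute values are linearized with one auxiliary magnitude variable per
reaction: minimize ``sum w_i * t_i`` subject to ``t_i >= r_i`` and
``t_i >= -r_i``; at any optimum with w_i > 0, t_i = |r_i|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import sparse

from .expression import WeightVector
from .model import MetabolicModel
from .solver import OPTIMAL, LPResult, solve_lp


@dataclass
class EfminConfig:
    """Numerical settings.

    epsilon
        Lower bound on biomass flux, mmol/(gDW*h).  Any positive value gives
        the same normalized solution; 0.01 is the conventional default.
    big_bound
        When set, replaces infinite flux bounds with +/-big_bound for
        backends without native unboundedness.  None keeps true infinities.
    tolerance
        Feasibility tolerance used when checking S @ r = 0 and classifying a
        flux as nonzero.
    """

    epsilon: float = 0.01
    big_bound: float | None = None
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class FluxDistribution:
    """A solved flux vector with solver status and objective value."""

    fluxes: dict[str, float]
    objective: float | None
    status: str
    biomass_flux: float | None = None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def active_set(self, tol: float = 1e-6) -> set[str]:
        """Reactions carrying flux of magnitude above ``tol``."""
        return {rid for rid, v in self.fluxes.items() if abs(v) > tol}

    def vector(self, reaction_ids) -> np.ndarray:
        return np.array([self.fluxes[rid] for rid in reaction_ids])

    def to_tsv(self, path: str | Path, fva: "FvaRange | None" = None) -> None:
        lines = ["reaction_id\tflux" + ("\tfva_min\tfva_max" if fva else "")]
        for rid, v in self.fluxes.items():
            row = f"{rid}\t{v:.10g}"
            if fva:
                row += f"\t{fva.minimum[rid]:.10g}\t{fva.maximum[rid]:.10g}"
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FvaRange:
    """Per-reaction flux range at the fixed optimal weighted-flux objective."""

    minimum: dict[str, float]
    maximum: dict[str, float]

    def width(self, rid: str) -> float:
        return self.maximum[rid] - self.minimum[rid]


def _resolve_weights(model: MetabolicModel, weights: WeightVector | None) -> np.ndarray:
    if weights is None:
        return np.ones(model.n)
    try:
        return np.array([weights.w[r.id] for r in model.reactions])
    except KeyError as exc:
        raise ValueError(f"weight vector missing reaction {exc.args[0]!r}") from None


def _clip_bounds(model: MetabolicModel, big: float | None):
    bounds = []
    for lb, ub in model.bounds():
        if big is not None:
            lb = max(lb, -big)
            ub = min(ub, big)
        bounds.append((None if math.isinf(lb) else lb, None if math.isinf(ub) else ub))
    return bounds


def _abs_min_lp(
    model: MetabolicModel,
    w: np.ndarray,
    required_fluxes: Mapping[str, float],
    big: float | None,
):
    """Assemble the split-variable LP: variables x = [r (n), t (n)]."""
    n = model.n
    S = sparse.csr_matrix(model.stoichiometric_matrix())
    A_eq = sparse.hstack([S, sparse.csr_matrix(S.shape)], format="csr") if S.shape[0] else None
    b_eq = np.zeros(S.shape[0]) if S.shape[0] else None

    I = sparse.identity(n, format="csr")
    rows = [sparse.hstack([I, -I]), sparse.hstack([-I, -I])]  # r - t <= 0, -r - t <= 0
    b_ub = [np.zeros(n), np.zeros(n)]
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rid, minimum in required_fluxes.items():
        row = sparse.csr_matrix(
            ([-1.0], ([0], [idx[rid]])), shape=(1, 2 * n)
        )  # -r_rid <= -minimum
        rows.append(row)
        b_ub.append(np.array([-minimum]))
    A_ub = sparse.vstack(rows, format="csr")
    b_ub = np.concatenate(b_ub)

    c = np.concatenate([np.zeros(n), w])
    bounds = _clip_bounds(model, big) + [(0, None)] * n
    return c, A_eq, b_eq, A_ub, b_ub, bounds


def _to_distribution(
    model: MetabolicModel, res: LPResult, objective_from_x=None
) -> FluxDistribution:
    if res.status != OPTIMAL:
        return FluxDistribution({}, None, res.status)
    n = model.n
    r = res.x[:n]
    fluxes = dict(zip(model.reaction_ids, map(float, r)))
    biomass = fluxes.get(model.biomass_reaction_id)
    obj = objective_from_x(res.x) if objective_from_x else res.objective
    return FluxDistribution(fluxes, float(obj), OPTIMAL, biomass)


def solve_efmin(
    model: MetabolicModel,
    weights: WeightVector | None = None,
    config: EfminConfig | None = None,
    required_fluxes: Mapping[str, float] | None = None,
) -> FluxDistribution:
    """Solve the E-Fmin LP.

    ``weights`` defaults to uniform 1 (pure flux minimization).
    ``required_fluxes`` maps reaction ids to minimum fluxes; by default the
    single biomass reaction is required to carry at least ``config.epsilon``,
    but any set of required functionalities may be imposed instead.
    """
    config = config or EfminConfig()
    w = _resolve_weights(model, weights)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if required_fluxes is None:
        if not model.biomass_reaction_id:
            raise ValueError("model has no biomass reaction and no required_fluxes given")
        required_fluxes = {model.biomass_reaction_id: config.epsilon}
    c, A_eq, b_eq, A_ub, b_ub, bounds = _abs_min_lp(model, w, required_fluxes, config.big_bound)
    res = solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds)
    return _to_distribution(model, res)


def normalize_fluxes(
    sol: FluxDistribution,
    reference_reaction: str,
    reference_value: float,
    tolerance: float = 1e-12,
) -> FluxDistribution:
    """Rescale all fluxes so |flux(reference_reaction)| equals reference_value.

    E-Fmin solutions are defined up to the overall scale set by epsilon;
    normalizing to a measured reference flux (e.g. glucose uptake = 100)
    puts them on an absolute scale.
    """
    ref = sol.fluxes.get(reference_reaction)
    if ref is None:
        raise KeyError(reference_reaction)
    if abs(ref) <= tolerance:
        raise ValueError(
            f"cannot normalize: reference reaction {reference_reaction!r} carries no flux"
        )
    factor = reference_value / abs(ref)
    return FluxDistribution(
        {rid: v * factor for rid, v in sol.fluxes.items()},
        sol.objective if sol.objective is None else sol.objective * factor,
        sol.status,
        None if sol.biomass_flux is None else sol.biomass_flux * factor,
    )


def run_fva(
    model: MetabolicModel,
    weights: WeightVector | None = None,
    config: EfminConfig | None = None,
    fraction: float = 1.0,
    required_fluxes: Mapping[str, float] | None = None,
) -> FvaRange:
    """Flux variability analysis at the E-Fmin optimum.

    First solves the E-Fmin LP for the optimal weighted objective z*, then
    minimizes and maximizes each reaction flux subject to the original
    constraints plus ``sum w_i t_i <= fraction * z*`` (fraction >= 1 allows
    slack).  Near-degenerate ranges indicate a practically unique optimum.
    """
    if fraction < 1.0:
        raise ValueError("fraction must be >= 1")
    config = config or EfminConfig()
    w = _resolve_weights(model, weights)
    if required_fluxes is None:
        required_fluxes = {model.biomass_reaction_id: config.epsilon}
    base = solve_efmin(model, weights, config, required_fluxes)
    if base.status != OPTIMAL:
        raise RuntimeError(f"E-Fmin LP not optimal (status={base.status}); FVA undefined")
    n = model.n
    c0, A_eq, b_eq, A_ub, b_ub, bounds = _abs_min_lp(model, w, required_fluxes, config.big_bound)
    # pin the objective: w @ t <= fraction * z* (tiny absolute slack guards z* = 0)
    cap = fraction * base.objective + 1e-12
    obj_row = sparse.csr_matrix(np.concatenate([np.zeros(n), w])[None, :])
    A_ub = sparse.vstack([A_ub, obj_row], format="csr")
    b_ub = np.concatenate([b_ub, [cap]])

    minimum: dict[str, float] = {}
    maximum: dict[str, float] = {}
    for j, rid in enumerate(model.reaction_ids):
        c = np.zeros(2 * n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds)
        hi = solve_lp(-c, A_eq, b_eq, A_ub, b_ub, bounds)
        if lo.status != OPTIMAL or hi.status != OPTIMAL:
            raise RuntimeError(f"FVA subproblem for {rid!r} not optimal")
        minimum[rid] = float(lo.objective)
        maximum[rid] = float(-hi.objective)
    return FvaRange(minimum, maximum)
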