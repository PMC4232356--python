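"""Benchmark methods: classical FBA, FBA with flux minimization, GIMME, E-Flux.

These share the feasibility contract of the E-Fmin core (S @ r = 0, bounds)
and its LP backend, differing only in objective and expression handling:

* FBA maximizes a target flux (biomass); classical FBA can leave fluxes
  stuck at arbitrary bounds when optima are degenerate.
* pFBA ("FBA with flux minimization") fixes the FBA optimum and minimizes
  total absolute flux as a secondary objective, removing such outliers.
* GIMME minimizes flux through under-expressed reactions (weights
  ``max(cutoff - g, 0)``) while forcing required metabolic functionalities
  (by default biomass) above a fraction of their FBA maximum.
* E-Flux caps each reaction's bounds in proportion to its expression and
  then maximizes biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .core import EfminConfig, FluxDistribution, solve_efmin
from .expression import ReactionExpression, compute_weights
from .model import MetabolicModel
from .solver import OPTIMAL, solve_lp


@dataclass
class GimmeConfig:
    """GIMME settings: RMF reactions held >= rmf_threshold x their FBA max,
    expression cutoff for penalization."""

    rmf_reactions: set[str] | None = None  # None -> {biomass}
    rmf_threshold: float = 0.90
    g_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.rmf_threshold <= 1.0):
            raise ValueError("rmf_threshold must be in (0, 1]")
        if not (0.0 < self.g_cutoff <= 1.0):
            raise ValueError("g_cutoff must be in (0, 1]")


@dataclass
class EfluxConfig:
    """E-Flux settings; bound_scale converts normalized expression to a flux cap.

    bound_scale=None picks the model's largest finite bound magnitude, or
    1e3 when the model is entirely unbounded.
    """

    bound_scale: float | None = None

    def resolve_scale(self, model: MetabolicModel) -> float:
        if self.bound_scale is not None:
            if self.bound_scale <= 0:
                raise ValueError("bound_scale must be positive")
            return self.bound_scale
        finite = [
            abs(b) for lb, ub in model.bounds() for b in (lb, ub) if math.isfinite(b) and b != 0
        ]
        return max(finite) if finite else 1e3


def solve_fba(model: MetabolicModel, objective_reaction: str | None = None) -> FluxDistribution:
    """Classical FBA: maximize one reaction's flux under S @ r = 0 and bounds.

    Returns one optimal vertex; with no bounded uptake the LP is unbounded
    and the returned status says so.
    """
    objective_reaction = objective_reaction or model.biomass_reaction_id
    j = model.reaction_ids.index(objective_reaction)
    S = model.stoichiometric_matrix()
    c = np.zeros(model.n)
    c[j] = -1.0  # maximize
    bounds = [
        (None if math.isinf(lb) else lb, None if math.isinf(ub) else ub)
        for lb, ub in model.bounds()
    ]
    A_eq = sparse.csr_matrix(S) if S.shape[0] else None
    b_eq = np.zeros(S.shape[0]) if S.shape[0] else None
    res = solve_lp(c, A_eq, b_eq, None, None, bounds)
    if res.status != OPTIMAL:
        return FluxDistribution({}, None, res.status)
    fluxes = dict(zip(model.reaction_ids, map(float, res.x)))
    return FluxDistribution(
        fluxes, float(fluxes[objective_reaction]), OPTIMAL, fluxes.get(model.biomass_reaction_id)
    )


def solve_pfba(model: MetabolicModel, objective_reaction: str | None = None) -> FluxDistribution:
    """FBA with flux minimization: fix the FBA optimum, minimize sum |r_i|.

    The secondary uniform-weight minimization reuses the E-Fmin split-variable
    linearization and removes bound-saturated degenerate solutions.
    """
    objective_reaction = objective_reaction or model.biomass_reaction_id
    fba = solve_fba(model, objective_reaction)
    if fba.status != OPTIMAL:
        return fba
    v_star = fba.objective
    pinned = MetabolicModel(
        list(model.metabolites),
        [
            replace(r, lower_bound=v_star, upper_bound=v_star)
            if r.id == objective_reaction
            else replace(r)
            for r in model.reactions
        ],
        model.biomass_reaction_id,
    )
    sol = solve_efmin(
        pinned,
        weights=None,  # uniform
        config=EfminConfig(),
        required_fluxes={},  # objective already pinned via bounds
    )
    return FluxDistribution(sol.fluxes, sol.objective, sol.status, sol.fluxes.get(model.biomass_reaction_id) if sol.fluxes else None)


def solve_gimme(
    model: MetabolicModel,
    rexpr: ReactionExpression,
    cfg: GimmeConfig | None = None,
) -> FluxDistribution:
    """GIMME: minimize expression-penalized flux with RMFs held near optimal.

    For each required metabolic functionality (default: biomass) the FBA
    maximum v* is computed and the constraint flux >= rmf_threshold * v* is
    imposed; the objective uses weights ``max(g_cutoff - g_i, 0)``.
    """
    cfg = cfg or GimmeConfig()
    rmf = cfg.rmf_reactions or {model.biomass_reaction_id}
    required: dict[str, float] = {}
    for rid in rmf:
        fba = solve_fba(model, rid)
        if fba.status != OPTIMAL:
            return FluxDistribution({}, None, fba.status)
        required[rid] = cfg.rmf_threshold * fba.objective
    weights = compute_weights(rexpr, mode="gimme", g_cutoff=cfg.g_cutoff)
    return solve_efmin(model, weights, EfminConfig(), required_fluxes=required)


def solve_eflux(
    model: MetabolicModel,
    rexpr: ReactionExpression,
    cfg: EfluxConfig | None = None,
    objective_reaction: str | None = None,
) -> FluxDistribution:
    """E-Flux: expression-proportional flux caps, then biomass maximization.

    For each reaction with mapped expression g, the upper bound becomes
    ``scale * g`` (and the lower bound ``-scale * g`` if reversible);
    reactions without data keep their default bounds.  Zero expression on an
    essential reaction legitimately yields zero biomass.
    """
    cfg = cfg or EfluxConfig()
    scale = cfg.resolve_scale(model)
    capped = []
    for r in model.reactions:
        g = rexpr.g.get(r.id)
        if g is None:
            capped.append(replace(r))
            continue
        ub = min(r.upper_bound, scale * g)
        lb = max(r.lower_bound, -scale * g) if r.reversible else r.lower_bound
        capped.append(replace(r, lower_bound=lb, upper_bound=ub))
    capped_model = MetabolicModel(list(model.metabolites), capped, model.biomass_reaction_id)
    return solve_fba(capped_model, objective_reaction)
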