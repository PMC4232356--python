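"""Synthetic networks and expression profiles for testing and demos.

The centrepiece is a small branched network with nine reactions, five
internal metabolites and four substrate-to-sink pathways: one product-
forming path (P1 = r1, r2) and three biomass-forming paths of increasing
length (P2 = r1, r3, r9; P3 = r1, r4, r5, r9; P4 = r1, r6, r7, r8, r9).
It is deliberately underdetermined — nine unknown fluxes, five balances —
so the choice among pathways is made entirely by the weighted flux
minimization, which makes pathway-selection behavior easy to assert.

Also provided: a variant with a planted stoichiometrically balanced
3-reaction cycle (for loop-freeness checks), seeded random expression
profiles, and "planted path" conditions where one of several parallel
routes is fully expressed and should be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FluxDistribution
from .expression import ExpressionProfile
from .model import MetabolicModel, Metabolite, Reaction

#: Reaction sets of the four pathways of the toy network.
TOY_PATHWAYS = {
    "P1": {"r1", "r2"},
    "P2": {"r1", "r3", "r9"},
    "P3": {"r1", "r4", "r5", "r9"},
    "P4": {"r1", "r6", "r7", "r8", "r9"},
}


@dataclass
class SyntheticCondition:
    """A generated model + expression profile, optionally with known truth."""

    model: MetabolicModel
    profile: ExpressionProfile
    ground_truth_fluxes: FluxDistribution | None
    seed: int
    planted_reactions: set[str] | None = None


def build_toy_network() -> MetabolicModel:
    """The 9-reaction / 5-internal-metabolite branched demo network.

    All reactions are irreversible with (0, inf) bounds; r9 (B -> biomass)
    is the biomass reaction.  Each reaction carries an identity GPR
    ``g1``..``g9``.
    """
    mets = [
        Metabolite("S_ext", "substrate", internal=False),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("C"),
        Metabolite("D"),
        Metabolite("E"),
        Metabolite("P_ext", "product", internal=False),
        Metabolite("BM_ext", "biomass", internal=False),
    ]
    arcs = [
        ("r1", {"S_ext": -1, "A": 1}),
        ("r2", {"A": -1, "P_ext": 1}),
        ("r3", {"A": -1, "B": 1}),
        ("r4", {"A": -1, "C": 1}),
        ("r5", {"C": -1, "B": 1}),
        ("r6", {"A": -1, "D": 1}),
        ("r7", {"D": -1, "E": 1}),
        ("r8", {"E": -1, "B": 1}),
        ("r9", {"B": -1, "BM_ext": 1}),
    ]
    rxns = [
        Reaction(rid, stoich, reversible=False, gpr=f"g{rid[1:]}") for rid, stoich in arcs
    ]
    return MetabolicModel(mets, rxns, "r9")


def build_cycle_fixture() -> MetabolicModel:
    """Toy network plus a balanced internal 3-cycle A -> C -> D -> A.

    The cycle (c1, c2, c3) produces nothing net, so any flux around it is
    thermodynamically infeasible; flux minimization with strictly positive
    weights must leave it at zero, whereas a pure FBA objective is
    indifferent to it.
    """
    base = build_toy_network()
    cycle = [
        Reaction("c1", {"A": -1, "C": 1}, gpr="gc1"),
        Reaction("c2", {"C": -1, "D": 1}, gpr="gc2"),
        Reaction("c3", {"D": -1, "A": 1}, gpr="gc3"),
    ]
    return MetabolicModel(list(base.metabolites), list(base.reactions) + cycle, "r9")


def gen_expression(
    model: MetabolicModel, seed: int, missing_fraction: float = 0.0
) -> ExpressionProfile:
    """Seeded uniform(0, 1) expression for every gene of the model, with a
    chosen fraction of genes left unmeasured (to exercise the no-data path)."""
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes())
    values = {g: float(rng.uniform()) for g in genes}
    n_missing = int(round(missing_fraction * len(genes)))
    if n_missing:
        drop = rng.choice(genes, size=n_missing, replace=False)
        for g in drop:
            del values[g]
    return ExpressionProfile(values)


def gen_planted_condition(
    n_parallel_paths: int = 3,
    seed: int = 0,
    noise_sd: float = 0.05,
    baseline: float = 0.2,
) -> SyntheticCondition:
    """A substrate -> biomass network of parallel linear paths, one of which
    is the fully expressed "true" route.

    Each path is a chain of 2-4 internal conversions with seeded random
    length.  Genes on the designated path (and the shared uptake/biomass
    reactions) are expressed at the maximum (1.0); all other genes sit at a
    low baseline plus Gaussian noise, clipped to [0, 1] so the planted
    ordering survives.  Ground-truth fluxes route one unit through the
    designated path.
    """
    if n_parallel_paths < 2:
        raise ValueError("need at least 2 parallel paths")
    rng = np.random.default_rng(seed)
    mets = [Metabolite("S_ext", internal=False), Metabolite("X"), Metabolite("B")]
    rxns = [Reaction("uptake", {"S_ext": -1, "X": 1}, gpr="g_uptake")]
    paths: list[list[str]] = []
    for p in range(n_parallel_paths):
        length = int(rng.integers(2, 5))
        chain = [f"p{p}_m{k}" for k in range(length - 1)]
        for mid in chain:
            mets.append(Metabolite(mid))
        nodes = ["X", *chain, "B"]
        path_rxns = []
        for k in range(length):
            rid = f"p{p}_r{k}"
            rxns.append(
                Reaction(rid, {nodes[k]: -1, nodes[k + 1]: 1}, gpr=f"g_{rid}")
            )
            path_rxns.append(rid)
        paths.append(path_rxns)
    mets.append(Metabolite("BM_ext", internal=False))
    rxns.append(Reaction("biomass", {"B": -1, "BM_ext": 1}, gpr="g_biomass"))
    model = MetabolicModel(mets, rxns, "biomass")

    true_idx = int(rng.integers(n_parallel_paths))
    true_set = {"uptake", "biomass", *paths[true_idx]}
    values: dict[str, float] = {}
    for r in model.reactions:
        gene = r.gpr
        if r.id in true_set:
            values[gene] = 1.0
        else:
            values[gene] = float(np.clip(baseline + rng.normal(0.0, noise_sd), 0.0, 1.0))
    profile = ExpressionProfile(values)
    truth = FluxDistribution(
        {r.id: (1.0 if r.id in true_set else 0.0) for r in model.reactions},
        objective=0.0,
        status="optimal",
        biomass_flux=1.0,
    )
    return SyntheticCondition(model, profile, truth, seed, planted_reactions=true_set)
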