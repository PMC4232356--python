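"""Metabolic network representation.

A :class:`MetabolicModel` holds metabolites, reactions (with sparse
stoichiometry, directionality bounds and gene-protein-reaction rules) and the
identity of the biomass reaction.  Internal metabolites are the ones subject
to the steady-state mass balance ``S @ r = 0``; external (boundary)
metabolites are sources/sinks and are excluded from the stoichiometric
matrix.  Declaration order of metabolites and reactions is preserved so that
matrix rows/columns — and therefore LP bases — are reproducible across runs.

Models can be read from and written to a small JSON format, a one-line-per-
reaction TSV format, or read from SBML (through cobrapy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


class ModelError(ValueError):
    """Raised when a model fails validation or a file fails to parse."""


@dataclass
class Metabolite:
    """A chemical species.  ``internal=True`` means mass-balanced at steady state."""

    id: str
    name: str = ""
    internal: bool = True


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/(gDW*h).

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed, positive = produced).  ``gpr`` is a Boolean gene association
    rule ("g1 and (g2 or g3)"), empty when no genes are associated.
    Unbounded directions are represented by +/-inf.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    gpr: str = ""

    def __post_init__(self) -> None:
        lb_def, ub_def = _default_bounds(self.reversible)
        if self.lower_bound is None:
            self.lower_bound = lb_def
        if self.upper_bound is None:
            self.upper_bound = ub_def


def _default_bounds(reversible: bool) -> tuple[float, float]:
    return (-math.inf, math.inf) if reversible else (0.0, math.inf)


@dataclass
class MetabolicModel:
    """A validated stoichiometric network.

    Parameters
    ----------
    metabolites, reactions
        Declaration-ordered lists; ids must be unique within each list.
    biomass_reaction_id
        Id of the biomass-producing reaction (the flux ``r_B`` that the
        E-Fmin constraint keeps strictly positive).
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.internal]

    @property
    def m(self) -> int:
        """Number of internal (mass-balanced) metabolites."""
        return len(self.internal_metabolites)

    @property
    def n(self) -> int:
        """Number of reactions."""
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(rid) from None

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def genes(self) -> set[str]:
        """All gene ids appearing in any GPR rule."""
        from .expression import parse_gpr, gpr_genes

        out: set[str] = set()
        for r in self.reactions:
            tree = parse_gpr(r.gpr)
            if tree is not None:
                out |= gpr_genes(tree)
        return out

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelError(f"reaction {r.id!r} has empty stoichiometry")
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id!r}: lower bound exceeds upper bound")
            if not r.reversible and r.lower_bound < 0:
                raise ModelError(f"irreversible reaction {r.id!r} has negative lower bound")
        if self.biomass_reaction_id and self.biomass_reaction_id not in rxn_ids:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction_id!r} not present in model"
            )

    # -- matrices ----------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense (m x n) stoichiometric matrix over internal metabolites.

        Entry (i, j) is the coefficient of internal metabolite i in reaction
        j; external metabolites are excluded.  Row/column order follows
        declaration order.
        """
        internal = self.internal_metabolites
        index = {m.id: i for i, m in enumerate(internal)}
        S = np.zeros((len(internal), self.n))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                i = index.get(met)
                if i is not None:
                    S[i, j] = coef
        return S

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    # -- bound policies ----------------------------------------------------

    def apply_thermodynamic_bounds(
        self, big: float = math.inf, keep_finite: bool = True
    ) -> "MetabolicModel":
        """Return a copy with directionality-only bounds.

        Reversible reactions get (-big, +big) and irreversible ones
        (0, +big).  With ``keep_finite=True`` (default) pre-existing finite
        bounds — e.g. a measured glucose uptake — are preserved; set it to
        False to discard all condition-specific bounds so that flux
        magnitudes vary freely, which is the convention for expression-only
        predictions.
        """
        if big <= 0:
            raise ValueError("big must be positive")
        new_rxns = []
        for r in self.reactions:
            lb_def, ub_def = (-big, big) if r.reversible else (0.0, big)
            lb, ub = r.lower_bound, r.upper_bound
            if keep_finite:
                lb = lb if math.isfinite(lb) else lb_def
                ub = ub if math.isfinite(ub) else ub_def
            else:
                lb, ub = lb_def, ub_def
            new_rxns.append(replace(r, lower_bound=lb, upper_bound=ub))
        return MetabolicModel(list(self.metabolites), new_rxns, self.biomass_reaction_id)


# -- file formats ----------------------------------------------------------


def to_json(model: MetabolicModel) -> str:
    def _b(x: float) -> float | None:
        return None if math.isinf(x) else x

    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "internal": m.internal} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoichiometry,
                "reversible": r.reversible,
                "lb": _b(r.lower_bound),
                "ub": _b(r.upper_bound),
                "gpr": r.gpr,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
    }
    return json.dumps(doc, indent=1)


def from_json(text: str) -> MetabolicModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"invalid model JSON: {exc}") from exc
    try:
        mets = [
            Metabolite(d["id"], d.get("name", ""), bool(d.get("internal", True)))
            for d in doc["metabolites"]
        ]
        rxns = []
        for d in doc["reactions"]:
            rev = bool(d.get("reversible", False))
            lb = d.get("lb")
            ub = d.get("ub")
            lb_def, ub_def = _default_bounds(rev)
            rxns.append(
                Reaction(
                    d["id"],
                    {k: float(v) for k, v in d["stoich"].items()},
                    reversible=rev,
                    lower_bound=lb_def if lb is None else float(lb),
                    upper_bound=ub_def if ub is None else float(ub),
                    gpr=d.get("gpr", "") or "",
                )
            )
        return MetabolicModel(mets, rxns, doc.get("biomass", ""))
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model record: {exc!r}") from exc


def _parse_stoich(spec: str, rid: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for item in spec.split(";"):
        item = item.strip()
        if not item:
            continue
        met, _, coef = item.rpartition(":")
        if not met:
            raise ModelError(f"reaction {rid!r}: bad stoichiometry item {item!r}")
        try:
            out[met.strip()] = float(coef)
        except ValueError:
            raise ModelError(f"reaction {rid!r}: bad coefficient in {item!r}") from None
    return out


def from_tsv(text: str, biomass: str = "") -> MetabolicModel:
    """Parse the one-reaction-per-line TSV format.

    Columns: id, reversible flag (0/1), gpr, stoichiometry as
    "met:coef;met:coef".  Metabolites are created on first mention;
    metabolites named with a trailing marker are NOT special-cased — a
    leading ``@`` on a metabolite id in the stoichiometry marks it external.
    """
    rxns: list[Reaction] = []
    met_order: dict[str, bool] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ModelError(f"line {lineno}: expected 4 tab-separated fields")
        rid, rev, gpr, stoich_spec = parts
        stoich_raw = _parse_stoich(stoich_spec, rid)
        stoich: dict[str, float] = {}
        for met, coef in stoich_raw.items():
            external = met.startswith("@")
            mid = met.lstrip("@")
            stoich[mid] = coef
            if mid not in met_order:
                met_order[mid] = not external
        reversible = rev.strip() in {"1", "true", "True"}
        lb, ub = _default_bounds(reversible)
        rxns.append(Reaction(rid, stoich, reversible, lb, ub, gpr.strip()))
    mets = [Metabolite(mid, internal=internal) for mid, internal in met_order.items()]
    return MetabolicModel(mets, rxns, biomass)


def from_sbml(path: str | Path, biomass_reaction_id: str | None = None) -> MetabolicModel:
    """Read an SBML model through cobrapy and convert it.

    fbc gene associations are preserved verbatim as GPR strings.  Boundary
    species (``boundaryCondition=true``) are dropped by the cobrapy reader
    and therefore simply do not constrain the matrix, which matches marking
    them external.  When ``biomass_reaction_id`` is omitted, the model's
    declared objective reaction is used.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.name or "", True) for m in cm.metabolites]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                r.id,
                {m.id: float(c) for m, c in r.metabolites.items()},
                reversible=r.lower_bound < 0,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
            )
        )
    if biomass_reaction_id is None:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if not coeffs:
            raise ModelError("SBML model declares no objective; pass biomass_reaction_id")
        biomass_reaction_id = next(iter(coeffs)).id
    return MetabolicModel(mets, rxns, biomass_reaction_id)


def load_model(
    path: str | Path, format: str | None = None, biomass: str | None = None
) -> MetabolicModel:
    """Load a model from JSON, TSV or SBML, inferring the format from the suffix."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".json": "json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(suffix)
        if format is None:
            raise ModelError(f"cannot infer model format from suffix {suffix!r}")
    if format == "json":
        return from_json(path.read_text())
    if format == "tsv":
        return from_tsv(path.read_text(), biomass or "")
    if format == "sbml":
        return from_sbml(path, biomass)
    raise ModelError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the package JSON format (lossless round-trip)."""
    Path(path).write_text(to_json(model))
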