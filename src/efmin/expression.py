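"""Mapping gene expression onto reactions through GPR rules.

Gene-protein-reaction (GPR) rules are Boolean expressions over gene ids.
``AND`` encodes an enzyme complex — every subunit is required, so the
complex's effective expression is the *minimum* over the genes — and ``OR``
encodes isozymes, so the effective expression is the *maximum*.  After
mapping, reaction-level values are divided by their maximum so that
normalized expression ``g_i`` lies in [0, 1], and the E-Fmin weight is the
linearly decreasing function ``w_i = 1 - g_i`` (reactions with no measured
gene get weight 1).  GIMME-style weights ``max(cutoff - g_i, 0)`` are also
provided, with a default cutoff of 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Union

from .model import MetabolicModel


class GprParseError(ValueError):
    """Raised on malformed GPR rules; message includes the character position."""


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class BoolOp:
    op: Literal["and", "or"]
    children: tuple["GprNode", ...]


GprNode = Union[Gene, BoolOp]


# -- parser ----------------------------------------------------------------

_OPS = {"and", "or"}


def _tokenize(rule: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(rule)
    while i < n:
        c = rule[i]
        if c.isspace():
            i += 1
        elif c in "()":
            tokens.append(("paren", c, i))
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            word = rule[i:j]
            kind = "op" if word.lower() in _OPS else "gene"
            tokens.append((kind, word, i))
            i = j
    return tokens


class _Parser:
    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def error(self, msg: str, at: int | None = None) -> GprParseError:
        tok = self.peek()
        where = at if at is not None else (tok[2] if tok else len(self.rule))
        return GprParseError(f"{msg} at position {where} in rule {self.rule!r}")

    def parse(self) -> GprNode:
        node = self.parse_or()
        if self.peek() is not None:
            raise self.error("unexpected token")
        return node

    def parse_or(self) -> GprNode:
        children = [self.parse_and()]
        while (tok := self.peek()) and tok[0] == "op" and tok[1].lower() == "or":
            self.pos += 1
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def parse_and(self) -> GprNode:
        children = [self.parse_atom()]
        while (tok := self.peek()) and tok[0] == "op" and tok[1].lower() == "and":
            self.pos += 1
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def parse_atom(self) -> GprNode:
        tok = self.peek()
        if tok is None:
            raise self.error("dangling operator or empty expression")
        kind, word, at = tok
        if kind == "gene":
            self.pos += 1
            return Gene(word)
        if kind == "paren" and word == "(":
            self.pos += 1
            node = self.parse_or()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise self.error("unbalanced parenthesis opened", at)
            self.pos += 1
            return node
        raise self.error(f"unexpected {word!r}")


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a GPR rule into an expression tree; empty/blank rules give None.

    Operators are case-insensitive; AND binds tighter than OR, so
    ``A and B or C`` parses as ``(A and B) or C``.
    """
    if not rule or not rule.strip():
        return None
    return _Parser(rule).parse()


def gpr_genes(tree: GprNode) -> set[str]:
    if isinstance(tree, Gene):
        return {tree.name}
    out: set[str] = set()
    for c in tree.children:
        out |= gpr_genes(c)
    return out


def evaluate_gpr(
    tree: GprNode,
    values: Mapping[str, float],
    missing: Literal["ignore", "propagate"] = "ignore",
) -> float | None:
    """Evaluate a GPR tree: AND -> min, OR -> max of child expression values.

    A gene absent from ``values`` evaluates to ``None`` (missing).  Under the
    default ``missing='ignore'`` policy, min/max are taken over the measured
    children only and a node with no measured child is itself missing; under
    ``'propagate'``, a missing child poisons an AND (complex incomplete) but
    is still skipped in an OR.
    """
    if isinstance(tree, Gene):
        return values.get(tree.name)
    vals = [evaluate_gpr(c, values, missing) for c in tree.children]
    if tree.op == "and" and missing == "propagate" and any(v is None for v in vals):
        return None
    present = [v for v in vals if v is not None]
    if not present:
        return None
    return min(present) if tree.op == "and" else max(present)


# -- profiles and mapped values -------------------------------------------


@dataclass
class ExpressionProfile:
    """Absolute expression levels per gene (arbitrary non-negative units)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.values.items() if v < 0 or not math.isfinite(v)]
        if bad:
            raise ValueError(f"expression values must be finite and >= 0; bad genes: {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionProfile":
        """Two-column TSV ``gene_id <tab> value``; header optional; duplicate ids error."""
        values: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, val = parts[0].strip(), parts[1].strip()
            try:
                v = float(val)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value {val!r}") from None
            if gene in values:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            values[gene] = v
        return cls(values)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{g}\t{v:g}" for g, v in self.values.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ReactionExpression:
    """Normalized per-reaction expression g_i in [0, 1].

    ``g`` contains only reactions with at least one measured associated gene;
    reactions absent from ``g`` are "missing" and later receive the
    no-data weight.  ``reaction_ids`` lists every reaction of the source
    model so weight vectors can be completed.
    """

    reaction_ids: list[str]
    g: dict[str, float]

    def __post_init__(self) -> None:
        for rid, v in self.g.items():
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"normalized expression out of [0,1] for {rid}: {v}")


@dataclass
class WeightVector:
    """Per-reaction objective weights w_i in [0, 1] (0 = unpenalized)."""

    w: dict[str, float]
    mode: str = "efmin"
    g_cutoff: float = 1.0

    def __getitem__(self, rid: str) -> float:
        return self.w[rid]

    @classmethod
    def uniform(cls, reaction_ids: Iterable[str], value: float = 1.0) -> "WeightVector":
        return cls({rid: value for rid in reaction_ids}, mode="uniform")


def map_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    missing: Literal["ignore", "propagate"] = "ignore",
) -> ReactionExpression:
    """Map a gene expression profile onto reactions and normalize to [0, 1].

    Each reaction with a non-empty GPR and at least one measured gene gets
    the min/max-evaluated rule value; all mapped values are then divided by
    their maximum (one global maximum, not per pathway).
    """
    raw: dict[str, float] = {}
    for r in model.reactions:
        tree = parse_gpr(r.gpr)
        if tree is None:
            continue
        val = evaluate_gpr(tree, profile.values, missing)
        if val is not None:
            raw[r.id] = val
    if not raw:
        warnings.warn("no reaction received expression data; all weights will default")
        return ReactionExpression(model.reaction_ids, {})
    top = max(raw.values())
    if top <= 0:  # all-zero profile: every mapped reaction is fully off
        g = {rid: 0.0 for rid in raw}
    else:
        g = {rid: v / top for rid, v in raw.items()}
    return ReactionExpression(model.reaction_ids, g)


def compute_weights(
    rexpr: ReactionExpression,
    mode: Literal["efmin", "gimme"] = "efmin",
    g_cutoff: float = 0.05,
) -> WeightVector:
    """Convert normalized reaction expression to objective weights.

    E-Fmin: ``w_i = 1 - g_i`` (cutoff fixed at the maximum, i.e. 1); a
    reaction with no data gets w = 1.  GIMME: ``w_i = max(cutoff - g_i, 0)``;
    a reaction with no data gets w = cutoff.
    """
    if mode == "efmin":
        w = {rid: 1.0 - rexpr.g.get(rid, 0.0) for rid in rexpr.reaction_ids}
        return WeightVector(w, mode="efmin", g_cutoff=1.0)
    if mode == "gimme":
        if not (0.0 < g_cutoff <= 1.0):
            raise ValueError(f"GIMME cutoff must be in (0, 1], got {g_cutoff}")
        w = {
            rid: max(g_cutoff - rexpr.g[rid], 0.0) if rid in rexpr.g else g_cutoff
            for rid in rexpr.reaction_ids
        }
        return WeightVector(w, mode="gimme", g_cutoff=g_cutoff)
    raise ValueError(f"unknown weight mode {mode!r}")


def write_mapping_tsv(
    rexpr: ReactionExpression, weights: WeightVector, path: str | Path
) -> None:
    """Write per-reaction g and w for inspection (missing g left blank)."""
    lines = ["reaction_id\tg\tw"]
    for rid in rexpr.reaction_ids:
        g = rexpr.g.get(rid)
        lines.append(f"{rid}\t{'' if g is None else format(g, 'g')}\t{weights.w[rid]:g}")
    Path(path).write_text("\n".join(lines) + "\n")
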