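"""Rank-based meta-statistics over method x condition correlation tables.

Given one or more tables of correlation coefficients (rows = conditions,
columns = methods), two questions are answered:

1.  *Within a table*: do the methods differ at all?  All N values are pooled
    and converted to percentile scores (ascending rank / N, mid-ranks for
    ties); a one-way ANOVA F test on the scores, with K-1 and N-K degrees of
    freedom, gives the P value.

2.  *Across tables*: is one method consistently ranked near the top?  In
    each table, methods are ranked by their (unrounded) column averages,
    rank 1 = best, ties mid-ranked.  A method's rank product is the
    geometric mean of its ranks; under the null that ranks are independent
    uniform draws over each table's method count, the P value is the exact
    fraction of rank tuples whose product is <= the observed one,
    enumerated exhaustively.

The three benchmark tables shipped with the package (yeast exchange fluxes,
wild-type E. coli dilution rates, E. coli knockout strains) are available
through :func:`load_reference_tables`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def load_score_table(path: str | Path) -> pd.DataFrame:
    """Read a correlation table TSV: first column condition labels, one column
    per method."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty score table: {path}")
    return df.astype(float)


_REFERENCE_FILES = ("yeast_exchange.tsv", "ecoli_wildtype.tsv", "ecoli_knockouts.tsv")


def load_reference_tables() -> list[pd.DataFrame]:
    """The three bundled benchmark correlation tables, in canonical order:
    S. cerevisiae exchange fluxes (7 methods x 2 uptake rates), wild-type
    E. coli (8 methods x 5 dilution rates), E. coli knockouts
    (7 methods x 24 strains)."""
    tables = []
    for name in _REFERENCE_FILES:
        with resources.as_file(resources.files("efmin").joinpath("data", name)) as p:
            tables.append(load_score_table(p))
    return tables


# -- percentile scores and ANOVA ------------------------------------------


def percentile_scores(
    table: pd.DataFrame, definition: Literal["rank", "rank-half"] = "rank"
) -> pd.DataFrame:
    """Pool all values, rank ascending with mid-rank ties, score = rank / N.

    ``definition='rank-half'`` uses (rank - 0.5) / N instead.  Scores are
    invariant to any strictly monotone transform of the inputs.
    """
    vals = table.to_numpy(float)
    flat = vals.ravel()
    mask = np.isfinite(flat)
    if not mask.all():
        raise ValueError("score table contains non-finite entries")
    ranks = stats.rankdata(flat)
    offset = 0.5 if definition == "rank-half" else 0.0
    scores = (ranks - offset) / flat.size
    return pd.DataFrame(scores.reshape(vals.shape), index=table.index, columns=table.columns)


@dataclass
class AnovaResult:
    f_ratio: float
    sigma_b2: float  # between-method mean square
    sigma_w2: float  # within-method mean square
    df_between: int
    df_within: int
    p_value: float


def anova_f_test(scored: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA across methods (columns) on percentile scores.

    F is the ratio of the between-method mean square (K-1 df) to the
    within-method mean square (N-K df); P is the upper tail of the F
    distribution.  Zero within-method variance gives an infinite F with
    P reported as 0.
    """
    groups = [scored[c].to_numpy(float) for c in scored.columns]
    K = len(groups)
    N = sum(len(g) for g in groups)
    if K < 2 or N <= K:
        raise ValueError("ANOVA needs >= 2 methods and N > K observations")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = K - 1, N - K
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        return AnovaResult(np.inf, ms_b, ms_w, df_b, df_w, 0.0)
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), float(ms_b), float(ms_w), df_b, df_w, p)


# -- rank product -----------------------------------------------------------


def method_ranks(table: pd.DataFrame) -> pd.Series:
    """Rank methods by unrounded column average, descending (1 = best),
    mid-ranks for ties."""
    means = table.mean(axis=0)
    ranks = stats.rankdata(-means.to_numpy(float))
    return pd.Series(ranks, index=means.index)


@dataclass
class RankProductResult:
    method: str
    ranks: list[float]  # observed rank in each table (mid-ranks may be fractional)
    rank_product: float  # geometric mean of the ranks
    p_value: float
    numerator: int  # favorable rank tuples
    denominator: int  # total rank tuples = product of table sizes

    @property
    def exact_p(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)


def rank_product_test(
    tables: Sequence[pd.DataFrame | Mapping[str, float]], method: str
) -> RankProductResult:
    """Exact rank-product permutation test for one method across tables.

    ``tables`` may be score tables (rows = conditions) or precomputed
    method -> average-score mappings.  The null hypothesis draws each
    table's rank independently and uniformly from {1..n_t}; the P value is
    the fraction of all rank tuples whose product is <= the observed
    product (enumerated exhaustively, so exactly rational).
    """
    ranks: list[float] = []
    sizes: list[int] = []
    for t in tables:
        if isinstance(t, pd.DataFrame):
            r = method_ranks(t)
        else:
            means = pd.Series(dict(t), dtype=float)
            r = pd.Series(stats.rankdata(-means.to_numpy()), index=means.index)
        if method not in r.index:
            raise KeyError(f"method {method!r} missing from a table")
        ranks.append(float(r[method]))
        sizes.append(len(r))
    observed = float(np.prod(ranks))
    favorable = sum(
        1
        for tup in itertools.product(*(range(1, n + 1) for n in sizes))
        if float(np.prod(tup)) <= observed + 1e-9
    )
    total = int(np.prod(sizes))
    rp = observed ** (1.0 / len(ranks))
    return RankProductResult(method, ranks, rp, favorable / total, favorable, total)
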