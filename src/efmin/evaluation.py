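"""Comparing predicted flux vectors with measured fluxes.

Predictions and measurements are put on a common scale by rescaling both so
that a reference reaction (typically glucose uptake) carries the same flux,
e.g. 100 mmol/(gDW*h).  Agreement is summarized by the Pearson correlation
rho with its two-sided t-based P value, and by the sum of squared error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import FluxDistribution
from .model import MetabolicModel


@dataclass
class MeasuredFluxes:
    """Measured fluxes per reaction (exchange rates or 13C-MFA estimates)."""

    values: dict[str, float]
    source: str = "exchange"

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "exchange") -> "MeasuredFluxes":
        values: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                values[parts[0].strip()] = float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise
        return cls(values, source)


@dataclass
class EvaluationResult:
    rho: float | None
    p_value: float | None
    sse: float
    n: int
    outliers_removed: list[str] = field(default_factory=list)


def match_and_scale(
    pred: FluxDistribution,
    meas: MeasuredFluxes,
    reference: str,
    reference_value: float = 100.0,
    use_absolute: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair predicted and measured fluxes on a common reference scale.

    Both vectors are rescaled so the reference reaction equals
    ``reference_value``; only reactions present in both are paired.
    Measurements naming reactions absent from the prediction are dropped
    with a warning.  ``use_absolute`` compares flux magnitudes instead of
    signed fluxes.
    """
    for name, vec in (("prediction", pred.fluxes), ("measurement", meas.values)):
        if reference not in vec:
            raise KeyError(f"reference reaction {reference!r} absent from {name}")
        if abs(vec[reference]) < 1e-12:
            raise ValueError(f"reference reaction carries no flux in {name}")
    dropped = sorted(set(meas.values) - set(pred.fluxes))
    if dropped:
        warnings.warn(f"measured reactions absent from prediction, dropped: {dropped}")
    ids = [rid for rid in meas.values if rid in pred.fluxes]
    if not ids:
        raise ValueError("no overlap between predicted and measured reactions")
    fp = reference_value / abs(pred.fluxes[reference])
    fm = reference_value / abs(meas.values[reference])
    x = np.array([pred.fluxes[rid] * fp for rid in ids])
    y = np.array([meas.values[rid] * fm for rid in ids])
    if use_absolute:
        x, y = np.abs(x), np.abs(y)
    return x, y, ids


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    """Pearson rho and its two-sided P value (t distribution, n-2 df).

    Returns (None, None) when rho is undefined (fewer than 2 points or zero
    variance in either vector).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def sse(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared differences, in squared flux units."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sum((x - y) ** 2))


def remove_bound_outliers(
    pred: FluxDistribution, model: MetabolicModel, tolerance: float = 1e-6
) -> tuple[FluxDistribution, list[str]]:
    """Drop fluxes stuck at a finite bound (degenerate-LP artifacts).

    A reaction whose flux is within ``tolerance`` (relative to the bound's
    magnitude, absolute for small bounds) of a finite lower or upper bound
    is excluded.  Returns the filtered distribution and the removed ids.
    """
    removed: list[str] = []
    kept: dict[str, float] = {}
    for r in model.reactions:
        v = pred.fluxes.get(r.id)
        if v is None:
            continue
        at_bound = False
        for b in (r.lower_bound, r.upper_bound):
            if math.isfinite(b) and b != 0 and abs(v - b) <= tolerance * max(1.0, abs(b)):
                at_bound = True
        if at_bound:
            removed.append(r.id)
        else:
            kept[r.id] = v
    out = FluxDistribution(kept, pred.objective, pred.status, pred.biomass_flux)
    return out, removed


def evaluate(
    pred: FluxDistribution,
    meas: MeasuredFluxes,
    reference: str,
    reference_value: float = 100.0,
    model: MetabolicModel | None = None,
    drop_bound_outliers: bool = False,
    use_absolute: bool = False,
) -> EvaluationResult:
    """Full evaluation: optional outlier removal, scaling, rho/P and SSE."""
    removed: list[str] = []
    if drop_bound_outliers:
        if model is None:
            raise ValueError("drop_bound_outliers requires the model (for bounds)")
        pred, removed = remove_bound_outliers(pred, model)
    x, y, ids = match_and_scale(pred, meas, reference, reference_value, use_absolute)
    rho, p = pearson_with_p(x, y)
    return EvaluationResult(rho, p, sse(x, y), len(ids), removed)
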