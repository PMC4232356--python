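# Methods

## Model and optimization problem

E-Fmin predicts a steady-state flux vector `r` for a stoichiometric network
by solving

    min  Σᵢ wᵢ·|rᵢ|
    s.t. S·r = 0                (internal metabolites only)
         r_L ≤ r ≤ r_U          (thermodynamic directionality)
         r_B ≥ ε                (biomass carries nonzero flux)

The rationale is enzyme frugality: flux magnitudes are taken as proportional
to enzyme investment, and reactions whose genes are weakly expressed are
penalized more. Weights are `wᵢ = 1 − gᵢ`, where `gᵢ ∈ [0,1]` is the
reaction's normalized expression; a reaction with no expression data gets
the full weight 1. Only biomass is forced active — no other context-specific
functionality, uptake limit, or maintenance requirement is assumed, so by
default all flux bounds are directionality-only (`(0, ∞)` irreversible,
`(−∞, ∞)` reversible). Supplied finite bounds can be kept or discarded via
`apply_thermodynamic_bounds(keep_finite=...)`, since conventions differ on
whether measured bounds belong in an expression-only prediction.

Key assumptions worth stating: transcript levels are treated as a proxy for
enzyme capacity (post-transcriptional regulation is ignored); the biomass
composition of the model is taken as given; and the prediction is a single
steady state of a fixed network.

### Linearization and solver

`|rᵢ|` is realized with one auxiliary magnitude variable per reaction:
minimize `Σ wᵢ·tᵢ` subject to `tᵢ ≥ rᵢ` and `tᵢ ≥ −rᵢ`. At any optimum with
`wᵢ > 0`, `tᵢ = |rᵢ|` exactly; for `wᵢ = 0` the reaction contributes nothing
but `tᵢ` remains constrained, which keeps the objective-capped FVA step
meaningful. This adds n columns and 2n rows; splitting each flux into
positive/negative parts would satisfy the same contract with twice the
columns. All LPs go through one backend function over scipy's HiGHS, which
supports genuinely infinite bounds; a big-M fallback (`EfminConfig.big_bound`)
exists for backends that do not.

### ε and normalization

`ε` (default 0.01 mmol/(gDW·h)) is not a tunable parameter: the feasible set
and objective are positively homogeneous, so the optimal solution scales
linearly with ε, and solutions normalized to a common reference flux (e.g.
glucose uptake = 100) coincide. The test suite asserts this for
ε ∈ {10⁻⁴, 10⁻², 1} at 10⁻⁸ relative tolerance. Through `required_fluxes`
the single biomass floor generalizes to any set of required functionalities,
each with its own minimum flux; the biomass-only form is the default because
it is the one context-independent choice.

### Alternative optima and FVA

The LP may have degenerate optima (e.g. two pathways with identical per-unit
cost). The solver's returned vertex is reported as-is — no lexicographic
tie-break is imposed — and flux variability analysis at the fixed optimal
objective (`Σ wᵢtᵢ ≤ z*`, optionally relaxed by a `fraction ≥ 1`) is the
sanctioned way to characterize the optimal family. A tiny absolute slack
(10⁻¹²) on the objective cap guards the z* = 0 case. On weighted instances
with a unique optimum the FVA ranges are numerically degenerate (width
≲ 10⁻⁹), and flux minimization leaves no circulation around stoichiometrically
balanced internal cycles, since removing a loop never hurts the objective
when weights are strictly positive.

## Expression mapping

GPR rules are parsed with a recursive-descent parser: operators are
case-insensitive, AND binds tighter than OR (the SBML-fbc convention;
curated models almost always parenthesize), and malformed rules report the
failing character position. Evaluation is AND → min, OR → max over child
values. Missing genes are ignored by default — min/max over measured leaves
only, a rule with no measured leaf leaving the reaction unmapped — because
this keeps partially measured complexes usable; the stricter convention
where a missing subunit poisons an AND is available
(`missing="propagate"`). Mapped values are normalized by one global maximum
across all reactions (not per pathway), after GPR evaluation.

GIMME-mode weights `max(g_cutoff − gᵢ, 0)` (cutoff default 0.05) and the
required-functionality threshold (default 90% of the FBA maximum) reproduce
the conventional GIMME setup; E-Flux caps each measured reaction's bounds at
`scale·gᵢ`, with the scale defaulting to the model's largest finite bound
magnitude (10³ when fully unbounded), since E-Flux only fixes bounds up to a
common factor. For irreversible reactions without data E-Flux keeps the
`(0, default)` bounds; the treatment of that case is genuinely
convention-dependent. iMAT and correlation-maximization methods are not
reimplemented; their flux vectors can be evaluated from TSV files.

## Evaluation

Predictions and measurements are paired by reaction id and both rescaled so
a reference reaction (typically glucose uptake) equals a common value,
100 mmol/(gDW·h) by convention. Agreement is Pearson ρ with the two-sided
t-based P value (n−2 degrees of freedom) and the sum of squared errors.
ρ is invariant to the common rescaling; SSE scales quadratically with the
reference value. Signed fluxes are compared by default, magnitudes on
request. Reactions whose predicted flux sits at a finite bound can be
excluded (`remove_bound_outliers`, relative tolerance 10⁻⁶) — a degenerate-LP
artifact seen with classical FBA and iMAT — and predictions with zero
variance yield ρ = NA rather than 0.

## Meta-statistics

Within one method×condition correlation table, all N values are pooled and
converted to percentile scores (ascending rank / N, mid-ranks for ties; the
(rank−0.5)/N variant is available), and a one-way ANOVA F-test across
methods — between-method mean square on K−1 df over within-method mean
square on N−K df — gives the P value for "the methods differ". Across
tables, methods are ranked per table by their unrounded average correlation
(rank 1 = best, mid-rank ties — with two-decimal rounding near-ties would
collapse), and a method's rank product is the geometric mean of its ranks.
Its P value is exact: all rank tuples over the tables' method counts are
enumerated and the fraction with product ≤ observed is returned as a
rational number. With a single table this reduces to rank/n. The Breitling
gamma approximation is unnecessary at these sizes (392 tuples).

On the three bundled benchmark tables this machinery yields ANOVA P = 0.04
for the yeast table and P < 10⁻¹⁰ for both *E. coli* tables, and rank-product
P = 13/392 ≈ 0.03 for E-Fmin and 16/392 ≈ 0.04 for FBA with flux
minimization — the values `scripts/acceptance.py` recomputes. Censored
entries printed as "<0.01" in the wild-type table are stored at the interval
midpoint 0.005; any value inside (0, 0.01) gives identical ranks.

## Synthetic fixtures

The demo network has nine irreversible reactions over five internal
metabolites: a substrate→product path P1 (r1, r2) and three biomass paths of
length 3, 4, 5 (P2 = r1,r3,r9; P3 = r1,r4,r5,r9; P4 = r1,r6,r7,r8,r9), each
reaction carrying a one-gene GPR. It is deliberately underdetermined so the
pathway choice is made entirely by the weighted minimization. The cycle
fixture adds a balanced A→C→D→A triangle; note its first two edges can also
serve acyclic routes, so the loop-freeness claim is about circulation (and
the return edge D→A), not about those reactions individually.

Planted-path conditions build 2+ parallel substrate→biomass chains of
seeded random length (2–4 reactions); the designated path's genes (and the
shared uptake/biomass reactions) are expressed at 1.0, all others at a 0.2
baseline plus Gaussian noise (default sd 0.05) clipped to [0,1] — clipping
rather than re-normalizing keeps the planted weight ordering intact. These
generators emulate the *structure* of expression-conditioned flux routing,
not real data: expression is one gene per reaction, noise is independent and
Gaussian, and networks are small linear chains. Passing the recovery tests
therefore demonstrates correctness of the optimization and mapping
machinery, not predictive accuracy on real transcriptomes, which is what
the benchmark correlation tables summarize.

## Numerical choices and problem sizes

Feasibility checks use 10⁻⁸–10⁻⁹ absolute tolerances against HiGHS defaults;
"active" means |flux| > 10⁻⁶. The vertex-enumeration oracle in the tests
(C(10,4) = 210 basic systems on the toy network) makes the LP objective
checkable exactly; property tests run 10–50 seeds per claim. The full suite
and the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Expression→flux proportionality is a modeling hypothesis; strongly
  post-transcriptionally regulated systems will violate it.
* One biomass composition is assumed; cells in unusual conditions may differ.
* Genome-scale correlation benchmarks require the external SBML models and
  expression datasets; the package supports that workflow (SBML ingestion,
  TSV flux import) but ships only the correlation tables, not the datasets.
* Thermodynamics enters only as directionality; no explicit loop-law or
  ΔG constraints (loop-freeness emerges from minimization instead).
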