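# Methods

This note records the modeling conventions, parameter choices, numerical
decisions and known limitations of `symbiofba`, in the order a user meets
them: model representation → community coupling → LP solving → the ratio
sweep → synthetic data → statistics.

## Model representation and I/O

A model is a set of compartments, metabolites and reactions; stoichiometric
coefficients are signed (negative = consumed) and flux bounds are in
mmol·gDW⁻¹·h⁻¹. Sign conventions, stated once and used everywhere: for
exchange reactions positive flux is export to the environment and uptake is
negative; a demand reaction with lb = ub > 0 is a *fixed demand* the
organism must drain regardless of any objective.

Native formats are a JSON schema and a TSV pair
(`metabolites.tsv`/`reactions.tsv`, sparse stoichiometry encoded
`met:coef;met:coef`); both round-trip losslessly, with model-level metadata
carried as `#key=json` comment lines in the reactions table. SBML Level 3
import (read-only, via libsbml) takes bounds from the fbc package, falls
back to kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters, and otherwise
defaults to ±1000 (0..1000 when the reaction is flagged irreversible) —
the usual convention of constraint-based modeling for "effectively
unbounded". Identifiers are preserved verbatim; role mapping (which
reaction is HisD, which metabolite is AICAR) is configuration, not
guesswork, and misconfigured ids fail with near-match suggestions. SBML
export, MAT/Excel dialects, gene-rule evaluation and mass/charge
auto-balancing are out of scope.

## Community coupling

Organism models merge into one LP. Identifiers are tagged
`<id>__<organism>` (collisions are errors, never renamed); each linked
metabolite gets one pool species and one reversible transport reaction per
organism that holds it; pool exchanges carry the growth medium (listed
metabolite → uptake lb = −rate; unlisted → uptake blocked, secretion
open). The linked set defaults to metabolites flagged `transportable` in
the organism files; an explicit allow-list overrides.

**Biomass-ratio mechanics.** All community fluxes are per gram dry weight
of a designated reference organism (the obligate symbiont). An organism at
biomass r grams per gram of reference contributes r × its per-gram flux;
this is implemented by multiplying that organism's bounds — including its
fixed-demand pins and its pool-transport capacities — by r. This keeps the
community a single LP and makes a ratio sweep a pure rescaling
(`set_biomass_ratio` multiplies by new r/old r, so setting the current
value is the identity). The convention is this package's own design; a
consequence verified in tests is that community flux / r recovers the same
per-gram flux at any r. r = 0 is deliberately rejected: the symbiont-free
baseline is a community *without* the organism, not a zero-scaled one.

**Host treatment.** The host is represented by fixed nutrient demands on
the pool (histidine and any other drains) plus a free by-product
accumulation sink, reflecting the assumption of a fixed host demand rather
than a growth objective. A host with a biomass objective is still
expressible — any organism model may carry an `objective` — but the
default workflow is demand-driven. The toy's default medium contains only
the precursor (all histidine is producer-derived); dietary histidine can
be added to the medium by configuration.

**Member feasibility pre-check.** Before assembly each member must satisfy
its own fixed demands given *free* exchange of its transportable
metabolites. The check deliberately opens exchanges wide rather than
medium-capping them: auxotrophic members (the facultative symbiont, the
host) are only feasible with pool supply, so a medium-only check would
reject every valid community. Community-level starvation is still caught —
an empty medium makes the assembled LP infeasible.

## LP solving

`solve_fba` optimizes cᵀv subject to S·v = 0, lb ≤ v ≤ ub with fixed
demands pinned; infeasibility/unboundedness is reported in the solution
status, never as silent zeros. Degenerate optima are resolved by
parsimonious FBA: minimize Σ|v| via the epigraph splitting t ≥ ±v (2n
inequality rows), after pinning the stage-1 objective value when an
objective is present. Flux variability analysis reports per-reaction
min/max inside the envelope Σ|v| ≤ (1+γ)·(pFBA optimum). `check_balance`
audits any flux vector against |S·v| ≤ ε.

Numerical choices: the back end is scipy's HiGHS interface behind a
minimal solve contract (matrix, bounds, objective), chosen so results
depend on no commercial solver and are deterministic run-to-run;
feasibility tolerance is HiGHS's (~1e-9); mass-balance reporting uses
ε = 1e-6; rows/columns are ordered by sorted id so the matrix, and hence
the vertex the solver returns, is reproducible. pFBA (not lexicographic
reaction ordering) is the degeneracy rule because it has a clean
variational statement and a brute-force oracle: on networks of ≤8
reactions the tests enumerate the flux polytope's vertices exhaustively
(including the |v| breakpoint hyperplanes v=0) and confirm the LP matches;
an independent solver route (cobra/GLPK) cross-checks FBA optima. MILP,
quadratic objectives and flux sampling are out of scope.

## The ratio sweep

`run_ratio_sweep` solves the symbiont-free baseline (the organism removed,
per the coupling convention) and then each ratio point by pFBA, reporting
HisD flux, AICAR overflow, percent HisD increase vs baseline and overflow
fold change. Ratio strings `a:b` are parsed as r = b/a (facultative grams
per obligate gram); the default grid {10:1, 6.7:1, 5:1, 2:1, 1:1, 1:2,
1:5} covers the studied endpoint range plus the empirically calibrated
ratio. Overflow is defined as net producer→pool export of AICAR (not pool
accumulation), since the by-product is attributed to the producer; the raw
signed transport flux is available, with clipping at zero only in
reporting. Because baseline overflow is exactly zero in the symbiont-free
model, fold changes use a numeric floor of 1e-9 (read "∞" for any positive
overflow); the absolute overflow column is the meaningful quantity there.
Infeasible ratio points are flagged and the sweep continues.

The cell↔biomass conversions are exact arithmetic: one matched
biomass-ratio/cell-ratio pair calibrates the per-cell mass factor
(cells_H/cells_B)/(mass_H/mass_B), which then maps any measured cell ratio
to a biomass ratio, normalized to `x:1`/`1:x` at two significant figures.

## Synthetic data: what it emulates, and what it does not

`make_toy_symbiosis` is the package's reference system. Defaults
(h_A = 1.0, a = 1.0, h_H = 0.0536, b = 0, uptake cap 10) are calibrated to
two anchors of the aphid system: baseline overflow exactly zero (a = h_A),
and +0.8% HisD flux at the empirical biomass ratio 6.7:1
(h_H/6.7 = 0.8% of h_A). The facultative symbiont's true per-gram
histidine demand is not an independently measured quantity, so h_H is a
calibration, not a measurement. Away from those anchors the toy's numbers
are its own: at 1:5 it predicts +26.8% HisD flux, whereas a genome-scale
model of the same system — with its internal pathway couplings and richer
medium — prints larger responses (+35%). Passing tests therefore
demonstrate that the framework reproduces the *mechanism* (demand-driven
overproduction with stoichiometric by-product overflow) exactly, not that
the toy quantitatively substitutes for a genome-scale reconstruction.

The other generators are pure functions of (parameters, seed), with no
hidden global RNG. Isotopologue tables use multiplicative lognormal noise
(peak areas are positive and right-skewed); defaults mirror a
three-replicate design with the fully-labeled fraction near 0.58.
Metabolomics matrices are log-scale abundances = feature baseline +
genotype random intercept + status effect + Gaussian noise, with status a
genotype-level property (half the genotypes carriers) — exactly the
confounding that motivates the mixed-model stage; defaults mirror a
6-genotype × 5-replicate layout. Performance samples are plain normal
draws behind a printed mean ± SE. None of these emulate raw LC-MS spectra,
retention-time structure, missingness, or genome-scale network randomness;
`random_network` builds small source→chain→sink networks that are feasible
by construction, as property-test fuel only.

## Statistics

Performance metrics: RGR = ln(w₇/w₂)/5 (mg·mg⁻¹·day⁻¹), r_m =
0.745·ln(M_d)/d (day⁻¹). The summary-statistics t test uses
t = (m₁−m₂)/√(se₁²+se₂²) with df = n₁+n₂−2 — the exact pooled-variance t
whenever n₁ = n₂ (tested as an identity against raw-sample computation);
pooled rather than Welch df is the default because equal-n designs are the
norm in this setting and printed df of the reference tables match n₁+n₂−2.
Welch and Mann–Whitney (normal approximation) variants are available, and
Shapiro–Wilk/Bartlett checks are advisory flags only — the test choice is
explicit configuration, never silent auto-switching.

Isotope enrichment offers two ratio conventions because "¹³C-labeled"
is ambiguous when partial isotopologues carry real signal: all-labeled
Σ_{k≥1}A_k/A₀ (default) and fully-labeled-only A_kmax/A₀; both are
reported by the CLI and neither is asserted as canonical. Fractions and
ratios satisfy ratio_all = (1−f₀)/f₀ and are invariant to area rescaling
(property-tested). No natural-abundance correction is applied by default
(a correction-matrix hook ships disabled). Two-group comparisons with both
soluble and protein fractions use a Bonferroni-adjusted critical
probability of 0.025 for the two tests.

Benjamini–Hochberg is implemented natively (step-up with monotonicity
enforcement, order-preserving) and cross-checked against statsmodels.

The metabolite screen is two-stage by design: an uncorrected per-feature
t test flags candidates (cheap, liberal), then each candidate is refit
with a linear mixed model — symbiont status fixed, host genotype a random
intercept — and the stage-2 p values are BH-adjusted. REML fitting is
delegated to statsmodels MixedLM; re-implementing REML would be out of
proportion when the pipeline's own contributions are the screening order,
candidate selection and FDR step. One deliberate correction: because
status varies at the genotype level, the Wald statistic is referred to a t
distribution with (genotypes − 2) degrees of freedom rather than the
asymptotic normal, which is badly anti-conservative with a handful of
genotypes. Constant features are reported not-applicable; a single-genotype
design falls back to t-only screening with a logged warning.

## Problem sizes used in the checks

The packaged verification runs use: 20 random toy parameter sets × 50
ratio points for the analytic-oracle audit; networks of ≤8 reactions for
exhaustive vertex enumeration; 500-feature null matrices (6 genotypes × 5
replicates) for screen calibration; and 200 generated tables for isotope
recovery. These sizes give tight checks (LP agreement at 1e-9, binomial
99% bands) while keeping the whole suite fast on a single CPU.

## Known limitations

- The coupling convention (bounds × r) assumes demands scale linearly with
  symbiont biomass; growth-rate coupling constraints, dynamic/temporal
  community FBA and thermodynamic constraints are not modeled.
- The toy host has no growth objective and its demands are inelastic;
  host demand plasticity (a likely contributor in the real symbiosis) is
  outside the model and must be imposed via parameter changes.
- SBML import targets Level 3 core + fbc; annotations, groups and
  gene-protein-reaction rules are ignored, and compartment roles in
  third-party files must be mapped by configuration.
- The screen's mixed stage has intrinsically low power when treatment
  varies only between a few genotypes (see `examples/04`); a null outcome
  there is expected behavior, not evidence of absence.
- Mann–Whitney p values use the normal approximation with continuity
  correction; exact small-sample p values are not computed.
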