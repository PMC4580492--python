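# Methods

## The vulnerability model

The unit of analysis is the HUC12 catchment (twelve-digit Hydrologic Unit
Code, roughly 1–792 km², mean ≈ 92 km²). The model assumes that a stream's
risk of degradation is the product of two separable components: the natural
**sensitivity** of its catchment (7 variables: 30-year mean precipitation,
% forest + grassland, % wetlands, stream density, mean slope, soil
erodibility K factor, % unconsolidated sediment) and its current
anthropogenic **exposure** (10 variables: vertical and non-vertical well
density, vertical and non-vertical well proximity to flowlines, road, mine
and dam density, % crops, % impervious surface, % pasture). Non-vertical
(horizontal/directional) wells proxy unconventional oil and gas (UOG)
development.

### Quartile scoring

Scores are ordinal, 0–4 per variable, assigned against the 25/50/75th
percentiles of the variable's values pooled over **all** catchments across
all plays (not per play — the index is meant to be comparable across
plays). Percentiles use sorted linear interpolation, the common empirical
definition. Binning is upper-inclusive: 0 → 0, (0, Q25] → 1, (Q25, Q50] → 2,
(Q50, Q75] → 3, > Q75 → 4; a value exactly at a break takes the lower bin.
Consequences worth noting:

- scoring depends only on ranks and zeros, so it is invariant under any
  strictly increasing zero-preserving transform of a variable;
- zeros are kept in the percentile pool (for heavily zero-inflated
  variables the lower breaks may themselves be zero, leaving the low bins
  empty — intended: absence of a stressor scores 0).

Two rules modify the mapping:

- **Inversion** (`lower_is_worse`): precipitation and both well-proximity
  variables score 4 for the smallest present values (drier catchments are
  more sensitive to water withdrawal; wells nearer streams are more likely
  to affect them). The mirrored mapping uses the same three breaks with
  labels 4, 3, 2, 1; score 0 is reserved for absent entries. Whether the
  original method awarded 0–4 or 1–4 on the inverted scale is not
  documented; this package's choice (1–4 with 0 reserved for absence) is a
  documented convention, not an inference.
- **Absence** (`undefined_when_absent`): well proximity is undefined in a
  catchment with no wells (stored as NaN, empty CSV field). Absent entries
  are dropped from the percentile pool and contribute score 0 to E, so
  well-free catchments still participate in every other part of the
  analysis.
- **Fixed breakpoints**: % impervious (0, (0,1], (1,5], (5,10], >10) and
  % crops / % pasture (0, (0,25], (25,50], (50,75], >75). The literature
  values used by the original index are not recoverable from it; these
  defaults are implementation choices, overridable per variable in config.

Totals are S = Σ(7 sensitivity scores) ∈ [0,28], E = Σ(10 exposure scores)
∈ [0,40], V = S × E ∈ [0,1120]. Before scoring, `screen_correlations`
reports variable pairs with |Spearman ρ| > 0.6 (the screening threshold of
the original variable selection); dropping a flagged variable is a
configuration action, never automatic.

## Influence analysis

The influence of variable *x* on a catchment's total is the percent change
when *x* is removed: (original − modified)/original × 100, computed against
the **role** total (S for sensitivity variables, E for exposure) — the
role-wise convention matches how such removal tables are reported, and it
makes the per-catchment changes of one role sum to exactly 100. Catchments
with a zero role total are excluded (the ratio is undefined) and counted in
the output. Several variables may be removed jointly (e.g. all four well
metrics as "all UOG metrics"); a wells-only variant repeats the analysis on
the subset of catchments with any well. UOG-only scores are
E_uog = non-vertical density score + non-vertical proximity score (≤ 8) and
V_uog = S × E_uog, equivalent to masking every non-UOG exposure variable to
zero.

## Severity-weighted play index

The catchment index does not say *which* postulated UOG effect — altered
natural flow regime, sedimentation, or chemical contamination — a play is
vulnerable to. The play-level index does, per effect:

1. rank the six plays 1 (low stress) to 6 (high stress) on each relevant
   variable's play mean, in the variable's stress direction (drier → higher
   for precipitation; closer wells → higher for proximity);
2. multiply each exposure variable's rank by its severity weight — the
   1 (least) to 3 (most severe) expert score averaged across raters — and
   round **half-up** to an integer cell. Proximity rows carry implicit
   weight 1. Half-up rounding is pinned by the reference block itself
   (4 × 1.33 = 5.32 → 5, 3 × 2.50 = 7.5 → 8, 5 × 2.50 = 12.5 → 13);
3. total = (sum of sensitivity ranks) × (sum of weighted exposure cells).

Ties share the minimum rank of their block (competition ranking) by
default; the rule is configurable because the published reference block is
internally inconsistent about it (see Limitations). The shipped severity
weights are the published author-averaged values for all three effects; the
flow-regime rank block is additionally shipped as reference data, and
`severity_index_from_means` re-derives ranks from any per-play means (e.g.
a synthetic table).

Reproduction status of the published flow-regime totals from the shipped
block: Bakken 459, Barnett 370, Fayetteville 448, Marcellus 320 and Mowry
410 recompose exactly; Hilliard's published 192 does not recompose from its
own published cells (they sum to 33, and 33 × 6 = 198), so the package
computes 198 and documents the discrepancy rather than patching either
number.

## Synthetic catchment generator

The original attribute table was derived from national GIS layers (PRISM,
NLCD, NHDPlus, TIGER, soil and well databases) that are out of scope here.
The generator emulates its statistical skeleton per play: for each
variable, a Bernoulli(frac_nonzero) presence mask times a non-negative
skewed non-zero part, parameterised so the expected mean matches the
published play mean exactly —

- log-normal for densities and distances (σ² = ln(1 + CV²), exact mean);
- scaled Beta on [0, 100] for percentage covers;
- zero-truncated normal for precipitation, slope and erodibility, rescaled
  multiplicatively to undo the truncation's mean shift.

Proximity values are generated only where the matching well density is
non-zero, and their target mean is the mean over well-containing catchments
(a mean distance is only defined there); all other targets are overall
means. Three published play means of 0.00 that coexist with a positive
non-zero percentage (Bakken and Barnett mine density, Hilliard dam density)
are replaced by 0.004 — below the source's printing precision — so the
zero-inflation identity stays representable.

Dispersion defaults to CV = 1.0 of the non-zero part for every variable:
within-play variances were never published, so any value is a stand-in, and
rank-based scoring is insensitive to it. For high percentage means CV = 1
exceeds the Beta feasibility bound, so Beta variance is clamped to
0.95·p(1−p). Draws go through each family's inverse CDF applied to uniform
variates, which makes generation deterministic per seed and lets an
optional Gaussian copula impose rank correlation across chosen variables
(by default variables are independent — the main structural departure from
real landscapes, where e.g. land-cover percentages are compositionally
linked). Multi-play tables give each play an independent child seed stream,
so plays can be added or resized without perturbing each other.

What passing tests on synthetic data do and do not show: they validate the
*machinery* (scoring, totals, influence algebra, ranking, clustering,
comparison) under realistic marginal distributions and zero inflation; they
do not validate ecological conclusions about real catchments, which depend
on spatial structure, cross-variable dependence and within-play variance
the generator does not reproduce.

## Clustering

K-medoids over catchments on z-scored variables (the variables span
incomparable units, so unstandardised Euclidean distance would be dominated
by precipitation), Euclidean dissimilarity, cluster count chosen by maximal
average silhouette width (ties toward smaller k, default range 2–15).
Instances with at most 10,000 candidate medoid subsets are solved exactly
by enumeration; larger instances use greedy BUILD seeding followed by
best-improvement SWAP to a local optimum. The split exists because
best-improvement SWAP can stall in a strict local optimum even at n < 10 —
as can the canonical PAM implementations — while desk-scale instances are
cheap to solve exactly; the SWAP objective still decreases strictly at
every accepted exchange, so termination is guaranteed. Silhouette follows
the standard (b − a)/max(a, b) with singletons contributing 0 and the
a = b = 0 degenerate case scored 0. The pipeline clusters on the 15
always-defined variables (proximity is undefined in well-free catchments)
and subsamples large tables (default 1000 rows, seeded) before the k-scan.

## Play comparison

One-way ANOVA on S, E and V with catchments as replicates, followed by
Tukey HSD (studentized-range adjusted p per pair) and a compact letter
display built by the sweep-and-absorb construction: start from one block of
all plays, split every block containing a significantly different pair,
absorb blocks contained in others; plays sharing a letter are not
significantly different. Significance defaults to α = 0.016 (0.05/3
metrics, used verbatim rather than re-derived). Normality and
variance-homogeneity diagnostics (Shapiro on residuals, Levene) are
reported as warnings only; the parametric path is always taken, matching
the method being implemented. Note the direction of the α-monotonicity:
raising α makes more pairs significant, so letter groups split as α rises
and merge as it falls.

## Pipeline defaults and problem sizes

The pipeline runs generate (or load) → screen → score → influence →
severity → cluster → compare, writing one CSV per product with a
`# seed=...` header and a final manifest. Default synthetic sizes are the
published per-play catchment counts (1060, 731, 211, 526, 3175, 215; total
5918). Tests and examples scale plays down (50–200 catchments per play) and
the clustering stage subsamples to keep the k-scan quick; statistical
checks of the generator run at 5000 catchments per play, where a mean's
standard error is ~1.4% of its standard deviation.

## Known limitations

- Hilliard's published flow-regime total (192) is not recomposable from its
  published cells; the package reports the recomposed 198 (see above).
- The published reference block's tie conventions are not fully
  recoverable: its mine-density row implies ties share a *higher* rank
  (2, 2, 4, 4 from two tied pairs) while its dam-density row implies
  competition-minimum ranking; and its stream-density sensitivity ranks for
  Barnett/Hilliard invert their published play means. The package defaults
  to competition ranking and ships the reference block verbatim rather than
  guessing an unstated adjustment.
- Fixed breakpoints for agriculture and impervious cover are implementation
  defaults, not the unpublished literature values.
- The generator matches first moments and zero inflation only; it does not
  reproduce spatial autocorrelation between neighbouring catchments,
  compositional closure among land-cover fractions, or published
  within-play variances (not available). Statistical acceptance checks that
  combine ~100 simultaneous nominal-99% / 3-SE criteria will fail
  occasionally by construction even for a perfectly calibrated generator;
  observed failures should be read against that base rate.
- HUC12s are treated as independent replicates in the ANOVA, inheriting the
  original method's acknowledged simplification.
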