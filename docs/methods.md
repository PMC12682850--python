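# Methods

This note documents the models, parameter choices, numerical rules and
known limitations of the `rootshift` pipeline.

## Experimental designs the package models

All computations assume the following layouts, expressed in days after
sowing (DAS):

* **Recovery field trial.** 20 genotypes × 2 treatments (drought,
  well-watered) × 4 replicate plots (randomized complete blocks) × 2
  marked plants, measured at four labels M1–M4. Drought plots are measured
  at 29/34/37/42 DAS; control plots at 29/35/38/42 — the control M2/M3
  visits lag one day behind for logistical reasons, so every interval Δt
  is taken from the treatment's own schedule (`MeasurementSchedule`),
  never a shared one. Missing measurements are absent rows; no value is
  ever imputed.
* **Multi-season GWAS.** Three seasons of association summary tables
  (SNP, chromosome, 1-based position, p-value, optional MAF). The package
  consumes summaries only; it never re-fits the mixed-model association.
* **Glasshouse root phenotyping.** Scanned root systems as segment tables
  (length, diameter, parent link) forming a forest whose roots are axial
  root bases, observed under well-watered, drought, and recovered
  conditions.

## Growth rates

`compute_rgr` implements RGR = (ln SDW2 − ln SDW1)/Δt. Weights must be
strictly positive: a zero or negative dry weight indicates a data error
and is rejected rather than clamped, since the logarithm is undefined
there. Per-compartment rates (shootGR from total leaf length, rootGR from
crown root number) are plain differences per day and may be negative —
destructive sampling measures different plants at successive timepoints.

Aggregation is the unweighted two-stage mean (plants within plot, then
plots within line), matching the stated order of averaging in the field
protocol. Spatial adjustment is additive block-centering: each
observation is shifted by its block's deviation from the grand mean
before genotype means are taken. This is exact on balanced designs and
conserves the grand mean to 1e−12; it is a deliberate, documented
approximation to a mixed-model least-squares mean (the augmented-design
model is not specified well enough to reproduce, and block-centering is
reproducible and dependency-light). Outputs are labelled
"block-adjusted", not "lsmeans".

## The Water Recovery Index

The WRI window defaults to M2→M3 (end of drought → early recovery), the
interval over which re-watering effects on crown-root production are
strongest; the window is a parameter. Rescaling to [1, 100] is
`x ↦ 1 + 99 (x − min)/(max − min)` applied to the vector of **line means**
within each (treatment, compartment) group — rescaling after line-level
averaging is the only reading consistent with the order of steps in the
index's construction. Compartments are rescaled separately; pooling
shoot and root rates into one vector per treatment would make the ratio
depend on the (arbitrary) relative units of the two traits.

Numerical rules: the expression is grouped so the extremes map to exactly
1 and 100; interior values are clipped against one-ulp spill; a constant
vector maps to the interval midpoint 50.5 so the subsequent log-ratio
stays defined. SRGR = ln(shoot/root) on the rescaled values; WRI is the
drought-minus-control SRGR difference. Ranking sorts WRI ascending with
lexicographic tie-breaks on genotype id for determinism; only the extreme
genotypes are labelled ("conservative" / "less-conservative") since the
dichotomy is defined by contrast, not by a threshold.

WRI values depend on plant age and growth stage and are not comparable
across experiments; no cross-experiment normalization is attempted.

## GWAS co-location

"logP" means −log₁₀(p) throughout. The −log₁₀(p) ≥ 3 retention filter is
boundary-inclusive (evaluated in log space with a 1e−9 slack so p-values
printed at the decimal boundary are retained); the genome-wide
significance flag p < 1e−4 is strict, as printed conventions dictate; no
multiple-testing correction is applied. Co-location is single-linkage
clustering of positions per chromosome with inclusive distance ≤ 100 kb;
on sorted positions this reduces to consecutive-gap chaining, which the
test suite verifies against an all-pairs + connected-components brute
force. Clusters must span ≥ 2 distinct seasons, and both members of any
linked pair must already have passed the filter (no single-anchor rule).
Coordinates are 1-based inclusive (GFF3 convention); gene extraction uses
closed-interval overlap against the cluster interval padded by a 100-kb
flank, and accepts either a cluster or a single SNP as the query.

## Root architecture

Diameter classes use closed upper bounds: d ≤ 0.15 mm is S-type,
0.15 < d ≤ 0.37 mm is L-type, d > 0.37 mm is axial. The rule is symmetric
at both cut points (a range written "0–0.15" includes its upper endpoint,
and "> 0.37" excludes 0.37 from the axial class) and the boundaries are
configurable. Class lengths are plain sums of member segment lengths, so
the three class sums reproduce the total in the same floating summation
order; proportions sum to 1 within 1e−9.

Link analysis treats a root as a maximal chain of segments from branch
point to tip: external links are segments with no children, internal
links have at least one child. The mean S-type lateral length estimator —
total S-class length divided by the number of S-class tips — mirrors the
external-link notion of scanner software without reimplementing image
analysis. It is exact when every S lateral is a single unbranched
segment (the biological norm: S-type laterals have determinate,
unbranched growth) and is validated only against the synthetic generator,
since the commercial implementation is proprietary. A system with no
S-class tips returns an explicit undefined marker (None), never 0/0.

Lateral order: walking up the parent chain and skipping the lateral's own
contiguous chain, reaching an axial segment first ⇒ first-order; meeting
an L-class segment first ⇒ second-order. First- and second-order S-type
laterals are pooled in link analysis by default (they cannot be separated
by diameter alone); `assign_lr_order` splits them when topology is
available.

Longevity staining scores are integers 0–5 (six intensities per root
class); only aggregation is implemented (photos within root, then roots
within group, unweighted), not the visual rubric.

## Synthetic data generators

All generators are pure functions of (config, seed) using
`numpy.random.default_rng`; identical configs reproduce bitwise-identical
tables, and each generator returns the latent truth needed to score
downstream estimators.

**Field trial.** Each genotype carries a strategy s ∈ [0, 1]
(0 = conservative). Traits grow piecewise-linearly between M1–M4. Under
drought, the shoot rate is multiplied by 0.5 + 0.5 s for the whole
episode and recovery; after re-watering the crown-root rate is multiplied
by 1.5 − 0.5 s; before re-watering drought suppresses root production
(factor 0.6 + 0.4 s). Baselines: 40 cm total leaf length and ~15 crown
roots at 29 DAS, growing 2 cm/d and 5 roots/d well-watered —
tillering-stage rice produces nodal roots at several per day, and the
5/d baseline keeps integer-count quantisation of rootGR (counts are
rounded at every timepoint, as real counts are) small relative to the
panel spread. Noise is multiplicative mean-one lognormal structured as
whole-plant effects: genotype vigor (CV 5 %), plot × window (CV 10 %) and
plant × window (CV 15 %) factors that multiply shoot and root rates of
the same plant alike, since both traits are recorded on the same marked
plants. This structure is what makes the planted strategy ordering
recoverable at the design's replication (4 plots × 2 plants): whole-plant
factors cancel in the shoot:root ratio, so the treatment contrast
dominates the WRI. Per-compartment-independent noise of the same
magnitude would leave the control-treatment SRGR rescaling pure noise and
cap the achievable rank recovery well below that level — a caveat for
real data, where compartment-specific genotype variation is substantial
(see Limitations).

**GWAS tables.** Background SNPs receive uniform p-values (optionally
bounded away from 0 via `background_min_p`, used when a test requires a
background guaranteed below the filter); planted peaks appear in their
designated seasons at p = 10^−(magnitude + U(0, 0.5)) with positional
jitter capped at window/4 per season, so realized positions within one
peak always chain into a single cluster. Configs asserting recovery
require planted peaks > 2× window apart.

**Root systems.** Axial roots are segment chains (one lateral per
internal segment, bare terminal tip). S-type lateral lengths are
lognormal with median 7 mm (first-order) or 3.5 mm (second-order) and
σ_log = 0.2 — a narrow spread reflecting their determinate growth;
L-type laterals are lognormal median 30 mm, σ_log = 0.4, and carry the
second-order S laterals. Diameters are drawn strictly inside each class
band. Drought halves the first-order S count per axial, raises the
L count by 1.25× and second-order S per L by 1.5×; the recovered
condition reuses well-watered parameters, encoding the observed
reversibility of the drought root phenotype.

**Watering targets.** `glasshouse_watering_target(max_whc, fraction)` is
the one in-protocol arithmetic identity (22.3 % w/w × 0.75 =
16.725 % w/w). The absolute soil/water gram amounts of the glasshouse
protocol are not modelled — only the fraction-of-WHC relation is treated
as normative.

## Statistics

One-sample t-tests and Tukey HSD are computed from closed forms
(scipy's t and studentized-range distributions) so that scipy and
statsmodels remain available as independent cross-checks; both agree to
≤ 1e−8 on random balanced designs in the test suite, and the t-test's
null type-I error rate calibrates within the binomial 99 % CI of α. The
Type II two-way ANOVA delegates to statsmodels (`ols` + `anova_lm`
typ=2) behind a fixed tidy contract and is checked against a hand-built
sums-of-squares decomposition on balanced designs (where Type II equals
the sequential decomposition). All tests are two-sided; no correction is
applied beyond Tukey. Degenerate inputs return explicit undefined
markers: zero sample variance (t) and constant response (ANOVA) give NaN
statistics rather than exceptions; a design without residual degrees of
freedom raises an error naming the problem.

A paired-difference option exists for the post-re-watering comparison
(`one_sample_t` on per-genotype treatment differences), since connected
per-genotype measurements admit a paired reading; the unpaired one-sample
form is the default.

## Problem sizes

The shipped analysis and acceptance runs use: 100 field-trial replicates
of the full default design (2560 observations each) for WRI strategy
recovery; 200 random co-location instances (≤ 100 hits, 3 seasons,
2 chromosomes) against the brute-force oracle; 50 seeds each for
planted-peak recovery and the link-analysis estimator (200 S-type
laterals per system); 1000 null simulations for t-test calibration.
These sizes give stable pass/fail behaviour at the thresholds tested
while keeping a full run in tens of seconds.

## Limitations

* Block-centering is not a mixed model; with strong genotype × block
  interactions or unbalanced augmented designs it only approximates
  lsmeans.
* The field generator's whole-plant noise structure is favourable to WRI
  rank recovery by construction. Real panels show compartment-specific
  genotype variation (e.g. genotypes with intrinsically high crown-root
  counts), which does not cancel in the rescaled log-ratio; recovery on
  real data is expected to be weaker than on these simulations, and
  passing tests here demonstrate correctness of the computations, not
  field-level power.
* The tip-count estimator of S-type lateral length is validated against
  the generator, not against scanner software output.
* Candidate-gene extraction reports positional overlap only; no
  functional annotation or expression evidence is consulted.
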