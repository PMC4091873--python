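# Methods

`feligut` re-implements, as a tested and reusable pipeline, the statistical
analysis of a two-diet longitudinal feeding trial read out by shotgun
metagenomics: twelve kittens (six per diet — HPLC, high-protein
low-carbohydrate; MPMC, moderate-protein moderate-carbohydrate), faecal
samples at 8, 12 and 16 weeks of age, and feature-by-sample count tables at
several taxonomic ranks plus KEGG-style ortholog groups. This note records
the models, the defaults and their rationale, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Differential abundance

Each feature's proportion `y = count / annotated_total` is modelled
marginally on the logit scale by generalized estimating equations with a
binomial variance function and the per-sample read total as a case weight:

    logit E[y] = β0 + β_diet·MPMC + β_week + β_diet:week

with categorical week (week 8 reference), HPLC as the diet reference (so
`OR = exp(β_diet) > 1` means more abundant with MPMC), kittens as clusters,
and an exchangeable working correlation. GEE targets the marginal
(population-averaged) effect, which matters here: the generator plants
effects on the marginal log-odds scale, and the marginal model recovers
them without attenuation regardless of the overdispersion.

**Model reduction.** The interaction term is tested first by a joint Wald
test; if it fails the data set's critical level it is dropped and the model
re-fitted, then the week main effect likewise. Diet is always retained so
every feature reports an odds ratio and 95% CI. One critical level per data
set is used both for elimination and for significance flags.

**Familywise control.** The Sidak critical value `1 − (1 − α)^(1/m)` uses
`m` = all features identified at the level, not the post-zero-filter count;
this reproduces the per-level criticals the convention implies (0.000089
for 578 genera, 0.000223 for 230 families; for 6,660 ortholog groups the
formula gives 7.7e-6, which rounds to 0.000008 — reports that print
0.000007 for this design disagree with the formula at the last digit, and
the formula value is used here). Features whose zero-count proportion
exceeds 25% (strict inequality: 9 of 36 zeros is retained, 10 is excluded)
are filtered before fitting and carry no estimates.

**Small-sample covariance.** With only 12 clusters the plain sandwich
covariance is anti-conservative (pilot: type-I ≈ 0.14 at nominal 0.05). The
package therefore defaults to the Mancl–DeRouen bias-corrected sandwich —
implemented in `diffabund._mancl_derouen_cov` because the library
implementation does not accept case weights — with t/F references on
`n_clusters − n_params` degrees of freedom. Pilot calibration on the study
design (300 replicates, Dirichlet-multinomial overdispersion): type-I
0.03–0.05, 95% CI coverage ≈ 0.95. The plain sandwich remains available via
`cov_type="robust"`.

**Degenerate inputs.** A diet arm with all-zero (or all-saturated) counts
is separation: the feature is flagged, no estimates are reported. GEE
iteration is capped at 100 with relative coefficient tolerance 1e-8;
non-convergence is flagged, never raised, so one bad feature cannot abort a
level's run.

## Diversity and variance heterogeneity

Shannon indices use natural logarithm (nats), `H = −Σ p_i ln p_i` over
positive-count species; values near 3–4 for ~10²–10³ observed species are
the expected range on this scale. `H` is modelled by a Gaussian linear
mixed model with kitten random intercepts, categorical diet, week and their
interaction, and **diet-specific residual variances**. Variance
heterogeneity is tested by a likelihood-ratio test against the pooled-variance
model on a χ²(1) reference (no boundary correction: a variance ratio of 1
is interior to the parameter space).

The mixed models are fitted by REML with the variance parameters optimised
on the log scale (Nelder-Mead on the profile likelihood, fixed effects
profiled out by GLS). REML rather than ML because the LRT compares models
with identical fixed effects — where REML is valid — and because ML
variance estimates inflated the null LRT rejection rate to ~8–9% in pilot
runs at this sample size, while REML pilots sit at 5–7%. Fixed effects are
backward-eliminated at p ≥ 0.05 (interaction, then week; diet retained for
reporting). Kitten blocks are compound-symmetric with one residual variance
each, so the likelihood uses a closed-form block inverse/determinant and
vectorises over kittens; non-uniform designs fall back to per-block
Cholesky factorisations. Fits with variance components within 1e-8 of zero
(relative to the data scale) are flagged singular.

## Rarefaction

Sub-samples are drawn **without replacement** as multivariate
hypergeometric draws on the count vector; the count vector is a sufficient
statistic for shuffling per-read annotation records, so this reproduces the
read-file-shuffling design exactly. Defaults are ten replicates per depth
and sample; desk-scale depths are fractions of the smallest library
(1%, 5%, 10%, 20%, 40%, 60%), with absolute depths configurable (the
original design used 1–60 million reads; on 36 samples with 6 depths and 10
replicates either grid yields 2,160 points). Depths exceeding a sample's
total are skipped with a warning. The analytic expectation
`E[S] = Σ_i (1 − C(N−n_i, d)/C(N, d))` is provided as an independent oracle
and used in tests.

Richness is modelled with kitten and week-within-kitten random intercepts
("time nested in kitten"), categorical diet × depth fixed effects, and
residual variance proportional to 1/depth (the "weighting by the number of
sequences"; the source text is not formulaic here, and inverse-depth
precision weighting is the natural reading). The diet contrast p-value
comes from the final model after backward elimination of the interaction.

## Pathway over-representation

For each pathway, `n_found` counts distinct observed member ortholog groups
and `n_sig` those in the significant set; a group in k pathways counts in
all k. The empirical p-value draws `n_perm` (default 1,000) uniform random
subsets of the observed universe of the same size as the significant set
and reports the fraction whose pathway member count is ≥ `n_sig` — exactly
the "percentage of subsets" estimate, so `p = 0` is possible; a
`(r+1)/(n+1)` correction is available behind `add_one` but off by default.
Under the null this converges to the hypergeometric tail
`P(X ≥ n_sig | N = n_observed, K = n_found, draws = |significant|)`, which
the tests use as the exact oracle. The resampling universe is the set of
ortholog groups that entered testing (post zero-filter); pathways "tested"
are those with ≥ 1 observed member, and the over-representation flag uses
the Sidak critical at that count. Significant members split by direction:
OR > 1 to MPMC, OR < 1 to HPLC; an OR of exactly 1 among significant
members is a contradiction and raises.

## Pathway profiles and parsimony

Pathway abundance in a sample is the plain sum of member ortholog-group
relative abundances (shared groups contribute fully to every pathway, so
disjoint-union additivity holds but overlapping pathways double-count by
design). Fold change divides the two diet means by the smaller one
(`fc ≥ 1`), with the direction named after the larger mean; the display cap
of 6 used in plots never touches numeric output. Completeness is
`100 · n_found / n_db` against the reference pathway size. Clustering is
unweighted average-linkage agglomeration on Euclidean distances over the
raw two-diet mean-abundance profiles — raw, not log-transformed or
standardised, matching the plotted quantity; items are sorted by id before
linkage so labels are input-order invariant.

The parsimony step finds a minimum-cardinality set of pathways whose
members cover all coverable observed ortholog groups (groups in no pathway
are reported as orphans). Up to 25 candidate pathways the solver is exact
(branch and bound with a covering lower bound, seeded by the pruned greedy
solution); above that, greedy set cover followed by redundancy pruning, so
the returned set always covers and is always irredundant even when not
provably minimal. The solver used is recorded in the output. This
implements the parsimony idea directly rather than any particular ILP
encoding.

## Synthetic data

The generator emulates the study's structure, not its content. Design: 6
kittens per diet, litters nested in diet (labels only — no litter variance
component is fitted, so none is planted), weeks {8, 12, 16}. Counts are
Dirichlet-multinomial: expected proportions follow a multinomial-logit
model over log-normal baseline weights (location 0, scale 2.0 — skewed
enough that the top 19 of 150 features carry well over half the reads, as
in real profiles), per-kitten feature effects (SD 0.3, drawn once per
kitten and shared across weeks, inducing the within-kitten correlation the
GEE targets), and a diet shift of ±1.5 log-odds on 10% of features with
random sign. A single concentration scalar (default 300) sets the
between-sample overdispersion; library sizes are Gamma with mean 1e5 reads
and CV 0.2 (desk scale; the study's ~1e8 is configurable, and CV 0 gives
exact totals).

Because the proportion model is multinomial-logit, shifting one feature's
log-weight by δ changes exactly that feature's marginal log-odds by δ; with
several affected features the marginal log odds ratio differs from δ by
`−log` of the weighted mean of `e^δ` over the other features, which the
random signs keep near zero. Recovery and coverage studies therefore plant
a single affected feature where the identity is exact.

Pathway membership is sampled per pathway from the ortholog-group pool,
with enriched pathways (20% by default) drawing diet-affected groups with
5-fold higher probability; database sizes exceed realized memberships by a
Poisson margin, mimicking partially observed reference pathways; some
groups land in several pathways by construction.

**What passing tests do not show.** The generator has no annotation noise,
no phylogenetic or co-occurrence structure among features, no litter
effects, symmetric Gaussian kitten effects, and a single overdispersion
scalar; real metagenome counts violate all of these. Calibration results
(type-I, coverage, LRT rates) demonstrate correctness of the machinery
under the stated model, not robustness to model misspecification.

## Reproducibility and numerics

All randomness flows from explicit integer seeds; the simulator derives
named substreams from its seed (hash-stable, process-independent), and the
pipeline CLI derives per-stage seeds from one global seed, so stages re-run
independently yet reproducibly. Validation studies in
`feligut.validation` are sized for a single CPU: 200 replicates for GEE
calibration, 500 for the LRT null, 100 for variance recovery, 10,000
permutations against the exact enrichment oracle, 25 exhaustive-search
parsimony instances, 2,000 rarefaction replicates per vector.

Known limitations: the GEE step fits one feature at a time and ignores
compositional coupling between features (a strong shift in a dominant
feature genuinely moves every other proportion — the tests account for
this); empirical enrichment p-values are granular at 1/n_perm; the
heteroscedastic model supports exactly the two-group variance structure the
design calls for.
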