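# Methods

## Data model

A plot table has one row per relevé: plot id, grid-cell coordinates
(lon/lat, decimal degrees), environmental attributes, and one column per
species holding an ordered cover-class label. The default scale is the
Braun-Blanquet-style convention

| class | interval (%) | midpoint (%) |
|------|---------------|--------------|
| 0 | {0} | 0 |
| + | (0, 1] | 0.5 |
| 1 | (1, 5] | 3 |
| 2 | (5, 25] | 15 |
| 3 | (25, 50] | 37.5 |
| 4 | (50, 75] | 62.5 |
| 5 | (75, 100] | 87.5 |

with half-open intervals `(lower, upper]` so every percent maps to exactly
one class; the scale is configurable and travels with the table in a JSON
sidecar. Class midpoints are the numeric abundance wherever a percent is
needed (SDM response, Bray-Curtis vectors, species predictors).

Grid-cell attributes follow the dominant-category rule (a category must
cover ≥ 70% of the cell, else "mix") and the growth-form rule (tree > 50%
tree cover, shrub < 25%, otherwise mix).

Two views of the same table feed the two model families:

* **categorical** (network learning): continuous attributes are binned into
  quartile classes (`q1..q4`, ordered); coordinates become one unordered
  spatial-block variable `spac` (3×3 equal-count lon/lat blocks); species
  keep their cover classes.
* **continuous** (SDMs): `Twarm`, `anualP`, lon, lat enter as numbers;
  unordered attributes are one-hot encoded against a reference level;
  species predictors enter as midpoint/100.

## Network inference

Structure learning is greedy hill climbing over DAGs with add/delete/reverse
moves, starting from the empty graph plus random-restart starts (default 5
starts per run), accepting the best score-improving move until a local
optimum. The score is BIC for multinomial networks,
`loglik − (log n)/2 · Σ_v (r_v − 1) q_v`, computed from maximum-likelihood
CPT estimates with `0·log 0 := 0`; family scores are cached, so move deltas
only rescore the families they touch. A BDeu alternative (`score="bde"`,
equivalent sample size 1) is available. Constraints are a hard blacklist:
no species → environment arc, no arc into `Twarm`, `anualP`, geology,
orientation, or the spatial block. On tables of ≤ 3 variables the climber
provably attains the global optimum found by exhaustive enumeration of all
25 DAGs (tested).

Consensus: the structure is learned `runs` times (default 500), each run on
a nonparametric bootstrap resample of the plots. We read "learned many
times" as bootstrap resampling because the arc-strength ECDF used by the
significance threshold presupposes resampling variability; restart-only
replication on the fixed data is available as `resample=False`. Per
undirected pair, `strength` = fraction of runs containing the arc either
way; the majority orientation is kept only if its share among containing
runs exceeds the direction cut-off (default 0.5), otherwise the arc is
direction-ambiguous: reported, but contributing to no parent set.

Significance threshold: among candidate thresholds t (0, the observed
strengths, and midpoints between consecutive distinct strengths), choose
the one minimising the L1 distance between the empirical CDF of strengths
and the idealised CDF that sends every strength ≤ t to 0 and every strength
> t to 1; arcs strictly above the chosen t are significant. The oriented
significant subgraph is kept acyclic by demoting, in increasing strength
order, any oriented arc that would close a cycle to direction-ambiguous
(bootstrap consensus does not otherwise guarantee acyclicity).

## Link signing

For each significant oriented link whose grouping variable has an ordered
domain, the Jonckheere-Terpstra statistic counts concordant cross-group
pairs with mid-rank ties (`+0.5` per tie), standardised by the null mean
`(N² − Σ nᵢ²)/4` and the tie-corrected null variance. For pooled N ≤ 10 an
exhaustive permutation enumeration replaces the normal approximation; the
p-value is two-sided in both cases and the sign is read post hoc from z at
α = 0.05. By default the parent defines the ordered groups and the child
provides the values (`group_by="child"` swaps the roles). Links from
unordered parents — geology, land use, orientation, growth form, spatial
block — are reported unsigned; quartile-binned climate inherits its numeric
order. No multiple-testing correction is applied across links.

## Species distribution models

Response: focal species cover midpoint / 100, a proportion in [0, 1],
fitted by penalized IRLS with logit link and binomial deviance at unit
weights (the proportion is not a count of trials, so the fit is
quasi-binomial in spirit; a trials-weighted variant was considered and
rejected because no trial count exists for percent cover). Predictors are
the focal species' significant parents — from the overall network (Env+Bio)
or its env-only network (Env); a species with no parents gets an
intercept-only model with no smooth.

Whenever the model has predictors it also receives a bivariate
thin-plate-type smooth of (lon, lat): two unpenalized linear terms in the
scaled coordinates plus radial functions `r² log r` centred on ~27 knots
spread deterministically over the observed plots (basis dimension 30 by
default), penalized by the bending-energy matrix. λ is selected on a
log-spaced grid (10⁻³…10⁷) by GCV, `n·deviance/(n − edf)²`. Effective
degrees of freedom are `tr[(XᵀWX + λS)⁻¹XᵀWX]`; AIC = deviance + 2·edf,
comparable across penalized fits. Non-convergence or separation is flagged
on the returned fit object (diagnostics string), never raised. The
unpenalized parametric path reproduces statsmodels' binomial GLM to 4+
decimals (tested).

The random baseline redraws k predictors uniformly from all non-focal
variables, with k equal to the species' Env+Bio predictor count.

## Evaluation

One global uniform split assigns `floor(2n/3)` plots to calibration
(1570 → 1046/524; the spec of the split is a single global partition so the
per-plot Bray-Curtis comparison has one shared validation set). Per
species, calibration rows are the calibration plots where the species is
present; species absent from all calibration plots are skipped with a
logged reason. Validation metrics use all validation plots: Spearman ρ
(mid-rank ties; undefined and reported missing when either vector is
constant), deviance explained `100·(1 − deviance/null deviance)`, AIC, and
per-plot Bray-Curtis similarity between the predicted community vector
(predicted proportions over all fitted species) and the observed midpoint
vector. Paired two-sided t-tests compare the families; zero-variance
difference vectors are flagged degenerate rather than producing spurious
t statistics.

## Synthetic communities

The generator's defaults are the study conditions: 68 species, 6
environmental attributes plus the spatial block, 1570 plots, 95% positive
signs, Poisson parent counts with mean 1.94, ~55% of parent draws biotic,
same-syndrome candidate arcs up-weighted ×3, and syndromes in the 33:27:8
T:Q:none proportion.

Signed dependence uses a proportional-odds construction: each ordered node
has latent cutpoints fixed by its base marginal (species are mostly absent:
base ≈ [0.45, 0.25, 0.15, 0.15] with Dirichlet jitter), and each ordered
parent shifts the latent scale by `sign · effect_strength · s(level)` with
levels centred onto [−1, 1]; multiple parents add on the latent scale.
Unordered parents contribute centred per-level offsets drawn uniformly in
±`effect_strength` and carry no sign. "+" arcs are therefore stochastically
increasing in the parent level (tested, including a Jonckheere-based
monotonicity property over 200 replicates).

Two deliberate identifiability choices, made at design time:

* **Species parent sets are capped at 2** (`max_parents`). A multinomial
  CPT family with q parent configurations and r child levels costs
  `(r−1)q` free parameters; with 4-level variables a 3-parent family has
  ≥ 192 parameters, which no score-based learner can justify at
  survey-scale n ≈ 1200–1600. A recovery benchmark against a ground truth
  that is unidentifiable at the stated sample size would measure nothing,
  so generated families are kept estimable.
* **The 9-level spatial block does not parent species by default**
  (`spatial_parent=False`); spatial structure reaches the data through the
  plots' coordinates (plots are placed uniformly within their block). A
  9-level confounder acting on many species sits exactly at the BIC margin
  and is otherwise absorbed into spurious species-species hub arcs.

Species use the lowest 4 classes of the cover scale (`n_cover_levels=4`,
the top class stretched to cover 100%): real relevés rarely populate the
high-cover bands for most species, and 4 levels keep CPT families
estimable while preserving a genuine abundance order.

What the generator does *not* emulate: spatially autocorrelated
environmental fields beyond block structure, realistic species-abundance
distributions (lognormal SADs), observation error in cover estimation, and
phylogenetic structure in the syndrome labels. Passing recovery tests
therefore show that the inference machinery is correct under the stated
generating process, not that real vegetation data satisfy it.

## Problem sizes used in tests and the acceptance script

Chosen once as the package's benchmark conditions: network recovery uses
20 species + 4 environmental nodes, 1200 plots, effect 2.5, 100 consensus
runs; the Env+Bio vs Env comparison uses 16 species, 900 plots, effect 2.0,
25 runs; the null calibration uses 20 communities of 8 species, 400 plots
with `fraction_species_parents=0`, 12 runs each; trend-test calibration
uses 1000 replicates of n = 120. The analysis scripts use 24 species and
1000 plots.

## Known limitations

* Hill climbing explores DAG space, not equivalence classes; orientation of
  covered edges rests on the bootstrap direction support and the
  constraint blacklist rather than on score differences.
* The significance threshold assumes a bimodal strength distribution; with
  very few consensus arcs it can place the cut so that all or none are
  significant.
* The thin-plate smooth shares one λ across both coordinates and is not
  the full mgcv-style basis with null-space absorption; at λ → ∞ it shrinks
  to the linear trend in lon/lat rather than to zero.
* AIC on unit-weight proportion deviance under-weights likelihood gains
  relative to a trials-weighted binomial AIC; it is comparable across
  models of the same species, which is the only use made of it.
* The evaluation treats observed covers of validation plots as known when
  species predictors enter the Env+Bio predictions, as in the source
  workflow; it measures conditional predictive skill, not forecasting of
  an unobserved community.
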