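# Methods

## Model

`mutrate` models somatic single-nucleotide variants as independent draws,
per genomic position and per tumor sample, from a categorical distribution
over "no mutation" and the three possible substitutions of the site. Under
strand symmetry a substitution and its reverse complement are one class,
reported on the strand carrying the pyrimidine: sites split into C-sites and
T-sites, with mutation classes {C>A, C>G, C>T} and {T>A, T>C, T>G} and 32
trinucleotide contexts (2 strand classes × 4 left × 4 right neighbors).

The site multinomial model places three logits per strand class against the
no-mutation reference:

    log(p_i,sam^{type} / p_i,sam^{ref}) =
        μ_sam^{type} + Σ_j β_j,can^{type} · x_i,j

with a sample-specific intercept μ and covariate effects β stratified by the
sample's cancer type. Because every term carries mutation-type-specific
coefficients, the likelihood factorizes exactly into the C-site and the
T-site block; the package fits the two 4-category blocks separately and
reports them jointly, which is algebraically identical to a single model
with strand-class dummies. Coarser granularities — a binomial site model of
mutated-versus-not and a Poisson region model with log(L_r) exposure offset —
share the same intercept/term structure and are provided for comparison.

Assumptions worth keeping in mind: independence across sites and samples (no
clustered mutational processes), no overdispersion beyond what the
covariates capture, and covariates treated as fixed and error-free.

## Collapsed count tables

Continuous annotations are discretized at genome-wide quantiles (quintiles
by default; quartiles for GC content, where windows under 10% G:C map to a
special bin with representative 0). Each bin is represented by its
within-bin mean, values at a boundary fall to the lower bin, and values
outside the fitted range are clamped. After binning, all sites sharing a
covariate combination are exchangeable, so the data collapse to one row per
(combination, sample) holding the three substitution counts and the
no-mutation count. The table is the sufficient statistic: the weighted
likelihood on the collapsed table equals the per-observation likelihood up
to a constant, which the test suite verifies by refitting on a fully
expanded table (agreement to 1e-6 on every coefficient).

Coordinates follow the field's conventions bit-exactly: 1-based mutation
positions (VCF), 0-based half-open intervals (BED), 0-based internal site
indices. Overlapping genomic-element annotations resolve by functional
precedence (coding > 5'UTR > 3'UTR > ncRNA > intron > intergenic); sites
with a missing continuous annotation are excluded rather than imputed.

## Estimation

The default estimation route fits each mutation type against the
no-mutation reference in a separate weighted binary logistic regression
(statsmodels GLM, binomial family) — cheap, embarrassingly separable, and
nearly exact in the rare-event regime where per-site probabilities are
~1e-3 (the routes agree below 0.02 per identified coefficient in the test
suite). The exact route maximizes the joint multinomial likelihood by
Newton–Raphson with step-halving, convergence when the relative
log-likelihood change drops below 1e-9, at most 100 iterations. Either way,
standard errors come from the observed information of the *full* multinomial
likelihood evaluated at the final estimates (block structure over outcome
pairs), inverted by Cholesky with a pseudo-inverse fallback for singular
designs.

Categorical terms use treatment coding (alphabetically first level as
reference), which keeps the design identifiable next to per-sample
intercepts. The nominal parameter accounting (`count_parameters`) instead
follows the conventional full-dummy bookkeeping of whole-genome designs —
e.g. 4·4·6 = 96 context parameters per cancer type, 6·505 = 3030 sample
intercepts — so its totals match published design sizes while the fitted
coefficient vector is slightly shorter.

Fractional counts are handled as observation weights throughout, which is
what makes the pseudo-count adjustment (below) transparent to the fitting
code.

## Pseudo counts

Sparse tables produce cells with zero observed mutations of some type, which
sends the corresponding logit to −∞. For every row with at least one zero
substitution count the count vector (including the no-mutation component) is
replaced by

    ñ_K,sam = ½ n_K,sam + (N_K,sam / 2 N_K,can) · n_K,can

where n_K,can is the componentwise sum over all samples of the row's cancer
type. This is a Dirichlet prior proportional to the cancer-type profile; it
preserves the per-sample row total exactly and leaves fully positive rows
untouched. Two deliberate consequences:

* Cells whose *cancer-aggregate* count is itself zero stay zero — the
  adjustment is proportional to the aggregate — so such coefficients remain
  unidentified (they are rare in realistic cohorts). If an entire aggregate
  row is empty (not reachable when aggregates come from the same table), a
  Jeffreys-style +0.5 per outcome is applied and logged.
* The adjustment is shrinkage and therefore biased. Parameter-recovery
  validation consequently uses the plain MLE (at the generator's default
  rates every sample × type stratum is populated); pseudo counts stay on
  inside cross-validated selection, where training folds routinely contain
  empty cells.

## Model fit and validation metrics

* **Deviance loss** D = −2 Σ n · log p̂ over the four outcomes, weighted by
  collapsed counts. Held-out probabilities below 1e-12 are floored (and
  logged) so an unseen level cannot produce an infinite loss.
* **McFadden's pseudo R²** = 1 − log L_M / log L_0. The no-predictor null
  assigns the same probability to each mutation type; the two natural
  readings — one shared per-type probability estimated from pooled data, and
  the total rate split equally over the three types — lead to the same ML
  estimate q̂ = M/(3N) under this likelihood, so they coincide. A `per-type`
  null (six pooled type-specific rates, no covariates) is also available.
  The single-rate reference model evaluated against itself gives R² = 0
  exactly.

## Forward selection

Selection runs on a random subsample of non-overlapping, grid-aligned 1 kb
windows. Folds for 5-fold cross-validation are assigned at the window level,
so kilobase-scale spatial correlation stays within folds. Each remaining
candidate is scored by the summed held-out deviance (tables rebuilt per
candidate, so no table carries more variables than its model); the argmin
joins the model, with ties broken by candidate declaration order and
non-converging candidates marked failed. The search stops after `max_steps`
(default 3) or when the improvement falls below 1e-4 of the base model's CV
deviance — a deliberately conservative proxy for "the improvement levels
off". Cancer types below a configurable mutation-count threshold can be
excluded; this only filters rows entering the tables, never the mechanics.

## Evaluation granularities

Expected window counts for site models are Σ sites × samples of
(1 − p̂(no mutation)); for the Poisson model, λ̂. For single-site scoring the
region-trained Poisson model has no sub-region information, so its rate is
spread uniformly: p̂_site = λ̂_r,sam / L_r with L_r the region's retained
sites — a modelling choice, documented here. Type-blind models (binomial,
Poisson) are scored on the type-resolved outcome by splitting their total
mutation probability uniformly over the three substitution types.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions
for every downstream validation:

* **Reference**: iid sequence with G:C fraction 0.41 (human-like), default
  200 kb on one chromosome.
* **Samples**: 3 cancer types × 17 samples by default.
* **Tracks**: replication-timing- and expression-like smooth tracks (moving
  average of white noise over a 10 kb window; the timing track rescaled to
  [0, 1] from early to late), a conservation-like iid per-base score
  (SD 1), CpG-island- and repeat-like interval dummies (≈2% and 5% of the
  genome), a six-label element partition (geometric blocks, mean 2 kb), and
  a GC-content track computed from the generated sequence in 1 kb windows.
* **Generative model**: per-type baseline probability 1e-3 per site and
  sample — a desk-scale analogue chosen once; real whole-genome per-site
  rates (~1e-5) would leave almost no mutations at 200 kb. On top sit a
  transition bias (C>T +0.7, T>C +0.3 log-odds), cancer-type shifts
  (SD 0.3), a shared per-sample rate spread (SD 0.5), neighbor-context
  effects (SD 0.3) with a +1 CpG C>T deamination boost, and covariate
  effects of −0.4 (conservation) and +0.8 (replication timing), jittered by
  cancer type (SD 0.1).
* Mutation outcomes are drawn from the softmax of the model logits using the
  **binned** covariate representatives — exactly the covariates the
  downstream regression sees — so the fitted family contains the truth and
  confidence-interval coverage can be measured cleanly. All randomness
  derives from the configuration seed; a fixed seed fixes every byte.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: mutation clustering and kataegis, signature
mixtures beyond the single context-effect layer, mappability and calling
artifacts, subclonal structure, chromatin realism, and covariate measurement
error. The generator validates the *machinery* (estimation, selection,
prediction), not the biology of any particular cohort.

## Problem sizes in the validation suite

The simulation-based checks use sizes picked to make their statistical
claims decisive at desk scale: parameter recovery on 200 kb × 51 samples ×
3 cancer types (≥90% Wald-interval coverage over ~600 coefficients);
the granularity comparison on 20 cohorts of 400 kb × 16 samples, scored on
1000 held-out sites and four 100 kb windows; forward selection on 20 runs
of 150 kb × 10 samples with 30 sampled 1 kb windows and 5 folds.

## Known limitations

* No overdispersion: unexplained variance beyond the covariates is not
  modelled (by design — it would not change point predictions).
* Coefficients for strata with zero cancer-aggregate counts are unidentified
  and surface as huge standard errors; downstream prediction floors their
  probabilities rather than refusing to predict.
* The Poisson single-site rule (uniform rate density) is one of several
  defensible choices; alternatives (e.g. covariate-weighted spreading) would
  blur the region/site contrast the comparison is designed to expose.
* Expression is emulated as a smooth track rather than a gene-level
  quantity; the gene-body dummy + cumulative-sum expression covariate path
  is implemented and tested, but the default generator does not couple the
  two.
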