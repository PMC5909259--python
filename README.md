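# mutrate

Site-specific regression models of the neutral somatic mutation rate in
cancer genomes.

Detecting driver mutations requires knowing how often a position would mutate
*by chance*. That neutral rate is anything but uniform: it differs between
cancer types, between patients, and along the genome with trinucleotide
context, replication timing, conservation, expression and chromatin state.
Region-based models average these covariates away; `mutrate` instead models
the probability of each substitution type at every single position and
compares that site-specific view with coarser alternatives.

The package is aimed at cancer-genomics researchers who want a transparent,
testable background model — e.g. as the null model for driver-detection
methods — and ships a synthetic-data generator so the whole pipeline can be
exercised and validated without any external data downloads.

## The models

All models share the structure "sample-specific intercept + cancer-type-
stratified covariate effects" and are fitted on collapsed count tables.
For sites, mutations are strand-symmetric: a substitution is reported on the
strand carrying the pyrimidine (C or T), giving 6 mutation classes and
2 × 4 × 4 = 32 trinucleotide contexts.

* **Poisson region model** — counts N_r,sam in region r of length L_r:

      log λ_r,sam = μ_sam + β_1,can x_r,1 + … + β_J,can x_r,J,   λ = L_r · p

* **Site binomial model** — mutated or not at site i:

      logit p_i,sam = μ_sam + β_1,can x_i,1 + … + β_J,can x_i,J

* **Site multinomial model** — three logits per strand class against the
  no-mutation reference, e.g. for a G:C base pair:

      log(p^{C>A}/p^{C>C}) = μ_sam^{C>A} + β_1,can^{C>A} x_i,1 + …
      log(p^{C>G}/p^{C>C}) = μ_sam^{C>G} + β_1,can^{C>G} x_i,1 + …
      log(p^{C>T}/p^{C>C}) = μ_sam^{C>T} + β_1,can^{C>T} x_i,1 + …

Continuous annotations are discretized into quantile bins (each bin
represented by its within-bin mean), so all sites sharing a covariate
combination collapse into one count-table row per sample — the table size is
bounded by combinations × samples, independent of genome length. Zero cells
are handled by a Dirichlet-prior pseudo-count rule that preserves each
sample's total count; explanatory variables are chosen by forward selection
under 5-fold cross-validated deviance loss; model fit is summarized by
McFadden's pseudo R².

## Worked example

```python
import numpy as np
from mutrate import synthetic, glm
from mutrate.glm import ModelSpec, Term
from mutrate.tabulate import build_count_table

config = synthetic.SyntheticConfig(genome_length=100_000, n_cancer_types=2,
                                   samples_per_cancer_type=5, seed=1)
ds = synthetic.synthesize(config)

table = build_count_table(ds.sites, ds.annotated_mutations(), ds.samples,
                          covariates=["conservation", "replication_timing"])

spec = ModelSpec(intercept_scope="per_sample", context=True,
                 terms=(Term("conservation"), Term("replication_timing")))
fit = glm.fit_multinomial(table, spec, method="exact")
print(f"log-likelihood {fit.loglik:.1f}, "
      f"McFadden R2 {glm.mcfadden_r2(fit, table):.4f}")

beta = fit.coefficients.set_index(["outcome", "term"]) \
    .loc[("C>T", "b[replication_timing|C1]")]
print(f"C>T replication-timing coefficient (C1): "
      f"{beta['estimate']:.3f} +/- {beta['se']:.3f} "
      f"(fold change late vs early: {np.exp(beta['estimate']):.2f})")
```

prints

```
log-likelihood -57329.7, McFadden R2 0.0465
C>T replication-timing coefficient (C1): 0.758 +/- 0.163 (fold change late vs early: 2.13)
```

The simulated cohort (8808 mutations, 10 samples, 100 kb) was generated with
a true replication-timing effect of +0.8 on the log-odds scale; the fit
recovers 0.76 ± 0.16. Since replication timing runs from 0 (early) to 1
(late), exp(β) ≈ 2.1 is the fitted fold increase in C>T mutation rate in
late- versus early-replicating DNA for cancer type C1.

The same pipeline is available from the shell:

```bash
mutrate simulate --out data/ --seed 1 --length 100000
mutrate tabulate --data data/ --covariates conservation --out table.tsv
mutrate fit --table table.tsv --pseudo-counts --out fits/model
mutrate select --data data/ --candidates conservation,replication_timing,gc --out path.tsv
```

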