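# moduledisease

Quantitative disease similarity from the expression responses of
functional modules.

Most disease-similarity resources are built from what is already known —
shared disease genes or shared clinical vocabulary — and so struggle to
reveal new relationships. This package implements an integrated,
data-driven alternative for systems biologists: it combines case/control
mRNA expression compendia with a catalog of functional modules (gene
sets standing in for protein complexes and pathways, typically mined
from a protein-interaction network) to score how strongly each module is
dysregulated in each disease, and then compares diseases by those module
responses.

## The method

For each disease *k* with one or more case/control expression studies:

1. **Normalization.** Every sample column is z-scored:
   `z_ij = (g_ij − mean(g_j)) / sd(g_j)`.
2. **Gene response score** `S_ik`: the t-statistic contrasting disease
   against control samples. With several studies per disease the score is
   the t-statistic of β₁ in the fixed-effects regression
   `Y = β₀ + β₁·X + Σ_k γ_k·I_k`, where `X` is the disease indicator and
   the `I_k` are experiment indicators absorbing between-study offsets;
   with a single study this is exactly the pooled two-sample t.
3. **Module Response Score** `M_ik`: the mean of `S_ik` over the module's
   member genes (positive = up-regulated in disease). A companion
   control-response matrix holds the mean control z-score of the same
   genes.
4. **Disease similarity**: the partial Spearman correlation of two
   diseases' MRS vectors conditioned on both diseases' control responses,
   computed by the recursion
   `r_xy·z = (r_xy − r_xz·r_yz) / √((1−r_xz²)(1−r_yz²))`
   applied twice on average-tie ranks (equivalently, correlation of rank
   residuals). Conditioning on the control responses removes shared
   tissue/cell-type structure.
5. **Significance**: a randomization null built by degree-preserving
   rewiring of the gene–module bipartite graph plus within-study
   disease/control label shuffling, repeated (default 100×) and pooled;
   empirical p-values use the add-one rule and an empirical FDR is
   reported at the chosen cutoff. Diseases are also clustered by average
   linkage at distance 1 − ρ, and the significant-pair network is
   exported in Cytoscape SIF form.
6. **Common disease-state signature**: modules whose median |MRS| across
   diseases beats a catalog-randomization null (p < 0.01) and whose
   |MRS| exceeds 1.5 in a minimum number of diseases.
7. **Enrichment**: hypergeometric upper-tail tests for shared disease
   genes and shared drugs between similar diseases, a one-sided Fisher
   concordance test, druggable-family enrichment of signature genes, and
   a permutation comparison of how many diseases the drugs of signature
   targets treat.

A seeded synthetic-data generator (`moduledisease.simulate`) produces
expression compendia, module catalogs and knowledge bases with known
planted structure, so every stage can be validated against ground truth.

## Worked example

```python
from moduledisease import (SimulationConfig, generate_module_catalog,
                           generate_disease_compendium)
from moduledisease.nulls import build_null, compute_response_matrices, empirical_pvalues
from moduledisease.similarity import pairwise_disease_similarity

cfg = SimulationConfig(seed=3, n_genes=300, n_modules=60, n_diseases=6,
                       planted_pairs=[("d00", "d01", 0.8)])
catalog = generate_module_catalog(cfg)
studies, truth = generate_disease_compendium(cfg, catalog)

mrs, ctrl = compute_response_matrices(studies, catalog)
sim = pairwise_disease_similarity(mrs, ctrl)
null = build_null(studies, catalog, replicates=100, seed=5)
sim.assign_pvalues(null.values)
print(sim.pairs.sort_values("rho", ascending=False).head(3).to_string(index=False))
```

```
disease_a disease_b      rho  n_modules        p  significant
      d00       d01 0.786888         60 0.000666        False
      d02       d04 0.392025         60 0.005996        False
      d01       d05 0.170992         60 0.131246        False
```

The planted pair (d00, d01) — two diseases sharing 80% of their
dysregulated modules at a 3σ effect — tops the ranking with a partial
Spearman ρ of 0.79 over 60 modules and an empirical p of ~7e-4 against
1,500 pooled null correlations (p-values are filled in by
`assign_pvalues`; the `significant` flag is set by
`sim.mark_significant(0.01)`). The remaining pairs correlate only
through chance module overlap.

The same analysis is available as a CLI (`moduledisease simulate`,
`score`, `mrs`, `similarity`, `null`, `signature`, `enrich`, or
`moduledisease run --config cfg.yaml` for the whole pipeline with a
manifest of checksummed outputs).

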