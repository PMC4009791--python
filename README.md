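# somportraits

Self-organizing-map (SOM) **expression portraits** for transcriptome cohorts:
a library and CLI for portraying each sample's genome-wide expression state,
carving the landscape into co-expression **spot modules**, annotating them
with gene sets, mapping sample similarity, and deriving **molecular
subtypes** with resampling-based validation and survival characterization.

## Who this is for

Groups analyzing cohort-scale expression matrices (microarray or summarized
RNA-seq; bulk or pseudo-bulked single cell) who want an interpretable,
module-level view of heterogeneity — e.g., refining molecular subtypes of a
tumor entity, spotting contaminated biopsies, or linking expression modules
to phenotype and outcome.

## The method in brief

Starting from a genes × samples matrix of raw intensities:

1. **Preprocessing.** Quantile normalization across samples, log10
   transformation, and centering of each gene on its cohort mean. The result
   is the log fold change Δe_{i,m} of gene *i* in sample *m*; Δe = 0 means
   "expressed at its cohort-average level".
2. **SOM training.** A rectangular grid of K metagenes (default 50×50,
   scaled down for smaller studies) is fitted to the gene cloud with the
   online SOM rule and a Gaussian neighborhood, giving a K × M metadata
   matrix Δe^meta_{k,m}. Each metagene is a prototype profile of a cluster
   of co-expressed genes; each sample's column, arranged on the grid, is its
   expression *portrait*.
3. **Spot modules.** Per sample, tiles beyond the 98th (over) / 2nd (under)
   percentile are selected; the selections are transferred onto one summary
   map whose 4-connected regions define disjoint, letter-labeled spots —
   the cohort's expression modules.
4. **Enrichment.** Spots are annotated by hypergeometric overrepresentation
   of GMT gene sets (Bonferroni threshold α/n, i.e. p < 10⁻⁵ at α = 0.05
   and n ≈ 5,000 sets) and by the per-sample **gene set Z-score**
   GSZ_m = (⟨Δe⟩_set,m − ⟨Δe⟩_all,m) / (s_m · √(1/n_set − 1/N)),
   plus population maps of set members on the grid.
5. **Similarity.** Pairwise Pearson correlation of sample meta-states
   (heatmap + thresholded correlation network, default r > 0.5),
   neighbor-joining tree on Euclidean distances, and a 2-component ICA
   embedding.
6. **Outlier correction.** Spots whose top-enriched set belongs to a flagged
   contamination category (tissue signatures, drug metabolism, …) are
   removed gene-wise and the SOM is retrained.
7. **Subtyping.** k-means on sample meta-states initialized at *artificial
   portraits* (max metadata value on a spot, 0 elsewhere), per-sample
   bootstrap stability scores, and consensus clustering over k = 2…6 with
   CDF-based assessment of the class number.
8. **Characterization.** Exact r×c Fisher tests of subtype × phenotype
   tables and Kaplan-Meier / log-rank survival comparison.

A built-in synthetic-cohort generator (four subtypes, two antagonistic main
modules, two intermediate modules, a contamination signature,
subtype-dependent survival) makes the whole pipeline testable end to end
without any external data.

## Worked example

```python
from somportraits import (SOMConfig, SyntheticConfig, generate_cohort,
                          generate_survival, preprocess, train_som)
from somportraits.spots import detect_spots
from somportraits.subtyping import kmeans_assign, prototype_from_spot
from somportraits.survival import logrank_test

cfg = SyntheticConfig(seed=1)                      # 2,000 genes x 120 samples
raw, truth = generate_cohort(cfg)
logfc = preprocess(raw)                            # quantile -> log10 -> center
model = train_som(logfc, SOMConfig(rows=20, cols=20, seed=1))
spots = detect_spots(model, percentile=98.0)
print(f"{len(spots)} over-expression spots; largest:")
for s in sorted(spots, key=lambda s: -len(s.genes))[:5]:
    print(f"  spot {s.label}: {len(s.metagenes)} metagenes, {len(s.genes)} genes")

top = sorted(spots, key=lambda s: -len(s.genes))[:5]
contam = set(truth.module_gene_ids("contamination"))
top4 = [s for s in top if len(contam & set(s.genes)) < len(s.genes) / 2][:4]
prototypes = {s.label: prototype_from_spot(s, model) for s in top4}
result = kmeans_assign(model.metadata, prototypes, sample_ids=model.sample_ids)
print("subtype sizes:", result.labels.value_counts().to_dict())

surv = generate_survival(truth, cfg)
stat, p = logrank_test(surv.times, surv.events, result.labels.to_numpy())
print(f"log-rank across subtypes: chi2 = {stat:.1f}, p = {p:.2g}")
```

Output:

```
37 over-expression spots; largest:
  spot E: 11 metagenes, 100 genes
  spot AH: 9 metagenes, 100 genes
  spot A: 8 metagenes, 80 genes
  spot AJ: 8 metagenes, 80 genes
  spot Q: 7 metagenes, 60 genes
subtype sizes: {'AH': 39, 'E': 34, 'AJ': 24, 'A': 23}
log-rank across subtypes: chi2 = 17.4, p = 0.00058
```

The four largest non-contamination spots are exactly the four planted
100/100/80/80-gene modules (spot Q, 60 genes, is the contamination
signature); prototype-guided k-means recovers the planted subtype sizes
(34/23/24/39), and survival differs strongly between subtypes because the
generator gives the two intermediate classes shorter median survival.

The same flow is available from the shell:

```bash
somportraits run-all --out run --seed 1       # synthetic cohort end to end
somportraits simulate --out data --seed 1     # or stage by stage:
somportraits preprocess --matrix data/expression_raw.tsv --out data/logfc.tsv
somportraits train --matrix data/logfc.tsv --rows 20 --cols 20 --out data/som.zip
somportraits spots --model data/som.zip --out data/spots
```

`run-all` writes all stage outputs (expression TSVs, the SOM model archive,
spot reports, enrichment tables, correlation matrix/network, NJ tree, ICA
coordinates, subtype labels with stability scores, consensus CDFs, KM
tables) plus a `manifest.json` recording stages, parameters and seeds into
one directory; a single global seed makes the bundle byte-reproducible.

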