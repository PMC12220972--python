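# clonotrace

Tracking T cell clones shared between blood and tumor from paired
single-cell RNA + TCR sequencing.

## The problem

Tumor-reactive T cells circulate: a clone seen infiltrating a tumor can
also be found in the patient's blood, where it is accessible for
monitoring and cell-therapy isolation. Because the rearranged TCRαβ
CDR3 amino-acid sequence is effectively unique per clone, an exact
match of both chains between a blood cell and a tumor cell of the same
patient is strong evidence that the two cells descend from one parent
T cell and share antigen specificity. `clonotrace` implements the
cell-level analysis that makes this usable on 10x-style data:

1. **Clonotype resolution** — per barcode and locus (TRA/TRB), the most
   abundant clonotype call wins; ties are broken by alignment score,
   then lexicographically. Only cells with both chains are kept.
2. **TCR identity networks** — per patient and lineage (CD4/CD8), cells
   are nodes and an edge requires Levenshtein distance 0 on **both**
   the α and β CDR3 (i.e., exact amino-acid identity). Connected
   components are *clonal clusters*; a cell is *expanded* if its node
   degree > 0 and *matched* if its cluster contains at least one blood
   and one tumor cell. Since distance 0 is string identity, components
   are computed by exact-match grouping — provably equivalent to the
   O(n²) pairwise-distance construction and tested against it.
3. **Network metrics** — per network, the number of clusters and the
   maximum cluster size, each normalized by cell count and log₁₀
   transformed:  `n_clusters_norm = log10(n_clusters / n_cells)`.
4. **Composition tracking** — phenotype proportions within all /
   expanded / matched cells per compartment, and per-cluster phenotype
   or KLRG1/MKI67 transcript-state fractions before and after
   immunotherapy (clusters weighted equally).
5. **Statistics** — cluster-count contrasts (blood vs tumor, matched vs
   nonmatched) via a linear mixed model, `log10(count) ~ specimen +
   (1 | patient)` fit by REML with small-sample t inference;
   Mann-Whitney / Wilcoxon / Kruskal-Wallis / Friedman with Dunn's
   multiple-comparison tests; Benjamini-Hochberg FDR.
6. **QC** — mitochondrial-fraction filtering (> 10% removed), scaling
   to 10,000 counts per cell with log₂(1 + x) transform,
   background-corrected gene-signature scores, transcript positivity.

A **synthetic repertoire generator** (`clonotrace.simulate`) produces
paired cell metadata, chain-level clonotype calls, and a marker-gene
count matrix with known clonal ground truth — multiple patients,
blood/tumor/NAT compartments, geometric clone sizes, phenotype-dependent
blood-tumor sharing, and a post-treatment shift that raises MKI67 and
lowers KLRG1 in cytotoxic clones — so every downstream stage is
testable without any sequencing data.

## Worked example

```python
from clonotrace import *
from clonotrace.simulate import SimConfig

cfg = SimConfig(n_patients=3, seed=42)
cells, adata, truth = simulate_dataset(cfg)     # 7,800 cells, 45 genes
calls = simulate_reads(cells, truth, cfg)       # 12,624 chain-level calls
res = run_pipeline(cells, calls)                # resolve -> network -> label
print(len(res.pairs), res.pairing_rate_pct)     # 3844 49.3
```

With the default per-chain dropout of 0.30, 49.3% of cells yield a
paired TCRαβ — the square of the per-chain capture rate, and in the
range typical of droplet scTCR enrichment. The label table then gives
per-lineage expansion and matching rates:

```
         expanded  matched
CD4         0.445    0.085
CD8         0.485    0.093
```

Matched blood CD4⁺ cells are dominated by cytotoxic phenotypes, because
the generator (like the biology it emulates) shares cytotoxic tumor
clones into blood far more often than naive or regulatory ones:

```python
comp = composition_by_category(res.labels, by=("compartment", "lineage"))
# matched blood CD4 composition, top 4:
# Prolif 0.272, GZMB+ 0.216, GZMK+ 0.208, Treg 0.112
```

Per-network metrics and the mixed-model specimen contrast:

```python
model = fit_cluster_count_model(res.metrics, value_col="n_clusters",
                                normalize_col="n_cells")
# coef 0.027 (SE 0.013, p = 0.078): tumor repertoires trend toward
# relatively more clusters per cell than blood in this small simulation
```

Against the simulation's ground truth, matched/nonmatched labels are
94.8% accurate under read dropout (dropout hides some tumor partners)
and exactly 100% accurate when reads are simulated noiselessly; the
recovered cluster partition is identical to the true clone partition
(adjusted Rand index 1.0):

```python
report = evaluate_recovery(res.labels, truth)
# report.matched_accuracy = 0.948, report.partition_ari = 1.0
```

The same stages are scriptable from a shell:

```bash
clonotrace simulate --out sim/ --seed 3
clonotrace qc --matrix sim/counts --out qc/
clonotrace resolve --airr sim/airr.tsv --cells sim/cells.tsv --out pairs.tsv
clonotrace network --pairs pairs.tsv --cells sim/cells.tsv --out net/ --graphml
clonotrace compose --labels net/labels.tsv --out comp/
clonotrace stats --metrics net/metrics.json --contrast compartment
```

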