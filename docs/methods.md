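# Methods

## Clonotype resolution

Chain-level clonotype calls (one row per barcode × locus × candidate
junction, with read counts and alignment scores) are resolved per cell
and locus by three ordered rules: highest read count, then highest
alignment score, then lexicographically smallest junction. The first
two rules are the standard abundance/score acceptance criteria for
10x-derived TCR amplicons; the third is our own addition so that
resolution is a pure function of the call set — without it, equal-count
equal-score ties would depend on input order. Cells lacking either a
resolved TRA or TRB are dropped with a reason code (`missing_TRA`,
`missing_TRB`, `no_tcr`); repertoire analyses use paired cells only.
Identity is at the amino-acid level throughout; dual-α biology is
ignored (one pair per cell).

## Identity networks

Networks are built per patient × lineage (CD4/CD8), pooling all
compartments and timepoints of that patient. Two cells are connected
iff the Levenshtein distance between their α junctions is 0 **and**
between their β junctions is 0. Distance 0 is string identity, so
connected components are computed by exact-match grouping on the
(cdr3a, cdr3b) pair — O(n) instead of O(n²) — and the test suite
verifies equivalence against a brute-force pairwise-distance
construction (edit distances via edlib, checked against an independent
dynamic-programming oracle). Clusters include singletons; ids are
assigned by smallest member cell id, making them stable under input
permutation. Labels: *expanded* = degree > 0 (cluster size > 1);
*matched* = cluster contains ≥ 1 blood and ≥ 1 tumor cell. NAT cells
ride along in networks but never confer matched status, since matching
is defined between blood and tumor only.

Network metrics are the number of clusters and the maximum cluster
size, each divided by the number of cells and log₁₀ transformed; both
are therefore ≤ 0 and a fully unique repertoire has
`n_clusters_norm = 0`. Metrics can be computed on any cell subset
(e.g. matched-only), which equals restricting the identity graph to
those nodes.

## QC and expression calls

Cells with a mitochondrial count fraction strictly greater than 10%
are removed (a cell at exactly 10% is retained); zero-count cells have
an undefined fraction and are removed with reason `zero_counts`.
Surviving cells are scaled to 10,000 counts and transformed
log₂(1 + x); we normalize first and log-transform second, the
conventional order, which makes per-cell totals comparable and
preserves within-cell rank order. Signature scores are the mean
normalized expression of the signature genes minus the mean of a
size-matched random background gene set drawn with a fixed seed;
scores are therefore centered near 0 for uninformative signatures and
deterministic given the seed. Rank comparisons between phenotypes are
insensitive to the choice between raw-mean and background-corrected
scoring. Transcript positivity (used for the KLRG1/MKI67 state
analysis) is raw count ≥ 1, exposed as a parameter since droplet data
gives no principled threshold between 0 and 1.

## Composition tables

Category tables (all / expanded / matched) are proportions over
*cells* within patient × compartment × lineage strata. Longitudinal
and transcript-state tables are per *cluster*, each cluster weighted
equally, matching the per-cluster unit of pre/post treatment
comparisons. Pre/post pairing is by cluster id within patient;
clusters observed at only one timepoint are excluded (with a warning),
not imputed. For the four-state KLRG1/MKI67 table
(K+M−, K−M+, K+M+, K−M−) clusters need `min_cells` (default 3) cells
at every requested timepoint; the original analysis does not state its
inclusion rule, so the default is our own choice and is a parameter.

## Statistics

Cluster-count contrasts use a linear mixed model: the outcome is
log₁₀(count) (optionally count / n_cells first), the 2-level contrast
(blood vs tumor, or matched vs nonmatched) is a fixed effect, and
patient a random intercept, fit by REML (statsmodels MixedLM). The
coefficient is the non-reference minus reference level. Inference uses
a t reference distribution with df = n_obs − n_patients − 1 rather
than Wald-normal: with a handful of patients, normal intervals
undercover a known effect, while the t correction restores ~95%
coverage (this is the same motivation as lmerTest-style df corrections
in R). A zero-variance outcome returns a flagged degenerate result
(coef 0, p 1); a non-converged or singular REML fit is refit by
Nelder-Mead and flagged, never silently dropped. Per-phenotype model
batteries are Benjamini-Hochberg adjusted.

Nonparametric comparisons dispatch on design and group count:
Mann-Whitney U (2 unpaired), Wilcoxon signed-rank (2 paired; identical
groups return p = 1 rather than an error), Kruskal-Wallis or Friedman
(≥ 3 groups) followed by Dunn's pairwise z-tests (pooled-rank form
with tie correction for the unpaired case, within-block rank sums for
the paired case), Bonferroni-adjusted as in Prism. Dunn's tests are
implemented here directly since no installed package provides them;
simulation shows family-wise error ≤ nominal under the null.

## The synthetic repertoire generator

The generator encodes the statistical structure of a multi-patient
bladder-cancer cohort with blood, tumor and optional NAT compartments:

- **Clone sizes** are geometric with parameter p = 0.65 (65%
  singletons, mean ≈ 1.5), giving the unique-dominated repertoires
  typical of T cell data. No empirical clone-size law is available to
  calibrate against, so this is a plausible stand-in, not a fit.
- **Sharing**: each tumor clone seeds blood with a phenotype-dependent
  probability (defaults 0.40/0.30/0.30/0.25 for GZMB+/GZMK+/Prolif/
  MAIT, 0.05 otherwise), reproducing the observation that cytotoxic
  phenotypes dominate the blood-tumor matched repertoire. A shared
  clone's blood size is the sum of r = 3 geometric draws (a negative
  binomial), because tumor-matched clones are clonally expanded in
  blood — large enough to be trackable across timepoints. The ground
  truth records the *realized* shared flag (≥ 1 blood and ≥ 1 tumor
  cell), so blood-quota truncation cannot desynchronize truth and
  labels.
- **Compartment quotas are exact**: clone sizes are drawn until the
  quota is filled and the last clone truncated, so every simulated
  dataset has precisely the configured cells per compartment.
- **Phenotypes** come from per-compartment frequency tables over the
  11 labels (Naive, GZMB+, Mito, CM, GZMK+, CXCL13+, Treg, Prolif,
  MAIT, EA, IFN); blood is naive/memory-dominated, tumor enriched for
  GZMK+, CXCL13+ and Treg.
- **Counts**: a small marker panel (GZMB, GZMK, MKI67, KLRG1, CCR7,
  SELL, IL7R, FOXP3, CXCL13, SLC4A10, IFIT1, CYCS), three
  mitochondrial genes, and 30 filler genes. Per-cell counts are
  negative binomial (gamma-Poisson, dispersion 2) with
  phenotype-dependent means. The Mito phenotype sits near the 10% QC
  boundary, and a 2% rate of high-mito "stressed" cells exercises the
  filter. Treatment effect: in cytotoxic clones at the post timepoint,
  MKI67 means ×4, KLRG1 means ×0.25, and each cell converts to the
  Prolif phenotype with probability 0.25 (clonal plasticity under
  PD-L1 blockade).
- **TCRs**: junctions are uniform random amino-acid strings of total
  length 8–20 with CA…F / CASS…F motifs, globally unique per clone
  (collisions rejected), so TCR identity ⇔ clone identity in truth.
- **Reads**: per chain, dropout probability 0.30 (pairing ≈ 0.7² ≈
  49%, matching observed droplet pairing rates of ~45–55%), decoy
  calls with equal count but strictly lower score at rate 0.05, and
  minor calls with strictly lower counts at rate 0.10. Decoys never
  beat the true call under the resolution rules, so read noise reduces
  *pairing*, not per-cell accuracy.
- **Reproducibility**: one RNG stream per patient derived from the
  master seed; a fixed seed gives byte-identical outputs.

What the generator does **not** emulate: transcriptome-wide
expression, batch effects, doublets, convergent recombination
(distinct clones sharing a junction), dual-α cells, chimeric/decoy
calls that outrank the truth, and clone-size laws calibrated to a real
cohort. Passing tests therefore demonstrate the correctness of the
pipeline's logic and its statistical behavior under a faithful
*structural* model — not performance on raw sequencing artifacts,
which upstream tools (Cell Ranger, miXCR) are responsible for.

## Validation experiment sizes

The replicated experiments (`clonotrace.experiments`) use desk-scale
designs chosen a priori: noiseless recovery at 10 patients × 5,000
cells; enrichment recovery at 8 patients (blood 2,500 / tumor 1,000)
per replicate with 4× sharing for GZMB+; mixed-model coverage at 12
patients × 2 specimens with a +0.5 log₁₀ effect, patient SD 0.1,
residual SD 0.1; treatment-shift detection at 3 treated patients per
replicate (the cohort size of the trial arm being emulated) using the
Wilcoxon signed-rank test across paired clusters. The acceptance
script runs reduced replicate counts of the same experiments.

## Known limitations

- Matching is exact-identity only; similarity-based (distance > 0)
  clustering, V-gene-aware metrics and antigen-specificity prediction
  are out of scope.
- The mixed model assumes a single random intercept; crossed or nested
  designs (e.g. timepoint within patient) are not modeled.
- With per-chain dropout, matched-label accuracy against ground truth
  is below 1 by construction (a clone's only tumor partner may lose a
  chain); this is a property of the data, not the labeling.
- Phenotype labels are taken as input; no re-annotation from
  expression is attempted, and batch correction / clustering /
  embedding belong to upstream tools.
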