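# immunosubtyper

Immune-signature subtyping of microsatellite-stable / MSI-low (MSS/MSI-L)
colon adenocarcinoma from bulk and single-cell transcriptomes.

MSS and MSI-low colon tumors respond poorly to immunotherapy as a group,
but their tumor immune microenvironments are heterogeneous. This package
stratifies such cohorts into three immune subtypes — **IM-H**, **IM-M**
and **IM-L** (high / medium / low immune infiltration) — from the
enrichment of 28 immune cell-type marker-gene signatures, predicts the
subtype of new cohorts, and quantifies the molecular correlates that
distinguish the subtypes: survival, tumor mutation burden, per-gene
mutation enrichment, differential expression, and single-cell copy-number
burden. It is aimed at computational oncologists who have an expression
matrix, a gene-set collection, and (optionally) mutation, clinical and
single-cell data.

## The method

**Scoring.** For gene set *G* in sample *j*, genes are ranked by
expression (average ranks on ties; highest expression receives rank *N*)
and the single-sample gene-set enrichment score (ssGSEA) is the running
sum over rank positions *i* = 1…*N*:

ES(G, j) = Σᵢ [ P_in(i) − P_out(i) ],  with
P_in(i) = Σ_{g∈G, r_g ≥ r_i} r_g^α / Σ_{g∈G} r_g^α and
P_out(i) the unweighted fraction of out-of-set genes passed so far
(α = 0.25 by default).

**Subtyping.** Scores are z-normalised per signature; samples are
clustered on Euclidean distances with the Ward criterion (the R
`ward.D2` convention), the tree is cut at k = 3, and clusters are
labelled IM-H > IM-M > IM-L by descending mean z-score. A 100-tree
random forest trained on the z-scores transfers the labels to new
cohorts (z-scored within themselves); performance is reported as
accuracy and the support-weighted F-score from a stratified 10-fold CV
confusion matrix.

**Cohort statistics.** Per-sample log2 ratios of mean marker expression
between two signatures; TMB as the total somatic mutation count;
per-gene Fisher 2×2 mutation screens (OR > 3, p < 0.05, Haldane +0.5
on zero cells for the OR only); Welch-t differential expression with
BH-FDR < 0.05 and fold change > 2; hypergeometric over-representation;
Kaplan–Meier curves with log-rank tests; the ESTIMATE purity closed form
cos(0.6049872018 + 0.0001467884·(immune + stromal)).

**Single cells.** Cancer cells are clustered the same way on four
immune-pathway scores (antigen processing, apoptosis, JAK-STAT, PD-L1);
inferred CNV matrices are centred by subtracting the global
(max + min)/2 so 0 is the normal state, and each cell's **CNV score**
is the mean of its squared centred values. Patients take the subtype
holding the largest share of their cells.

## Worked example

Everything runs on synthetic cohorts with planted subtypes — no
downloads needed:

```python
import immunosubtyper as im
from sklearn.metrics import adjusted_rand_score

cohort = im.generate_bulk_cohort(im.CohortSpec(seed=1))   # 150 samples, 28 signatures
sets   = im.intersect_genes(cohort.expression, cohort.gene_sets)
scores = im.zscore_rows(im.ssgsea_score(cohort.expression, sets, alpha=0.25))
labels = im.discover_subtypes(scores)                      # IM-H / IM-M / IM-L
print(adjusted_rand_score(cohort.true_labels, labels.labels))
# 1.0
clf, report = im.fit_subtype_classifier(scores, labels, seed=1)
print(round(report.accuracy, 3), round(report.weighted_f, 3))
# 0.987 0.987
```

The ARI of 1.0 says discovery recovered the planted three-group
structure perfectly; the 10-fold cross-validated accuracy and weighted
F-score of 0.987 say the subtypes are predictable from the same 28
signature scores. The same is available from the shell:

```bash
immunosubtyper simulate --kind bulk --seed 1 --out sim/
immunosubtyper score --expr sim/expression.tsv --gmt sim/signatures.gmt --zscore --out scores.tsv
immunosubtyper subtype --scores scores.tsv --out labels.tsv
```

or end-to-end from a YAML config with `immunosubtyper run --config cfg.yaml`
(and `run-sc` for the single-cell stages). One-command demos:
`im.run_bulk_demo(outdir, seed)` and `im.run_single_cell_demo(outdir, seed)`
write a full output bundle with a manifest that byte-reproduces the run.

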