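# Methods

## Model and procedure

The pipeline treats the tumor immune microenvironment of an MSS/MSI-L
colon adenocarcinoma cohort as a three-state latent class (IM-H, IM-M,
IM-L) observable through the coordinated expression of immune cell-type
marker-gene sets. The observable is the ssGSEA score: a rank statistic
that, walking the within-sample expression ranking from top to bottom,
accumulates the difference between the weighted cumulative distribution
of in-set genes and the unweighted cumulative distribution of out-of-set
genes. Because only ranks enter, the score is invariant to any strictly
increasing per-sample transform of expression — normalisation pipelines
(RSEM, TPM, log2 microarray intensities) that preserve within-sample
order give identical scores, which is what makes cross-cohort transfer
defensible.

Subtype discovery is agglomerative clustering of samples on z-normalised
scores under the Ward criterion with Euclidean inputs. The `ward.D2`
convention is pinned deliberately: R's two Ward variants differ in
whether distances are squared before the Lance–Williams update, and
scipy's `linkage(X, method="ward")` on observations implements the D2
convention. The tree is cut at exactly k = 3 (`fcluster` maxclust);
clusters are ordered by the descending mean of all z-scores, with rank
ties broken toward the cluster containing the first-occurring sample so
discovery is deterministic and order-invariant.

Prediction delegates the ensemble learner to scikit-learn's
100-tree random forest; the evaluation layer (confusion matrix pooled
over stratified CV folds, accuracy = trace/total, weighted F =
Σ support-fraction × F1) is implemented and tested here, so the reported
numbers are always recomputable from the stored confusion matrix. Test
cohorts are z-scored within themselves, not with training parameters:
the normalisation-then-predict order matches how independent datasets on
different platforms must be handled.

## Statistics conventions

- t-tests are Welch (unequal variance) by default, configurable to
  pooled; contingency tests are two-sided; one-tailed Mann–Whitney calls
  must state their direction explicitly and the direction is recorded in
  the output.
- The mutation screen's odds ratio applies the Haldane +0.5 correction
  only when a zero cell is present; the Fisher p always uses the raw
  counts.
- BH-FDR is applied within each screen separately.
- Fold change is a linear-scale mean ratio; for matrices flagged
  log-transformed it is 2^(mean difference). The flag exists because
  RSEM-style data are linear while most array data are log2.
- ESTIMATE purity constants (0.6049872018, 0.0001467884) follow the
  published closed form and are overridable; purity is clamped to [0, 1]
  with a warning.
- The per-cell CNV score reads "average of the squared values over
  genes"; the unaveraged sum of squares differs only by the constant
  gene count and is exposed via a flag. CNV centring uses the global
  matrix (max + min)/2, not per-cell extrema.
- Patient assignment from cell labels breaks proportion ties toward the
  higher-immune label (H > M > L), deterministically and logged.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants exactly the structure the method is designed to
detect. Baseline expression is log-normal (per-gene log-mean uniform on
[1, 6], per-sample Gaussian log-noise, SD 1), giving heavy-tailed
positive values resembling RSEM/TPM data without modelling counts.
Defaults, chosen once as realistic study conditions:

- **Bulk:** 50 samples per subtype; 28 mutually disjoint signatures of
  20 genes plus 1000 background genes; additive log-shifts 1.0/0.5/0.0
  SD on signature genes for IM-H/IM-M/IM-L. Survival is exponential with
  per-day hazards 0.0020/0.0010/0.0005 (worst prognosis in IM-H, the
  clinically observed ordering), censored by an independent exponential
  whose hazard is set to achieve a 30% expected censoring rate. Therapy
  response probabilities are 0.7778/0.7059/0.50, the response-rate
  ordering the subtypes are expected to show. Mutations are per-gene,
  per-subtype Bernoulli draws; the default rate table plants ten genes
  enriched in IM-H and ten in IM-L (0.45 vs 0.05) over a 0.10 background.
- **Single cell:** 200 cells per tier; four immune-pathway sets of 50
  genes each (real KEGG pathways of this kind carry 50–150 genes) with
  the same 1.0/0.5/0.0 shifts; CNV matrices centred at the diploid 1.0
  with Gaussian jitter (SD 0.02) and per-tier gain/loss segments of
  magnitude 0.05/0.2/0.4 for IM-H/IM-M/IM-L — burden deliberately
  anti-correlated with immune infiltration. One T-cell marker set is
  elevated per configured tier (regulatory CD4+FOXP3 in IM-H by
  default).
- **DE fixture:** 100 true genes shifted by log2FC = 2 over 1000 nulls
  at n = 50/50. The planted shift is 4-fold, not 2-fold: a shift sitting
  exactly on the FC > 2 gate would lose about half the true genes to
  sampling noise regardless of test power, so the planted effect clears
  the gate while the nulls still measure the FDR behaviour.

All triples are given in subtype order (IM-H, IM-M, IM-L). Effect-size
triples must be non-increasing toward IM-L (all-zero triples are valid
and produce null cohorts); CNV magnitudes must be non-decreasing toward
IM-L.

What the generator does **not** emulate: batch and platform effects,
count noise/overdispersion, correlated or overlapping real marker sets
(overlap is configurable but off by default), informative censoring,
copy-number breakpoint structure, and doublets/ambient RNA in the
single-cell stage. Passing the planted-recovery tests therefore shows
the machinery is correct and well-calibrated under its own model, not
that real cohorts will separate this cleanly.

## Numerical choices

- Ties in expression get average ranks; the descending walk breaks
  remaining ties by gene-index order (stable argsort), matching the
  brute-force oracle used in tests.
- ssGSEA's global-range normalisation divides by (max − min) over the
  raw score matrix; a degenerate all-equal matrix is left unscaled.
- z-scoring uses the population SD; zero-variance rows map to zeros with
  a warning rather than NaN.
- "Exact" algebraic invariances (CNV score under gene permutation and
  quadratic scaling) are asserted at 1e-12 relative tolerance: floating
  point summation order perturbs them by an ulp.
- The zero-signal invariant is checked as a bound on the difference
  between the discovered-label silhouette and a random-label silhouette
  over 20 seeds, because a cluster cut optimises silhouette somewhat
  even on pure noise.
- Simulation sizes in tests (10 recovery seeds, 20 permutation seeds,
  2000-replicate log-rank null) are sized to keep the whole suite in a
  few minutes on one CPU while leaving the binomial error on estimated
  rates well inside the asserted bands.

## Known limitations

- k is fixed at 3 by design; no model-selection machinery (gap
  statistic, consensus clustering) is provided.
- The classifier transfer assumes the same signature list scores in both
  cohorts; missing signatures are an error, not imputed.
- SC3-style consensus clustering and inferCNV inference are consumed as
  inputs, not reimplemented; WGCNA, GISTIC2 G-scores and DNA-level ITH
  scores are out of scope.
- The MAF reader consumes only (sample, gene, variant class); no full
  MAF parsing.
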