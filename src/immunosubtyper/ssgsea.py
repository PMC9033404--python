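"""Single-sample gene-set enrichment (ssGSEA) scoring.

For each sample independently, genes are ranked by expression (average
ranks on ties, highest expression receiving the largest rank).  Walking
down the ranking from the top, the enrichment score of a gene set is the
sum over all rank positions of the weighted cumulative fraction of in-set
genes minus the unweighted cumulative fraction of out-of-set genes; the
weight of an in-set gene is its rank raised to the exponent ``alpha``.
A positive score means the set's genes are coordinately up-regulated in
that sample, a negative score coordinately down-regulated.

Scores depend only on within-sample expression ranks, so any strictly
increasing per-sample transform of the expression values leaves them
unchanged.  With ``normalize`` on, all raw scores are rescaled by the
global (max - min) over the score matrix, the customary ssGSEA
normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSetCollection, ValidationError

log = logging.getLogger("immunosubtyper")


@dataclass
class EnrichmentMatrix:
    """Signatures x samples enrichment scores with provenance flags."""

    scores: pd.DataFrame
    normalized: bool = False
    z_scored: bool = False
    alpha: float = 0.25

    @property
    def signatures(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentMatrix:
    """Score every gene set in every sample.

    Parameters
    ----------
    matrix
        Expression values, genes x samples.  Every set must be a strict,
        non-empty subset of the matrix genes (run
        :func:`~immunosubtyper.io_formats.intersect_genes` first).
    alpha
        Rank-weighting exponent for in-set genes; 0 weights all ranks
        equally, the customary default is 0.25.
    normalize
        Divide all scores by the global (max - min) of the raw score
        matrix.
    """
    if alpha < 0:
        raise ValidationError("alpha must be non-negative")
    if len(sets) == 0:
        raise ValidationError("no gene sets to score")
    X = matrix.values
    genes = X.index
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    masks = {}
    for name, members in sets.items():
        missing = [g for g in members if g not in gene_pos]
        if missing:
            raise ValidationError(f"set {name!r} has genes absent from the matrix: {missing[:5]}")
        if len(members) == 0:
            raise ValidationError(f"set {name!r} is empty")
        if len(members) >= n_genes:
            raise ValidationError(f"set {name!r} covers all matrix genes; out-of-set fraction undefined")
        m = np.zeros(n_genes, dtype=bool)
        m[[gene_pos[g] for g in members]] = True
        masks[name] = m

    # rank from the bottom: highest expression gets rank n_genes; ties average
    ranks = rankdata(X.to_numpy(), axis=0, method="average")
    order = np.argsort(-ranks, axis=0, kind="stable")  # descending walk
    weights = ranks**alpha
    w_ord = np.take_along_axis(weights, order, axis=0)

    rows = []
    for name, m in masks.items():
        m_ord = m[order]  # genes x samples bool, in descending rank order
        in_w = w_ord * m_ord
        in_cum = np.cumsum(in_w, axis=0) / in_w.sum(axis=0, keepdims=True)
        out_cum = np.cumsum(~m_ord, axis=0) / float(n_genes - m.sum())
        rows.append((in_cum - out_cum).sum(axis=0))
    scores = pd.DataFrame(np.vstack(rows), index=list(masks), columns=X.columns)

    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    log.info("ssgsea_score: %d sets x %d samples (alpha=%g, normalize=%s)", len(sets), X.shape[1], alpha, normalize)
    return EnrichmentMatrix(scores, normalized=normalize, z_scored=False, alpha=alpha)


def zscore_rows(scores: EnrichmentMatrix) -> EnrichmentMatrix:
    """Centre and scale each signature row by its own mean and population SD.

    Zero-variance rows are mapped to all zeros with a warning.  Requires at
    least two samples; a z-score over a single sample is undefined.
    """
    S = scores.scores
    if S.shape[1] < 2:
        raise ValidationError("z-scoring requires >= 2 samples")
    arr = S.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("zscore_rows: %d zero-variance rows mapped to zeros: %s", flat.sum(), list(S.index[flat]))
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (arr - mu) / sd_safe
    z[flat, :] = 0.0
    return EnrichmentMatrix(
        pd.DataFrame(z, index=S.index, columns=S.columns),
        normalized=scores.normalized,
        z_scored=True,
        alpha=scores.alpha,
    )
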