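"""Single-cell stage: subtype cancer cells by immune-pathway enrichment,
normalise relative copy-number matrices, compute the per-cell CNV score,
quantify T-cell subpopulation enrichment, and roll cell subtypes up to
patients.

The per-cell CNV score is the mean over genes of the squared
reference-centred copy-number value, so genomically quiet cells score
near 0 and cells carrying large gains or losses score high regardless of
sign.  Normalisation subtracts the mid-range (max + min)/2 of the whole
matrix so that 0 represents the copy number of normal cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import CNVMatrix, ExpressionMatrix, GeneSetCollection, ValidationError, intersect_genes
from .ssgsea import ssgsea_score, zscore_rows
from .subtyping import SUBTYPE_ORDER, SubtypeAssignment, discover_subtypes

log = logging.getLogger("immunosubtyper")


def subtype_cells(
    cell_matrix: ExpressionMatrix,
    pathway_sets: GeneSetCollection,
    alpha: float = 0.25,
    k: int = 3,
    min_set_size: int = 2,
) -> SubtypeAssignment:
    """Cluster cells into immune subtypes on their pathway enrichment scores.

    Reuses the bulk machinery: ssGSEA over the (typically four) immune
    pathway sets, per-pathway z-scoring across cells, then Ward
    (ward.D2) hierarchical clustering cut at ``k`` with clusters labelled
    IM-H/IM-M/IM-L by descending mean z-score.
    """
    if cell_matrix.values.shape[1] < 3:
        raise ValidationError("need at least 3 cells to subtype")
    sets = intersect_genes(cell_matrix, pathway_sets, min_size=min_set_size)
    if set(sets.names()) != set(pathway_sets.names()):
        missing = set(pathway_sets.names()) - set(sets.names())
        raise ValidationError(f"pathway sets lost in intersection: {sorted(missing)}")
    scores = zscore_rows(ssgsea_score(cell_matrix, sets, alpha=alpha, normalize=True))
    return discover_subtypes(scores, k=k)


def normalize_cnv(raw: CNVMatrix) -> CNVMatrix:
    """Shift every entry by -(max + min)/2 of the whole matrix.

    Centres the normal (diploid-reference) state at 0.  Refuses to run on
    an already-normalised matrix.
    """
    if raw.normalized:
        raise ValidationError("CNV matrix already normalized")
    arr = raw.values.to_numpy()
    shift = (arr.max() + arr.min()) / 2.0
    log.info("normalize_cnv: shifting by %+.6g", -shift)
    return CNVMatrix(raw.values - shift, normalized=True)


def cnv_score(normalized: CNVMatrix, average: bool = True) -> pd.Series:
    """Per-cell CNV burden: mean over genes of squared normalised values.

    ``average=False`` returns the plain sum of squares (differs only by
    the constant gene count).
    """
    if not normalized.normalized:
        raise ValidationError("cnv_score requires a normalized CNV matrix")
    sq = normalized.values.to_numpy() ** 2
    score = sq.mean(axis=1) if average else sq.sum(axis=1)
    return pd.Series(score, index=normalized.cells, name="cnv_score")


def tcell_enrichment(
    cell_matrix: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    cell_labels: SubtypeAssignment | None = None,
) -> pd.DataFrame:
    """Per-cell mean expression of each T-cell subpopulation's markers.

    Returns cells x subpopulations; if ``cell_labels`` is given an extra
    ``subtype`` column is appended for downstream group comparisons.
    """
    present = set(cell_matrix.genes)
    cols = {}
    for name, genes in marker_sets.items():
        found = [g for g in genes if g in present]
        if not found:
            raise ValidationError(f"all markers of set {name!r} absent from the matrix")
        if len(found) < len(genes):
            log.warning("tcell_enrichment: set %r reduced to %d/%d markers", name, len(found), len(genes))
        cols[name] = cell_matrix.values.loc[found].mean(axis=0)
    out = pd.DataFrame(cols)
    if cell_labels is not None:
        out["subtype"] = cell_labels.labels.reindex(out.index)
    return out


def assign_patients(cell_labels: SubtypeAssignment, cell_to_patient: pd.Series) -> pd.Series:
    """Assign each patient the subtype holding the largest share of its cells.

    Proportion ties break toward the higher-immune label (IM-H > IM-M >
    IM-L) and are logged.
    """
    cell_to_patient = pd.Series(cell_to_patient)
    unmapped = cell_labels.labels.index.difference(cell_to_patient.index)
    if len(unmapped):
        raise ValidationError(f"cells without a patient mapping: {list(unmapped[:5])}")
    df = pd.DataFrame({"label": cell_labels.labels, "patient": cell_to_patient.reindex(cell_labels.labels.index)})
    rank = {lab: i for i, lab in enumerate(SUBTYPE_ORDER)}
    out = {}
    for patient, grp in df.groupby("patient", sort=True):
        props = grp["label"].value_counts(normalize=True)
        top = props.max()
        tied = sorted(props.index[props == top], key=lambda l: rank.get(l, len(rank)))
        if len(props.index[props == top]) > 1:
            log.info("assign_patients: %s tie among %s -> %s", patient, list(props.index[props == top]), tied[0])
        out[patient] = tied[0]
    return pd.Series(out, name="subtype")
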