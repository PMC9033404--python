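"""Synthetic bulk and single-cell cohorts with planted immune subtypes.

The generator emulates the structure the downstream analysis is built to
detect: three sample groups (IM-H, IM-M, IM-L) whose marker-gene sets for
~28 immune signatures are coordinately shifted by a high / medium / low
additive effect in log-expression space, with subtype-dependent
exponential survival hazards, per-gene mutation probabilities and therapy
response probabilities; and single-cell cohorts with three planted
copy-number aberration tiers whose burden runs opposite to immune
infiltration (highest in IM-L).

Baseline expression is log-normal: per-gene log-means are drawn uniformly
over a configurable range and per-sample noise is Gaussian in log space,
giving the heavy-tailed positive values typical of RSEM/TPM-style data
without modelling counts.  All triples are in subtype order
(IM-H, IM-M, IM-L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io_formats as io
from .io_formats import (
    ClinicalTable,
    CNVMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    ValidationError,
)
from .subtyping import IM_H, IM_L, IM_M, SUBTYPE_ORDER, SubtypeAssignment

log = logging.getLogger("immunosubtyper")

VARIANT_CLASSES = ["missense", "nonsense", "frameshift", "splice_site"]


def _check_triple(name, triple, positive=False, prob=False):
    t = tuple(float(x) for x in triple)
    if len(t) != 3 or not all(np.isfinite(t)):
        raise ValidationError(f"{name} must be a finite triple")
    if positive and any(x <= 0 for x in t):
        raise ValidationError(f"{name} must be positive")
    if prob and any(not 0 <= x <= 1 for x in t):
        raise ValidationError(f"{name} must lie in [0, 1]")
    return t


@dataclass
class CohortSpec:
    """Parameters of a planted bulk cohort.

    ``effect_sizes`` are additive shifts (in log-expression SD units when
    ``noise_sd`` is 1) applied to signature genes of IM-H/IM-M/IM-L
    samples and must be non-increasing H -> M -> L (all equal gives a
    null cohort with no planted signal).  ``survival_hazards`` are
    per-day exponential hazards; the defaults put the worst prognosis in
    IM-H.  ``response_probs`` default to the 77.78%/70.59%/50.00% therapy
    response rates the subtypes are expected to show.
    """

    n_samples_per_subtype: tuple[int, int, int] = (50, 50, 50)
    n_signatures: int = 28
    genes_per_signature: int = 20
    n_background_genes: int = 1000
    effect_sizes: tuple[float, float, float] = (1.0, 0.5, 0.0)
    noise_sd: float = 1.0
    baseline_log_mean_range: tuple[float, float] = (1.0, 6.0)
    signature_overlap: float = 0.0
    survival_hazards: tuple[float, float, float] = (0.0020, 0.0010, 0.0005)
    censoring_rate: float = 0.3
    mutation_rates: pd.DataFrame | None = None  # genes x [IM-H, IM-M, IM-L]
    response_probs: tuple[float, float, float] = (0.7778, 0.7059, 0.50)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.n_samples_per_subtype):
            raise ValidationError("n_samples_per_subtype must be positive")
        if min(self.n_signatures, self.genes_per_signature, self.n_background_genes) < 1:
            raise ValidationError("counts must be positive")
        e = _check_triple("effect_sizes", self.effect_sizes)
        if not (e[0] >= e[1] >= e[2]):
            raise ValidationError("effect_sizes must be non-increasing H -> M -> L")
        if not (np.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ValidationError("noise_sd must be positive")
        _check_triple("survival_hazards", self.survival_hazards, positive=True)
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        _check_triple("response_probs", self.response_probs, prob=True)
        if not 0 <= self.signature_overlap < 1:
            raise ValidationError("signature_overlap must lie in [0, 1)")
        if self.mutation_rates is not None:
            arr = self.mutation_rates.to_numpy()
            if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
                raise ValidationError("mutation_rates must lie in [0, 1]")


def default_mutation_rates(n_genes: int = 60) -> pd.DataFrame:
    """Per-gene, per-subtype mutation probabilities with planted enrichment.

    The first 10 genes are enriched in IM-H, the next 10 in IM-L; the
    remainder mutate at a flat background rate in every subtype.
    """
    genes = [f"MUT{i + 1:03d}" for i in range(n_genes)]
    rates = pd.DataFrame(0.10, index=genes, columns=SUBTYPE_ORDER)
    hi = min(10, n_genes)
    rates.iloc[:hi, :] = 0.05
    rates.iloc[:hi, 0] = 0.45  # enriched in IM-H
    lo = min(20, n_genes)
    rates.iloc[hi:lo, :] = 0.05
    rates.iloc[hi:lo, 2] = 0.45  # enriched in IM-L
    return rates


class BulkCohort(NamedTuple):
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    mutations: MutationTable
    clinical: ClinicalTable
    true_labels: pd.Series


def generate_bulk_cohort(spec: CohortSpec) -> BulkCohort:
    """Draw a full bulk cohort (expression, gene sets, mutations,
    clinical covariates, planted labels) from ``spec``.

    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = tuple(int(n) for n in spec.n_samples_per_subtype)
    n_total = sum(n_per)
    samples = [f"S{i + 1:04d}" for i in range(n_total)]
    subtype_idx = np.repeat([0, 1, 2], n_per)
    labels = pd.Series([SUBTYPE_ORDER[k] for k in subtype_idx], index=samples, name="subtype")

    # gene universe: signature genes (optionally overlapping consecutive sets)
    # followed by background genes
    sets: dict[str, list[str]] = {}
    sig_genes: list[str] = []
    n_shared = int(round(spec.signature_overlap * spec.genes_per_signature))
    for s in range(spec.n_signatures):
        name = f"SIG{s + 1:02d}"
        fresh = [f"{name}_G{j + 1:02d}" for j in range(spec.genes_per_signature - (n_shared if s > 0 else 0))]
        shared = sets[f"SIG{s:02d}"][:n_shared] if s > 0 and n_shared else []
        sets[name] = shared + fresh
        sig_genes.extend(fresh)
    bg_genes = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = sig_genes + bg_genes

    lo, hi = spec.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=len(genes))
    shift = np.zeros((len(genes), n_total))
    effects = np.asarray(spec.effect_sizes)
    shift[: len(sig_genes), :] = effects[subtype_idx][None, :]
    log_expr = base[:, None] + shift + rng.normal(0.0, spec.noise_sd, size=(len(genes), n_total))
    expr = ExpressionMatrix(pd.DataFrame(np.exp(log_expr), index=genes, columns=samples))
    collection = GeneSetCollection(dict(sets), {n: "immune-cell" for n in sets})

    # survival: exponential event times, independent exponential censoring
    # with hazard chosen so the expected censored fraction matches the spec
    hazards = np.asarray(spec.survival_hazards)[subtype_idx]
    os_t = rng.exponential(1.0 / hazards)
    dfs_t = rng.exponential(1.0 / (1.5 * hazards))  # recurrence precedes death on average
    if spec.censoring_rate > 0:
        gamma = hazards * spec.censoring_rate / (1.0 - spec.censoring_rate)
        cens_os = rng.exponential(1.0 / gamma)
        cens_dfs = rng.exponential(1.0 / (1.5 * gamma))
    else:
        cens_os = np.full(n_total, np.inf)
        cens_dfs = np.full(n_total, np.inf)
    os_event = (os_t <= cens_os).astype(int)
    dfs_event = (dfs_t <= cens_dfs).astype(int)

    # therapy response
    resp_p = np.asarray(spec.response_probs)[subtype_idx]
    responder = rng.random(n_total) < resp_p
    fine = rng.random(n_total) < 0.5
    response = np.where(responder, np.where(fine, "complete", "partial"), np.where(fine, "stable", "progressive"))
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": np.minimum(os_t, cens_os).round(2),
                "os_event": os_event,
                "dfs_time": np.minimum(dfs_t, cens_dfs).round(2),
                "dfs_event": dfs_event,
                "response": response,
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    # mutations
    rates = spec.mutation_rates if spec.mutation_rates is not None else default_mutation_rates()
    rate_arr = rates[SUBTYPE_ORDER].to_numpy()  # genes x 3
    hit = rng.random((len(rates), n_total)) < rate_arr[:, subtype_idx]
    gi, si = np.nonzero(hit)
    vclass = rng.choice(VARIANT_CLASSES, size=len(gi))
    mutations = MutationTable(
        pd.DataFrame(
            {
                "sample": np.asarray(samples)[si],
                "gene": rates.index.to_numpy()[gi],
                "variant_class": vclass,
            }
        ).sort_values(["sample", "gene"], kind="stable").reset_index(drop=True)
    )
    log.info(
        "generate_bulk_cohort: %d samples (%s), %d genes, %d sets, %d mutation records",
        n_total, n_per, len(genes), len(collection), len(mutations.records),
    )
    return BulkCohort(expr, collection, mutations, clinical, labels)


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------


@dataclass
class SingleCellSpec:
    """Parameters of a planted single-cell cohort.

    ``cnv_segment_means`` give the magnitude of the planted copy-number
    deviation per subtype in (IM-H, IM-M, IM-L) order; the planted burden
    must be non-decreasing toward IM-L (the least immune-infiltrated tier
    carries the most aberration).  ``pathway_sets`` defaults to four
    generated immune-pathway sets; user-supplied sets need >= 2 genes
    each.
    """

    n_cells_per_subtype: tuple[int, int, int] = (200, 200, 200)
    pathway_sets: GeneSetCollection | None = None
    genes_per_pathway: int = 50
    n_background_genes: int = 400
    pathway_effect_sizes: tuple[float, float, float] = (1.0, 0.5, 0.0)
    noise_sd: float = 1.0
    baseline_log_mean_range: tuple[float, float] = (1.0, 6.0)
    cnv_segment_means: tuple[float, float, float] = (0.05, 0.2, 0.4)
    n_cnv_genes: int = 300
    cnv_noise_sd: float = 0.02
    cnv_segment_fraction: float = 0.3
    tcell_marker_genes_per_set: int = 5
    tcell_effect: float = 1.0
    tcell_elevated: dict[str, str] = field(
        default_factory=lambda: {"CD4_FOXP3": IM_H, "CD4_IL7R": IM_L, "CD4_CXCL13": IM_M, "CD8_GZMB": IM_M}
    )
    n_patients_per_subtype: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.n_cells_per_subtype):
            raise ValidationError("n_cells_per_subtype must be positive")
        c = _check_triple("cnv_segment_means", self.cnv_segment_means)
        if any(x < 0 for x in c):
            raise ValidationError("cnv_segment_means must be non-negative")
        if not (c[2] >= c[1] >= c[0]):
            raise ValidationError("planted CNV burden must be non-decreasing IM-H -> IM-L")
        e = _check_triple("pathway_effect_sizes", self.pathway_effect_sizes)
        if not (e[0] >= e[1] >= e[2]):
            raise ValidationError("pathway_effect_sizes must be non-increasing H -> M -> L")
        if self.pathway_sets is not None:
            if len(self.pathway_sets) != 4:
                raise ValidationError("exactly 4 pathway sets required")
            for name, genes in self.pathway_sets.items():
                if len(genes) < 2:
                    raise ValidationError(f"pathway set {name!r} needs >= 2 genes")
        if not 0 < self.cnv_segment_fraction <= 0.5:
            raise ValidationError("cnv_segment_fraction must lie in (0, 0.5]")


PATHWAY_NAMES = ["ANTIGEN_PROCESSING", "APOPTOSIS", "JAK_STAT", "PD_L1_EXPRESSION"]
TCELL_SET_NAMES = ["CD4_FOXP3", "CD4_IL7R", "CD4_CXCL13", "CD8_GZMB"]


class SingleCellCohort(NamedTuple):
    expression: ExpressionMatrix
    cnv: CNVMatrix
    true_labels: pd.Series
    cell_to_patient: pd.Series
    pathway_sets: GeneSetCollection
    tcell_sets: GeneSetCollection


def generate_single_cell_cohort(spec: SingleCellSpec) -> SingleCellCohort:
    """Draw a single-cell cohort with planted pathway tiers, CNV tiers and
    T-cell marker elevations.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_per = tuple(int(n) for n in spec.n_cells_per_subtype)
    n_cells = sum(n_per)
    cells = [f"C{i + 1:05d}" for i in range(n_cells)]
    tier_idx = np.repeat([0, 1, 2], n_per)
    labels = pd.Series([SUBTYPE_ORDER[k] for k in tier_idx], index=cells, name="subtype")

    if spec.pathway_sets is None:
        psets = {
            name: [f"{name}_G{j + 1:02d}" for j in range(spec.genes_per_pathway)] for name in PATHWAY_NAMES
        }
        pathway_sets = GeneSetCollection(psets, {n: "pathway" for n in psets})
    else:
        pathway_sets = spec.pathway_sets
    tsets = {
        name: [f"{name}_M{j + 1}" for j in range(spec.tcell_marker_genes_per_set)] for name in TCELL_SET_NAMES
    }
    tcell_sets = GeneSetCollection(tsets, {n: "T-cell-subpopulation" for n in tsets})

    pathway_genes = [g for gs in pathway_sets.sets.values() for g in gs]
    pathway_genes = list(dict.fromkeys(pathway_genes))
    tcell_genes = [g for gs in tsets.values() for g in gs]
    bg = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = pathway_genes + tcell_genes + bg

    lo, hi = spec.baseline_log_mean_range
    base = rng.uniform(lo, hi, size=len(genes))
    shift = np.zeros((len(genes), n_cells))
    effects = np.asarray(spec.pathway_effect_sizes)
    pset = set(pathway_genes)
    is_pathway = np.array([g in pset for g in genes])
    shift[is_pathway, :] = effects[tier_idx][None, :]
    for set_name, tier in spec.tcell_elevated.items():
        if set_name not in tsets or tier not in SUBTYPE_ORDER:
            raise ValidationError(f"unknown tcell elevation {set_name!r} -> {tier!r}")
        gmask = np.array([g in set(tsets[set_name]) for g in genes])
        shift[np.ix_(gmask, tier_idx == SUBTYPE_ORDER.index(tier))] += spec.tcell_effect
    log_expr = base[:, None] + shift + rng.normal(0.0, spec.noise_sd, size=(len(genes), n_cells))
    expr = ExpressionMatrix(pd.DataFrame(np.exp(log_expr), index=genes, columns=cells))

    # CNV: diploid reference 1.0 plus a per-tier segment of gains and losses
    cnv_genes = [f"CNVG{i + 1:04d}" for i in range(spec.n_cnv_genes)]
    cnv = 1.0 + rng.normal(0.0, spec.cnv_noise_sd, size=(n_cells, spec.n_cnv_genes))
    seg_len = max(2, int(spec.cnv_segment_fraction * spec.n_cnv_genes))
    for k in range(3):
        m = spec.cnv_segment_means[k]
        if m == 0:
            continue
        start = (k * seg_len) % max(1, spec.n_cnv_genes - seg_len)
        rows = np.flatnonzero(tier_idx == k)
        half = seg_len // 2
        cnv[np.ix_(rows, range(start, start + half))] += m  # gain
        cnv[np.ix_(rows, range(start + half, start + seg_len))] -= m  # loss
    cnv_matrix = CNVMatrix(pd.DataFrame(cnv, index=cells, columns=cnv_genes), normalized=False)

    patients = [f"P{SUBTYPE_ORDER[k][-1]}{j + 1}" for k in range(3) for j in range(spec.n_patients_per_subtype)]
    cell_patients = []
    for i, k in enumerate(tier_idx):
        pool = patients[k * spec.n_patients_per_subtype : (k + 1) * spec.n_patients_per_subtype]
        cell_patients.append(pool[int(rng.integers(len(pool)))])
    cell_to_patient = pd.Series(cell_patients, index=cells, name="patient")

    log.info("generate_single_cell_cohort: %d cells (%s), %d genes, %d CNV genes", n_cells, n_per, len(genes), spec.n_cnv_genes)
    return SingleCellCohort(expr, cnv_matrix, labels, cell_to_patient, pathway_sets, tcell_sets)


# ---------------------------------------------------------------------------
# planted differential-expression fixture
# ---------------------------------------------------------------------------


def plant_de_matrix(
    n_true: int = 100,
    n_null: int = 1000,
    n_per_group: int = 50,
    log2_fc: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Two-group log2-scale matrix with ``n_true`` genes shifted up in
    group 1 by ``log2_fc`` log2 units and ``n_null`` unshifted genes.

    Returns ``(matrix, labels, true_genes)`` where the matrix is flagged
    log-transformed so fold changes downstream are 2^(mean difference).
    """
    rng = np.random.default_rng(seed)
    genes = [f"DE{i + 1:04d}" for i in range(n_true)] + [f"NULL{i + 1:04d}" for i in range(n_null)]
    samples = [f"G1_{i + 1:03d}" for i in range(n_per_group)] + [f"G2_{i + 1:03d}" for i in range(n_per_group)]
    base = rng.uniform(3.0, 10.0, size=len(genes))
    X = base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), 2 * n_per_group))
    X[:n_true, :n_per_group] += log2_fc
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), log_transformed=True)
    labels = SubtypeAssignment(
        pd.Series([IM_H] * n_per_group + [IM_L] * n_per_group, index=samples, name="subtype"),
        provenance="discovered",
    )
    return matrix, labels, genes[:n_true]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_bulk_cohort(cohort: BulkCohort, outdir) -> dict[str, str]:
    """Write every bulk artifact as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "gene_sets": outdir / "signatures.gmt",
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "true_labels": outdir / "true_labels.tsv",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_gmt(cohort.gene_sets, paths["gene_sets"])
    io.write_mutations(cohort.mutations, paths["mutations"])
    io.write_clinical(cohort.clinical, paths["clinical"])
    cohort.true_labels.to_csv(paths["true_labels"], sep="\t", index_label="sample")
    return {k: str(v) for k, v in paths.items()}


def write_single_cell_cohort(cohort: SingleCellCohort, outdir) -> dict[str, str]:
    """Write every single-cell artifact as plain text under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "cell_expression.tsv",
        "cnv": outdir / "cnv_matrix.tsv",
        "true_labels": outdir / "cell_true_labels.tsv",
        "cell_to_patient": outdir / "cell_to_patient.tsv",
        "pathway_sets": outdir / "pathways.gmt",
        "tcell_sets": outdir / "tcell_markers.gmt",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_cnv(cohort.cnv, paths["cnv"])
    cohort.true_labels.to_csv(paths["true_labels"], sep="\t", index_label="cell")
    cohort.cell_to_patient.to_csv(paths["cell_to_patient"], sep="\t", index_label="cell")
    io.write_gmt(cohort.pathway_sets, paths["pathway_sets"])
    io.write_gmt(cohort.tcell_sets, paths["tcell_sets"])
    return {k: str(v) for k, v in paths.items()}
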