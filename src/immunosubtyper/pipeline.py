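"""End-to-end orchestration: run the bulk and single-cell analyses from a
declarative config, with seeds and every parameter recorded in a JSON
manifest so a bundle can be re-run and byte-reproduced.

Bulk stage order: read -> intersect -> ssGSEA -> z-score -> discover ->
(optionally train/predict on a second cohort) -> ratios / TMB / mutation
screen / DE + ORA / survival / response.  Single-cell stage order:
read -> subtype cells -> normalise CNV -> CNV score -> T-cell enrichment
-> assign patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import pandas as pd
import yaml

from . import __version__, cohort_stats, io_formats as io, single_cell, ssgsea, subtyping
from .io_formats import ValidationError
from .synthetic_data import CohortSpec, SingleCellSpec, generate_bulk_cohort, generate_single_cell_cohort, write_bulk_cohort, write_single_cell_cohort

log = logging.getLogger("immunosubtyper")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "results"
    # bulk inputs
    expression: str | None = None
    gene_sets: str | None = None
    mutations: str | None = None
    clinical: str | None = None
    test_expression: str | None = None  # second cohort for cross-cohort prediction
    expression_log_transformed: bool = False
    # single-cell inputs
    cell_expression: str | None = None
    cnv: str | None = None
    pathway_sets: str | None = None
    tcell_sets: str | None = None
    cell_to_patient: str | None = None
    # parameters
    alpha: float = 0.25
    k: int = 3
    n_trees: int = 100
    min_set_size: int = 5
    seed: int = 0
    ratio_set_a: str | None = None
    ratio_set_b: str | None = None
    mutscreen_min_or: float = 3.0
    mutscreen_alpha_p: float = 0.05
    de_fdr_max: float = 0.05
    de_fc_min: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self, fields: list[str]) -> None:
        for f in fields:
            p = getattr(self, f)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config path {f} = {p!r} does not exist")


def _stage(name, code, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, code, str(exc)) from exc


def _write_manifest(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    manifest = {"version": __version__, "config": asdict(config), **extra}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_bulk_pipeline(config: PipelineConfig) -> dict:
    """Run the bulk stages and write the output bundle under ``config.outdir``.

    Returns a dict of the main in-memory results.
    """
    config.validate_paths(["expression", "gene_sets", "mutations", "clinical", "test_expression"])
    if config.expression is None or config.gene_sets is None:
        raise PipelineError("config", "missing_input", "expression and gene_sets are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    expr = _stage("read", "bad_expression", io.read_expression, config.expression, config.expression_log_transformed)
    sets = _stage("read", "bad_gmt", io.read_gmt, config.gene_sets)
    sets = _stage("intersect", "no_sets", io.intersect_genes, expr, sets, config.min_set_size)
    scores = _stage("score", "ssgsea_failed", ssgsea.ssgsea_score, expr, sets, config.alpha, True)
    zscores = _stage("zscore", "zscore_failed", ssgsea.zscore_rows, scores)
    labels = _stage("discover", "clustering_failed", subtyping.discover_subtypes, zscores, config.k)
    results["labels"] = labels
    zscores.scores.to_csv(outdir / "scores_z.tsv", sep="\t", index_label="signature")
    labels.labels.to_frame().assign(provenance=labels.provenance).to_csv(outdir / "subtypes.tsv", sep="\t", index_label="sample")

    clf, report = _stage(
        "train", "cv_failed", subtyping.fit_subtype_classifier, zscores, labels, config.n_trees, config.seed
    )
    results["report"] = report
    (outdir / "prediction_report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    joblib.dump(clf, outdir / "classifier.joblib")

    if config.test_expression:
        expr2 = _stage("read", "bad_expression", io.read_expression, config.test_expression, config.expression_log_transformed)
        sets2 = _stage("intersect", "no_sets", io.intersect_genes, expr2, sets, config.min_set_size)
        z2 = _stage("zscore", "zscore_failed", ssgsea.zscore_rows, _stage("score", "ssgsea_failed", ssgsea.ssgsea_score, expr2, sets2, config.alpha, True))
        pred = _stage("predict", "predict_failed", subtyping.predict_subtypes, clf, z2)
        results["predicted"] = pred
        pred.labels.to_frame().assign(provenance="predicted").to_csv(outdir / "subtypes_test.tsv", sep="\t", index_label="sample")

    set_names = sets.names()
    name_a = config.ratio_set_a or set_names[0]
    name_b = config.ratio_set_b or set_names[-1]
    ratio = _stage("ratio", "ratio_failed", cohort_stats.signature_ratio, expr, sets[name_a], sets[name_b], 0.0, name_a, name_b)
    ratio.values.to_csv(outdir / "signature_ratio.tsv", sep="\t", index_label="sample")
    results["ratio"] = ratio

    stats_summary: dict = {}
    if config.mutations and config.clinical:
        muts = _stage("read", "bad_mutations", io.read_mutations, config.mutations)
        clin = _stage("read", "bad_clinical", io.read_clinical, config.clinical)
        roster = list(expr.samples)
        tmb = _stage("tmb", "tmb_failed", cohort_stats.compute_tmb, muts, roster)
        tmb.to_csv(outdir / "tmb.tsv", sep="\t", index_label="sample")
        results["tmb"] = tmb
        present = [g for g in ("IM-H", "IM-L") if g in set(labels.labels)]
        if len(present) == 2:
            screen = _stage(
                "mutscreen", "screen_failed", cohort_stats.mutation_enrichment,
                muts, labels, "IM-H", "IM-L", config.mutscreen_min_or, config.mutscreen_alpha_p,
            )
            screen.to_csv(outdir / "mutation_screen.tsv", sep="\t", index=False)
            results["mutation_screen"] = screen
            de = _stage(
                "de", "de_failed", cohort_stats.differential_genes,
                expr, labels, "IM-H", "IM-L", config.de_fdr_max, config.de_fc_min,
            )
            de.to_csv(outdir / "differential_genes.tsv", sep="\t", index=False)
            results["de"] = de
            up = de.loc[de["up_in_group1"], "gene"].tolist()
            ora = _stage("ora", "ora_failed", cohort_stats.overrepresentation, up, sets, list(expr.genes))
            ora.to_csv(outdir / "overrepresentation.tsv", sep="\t", index=False)
            results["ora"] = ora
        for endpoint in ("OS", "DFS"):
            surv = _stage("survival", "survival_failed", cohort_stats.km_logrank, clin, labels, endpoint)
            stats_summary[f"logrank_{endpoint.lower()}"] = {"chi2": surv.statistic, "p": surv.p, "df": surv.df}
            results[f"survival_{endpoint.lower()}"] = surv
        # therapy response rates per subtype + chi-square on responder counts
        resp = clin.table["response"].reindex(labels.labels.index)
        responder = resp.isin(["complete", "partial"])
        counts = pd.crosstab(labels.labels, responder)
        rates = {g: float(responder[labels.labels == g].mean()) for g in sorted(set(labels.labels))}
        chi = _stage("compare", "chi_failed", cohort_stats.group_compare, None, None, "chi_square", None, counts.to_numpy())
        stats_summary["response_rates"] = rates
        stats_summary["response_chi_square"] = chi
        results["response_rates"] = rates
    (outdir / "stats_summary.json").write_text(json.dumps(stats_summary, indent=2, sort_keys=True) + "\n")
    _write_manifest(outdir, config, {"stage_order": ["read", "intersect", "score", "zscore", "discover", "train", "predict", "ratio", "tmb", "mutscreen", "de", "ora", "survival", "compare"]})
    log.info("run_bulk_pipeline: bundle written to %s", outdir)
    return results


def run_single_cell_pipeline(config: PipelineConfig) -> dict:
    """Run the single-cell stages and write the bundle under ``config.outdir``."""
    config.validate_paths(["cell_expression", "cnv", "pathway_sets", "tcell_sets", "cell_to_patient"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    labels = None

    if config.cell_expression and config.pathway_sets:
        cexpr = _stage("read", "bad_expression", io.read_expression, config.cell_expression, config.expression_log_transformed)
        psets = _stage("read", "bad_gmt", io.read_gmt, config.pathway_sets)
        labels = _stage("sc-subtype", "clustering_failed", single_cell.subtype_cells, cexpr, psets, config.alpha, config.k)
        results["cell_labels"] = labels
        labels.labels.to_frame().to_csv(outdir / "cell_subtypes.tsv", sep="\t", index_label="cell")
        if config.tcell_sets:
            tsets = _stage("read", "bad_gmt", io.read_gmt, config.tcell_sets)
            tc = _stage("tcell", "tcell_failed", single_cell.tcell_enrichment, cexpr, tsets, labels)
            tc.to_csv(outdir / "tcell_enrichment.tsv", sep="\t", index_label="cell")
            results["tcell"] = tc
        if config.cell_to_patient:
            mapping = pd.read_csv(config.cell_to_patient, sep="\t", index_col=0).iloc[:, 0]
            patient_labels = _stage("assign-patients", "assign_failed", single_cell.assign_patients, labels, mapping)
            patient_labels.to_csv(outdir / "patient_subtypes.tsv", sep="\t", index_label="patient")
            results["patient_labels"] = patient_labels
    else:
        log.info("run_single_cell_pipeline: no cell expression configured; skipping subtype/tcell stages")

    if config.cnv:
        raw = _stage("read", "bad_cnv", io.read_cnv, config.cnv)
        norm = _stage("cnv-normalize", "normalize_failed", single_cell.normalize_cnv, raw)
        score = _stage("cnv-score", "score_failed", single_cell.cnv_score, norm)
        score.to_csv(outdir / "cnv_scores.tsv", sep="\t", index_label="cell")
        results["cnv_scores"] = score
        if labels is not None:
            means = {g: float(score[labels.members(g)].mean()) for g in sorted(set(labels.labels))}
            (outdir / "cnv_score_by_subtype.json").write_text(json.dumps(means, indent=2, sort_keys=True) + "\n")
            results["cnv_score_means"] = means
    else:
        log.info("run_single_cell_pipeline: no CNV matrix configured; skipping CNV stages")

    _write_manifest(outdir, config, {"stage_order": ["read", "sc-subtype", "cnv-normalize", "cnv-score", "tcell", "assign-patients"]})
    log.info("run_single_cell_pipeline: bundle written to %s", outdir)
    return results


# ---------------------------------------------------------------------------
# one-command synthetic demos
# ---------------------------------------------------------------------------


def run_bulk_demo(outdir, seed: int = 0) -> dict:
    """Generate a synthetic bulk cohort pair (training + independent test
    cohort) under the default planted conditions and run the full bulk
    pipeline on it."""
    outdir = Path(outdir)
    train = generate_bulk_cohort(CohortSpec(seed=seed))
    test = generate_bulk_cohort(CohortSpec(seed=seed + 1))
    paths = write_bulk_cohort(train, outdir / "inputs")
    test_paths = write_bulk_cohort(test, outdir / "inputs_test")
    config = PipelineConfig(
        outdir=str(outdir / "bundle"),
        expression=paths["expression"],
        gene_sets=paths["gene_sets"],
        mutations=paths["mutations"],
        clinical=paths["clinical"],
        test_expression=test_paths["expression"],
        seed=seed,
    )
    results = run_bulk_pipeline(config)
    results["true_labels"] = train.true_labels
    results["test_true_labels"] = test.true_labels
    return results


def run_single_cell_demo(outdir, seed: int = 0) -> dict:
    """Generate a synthetic single-cell cohort under the default planted
    conditions and run the full single-cell pipeline on it."""
    outdir = Path(outdir)
    cohort = generate_single_cell_cohort(SingleCellSpec(seed=seed))
    paths = write_single_cell_cohort(cohort, outdir / "inputs")
    config = PipelineConfig(
        outdir=str(outdir / "bundle"),
        cell_expression=paths["expression"],
        cnv=paths["cnv"],
        pathway_sets=paths["pathway_sets"],
        tcell_sets=paths["tcell_sets"],
        cell_to_patient=paths["cell_to_patient"],
        seed=seed,
    )
    results = run_single_cell_pipeline(config)
    results["true_labels"] = cohort.true_labels
    return results
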