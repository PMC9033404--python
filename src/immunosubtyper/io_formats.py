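"""Readers, writers and validated in-memory containers for every on-disk
artifact the pipeline touches.

All tabular artifacts are plain tab-separated text: expression and CNV
matrices with a header row of sample/cell identifiers, gene sets in GMT,
mutations as three-column records, clinical covariates as one row per
sample.  Gene identifiers are bare symbols; no alias resolution is
attempted — mismatches between a gene-set collection and an expression
matrix are resolved explicitly (and loudly) by :func:`intersect_genes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("immunosubtyper")

CLINICAL_COLUMNS = ["os_time", "os_event", "dfs_time", "dfs_event", "response"]
RESPONSE_CATEGORIES = {"complete", "partial", "stable", "progressive", "missing"}


class ValidationError(ValueError):
    """Input violates a container invariant or an operation precondition."""


class ParseError(ValueError):
    """On-disk artifact is malformed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples (or genes x cells) expression values.

    Values are non-negative on the linear scale unless ``log_transformed``
    is set, in which case negatives are legitimate.  Gene and sample
    identifiers must be unique and all values finite.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        if any(not g for g in v.index):
            raise ValidationError("empty gene identifier")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if not self.log_transformed and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {v.index[bad[0]]!r}, sample "
                f"{v.columns[bad[1]]!r} in a matrix not flagged log-transformed"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> gene list, with optional category tags."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class MutationTable:
    """Somatic mutation records: one row per (sample, gene, variant class)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample", "gene", "variant_class") if c not in self.records.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns: {missing}")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates: OS/DFS time+event and therapy response."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        for col in ("os_time", "dfs_time"):
            if (t[col].to_numpy() < 0).any():
                raise ValidationError(f"negative {col}")
        for col in ("os_event", "dfs_event"):
            if not set(np.unique(t[col].to_numpy())) <= {0, 1}:
                raise ValidationError(f"{col} must be binary 0/1")
        bad = set(t["response"]) - RESPONSE_CATEGORIES
        if bad:
            raise ValidationError(f"unknown response categories: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index


@dataclass
class CNVMatrix:
    """Cells x genes relative copy-number values.

    Raw matrices are centred at the diploid reference value (conventionally
    1.0); after normalisation the normal state is represented by 0 and the
    ``normalized`` flag is set.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite CNV value")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate cell or gene identifiers in CNV matrix")

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description,
    then genes.  Duplicate genes within a line are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            genes, seen = [], set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    log.warning("GMT %s line %d: duplicate gene %r in set %r dropped", path, lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    log.info("read_gmt(%s): %d sets", path, len(sets))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.categories.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    log.info("write_gmt(%s): %d sets", path, len(collection))


# ---------------------------------------------------------------------------
# expression / CNV matrices
# ---------------------------------------------------------------------------


def _read_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    bad = df.columns[df.columns.str.startswith("Unnamed:")]
    if len(bad):
        raise ParseError(f"{path}: ragged rows (unnamed trailing columns)")
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    num.index.name = None
    return num


def read_expression(path, log_transformed: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV with a header row of sample identifiers.

    Duplicate gene rows are collapsed by their mean, with a warning.
    """
    df = _read_matrix(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        log.warning("read_expression(%s): collapsing duplicate gene rows by mean: %s", path, dups)
        order = df.index.unique()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    mat = ExpressionMatrix(df, log_transformed=log_transformed)
    log.info("read_expression(%s): %d genes x %d samples", path, *df.shape)
    return mat


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    log.info("write_expression(%s): %d genes x %d samples", path, *matrix.values.shape)


def read_cnv(path, normalized: bool = False) -> CNVMatrix:
    """Read a cell x gene TSV of relative copy-number values."""
    df = _read_matrix(path)
    mat = CNVMatrix(df, normalized=normalized)
    log.info("read_cnv(%s): %d cells x %d genes", path, *df.shape)
    return mat


def write_cnv(matrix: CNVMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="cell")
    log.info("write_cnv(%s): %d cells x %d genes", path, *matrix.values.shape)


# ---------------------------------------------------------------------------
# mutation / clinical tables
# ---------------------------------------------------------------------------


def read_mutations(path, roster=None) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    tab = MutationTable(df)
    if roster is not None:
        extra = set(df["sample"]) - set(roster)
        if extra:
            raise ValidationError(f"mutation records for samples outside roster: {sorted(extra)[:5]}")
    log.info("read_mutations(%s): %d records", path, len(df))
    return tab


def write_mutations(table: MutationTable, path) -> None:
    table.records[["sample", "gene", "variant_class"]].to_csv(path, sep="\t", index=False)
    log.info("write_mutations(%s): %d records", path, len(table.records))


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    tab = ClinicalTable(df)
    log.info("read_clinical(%s): %d samples", path, len(df))
    return tab


def write_clinical(table: ClinicalTable, path) -> None:
    table.table.to_csv(path, sep="\t", index_label="sample")
    log.info("write_clinical(%s): %d samples", path, len(table.table))


# ---------------------------------------------------------------------------
# gene-set / matrix reconciliation
# ---------------------------------------------------------------------------


def intersect_genes(matrix: ExpressionMatrix, sets: GeneSetCollection, min_size: int = 5) -> GeneSetCollection:
    """Restrict every gene set to the genes present in ``matrix``.

    Sets that fall below ``min_size`` genes after restriction are dropped
    with a warning; if every set is dropped there is nothing left to score
    and a hard error is raised.
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    present = set(matrix.genes)
    kept: dict[str, list[str]] = {}
    dropped: list[str] = []
    for name, genes in sets.items():
        inter = [g for g in genes if g in present]
        if len(inter) < min_size:
            dropped.append(name)
        else:
            kept[name] = inter
    if dropped:
        log.warning("intersect_genes: dropped %d sets below min_size=%d: %s", len(dropped), min_size, dropped)
    if not kept:
        raise ValidationError("all gene sets dropped after intersection with the matrix")
    cats = {n: c for n, c in sets.categories.items() if n in kept}
    return GeneSetCollection(kept, cats)
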