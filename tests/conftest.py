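import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from immunosubtyper import (
    CohortSpec,
    ExpressionMatrix,
    GeneSetCollection,
    generate_bulk_cohort,
    intersect_genes,
    ssgsea_score,
    zscore_rows,
)


def ssgsea_brute_force(expr_col: pd.Series, members: set, alpha: float) -> float:
    """Independent ssGSEA oracle: explicit loop over rank positions.

    Genes are walked in descending rank order (rank from the bottom,
    average ties, index order within ties); the running sum accumulates
    the weighted in-set CDF minus the unweighted out-of-set CDF.
    """
    genes = list(expr_col.index)
    ranks = rankdata(expr_col.to_numpy())  # 1 = lowest expression
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], i))
    in_total = sum(ranks[i] ** alpha for i in range(len(genes)) if genes[i] in members)
    n_out = len(genes) - len(members)
    es, in_cum, out_cum = 0.0, 0.0, 0
    for i in order:
        if genes[i] in members:
            in_cum += ranks[i] ** alpha
        else:
            out_cum += 1
        es += in_cum / in_total - out_cum / n_out
    return es


@pytest.fixture
def descending_matrix():
    """Five genes, one sample, strictly decreasing expression g1 > ... > g5."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [50.0, 40.0, 30.0, 20.0, 10.0]}, index=[f"g{i}" for i in range(1, 6)])
    )


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default planted bulk cohort, shared across tests (read-only)."""
    return generate_bulk_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def bulk_zscores(bulk_cohort):
    sets = intersect_genes(bulk_cohort.expression, bulk_cohort.gene_sets)
    return zscore_rows(ssgsea_score(bulk_cohort.expression, sets, alpha=0.25, normalize=True))


def random_expression(rng, n_genes=50, n_samples=10) -> ExpressionMatrix:
    vals = rng.lognormal(2.0, 1.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{j}" for j in range(n_samples)])
    )


def random_set(rng, genes, lo=5, hi=20) -> list:
    size = int(rng.integers(lo, hi + 1))
    return list(rng.choice(genes, size=size, replace=False))
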