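"""Cohort-level statistics and the hypothesis-test battery comparing
immune subtypes: signature ratios, tumor mutation burden, per-gene
mutation-enrichment screens, differential expression with
over-representation analysis, Kaplan-Meier/log-rank survival contrasts,
ESTIMATE-style immune score and purity, and a uniformly logged wrapper
over the standard two-group tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ClinicalTable, ExpressionMatrix, MutationTable, ValidationError
from .ssgsea import ssgsea_score
from .io_formats import GeneSetCollection
from .subtyping import SubtypeAssignment

log = logging.getLogger("immunosubtyper")

# constants of the published ESTIMATE purity formula (overridable)
ESTIMATE_PURITY_INTERCEPT = 0.6049872018
ESTIMATE_PURITY_SLOPE = 0.0001467884


# ---------------------------------------------------------------------------
# signature ratio
# ---------------------------------------------------------------------------


@dataclass
class RatioStatistic:
    """Per-sample log2 ratio of mean marker expression of two signatures."""

    values: pd.Series  # sample -> R
    signature_a: str
    signature_b: str


def signature_ratio(
    matrix: ExpressionMatrix,
    set_a: list[str],
    set_b: list[str],
    pseudocount: float = 0.0,
    name_a: str = "A",
    name_b: str = "B",
) -> RatioStatistic:
    """R = log2(mean expression of A markers / mean expression of B markers),
    per sample, on the linear scale with an optional pseudocount added to
    both means.  Antisymmetric in (A, B) when the pseudocount is zero."""
    genes = set(matrix.genes)
    a = [g for g in set_a if g in genes]
    b = [g for g in set_b if g in genes]
    if not a or not b:
        raise ValidationError("both signatures must be non-empty after intersection")
    mean_a = matrix.values.loc[a].mean(axis=0) + pseudocount
    mean_b = matrix.values.loc[b].mean(axis=0) + pseudocount
    if ((mean_a == 0) | (mean_b == 0)).any() and pseudocount == 0:
        raise ValidationError("zero signature mean with pseudocount 0; ratio undefined")
    r = np.log2(mean_a / mean_b)
    return RatioStatistic(r.rename(f"log2({name_a}/{name_b})"), name_a, name_b)


# ---------------------------------------------------------------------------
# tumor mutation burden
# ---------------------------------------------------------------------------


def compute_tmb(muts: MutationTable, roster, dedup: bool = False) -> pd.Series:
    """Total somatic mutation count per sample; samples absent from the
    table get 0.  Duplicated identical records count twice by default
    (``dedup`` collapses them, with a warning either way)."""
    rec = muts.records
    extra = set(rec["sample"]) - set(roster)
    if extra:
        raise ValidationError(f"mutation records outside roster: {sorted(extra)[:5]}")
    if rec.duplicated().any():
        ndup = int(rec.duplicated().sum())
        if dedup:
            log.warning("compute_tmb: dropping %d duplicated records (dedup on)", ndup)
            rec = rec.drop_duplicates()
        else:
            log.warning("compute_tmb: %d duplicated records counted twice (dedup off)", ndup)
    counts = rec.groupby("sample").size()
    tmb = counts.reindex(list(roster), fill_value=0).astype(int)
    tmb.name = "tmb"
    return tmb


# ---------------------------------------------------------------------------
# mutation-enrichment screen
# ---------------------------------------------------------------------------


def mutation_enrichment(
    muts: MutationTable,
    labels: SubtypeAssignment,
    group1: str | list[str],
    group2: str | list[str],
    min_or: float = 3.0,
    alpha_p: float = 0.05,
) -> pd.DataFrame:
    """Per-gene 2x2 mutated/wild x group1/group2 screen.

    Fisher's exact test (two-sided) on the raw counts; the sample odds
    ratio uses the Haldane correction (+0.5 to every cell) only when a
    zero cell is present.  A gene passes when p < ``alpha_p`` and
    OR > ``min_or`` (mutation enriched in group1).
    """
    g1 = [group1] if isinstance(group1, str) else list(group1)
    g2 = [group2] if isinstance(group2, str) else list(group2)
    if set(g1) & set(g2):
        raise ValidationError("groups must be disjoint")
    s1 = labels.labels.index[labels.labels.isin(g1)]
    s2 = labels.labels.index[labels.labels.isin(g2)]
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("each group needs >= 2 samples")

    rec = muts.records.drop_duplicates(subset=["sample", "gene"])
    mutated = rec.groupby("gene")["sample"].apply(set)
    rows = []
    for gene, carriers in mutated.items():
        a = len(carriers & set(s1))  # mutated in group1
        c = len(carriers & set(s2))  # mutated in group2
        if a + c == 0:
            log.info("mutation_enrichment: %s mutated in neither group, skipped", gene)
            continue
        b = len(s1) - a
        d = len(s2) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append((gene, a, b, c, d, orr, p))
    out = pd.DataFrame(rows, columns=["gene", "mut_g1", "wild_g1", "mut_g2", "wild_g2", "odds_ratio", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["direction"] = np.where(out["odds_ratio"] > 1, "group1", "group2")
        out["significant"] = (out["p"] < alpha_p) & (out["odds_ratio"] > min_or)
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    log.info("mutation_enrichment: %d genes tested, %d pass p<%g & OR>%g", len(out), int(out["significant"].sum()) if len(out) else 0, alpha_p, min_or)
    return out


# ---------------------------------------------------------------------------
# differential expression + over-representation
# ---------------------------------------------------------------------------


def differential_genes(
    matrix: ExpressionMatrix,
    labels: SubtypeAssignment,
    group1: str,
    group2: str,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Genes up-regulated in ``group1`` versus ``group2``.

    Two-sided two-sample t-test per gene (Welch by default), BH-FDR across
    tested genes, fold change on the linear scale (or 2^mean-difference if
    the matrix is flagged log-transformed).  Kept genes satisfy
    FDR < ``fdr_max`` and FC > ``fc_min``.
    """
    s1 = labels.members(group1)
    s2 = labels.members(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("each group needs >= 2 samples")
    X1 = matrix.values[s1].to_numpy()
    X2 = matrix.values[s2].to_numpy()

    var_ok = ~((X1.std(axis=1) == 0) & (X2.std(axis=1) == 0))
    skipped = matrix.genes[~var_ok]
    if len(skipped):
        log.info("differential_genes: %d zero-variance genes skipped", len(skipped))
    t, p = stats.ttest_ind(X1[var_ok], X2[var_ok], axis=1, equal_var=equal_var)
    if matrix.log_transformed:
        fc = 2.0 ** (X1[var_ok].mean(axis=1) - X2[var_ok].mean(axis=1))
    else:
        fc = X1[var_ok].mean(axis=1) / X2[var_ok].mean(axis=1)
    out = pd.DataFrame(
        {"gene": matrix.genes[var_ok], "t": t, "p": p, "fdr": bh_adjust(p), "fold_change": fc}
    )
    out["up_in_group1"] = (out["fdr"] < fdr_max) & (out["fold_change"] > fc_min)
    log.info("differential_genes: %d tested, %d up in %s (FDR<%g, FC>%g)", len(out), int(out["up_in_group1"].sum()), group1, fdr_max, fc_min)
    return out.reset_index(drop=True)


def overrepresentation(
    gene_list: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    One-sided upper-tail p per set (probability of at least the observed
    overlap), BH-FDR over tested sets.
    """
    uni = set(universe)
    if not set(gene_list) <= uni:
        raise ValidationError("gene_list must be a subset of the universe")
    if not gene_list:
        log.warning("overrepresentation: empty gene list; empty result")
        return pd.DataFrame(columns=["set", "overlap", "set_size", "list_size", "p", "fdr", "enriched"])
    M, N = len(uni), len(gene_list)
    rows = []
    for name, genes in sets.items():
        inset = set(genes) & uni
        k = len(inset & set(gene_list))
        p = float(stats.hypergeom.sf(k - 1, M, len(inset), N))
        rows.append((name, k, len(inset), N, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "list_size", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["fdr"] < fdr_max
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit curve for one group."""

    group: str
    times: np.ndarray  # event/censoring times in ascending order
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray
    censored_times: np.ndarray


@dataclass
class LogrankResult:
    curves: dict[str, SurvivalCurve]
    statistic: float
    p: float
    df: int
    endpoint: str


def km_logrank(
    clinical: ClinicalTable,
    labels: SubtypeAssignment,
    endpoint: str = "OS",
    groups: list[str] | None = None,
) -> LogrankResult:
    """Kaplan-Meier curves per group plus a k-group log-rank test.

    ``endpoint`` is OS or DFS; groups default to every label present.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "DFS"):
        raise ValidationError("endpoint must be OS or DFS")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")
    lab = labels.labels
    groups = groups or [g for g in ["IM-H", "IM-M", "IM-L"] if g in set(lab)] or sorted(set(lab))

    frames, curves = [], {}
    for g in groups:
        members = lab.index[lab == g]
        sub = clinical.table.reindex(members).dropna(subset=[tcol, ecol])
        if len(sub) == 0:
            raise ValidationError(f"group {g!r} has zero samples with {endpoint} data")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], sub[ecol])
        tl = kmf.event_table.index.to_numpy()
        keep = tl > 0 if 0 in tl else np.ones(len(tl), bool)
        curves[g] = SurvivalCurve(
            group=g,
            times=tl[keep],
            survival=kmf.survival_function_.to_numpy().ravel()[keep],
            at_risk=kmf.event_table["at_risk"].to_numpy()[keep],
            censored_times=np.sort(sub.loc[sub[ecol] == 0, tcol].to_numpy()),
        )
        frames.append(pd.DataFrame({"t": sub[tcol], "e": sub[ecol], "g": g}))
    data = pd.concat(frames)
    if data["e"].sum() == 0:
        raise ValidationError("no events observed; log-rank undefined")
    res = multivariate_logrank_test(data["t"], data["g"], data["e"])
    log.info("km_logrank[%s]: chi2=%.4f df=%d p=%.4g n=%s", endpoint, res.test_statistic, len(groups) - 1, res.p_value, {g: int((data["g"] == g).sum()) for g in groups})
    return LogrankResult(curves, float(res.test_statistic), float(res.p_value), len(groups) - 1, endpoint)


# ---------------------------------------------------------------------------
# generic group comparisons
# ---------------------------------------------------------------------------

_TESTS = {"mann_whitney_one_tailed", "t_two_tailed", "kruskal_wallis", "fisher_exact", "chi_square"}


def group_compare(
    values,
    labels=None,
    test: str = "t_two_tailed",
    direction: str | None = None,
    table=None,
    equal_var: bool = False,
):
    """Uniformly logged wrapper over the standard two-/k-group tests.

    For sample-level tests pass ``values`` (per-sample) and ``labels``
    (two or more groups, in the order group comparisons are stated).  For
    contingency tests pass ``table`` (2D counts).  One-tailed tests
    require an explicit ``direction`` ('greater' or 'less', stated for the
    first group) which is recorded in the output.

    Returns a dict with test name, sidedness, statistic, p and group sizes.
    """
    if test not in _TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")

    if test in ("fisher_exact", "chi_square"):
        tab = np.asarray(table, dtype=float)
        if test == "fisher_exact":
            stat, p = stats.fisher_exact(tab, alternative="two-sided")
            side = "two-sided"
        else:
            stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
            side = "two-sided"
        out = {"test": test, "sidedness": side, "statistic": float(stat), "p": float(p), "n": int(tab.sum())}
        log.info("group_compare: %s", out)
        return out

    values = pd.Series(values)
    labels = pd.Series(labels, index=values.index) if not isinstance(labels, pd.Series) else labels
    group_names = list(dict.fromkeys(labels))
    samples = [values[labels == g].to_numpy() for g in group_names]

    if test == "kruskal_wallis":
        stat, p = stats.kruskal(*samples)
        side = "two-sided"
    elif test == "t_two_tailed":
        if len(samples) != 2:
            raise ValidationError("t-test needs exactly two groups")
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        side = "two-sided"
    else:  # mann_whitney_one_tailed
        if len(samples) != 2:
            raise ValidationError("Mann-Whitney needs exactly two groups")
        if direction not in ("greater", "less"):
            raise ValidationError("one-tailed Mann-Whitney requires direction 'greater' or 'less' for the first group")
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative=direction)
        side = f"one-sided ({direction})"
    out = {
        "test": test,
        "sidedness": side,
        "statistic": float(stat),
        "p": float(p),
        "n": {g: len(s) for g, s in zip(group_names, samples)},
    }
    log.info("group_compare: %s", out)
    return out


# ---------------------------------------------------------------------------
# ESTIMATE-style immune score and purity
# ---------------------------------------------------------------------------


def immune_score_purity(
    matrix: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
    intercept: float = ESTIMATE_PURITY_INTERCEPT,
    slope: float = ESTIMATE_PURITY_SLOPE,
) -> pd.DataFrame:
    """Per-sample immune score, stromal score and tumor purity.

    Immune and stromal scores are raw (unnormalised) ssGSEA scores of the
    two signatures; purity follows the published closed form
    cos(intercept + slope * (immune + stromal)), clamped to [0, 1] with a
    warning outside that range.
    """
    coll = GeneSetCollection({"immune": list(immune_set), "stromal": list(stromal_set)})
    present = set(matrix.genes)
    for name, genes in coll.items():
        if not set(genes) & present:
            raise ValidationError(f"{name} signature absent from the matrix")
    em = ssgsea_score(matrix, coll, alpha=0.25, normalize=False)
    immune = em.scores.loc["immune"]
    stromal = em.scores.loc["stromal"]
    purity = np.cos(intercept + slope * (immune + stromal))
    if ((purity < 0) | (purity > 1)).any():
        log.warning("immune_score_purity: %d purity values clamped to [0, 1]", int(((purity < 0) | (purity > 1)).sum()))
        purity = purity.clip(0.0, 1.0)
    return pd.DataFrame({"immune_score": immune, "stromal_score": stromal, "purity": purity})
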