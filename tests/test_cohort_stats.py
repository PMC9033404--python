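import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from immunosubtyper import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    SubtypeAssignment,
    ValidationError,
    bh_adjust,
    compute_tmb,
    differential_genes,
    group_compare,
    immune_score_purity,
    km_logrank,
    mutation_enrichment,
    overrepresentation,
    plant_de_matrix,
    signature_ratio,
)


def labels_of(mapping) -> SubtypeAssignment:
    return SubtypeAssignment(pd.Series(mapping, name="subtype"), provenance="discovered")


class TestSignatureRatio:
    def setup_method(self):
        # mean(A) = 8, mean(B) = 2 in sample s1
        self.m = ExpressionMatrix(
            pd.DataFrame({"s1": [6.0, 10.0, 1.0, 3.0], "s2": [4.0, 4.0, 4.0, 4.0]}, index=list("abcd"))
        )

    def test_log2_of_mean_ratio(self):
        r = signature_ratio(self.m, ["a", "b"], ["c", "d"])
        assert r.values["s1"] == pytest.approx(2.0)
        assert r.values["s2"] == pytest.approx(0.0)

    def test_identical_sets_give_zero(self):
        r = signature_ratio(self.m, ["a", "b"], ["a", "b"])
        assert (r.values == 0).all()

    def test_antisymmetry_exact(self):
        fwd = signature_ratio(self.m, ["a", "b"], ["c", "d"])
        rev = signature_ratio(self.m, ["c", "d"], ["a", "b"])
        assert (fwd.values == -rev.values).all()

    def test_zero_mean_without_pseudocount_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 1.0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="zero"):
            signature_ratio(m, ["a"], ["b"])
        r = signature_ratio(m, ["a"], ["b"], pseudocount=1.0)
        assert r.values["s1"] == pytest.approx(-1.0)


class TestTMB:
    def setup_method(self):
        self.muts = MutationTable(
            pd.DataFrame(
                {"sample": ["s1", "s1", "s1"], "gene": ["A", "B", "C"], "variant_class": ["missense"] * 3}
            )
        )

    def test_counts_records_per_sample(self):
        tmb = compute_tmb(self.muts, ["s1", "s2"])
        assert tmb["s1"] == 3 and tmb["s2"] == 0

    def test_duplicate_record_counts_twice_by_default(self, caplog):
        rec = pd.concat([self.muts.records, self.muts.records.iloc[[0]]], ignore_index=True)
        with caplog.at_level("WARNING"):
            tmb = compute_tmb(MutationTable(rec), ["s1"])
        assert tmb["s1"] == 4
        assert "counted twice" in caplog.text
        assert compute_tmb(MutationTable(rec), ["s1"], dedup=True)["s1"] == 3

    def test_sample_outside_roster_rejected(self):
        with pytest.raises(ValidationError, match="roster"):
            compute_tmb(self.muts, ["s2"])


def screen_fixture(a, b, c, d, gene="G"):
    """Mutation table + labels realizing a 2x2 (mutated/wild x H/L) table."""
    n1, n2 = a + b, c + d
    samples = [f"h{i}" for i in range(n1)] + [f"l{i}" for i in range(n2)]
    lab = labels_of({s: ("IM-H" if s.startswith("h") else "IM-L") for s in samples})
    carriers = samples[:a] + samples[n1 : n1 + c]
    muts = MutationTable(pd.DataFrame({"sample": carriers, "gene": [gene] * len(carriers), "variant_class": ["missense"] * len(carriers)}))
    return muts, lab


class TestMutationEnrichment:
    def test_hand_odds_ratio(self):
        muts, lab = screen_fixture(8, 2, 2, 8)
        out = mutation_enrichment(muts, lab, "IM-H", "IM-L")
        row = out.iloc[0]
        assert row["odds_ratio"] == pytest.approx(16.0)
        assert row["direction"] == "group1"

    def test_equal_rates_not_reported(self):
        muts, lab = screen_fixture(5, 5, 5, 5)
        out = mutation_enrichment(muts, lab, "IM-H", "IM-L")
        assert out.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert not out.iloc[0]["significant"]

    def test_haldane_correction_on_zero_cells(self):
        muts, lab = screen_fixture(5, 0, 0, 5)
        out = mutation_enrichment(muts, lab, "IM-H", "IM-L")
        row = out.iloc[0]
        assert row["odds_ratio"] == pytest.approx(121.0)
        # Fisher p from the raw table: hypergeometric, only extreme tables
        p_hand = hypergeom.pmf(5, 10, 5, 5) * 2
        assert row["p"] == pytest.approx(p_hand, rel=1e-9)

    def test_swapping_groups_inverts_odds_ratio(self):
        muts, lab = screen_fixture(8, 2, 2, 8)
        fwd = mutation_enrichment(muts, lab, "IM-H", "IM-L").iloc[0]["odds_ratio"]
        rev = mutation_enrichment(muts, lab, "IM-L", "IM-H").iloc[0]["odds_ratio"]
        assert fwd == pytest.approx(1.0 / rev)

    def test_overlapping_groups_rejected(self):
        muts, lab = screen_fixture(2, 2, 2, 2)
        with pytest.raises(ValidationError, match="disjoint"):
            mutation_enrichment(muts, lab, "IM-H", "IM-H")


class TestDifferentialGenes:
    def test_fold_change_and_fdr_gates(self):
        rng = np.random.default_rng(0)
        n = 30
        genes = {"big_shift": 2.5, "tiny_shift": 0.3}
        rows = {}
        for g, shift in genes.items():
            rows[g] = np.concatenate([rng.normal(8 + shift, 0.1, n), rng.normal(8, 0.1, n)])
        m = ExpressionMatrix(
            pd.DataFrame(rows, index=[f"x{i}" for i in range(2 * n)]).T, log_transformed=True
        )
        lab = labels_of({f"x{i}": ("IM-H" if i < n else "IM-L") for i in range(2 * n)})
        out = differential_genes(m, lab, "IM-H", "IM-L").set_index("gene")
        assert bool(out.loc["big_shift", "up_in_group1"])  # FC = 2^2.5 > 2, tiny p
        assert not bool(out.loc["tiny_shift", "up_in_group1"])  # FC = 2^0.3 < 2 despite small p

    def test_planted_truth_recall_and_fdr(self):
        m, lab, true_genes = plant_de_matrix(n_true=50, n_null=500, n_per_group=30, seed=3)
        out = differential_genes(m, lab, "IM-H", "IM-L")
        called = set(out.loc[out["up_in_group1"], "gene"])
        recall = len(called & set(true_genes)) / len(true_genes)
        fdr = len(called - set(true_genes)) / max(1, len(called))
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_zero_variance_gene_skipped(self, caplog):
        m = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [1.0, 1.0], "s2": [1.0, 2.0], "s3": [1.0, 3.0], "s4": [1.0, 4.0]}, index=["flat", "ok"]
            )
        )
        lab = labels_of({"s1": "IM-H", "s2": "IM-H", "s3": "IM-L", "s4": "IM-L"})
        with caplog.at_level("INFO"):
            out = differential_genes(m, lab, "IM-H", "IM-L")
        assert "flat" not in set(out["gene"]) and "ok" in set(out["gene"])


class TestOverrepresentation:
    def test_hand_hypergeometric(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"S": universe[:5]})
        out = overrepresentation(universe[:4], sets, universe)
        # P(overlap >= 4) with M=10, K=5, N=4 = C(5,4)C(5,0)/C(10,4) = 5/210
        assert out.iloc[0]["p"] == pytest.approx(5 / 210, rel=1e-9)

    def test_disjoint_list_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"S": universe[:5]})
        out = overrepresentation(universe[5:9], sets, universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_set_equal_to_universe_degenerate(self):
        universe = [f"u{i}" for i in range(6)]
        out = overrepresentation(universe[:3], GeneSetCollection({"S": universe}), universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            overrepresentation(["zzz"], GeneSetCollection({"S": ["a", "b"]}), ["a", "b"])

    def test_empty_list_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = overrepresentation([], GeneSetCollection({"S": ["a"]}), ["a", "b"])
        assert len(out) == 0


def bh_step_up_oracle(p):
    """Brute-force BH: sort, scale by m/rank, enforce monotonicity, cap at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up_oracle(p), atol=1e-12)

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.random(25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def clinical_of(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"os_time": times, "os_event": events, "dfs_time": times, "dfs_event": events, "response": ["missing"] * len(times)},
            index=pd.Index(samples, name="sample"),
        )
    )


class TestKMLogrank:
    def test_hand_product_limit_two_events(self):
        clin = clinical_of([1.0, 2.0], [1, 1])
        lab = labels_of({"s0": "IM-H", "s1": "IM-H"})
        res = km_logrank(clin, lab, "OS", groups=["IM-H"])
        curve = res.curves["IM-H"]
        np.testing.assert_allclose(curve.survival, [0.5, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [2, 1])

    def test_hand_product_limit_with_censoring(self):
        # times 1(event), 2(censored), 3(event): S = 1/2 at t=3 -> 0.5*... wait
        clin = clinical_of([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        lab = labels_of({f"s{i}": "IM-H" for i in range(4)})
        res = km_logrank(clin, lab, "OS", groups=["IM-H"])
        c = res.curves["IM-H"]
        # S(1) = 3/4; S(3) = 3/4 * 1/2 = 3/8; censored at 2 and 4
        s = dict(zip(c.times, c.survival))
        assert s[1.0] == pytest.approx(0.75)
        assert s[3.0] == pytest.approx(0.375)
        np.testing.assert_allclose(c.censored_times, [2.0, 4.0])

    def test_identical_groups_give_null_logrank(self):
        clin = clinical_of([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        lab = labels_of({f"s{i}": ("IM-H" if i < 3 else "IM-L") for i in range(6)})
        res = km_logrank(clin, lab, "DFS")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_empty_group_rejected(self):
        clin = clinical_of([1.0, 2.0], [1, 1])
        lab = labels_of({"s0": "IM-H", "s1": "IM-H"})
        with pytest.raises(ValidationError, match="zero samples"):
            km_logrank(clin, lab, "OS", groups=["IM-H", "IM-L"])


class TestGroupCompare:
    def test_identical_groups_t_test_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labs = pd.Series(["a"] * 3 + ["b"] * 3)
        out = group_compare(vals, labs, test="t_two_tailed")
        assert out["p"] == pytest.approx(1.0)

    def test_exact_mann_whitney_enumeration(self):
        out = group_compare(
            pd.Series([1, 2, 3, 4, 5, 6]), pd.Series(["a"] * 3 + ["b"] * 3),
            test="mann_whitney_one_tailed", direction="less",
        )
        assert out["statistic"] == 0.0  # U for the first group
        assert out["p"] == pytest.approx(1 / 20)  # 1 of C(6,3)=20 orderings
        assert "less" in out["sidedness"]

    def test_one_tailed_requires_direction(self):
        with pytest.raises(ValidationError, match="direction"):
            group_compare(pd.Series([1, 2, 3, 4]), pd.Series(["a", "a", "b", "b"]), test="mann_whitney_one_tailed")

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[8, 2], [2, 8]]
        out = group_compare(None, None, test="fisher_exact", table=table)
        # two-sided exact p: sum of all tables with pmf <= observed
        p_obs = hypergeom.pmf(8, 20, 10, 10)
        p_hand = sum(
            hypergeom.pmf(k, 20, 10, 10) for k in range(11) if hypergeom.pmf(k, 20, 10, 10) <= p_obs * (1 + 1e-9)
        )
        assert out["p"] == pytest.approx(p_hand, rel=1e-9)

    def test_kruskal_three_groups_runs(self):
        vals = pd.Series(np.arange(9.0))
        labs = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = group_compare(vals, labs, test="kruskal_wallis")
        assert 0 <= out["p"] <= 1


class TestImmuneScorePurity:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.m = ExpressionMatrix(
            pd.DataFrame(
                rng.lognormal(2, 1, size=(60, 5)),
                index=[f"g{i}" for i in range(60)],
                columns=[f"s{i}" for i in range(5)],
            )
        )
        self.immune = [f"g{i}" for i in range(10)]
        self.stromal = [f"g{i}" for i in range(10, 20)]

    def test_closed_form_at_zero_slope(self):
        out = immune_score_purity(self.m, self.immune, self.stromal, slope=0.0)
        np.testing.assert_allclose(out["purity"], np.cos(0.6049872018), atol=1e-12)
        assert np.cos(0.6049872018) == pytest.approx(0.8224, abs=5e-4)

    def test_purity_recomputable_from_scores(self):
        out = immune_score_purity(self.m, self.immune, self.stromal)
        expected = np.cos(0.6049872018 + 0.0001467884 * (out["immune_score"] + out["stromal_score"]))
        np.testing.assert_allclose(out["purity"], np.clip(expected, 0, 1), atol=1e-12)

    def test_purity_monotone_decreasing_in_combined_score(self):
        x = np.linspace(0, (np.pi - 0.6049872018) / 0.0001467884, 50)
        purity = np.cos(0.6049872018 + 0.0001467884 * x)
        assert (np.diff(purity) < 0).all()

    def test_in_set_genes_at_top_maximise_immune_score(self):
        boosted = self.m.values.copy()
        boosted.loc[self.immune, "s0"] = boosted.to_numpy().max() * 10
        out = immune_score_purity(ExpressionMatrix(boosted), self.immune, self.stromal)
        assert out["immune_score"].idxmax() == "s0"

    def test_missing_set_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            immune_score_purity(self.m, ["nope"], self.stromal)
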