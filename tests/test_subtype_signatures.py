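"""Signature derivation, BH control, clustering, bulk classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amlss import subtype_signatures as ss
from amlss.synthetic_data import make_concordance_fixture


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up adjusted p-values, spelled out."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestBhQvalues:
    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(1, 300))
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(ss.bh_qvalues(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 100)
        assert (ss.bh_qvalues(p) >= p - 1e-15).all()


class TestLog2ThresholdTransform:
    @pytest.mark.parametrize(
        "x, expected", [(0.005, np.log2(0.01)), (1.0, 0.0), (8.0, 3.0), (0.01, np.log2(0.01))]
    )
    def test_values(self, x, expected):
        assert ss.log2_threshold_transform(np.array([[x]]))[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ss.log2_threshold_transform(np.array([-0.1]))

    def test_dataframe_roundtrip(self):
        df = pd.DataFrame({"s": [0.5, 2.0]}, index=["g1", "g2"])
        out = ss.log2_threshold_transform(df)
        assert isinstance(out, pd.DataFrame) and list(out.index) == ["g1", "g2"]


class TestVarianceFilter:
    def test_threshold_example(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 20)
        rows = {}
        for name, sd in (("g1", 1.0), ("g2", 0.5), ("g3", 0.44)):
            z = base / base.std(ddof=1) * sd
            rows[name] = z - z.mean()
        m = pd.DataFrame(rows).T
        assert ss.variance_filter(m, 0.45) == ["g1", "g2"]
        assert ss.variance_filter(m, 0.0) == ["g1", "g2", "g3"]
        assert ss.variance_filter(m, 1.01) == []

    def test_constant_matrix_warns_empty(self):
        m = pd.DataFrame(np.ones((3, 4)), index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            assert ss.variance_filter(m, 0.5) == []


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 30)
        m = pd.DataFrame({"s1": col, "s2": col, "s3": -col})
        res = ss.hierarchical_cluster(m, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.labels["s1"] == res.labels["s2"] != res.labels["s3"]

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(2)
        block = rng.normal(0, 1, (40, 1))
        a = block + rng.normal(0, 0.1, (40, 6))
        b = -block + rng.normal(0, 0.1, (40, 6))
        m = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(12)])
        res = ss.hierarchical_cluster(m, k=2)
        left = set(res.labels[res.labels == res.labels["s0"]].index)
        assert left == {f"s{i}" for i in range(6)}

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            ss.hierarchical_cluster(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestImmatureVsMatureSelect:
    @staticmethod
    def _avg_matrix(rng, n_samples=6, n_genes=30, up_genes=(0, 1, 2), effect=4.0):
        rows, idx = [], []
        for s in range(n_samples):
            for ct in ss.IMMATURE_TYPES + ss.MATURE_TYPES:
                x = rng.normal(3, 0.3, n_genes)
                if ct in ss.IMMATURE_TYPES:
                    x[list(up_genes)] += effect
                rows.append(x)
                idx.append((f"s{s}", ct))
        return pd.DataFrame(
            rows, index=pd.MultiIndex.from_tuples(idx), columns=[f"g{i}" for i in range(n_genes)]
        )

    def test_separated_genes_selected(self):
        rng = np.random.default_rng(3)
        avg = self._avg_matrix(rng)
        de, sel = ss.immature_vs_mature_select(avg, [f"s{i}" for i in range(6)], 10, 1e-4)
        assert set(sel) == {"g0", "g1", "g2"}

    def test_statistics_match_scipy_oracle(self):
        rng = np.random.default_rng(4)
        avg = self._avg_matrix(rng)
        samples = [f"s{i}" for i in range(6)]
        de, _ = ss.immature_vs_mature_select(avg, samples, 10, 1e-4)
        sub = avg.loc[avg.index.get_level_values(0).isin(samples)]
        ct = sub.index.get_level_values(1)
        for gene in rng.choice(avg.columns, 10, replace=False):
            a = sub.loc[ct.isin(ss.IMMATURE_TYPES), gene]
            b = sub.loc[ct.isin(ss.MATURE_TYPES), gene]
            t, p = stats.ttest_ind(a, b)
            row = de.set_index("gene").loc[gene]
            assert row["t_statistic"] == pytest.approx(t)
            assert row["p_value"] == pytest.approx(p)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(5)
        avg = self._avg_matrix(rng, n_samples=1).iloc[:4]  # drop all mature rows
        with pytest.raises(ValueError, match="mature"):
            ss.immature_vs_mature_select(avg, ["s0"], 10, 1e-4)


class TestDeriveSignature:
    def test_truth_recovery_on_cohort(self, cohort, cohort_signature):
        _, truth = cohort
        sig = cohort_signature
        planted = set(truth.class1_up_genes) | set(truth.class2_up_genes)
        got = set(sig.class1_up) | set(sig.class2_up)
        assert len(planted & got) / len(got) >= 0.9  # precision
        assert len(planted & got) / len(planted) >= 0.75  # recall with exclusion stage on
        # signs are oriented correctly
        assert set(sig.class1_up) <= set(truth.class1_up_genes) | (got - planted)
        assert not set(sig.class2_up) & set(truth.class1_up_genes)

    def test_provenance_union_is_set_union(self, cohort_signature):
        p = cohort_signature.provenance
        assert p["n_union"] <= p["n_class1_selected"] + p["n_class2_selected"]
        assert p["n_union"] >= max(p["n_class1_selected"], p["n_class2_selected"])
        assert p["n_final"] == p["n_stage3_hits"] - p["n_cross_celltype_excluded"]

    def test_cross_celltype_exclusion_drops_leaky_gene(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(8)]
        rows, idx = [], []
        sample_class = {}
        for c, cls in (("A", "I"), ("B", "I"), ("C", "II"), ("D", "II")):
            sample_class[c] = cls
            for ct in ss.IMMATURE_TYPES + ss.MATURE_TYPES:
                x = rng.normal(2, 0.05, len(genes))
                if ct in ss.IMMATURE_TYPES:
                    x[:4] += 5.0  # immature-up block
                if ct == "AML_immature" and cls == "I":
                    x[:2] += 2.0  # class-I contrast on g0, g1
                rows.append(x)
                idx.append((c, ct))
        avg = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(idx), columns=genes)
        # g0 leaks into monocytes on the linear scale; g1 is immature-specific
        ct_means = pd.DataFrame(
            {g: {"AML_immature": 100.0, "Monocyte": 1.0, "T": 1.0} for g in genes}
        )
        ct_means["g0"] = pd.Series({"AML_immature": 100.0, "Monocyte": 80.0, "T": 1.0})
        sig = ss.derive_signature(
            avg,
            pd.Series(sample_class),
            celltype_means=ct_means,  # celltype x gene
            class1_selection=ss.SelectionParams(n_top=6, q_max=0.05),
            class2_selection=ss.SelectionParams(n_top=6, q_max=0.05),
        )
        assert "g0" not in sig.genes
        assert "g1" in sig.class1_up
        assert sig.provenance["n_cross_celltype_excluded"] >= 1


class TestShortlist30:
    def test_planted_markers_recovered_exactly(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:02d}" for i in range(60)]
        labels = pd.Series(
            ["class_I"] * 5 + ["class_II"] * 5 + ["unclassified"] * 5,
            index=[f"s{i}" for i in range(15)],
        )
        expr = pd.DataFrame(
            rng.normal(0, 0.1, (15, 60)), index=labels.index, columns=genes
        )
        expr.iloc[0:5, 0:10] += 3.0
        expr.iloc[5:10, 10:20] += 3.0
        expr.iloc[10:15, 20:30] += 3.0
        sig = ss.shortlist_30(expr, labels)
        assert set(sig.class1_up) == set(genes[0:10])
        assert set(sig.class2_up) == set(genes[10:20])
        assert set(sig.unclassified_up) == set(genes[20:30])
        assert len(sig.genes) == 30 and len(set(sig.genes)) == 30

    def test_identical_groups_deterministic(self):
        labels = pd.Series(
            ["class_I", "class_II", "unclassified"], index=["a", "b", "c"]
        )
        expr = pd.DataFrame(1.0, index=["a", "b", "c"], columns=[f"g{i}" for i in range(40)])
        s1 = ss.shortlist_30(expr, labels)
        s2 = ss.shortlist_30(expr, labels)
        assert s1.genes == s2.genes and len(set(s1.genes)) == 30

    def test_too_few_genes_rejected(self):
        labels = pd.Series(["class_I", "class_II", "unclassified"], index=list("abc"))
        expr = pd.DataFrame(1.0, index=list("abc"), columns=[f"g{i}" for i in range(12)])
        with pytest.raises(ValueError, match="distinct genes|rankable"):
            ss.shortlist_30(expr, labels)


class TestClassifyBulk:
    @staticmethod
    def _toy_signature():
        return ss.SignatureSet(class1_up=[f"a{i}" for i in range(5)],
                               class2_up=[f"b{i}" for i in range(5)])

    @staticmethod
    def _toy_bulk(rng, n_per_class=6):
        sig_genes = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        cols = {}
        for j in range(n_per_class):
            x = rng.normal(2, 0.1, 10)
            x[:5] += 2.0
            cols[f"I{j}"] = x
            y = rng.normal(2, 0.1, 10)
            y[5:] += 2.0
            cols[f"II{j}"] = y
        return pd.DataFrame(cols, index=sig_genes)

    def test_centroid_samples_called_correctly(self):
        rng = np.random.default_rng(8)
        bulk = self._toy_bulk(rng)
        res = ss.classify_bulk(bulk, self._toy_signature())
        calls = res.calls
        class1_cols = [c for c in bulk if not c.startswith("II")]
        class2_cols = [c for c in bulk if c.startswith("II")]
        assert (calls[class1_cols] == "class_I").all()
        assert (calls[class2_cols] == "class_II").all()

    def test_balanced_mixture_unclassified(self):
        rng = np.random.default_rng(9)
        bulk = self._toy_bulk(rng)
        mix = bulk.mean(axis=1)
        bulk["mix"] = mix
        res = ss.classify_bulk(bulk, self._toy_signature())
        assert res.calls["mix"] == "unclassified"

    def test_invariant_to_genewise_affine_rescaling(self):
        rng = np.random.default_rng(10)
        bulk = self._toy_bulk(rng)
        a = rng.uniform(0.5, 3.0, len(bulk))
        b = rng.uniform(-2, 2, len(bulk))
        rescaled = bulk.mul(a, axis=0).add(b, axis=0)
        r1 = ss.classify_bulk(bulk, self._toy_signature())
        r2 = ss.classify_bulk(rescaled, self._toy_signature())
        assert (r1.calls == r2.calls).all()
        np.testing.assert_allclose(r1.frame["score_I"], r2.frame["score_I"], atol=1e-10)

    def test_insufficient_overlap_rejected(self):
        rng = np.random.default_rng(11)
        bulk = self._toy_bulk(rng).iloc[:4]  # only 4/10 signature genes present
        with pytest.raises(ValueError, match="signature genes"):
            ss.classify_bulk(bulk, self._toy_signature())

    def test_clustering_route_agrees_on_separated_cohort(self):
        rng = np.random.default_rng(12)
        bulk = self._toy_bulk(rng)
        margin_calls = ss.classify_bulk(bulk, self._toy_signature()).calls
        cluster_calls = ss.classify_bulk_by_clustering(bulk, self._toy_signature(), k=2)
        assert (margin_calls == cluster_calls).all()


class TestConcordance:
    def test_identical_calls(self):
        calls = pd.Series(["class_I", "class_II", "unclassified"], index=list("abc"))
        rep = ss.concordance_report(calls, calls)
        assert rep["agreement"] == 1.0 and rep["n_discordant"] == 0

    def test_fixture_reproduces_planted_structure(self):
        a, b = make_concordance_fixture(seed=1)
        rep = ss.concordance_report(a, b)
        assert rep["n_samples"] == 370
        assert rep["n_agree"] == 315
        assert rep["n_discordant"] == 55
        assert rep["n_discordant_unclassified"] == 49
        assert rep["n_class_swap"] == 6

    def test_confusion_row_sums(self):
        a, b = make_concordance_fixture(seed=2)
        rep = ss.concordance_report(a, b)
        row_sums = rep["confusion"].sum(axis=1)
        for level in ss.CALL_LEVELS:
            assert row_sums[level] == (a == level).sum()

    def test_empty_intersection_rejected(self):
        a = pd.Series(["class_I"], index=["x"])
        b = pd.Series(["class_I"], index=["y"])
        with pytest.raises(ValueError, match="share no sample"):
            ss.concordance_report(a, b)
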