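import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import newmanbank as nb

from conftest import random_assignment


def _assignment(labels):
    labels = np.asarray(labels, int)
    return nb.ClusterAssignment(
        sample_ids=pd.Index([f"s{i}" for i in range(len(labels))]),
        labels=labels,
        k=int(labels.max()),
    )


def _calls_from_cluster_pattern(pattern, cluster_sizes):
    """Build a calls frame: pattern[gene][cluster] = number of 1-calls there."""
    labels = np.concatenate(
        [np.full(n, c + 1) for c, n in enumerate(cluster_sizes)]
    )
    cols = [f"s{i}" for i in range(labels.size)]
    data = {}
    for gene, per_cluster in pattern.items():
        row = np.zeros(labels.size, int)
        for c, count in enumerate(per_cluster):
            idx = np.where(labels == c + 1)[0][:count]
            row[idx] = 1
        data[gene] = row
    frame = pd.DataFrame(data, index=cols).T
    return frame, _assignment(labels)


class TestFrequencies:
    def test_full_presence_is_hundred_percent(self):
        calls, asg = _calls_from_cluster_pattern({"gA": [10, 0]}, [10, 10])
        table = nb.feature_frequencies(calls, asg)
        assert table.frequencies.loc["gA", "cluster_1"] == 100.0
        assert table.frequencies.loc["gA", "cluster_2"] == 0.0

    def test_overall_is_weighted_cluster_mean(self):
        rng = np.random.default_rng(21)
        calls = pd.DataFrame(
            (rng.random((30, 25)) < 0.3).astype(int),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(25)],
        )
        asg = _assignment(random_assignment(rng, 25, 3))
        table = nb.feature_frequencies(calls, asg)
        sizes = table.cluster_sizes.to_numpy()
        weighted = (
            table.frequencies[[f"cluster_{c}" for c in (1, 2, 3)]].to_numpy()
            * sizes / sizes.sum()
        ).sum(axis=1)
        np.testing.assert_allclose(table.frequencies["overall"], weighted, atol=1e-9)

    def test_top_listing_matches_hand_ranking(self):
        pattern = {
            "gA": [9, 0], "gB": [7, 0], "gC": [7, 0],
            "gD": [4, 0], "gE": [2, 0], "gF": [1, 0],
        }
        calls, asg = _calls_from_cluster_pattern(pattern, [10, 10])
        table = nb.feature_frequencies(calls, asg, top_k=5)
        top1 = table.top[table.top["cluster"] == 1]
        # gB/gC tie at 70% resolved alphabetically
        assert list(top1["feature"]) == ["gA", "gB", "gC", "gD", "gE"]


class TestChisqOneVsRest:
    def test_perfect_association_statistic(self):
        # 2x2 table [[10, 0], [0, 10]] -> chi2 = 20
        calls, asg = _calls_from_cluster_pattern({"g": [10, 0]}, [10, 10])
        res = nb.chisq_one_vs_rest(calls, asg)
        row = res[(res["feature"] == "g") & (res["cluster"] == 1)].iloc[0]
        assert row["chi2"] == pytest.approx(20.0)
        assert row["enriched"]

    def test_esophageal_histology_table_statistic(self):
        # [[57, 6], [29, 28]] -> 23.109 by n(ad-bc)^2/(r1 r2 c1 c2)
        calls, asg = _calls_from_cluster_pattern({"adeno": [57, 6]}, [86, 34])
        res = nb.chisq_one_vs_rest(calls, asg)
        row = res[(res["feature"] == "adeno") & (res["cluster"] == 1)].iloc[0]
        assert row["chi2"] == pytest.approx(23.109, abs=0.001)

    def test_uniform_feature_gives_zero(self):
        calls, asg = _calls_from_cluster_pattern({"g": [5, 5]}, [10, 10])
        res = nb.chisq_one_vs_rest(calls, asg)
        np.testing.assert_allclose(res["chi2"], 0.0, atol=1e-12)

    def test_degenerate_feature(self):
        calls, asg = _calls_from_cluster_pattern({"none": [0, 0], "all": [10, 10]},
                                                 [10, 10])
        res = nb.chisq_one_vs_rest(calls, asg)
        assert (res["chi2"] == 0.0).all() and (res["p"] == 1.0).all()

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(22)
        calls = pd.DataFrame(
            (rng.random((20, 40)) < 0.3).astype(int),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(40)],
        )
        asg = _assignment(random_assignment(rng, 40, 3))
        res = nb.chisq_one_vs_rest(calls, asg).set_index(["feature", "cluster"])
        for gene in calls.index[:8]:
            for c in (1, 2, 3):
                row = res.loc[(gene, c)]
                table = np.array([
                    [row["n11"], row["n10"]],
                    [row["n01"], row["n00"]],
                ])
                if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                    continue
                ref = stats.chi2_contingency(table, correction=False)
                assert row["chi2"] == pytest.approx(ref.statistic, rel=1e-9)
                assert row["p"] == pytest.approx(ref.pvalue, rel=1e-6)


class TestChisqAcross:
    def test_two_clusters_equals_one_vs_rest(self):
        rng = np.random.default_rng(23)
        calls = pd.DataFrame(
            (rng.random((15, 30)) < 0.4).astype(int),
            index=[f"g{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(30)],
        )
        asg = _assignment(random_assignment(rng, 30, 2))
        across = nb.chisq_across_clusters(calls, asg)
        ovr = nb.chisq_one_vs_rest(calls, asg)
        ovr1 = ovr[ovr["cluster"] == 1].set_index("feature")["chi2"]
        np.testing.assert_allclose(across["chi2"], ovr1.loc[across.index], atol=1e-9)

    def test_matches_expected_counts_oracle(self):
        rng = np.random.default_rng(24)
        calls = pd.DataFrame(
            (rng.random((25, 60)) < 0.3).astype(int),
            index=[f"g{i}" for i in range(25)],
            columns=[f"s{i}" for i in range(60)],
        )
        asg = _assignment(random_assignment(rng, 60, 4))
        across = nb.chisq_across_clusters(calls, asg)
        for gene in calls.index:
            obs = np.zeros((2, 4))
            for c in range(1, 5):
                members = asg.labels == c
                obs[0, c - 1] = calls.loc[gene].to_numpy()[members].sum()
                obs[1, c - 1] = members.sum() - obs[0, c - 1]
            if obs.sum(axis=1).min() == 0:
                assert across.loc[gene, "chi2"] == 0.0
                continue
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            ref = ((obs - expected) ** 2 / expected).sum()
            assert across.loc[gene, "chi2"] == pytest.approx(ref, rel=1e-9)


class TestAnova:
    def test_textbook_toy_f(self):
        nu = pd.DataFrame(
            [[0.0, 1.0, 2.0, 10.0, 11.0, 12.0]],
            index=["g"], columns=[f"s{i}" for i in range(6)],
        )
        asg = _assignment([1, 1, 1, 2, 2, 2])
        res = nb.anova_nu(nu, asg)
        assert res.loc["g", "F"] == pytest.approx(150.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(25)
        nu = pd.DataFrame(
            rng.normal(size=(10, 50)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(50)],
        )
        labels = random_assignment(rng, 50, 4)
        asg = _assignment(labels)
        res = nb.anova_nu(nu, asg)
        for gene in nu.index:
            groups = [nu.loc[gene].to_numpy()[labels == c] for c in range(1, 5)]
            ref = stats.f_oneway(*groups)
            assert res.loc[gene, "F"] == pytest.approx(ref.statistic, rel=1e-9)
            assert res.loc[gene, "p"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(26)
        nu = pd.DataFrame(
            rng.normal(size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = random_assignment(rng, 30, 3)
        res1 = nb.anova_nu(nu, _assignment(labels))
        perm = rng.permutation(30)
        nu2 = nu.iloc[:, perm]
        asg2 = nb.ClusterAssignment(
            sample_ids=pd.Index(nu2.columns), labels=labels[perm],
            k=3,
        )
        res2 = nb.anova_nu(nu2, asg2)
        np.testing.assert_allclose(res1["F"], res2["F"], rtol=1e-9)

    def test_degenerate_zero_within_variance(self):
        nu = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0]],
            index=["sep", "flat"], columns=[f"s{i}" for i in range(4)],
        )
        res = nb.anova_nu(nu, _assignment([1, 1, 2, 2]))
        assert res.loc["sep", "degenerate"] and res.loc["sep", "p"] == 0.0
        assert not res.loc["flat", "degenerate"] and res.loc["flat", "p"] == 1.0


class TestFdr:
    def test_hand_computed_step_up(self):
        q = nb.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(nb.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(nb.ValidationError):
            nb.fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_q_dominates_p(self, p):
        q = nb.fdr_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


def _selection_fixture():
    """200 samples in 4 clusters of 50 with genes probing every filter arm."""
    sizes = [50, 50, 50, 50]
    pattern = {
        # abnormal in 50% of cluster 2, ~2% elsewhere: passes everything
        "g_planted": [1, 25, 1, 1],
        # tiny p-values but only 9% of all samples: blocked by the 10% rule
        "g_lowfreq": [18, 0, 0, 0],
        # frequent and cluster-biased calls but flat nu: blocked by ANOVA
        "g_noanova": [40, 8, 8, 8],
        # frequent but uniform calls: blocked by the chi-squared test
        "g_nochisq": [13, 13, 12, 12],
    }
    calls, asg = _calls_from_cluster_pattern(pattern, sizes)
    rng = np.random.default_rng(27)
    nu = pd.DataFrame(
        rng.normal(0, 0.3, calls.shape), index=calls.index, columns=calls.columns
    )
    # planted gene and the low-frequency gene track their calls in nu space
    nu.loc["g_planted"] += 6.0 * calls.loc["g_planted"].to_numpy()
    nu.loc["g_lowfreq"] += 6.0 * calls.loc["g_lowfreq"].to_numpy()
    return calls, nu, asg


class TestSelection:
    def test_joint_filter_and_allocation(self):
        calls, nu, asg = _selection_fixture()
        across = nb.chisq_across_clusters(calls, asg)
        anova = nb.anova_nu(nu, asg)
        sel = nb.select_cluster_genes(across, anova, calls, asg)
        assert sel.genes == ["g_planted"]
        assert sel.table.loc["g_planted", "cluster"] == 2
        assert sel.per_cluster[2] == ["g_planted"]
        # exhaustive filter semantics over every gene in the fixture
        x = calls.to_numpy()
        overall = x.mean(axis=1)
        for i, gene in enumerate(calls.index):
            should = (
                across.loc[gene, "p"] < 0.01
                and anova.loc[gene, "p"] < 0.01
                and overall[i] >= 0.10
            )
            assert (gene in sel.genes) == should

    def test_partition_property(self):
        calls, nu, asg = _selection_fixture()
        across = nb.chisq_across_clusters(calls, asg)
        anova = nb.anova_nu(nu, asg)
        sel = nb.select_cluster_genes(across, anova, calls, asg, p_cut=0.5, min_frac=0.0)
        sizes = sum(len(v) for v in sel.per_cluster.values())
        assert sizes == len(sel.genes)

    def test_export_and_determinism(self, tmp_path):
        calls, nu, asg = _selection_fixture()
        across = nb.chisq_across_clusters(calls, asg)
        anova = nb.anova_nu(nu, asg)
        sel = nb.select_cluster_genes(across, anova, calls, asg)
        paths = nb.export_gene_lists(sel, tmp_path / "lists")
        assert len(paths) == 1
        first = paths[0].read_bytes()
        assert first == b"g_planted\n"
        nb.export_gene_lists(sel, tmp_path / "lists")
        assert paths[0].read_bytes() == first

    def test_empty_selection_warns(self, tmp_path):
        calls, nu, asg = _selection_fixture()
        across = nb.chisq_across_clusters(calls, asg)
        anova = nb.anova_nu(nu, asg)
        sel = nb.select_cluster_genes(across, anova, calls, asg, p_cut=1e-300)
        with pytest.warns(UserWarning):
            assert nb.export_gene_lists(sel, tmp_path / "none") == []


class TestContrast:
    def test_extreme_mean_membership(self):
        labels = np.repeat([1, 2, 3, 4], 5)
        asg = _assignment(labels)
        cols = [f"s{i}" for i in range(20)]
        nu = pd.DataFrame(
            {
                # max mean in cluster 1 -> included for pair (1, 2)
                "g_hi1": np.where(labels == 1, 5.0, 0.0),
                # min mean in cluster 2 -> included (symmetric)
                "g_lo2": np.where(labels == 2, -5.0, 0.0),
                # extremes in clusters 3 and 4 -> excluded despite allocation
                "g_out": np.where(labels == 3, 5.0, np.where(labels == 4, -5.0, 0.0)),
            },
            index=cols,
        ).T
        table = pd.DataFrame(
            {"cluster": [1, 2, 1], "chisq_p": 0.0, "anova_p": 0.0,
             "overall_frac": 0.5, "tie": False},
            index=["g_hi1", "g_lo2", "g_out"],
        )
        sel = nb.GeneSelectionResult(table=table)
        picked = nb.contrast_select(sel, nu, asg, pair=(1, 2))
        assert picked == ["g_hi1", "g_lo2"]

    def test_missing_cluster_rejected(self):
        _, nu, asg = _selection_fixture()
        sel = nb.GeneSelectionResult(table=pd.DataFrame())
        with pytest.raises(nb.ValidationError):
            nb.contrast_select(sel, nu, asg, pair=(1, 9))
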