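import itertools

import numpy as np
import pandas as pd
import pytest

from azenet.community import (
    ASVTable,
    alpha_diversity,
    bray_curtis,
    differential_abundance,
    mean_taxonomic_proportion,
    pcoa,
    permanova,
    wilcoxon_rank_sum,
)
from azenet.errors import DegenerateInputError, ValidationError
from azenet.synthetic import AsvSimParams, simulate_asv_table


def toy_table(counts, groups, families=None):
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"asv{i}" for i in range(np.asarray(counts).shape[0])],
        columns=[f"s{i}" for i in range(np.asarray(counts).shape[1])],
    )
    tax = pd.DataFrame(
        {
            "family": families or ["fam0"] * counts.shape[0],
            "genus": ["gen0"] * counts.shape[0],
        },
        index=counts.index,
    )
    group = pd.Series(groups, index=counts.columns)
    return ASVTable(counts=counts, taxonomy=tax, group=group)


class TestAlphaDiversity:
    def test_uniform_four_species(self):
        df = pd.DataFrame({"s": [10, 10, 10, 10]})
        rep = alpha_diversity(df)
        assert rep.loc["s", "shannon"] == pytest.approx(np.log(4))
        assert rep.loc["s", "simpson"] == pytest.approx(0.75)

    def test_chao1_hand_example(self):
        # counts [5,2,1,1]: F1=2, F2=1 -> chao1 = 4 + 2*1/(2*2) = 4.5
        df = pd.DataFrame({"s": [5, 2, 1, 1]})
        rep = alpha_diversity(df)
        assert rep.loc["s", "observed"] == 4
        assert rep.loc["s", "chao1"] == pytest.approx(4.5)

    def test_single_species(self):
        df = pd.DataFrame({"s": [7, 0, 0]})
        rep = alpha_diversity(df)
        assert rep.loc["s", "observed"] == 1
        assert rep.loc["s", "chao1"] == pytest.approx(1.0)
        assert rep.loc["s", "shannon"] == 0.0
        assert rep.loc["s", "simpson"] == 0.0

    def test_observed_at_most_chao1(self, rng):
        df = pd.DataFrame(rng.poisson(2, size=(40, 5)), columns=list("abcde"))
        df.iloc[0] += 1  # avoid the all-zero-sample error
        rep = alpha_diversity(df)
        assert (rep["chao1"] >= rep["observed"] - 1e-12).all()
        assert (rep["shannon"] >= 0).all()
        assert rep["simpson"].between(0, 1).all()

    def test_all_zero_sample_errors(self):
        df = pd.DataFrame({"s": [0, 0]})
        with pytest.raises(DegenerateInputError):
            alpha_diversity(df)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = pd.DataFrame({"a": [5, 5, 0, 0], "b": [5, 5, 0, 0], "c": [0, 0, 3, 3]})
        d = bray_curtis(df)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_hand_example(self):
        # BC(a,b) = 1 - 2*min_sum/(sum_a+sum_b); a=[3,1,0], b=[1,1,2]
        df = pd.DataFrame({"a": [3, 1, 0], "b": [1, 1, 2]})
        d = bray_curtis(df)
        # min sums: 1+1+0=2 -> 1 - 2*2/(4+4) = 0.5
        assert d.loc["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_bounds_zero_diag(self, rng):
        df = pd.DataFrame(
            rng.poisson(10, size=(30, 6)) + 1, columns=[f"s{i}" for i in range(6)]
        )
        d = bray_curtis(df).values
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()

    def test_zero_total_sample_errors(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(DegenerateInputError):
            bray_curtis(df)


class TestPCoA:
    def test_euclidean_matches_pca(self, rng):
        # classical MDS on Euclidean distances reproduces PCA coordinates up
        # to sign, and variance fractions match
        x = rng.standard_normal((8, 3))
        from scipy.spatial.distance import cdist

        d = pd.DataFrame(cdist(x, x), index=range(8), columns=range(8))
        res = pcoa(d)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        pca_coords = u * s
        k = min(res.coordinates.shape[1], 3)
        for j in range(k):
            a = res.coordinates.values[:, j]
            b = pca_coords[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8
        np.testing.assert_allclose(
            res.proportion_explained[:k], s[:k] ** 2 / (s**2).sum(), atol=1e-10
        )

    def test_variance_fractions_valid(self, rng):
        df = pd.DataFrame(rng.poisson(10, size=(20, 7)) + 1, columns=range(7))
        res = pcoa(bray_curtis(df))
        assert (res.proportion_explained >= 0).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9


def permanova_oracle(d2, labels):
    """Independent exhaustive-permutation PERMANOVA for tests."""
    labels = np.asarray(labels)
    n = len(labels)
    k = len(set(labels))

    def stat(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            for ii, i in enumerate(idx):
                for j in idx[ii + 1 :]:
                    ss_within += d2[i, j]
        # note: per-group division
        ss_within2 = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            tot = sum(d2[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1 :])
            ss_within2 += tot / len(idx)
        ss_between = ss_total - ss_within2
        return (ss_between / (k - 1)) / (ss_within2 / (n - k))

    f_obs = stat(labels)
    perms = set(itertools.permutations(labels))
    hits = sum(stat(np.asarray(p)) >= f_obs - 1e-12 for p in perms)
    return f_obs, hits / len(perms)


class TestPermanova:
    def _dist(self, rng, n_samples=6, n_feat=25):
        df = pd.DataFrame(
            rng.poisson(30, size=(n_feat, n_samples)) + 1,
            columns=[f"s{i}" for i in range(n_samples)],
        )
        return bray_curtis(df)

    def test_exact_matches_enumeration_oracle(self, rng):
        d = self._dist(rng)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.index)
        res = permanova(d, groups, n_permutations="exact")
        f_oracle, p_oracle = permanova_oracle(d.values**2, groups.values)
        assert res["pseudo_F"] == pytest.approx(f_oracle, rel=1e-10)
        assert res["p_value"] == pytest.approx(p_oracle, abs=1e-12)
        assert res["n_permutations"] == 20

    def test_identical_groups_null(self):
        base = np.array([[3, 1, 4, 3, 1, 4], [1, 5, 9, 1, 5, 9], [2, 6, 5, 2, 6, 5]])
        df = pd.DataFrame(base, columns=[f"s{i}" for i in range(6)])
        d = bray_curtis(df)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=d.index)
        res = permanova(d, groups, n_permutations="exact")
        assert res["R2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p_value"] >= 0.9

    def test_singleton_group_errors(self, rng):
        d = self._dist(rng, n_samples=4)
        groups = pd.Series(["a", "b", "b", "b"], index=d.index)
        with pytest.raises(DegenerateInputError):
            permanova(d, groups)

    def test_seeded_reproducible(self, rng):
        d = self._dist(rng, n_samples=8)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=d.index)
        r1 = permanova(d, groups, n_permutations=199, seed=5)
        r2 = permanova(d, groups, n_permutations=199, seed=5)
        assert r1 == r2

    def test_strong_separation_low_p(self, rng):
        df = pd.DataFrame(
            np.hstack(
                [rng.poisson(5, size=(30, 4)), rng.poisson(50, size=(30, 4))]
            ),
            columns=[f"s{i}" for i in range(8)],
        )
        d = bray_curtis(df)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=d.index)
        # only C(8,4)=70 distinct splits exist, so p bottoms out near 0.015
        res = permanova(d, groups, n_permutations=999, seed=0)
        assert res["p_value"] < 0.05
        assert res["R2"] > 0.5

    def test_permutation_count_stability(self, rng):
        d = self._dist(rng, n_samples=10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=d.index)
        p1 = permanova(d, groups, n_permutations=999, seed=1)["p_value"]
        p2 = permanova(d, groups, n_permutations=1998, seed=2)["p_value"]
        assert abs(p1 - p2) < 2 / np.sqrt(999)


def wilcoxon_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().values
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    lo = min(u_obs, n1n2 - u_obs)
    return ((us <= lo + 1e-9).sum() + (us >= n1n2 - lo - 1e-9).sum()) / len(us)


class TestWilcoxon:
    def test_complete_separation_4v4(self):
        p = wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 6), (6, 6)])
    def test_matches_enumeration_oracle(self, rng, n1, n2):
        for _ in range(5):
            a = rng.standard_normal(n1)
            b = rng.standard_normal(n2) + rng.uniform(-1, 1)
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                wilcoxon_oracle(a, b), abs=1e-9
            )

    def test_large_sample_agreement(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 0.5
        from scipy import stats

        exact = stats.mannwhitneyu(a, b, method="exact").pvalue
        assert wilcoxon_rank_sum(a, b) == pytest.approx(exact, abs=0.01)

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestDifferentialAbundance:
    def test_planted_enrichment_recovered(self):
        params = AsvSimParams(
            base_concentrations=50.0, enriched_families=[(0, 8.0)], seed=0
        )
        table, truth = simulate_asv_table(params)
        da = differential_abundance(table, ("control", "treatment"))
        planted = truth["enriched_families"][0]["asvs"]
        hits = sum(bool(da.loc[a, "significant"]) for a in planted if a in da.index)
        assert hits >= 3

    def test_depth_rescaling_invariance(self):
        params = AsvSimParams(enriched_families=[(0, 8.0)], seed=1)
        table, _ = simulate_asv_table(params)
        da1 = differential_abundance(table, ("control", "treatment"))
        scaled = ASVTable(
            counts=table.counts * 4,
            taxonomy=table.taxonomy,
            group=table.group,
        )
        da2 = differential_abundance(scaled, ("control", "treatment"))
        np.testing.assert_array_equal(
            da1["significant"].values, da2["significant"].values
        )

    def test_all_zero_asv_excluded(self):
        t = toy_table(
            [[5, 6, 7, 8, 5, 6, 7, 8], [0, 0, 0, 0, 0, 0, 0, 0]],
            ["c"] * 4 + ["t"] * 4,
        )
        da = differential_abundance(t, ("c", "t"))
        assert "asv1" not in da.index


class TestMeanTaxonomicProportion:
    def test_single_asv_family_ratio_one(self):
        t = toy_table([[10, 20]], ["a", "b"])
        props = mean_taxonomic_proportion(t, ["asv0"])
        assert props["asv0"] == pytest.approx(1.0)

    def test_two_asv_split(self):
        # per-sample means 10 and 30 -> ratios 0.25 and 0.75
        t = toy_table([[10, 10], [30, 30]], ["a", "b"])
        props = mean_taxonomic_proportion(t, ["asv0", "asv1"])
        assert props["asv0"] == pytest.approx(0.25)
        assert props["asv1"] == pytest.approx(0.75)

    def test_partition_identity(self, rng):
        counts = rng.poisson(20, size=(6, 4)) + 1
        t = toy_table(counts, ["a"] * 2 + ["b"] * 2, families=["famA"] * 3 + ["famB"] * 3)
        props = mean_taxonomic_proportion(t, [f"asv{i}" for i in range(6)])
        assert props[:3].sum() == pytest.approx(1.0)
        assert props[3:].sum() == pytest.approx(1.0)

    def test_unknown_level_errors(self):
        t = toy_table([[1, 1]], ["a", "b"])
        with pytest.raises(ValidationError):
            mean_taxonomic_proportion(t, ["asv0"], level="order")
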