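"""Module detection, eigengenes, supermodule selection, exact enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from xdosage import module_trend as mt
from xdosage.io import ExpressionMatrix
from xdosage.karyotype import KaryotypeSpec, SampleMeta
from xdosage.simulate import simulate_module_structure


class TestFilterCpm:
    def test_at_least_one_cpm_in_four_samples(self):
        # library size 1e6 makes counts == CPM
        lib = np.full(6, 0.0)
        data = pd.DataFrame(0.0, index=["keep", "drop"],
                            columns=[f"s{i}" for i in range(6)])
        data.loc["keep", ["s0", "s1", "s2", "s3"]] = 1.0
        data.loc["drop", ["s0", "s1", "s2"]] = 5.0
        filler = pd.DataFrame(
            np.full((1, 6), 1e6) - data.sum(axis=0).to_numpy(),
            index=["filler"], columns=data.columns)
        m = ExpressionMatrix(pd.concat([data, filler]), unit="counts")
        kept = mt.filter_cpm(m)
        assert "keep" in kept.genes and "drop" not in kept.genes

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix(pd.DataFrame(np.ones((2, 3)), index=["a", "b"],
                                          columns=["s1", "s2", "s3"]),
                             unit="counts")
        with pytest.raises(ValueError):
            mt.filter_cpm(m)


class TestBuildModules:
    def test_block_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score
        matrix, truth, _ = simulate_module_structure(seed=3)
        ms = mt.build_modules(matrix)
        codes = ms.labels.astype("category").cat.codes
        assert adjusted_rand_score(truth.loc[ms.labels.index, "module"], codes) >= 0.9

    def test_null_matrix_is_mostly_grey(self, rng):
        matrix, _, _ = simulate_module_structure(seed=4)
        vals = matrix.data.to_numpy().copy()
        for row in vals:
            rng.shuffle(row)
        null = ExpressionMatrix(pd.DataFrame(vals, index=matrix.genes,
                                             columns=matrix.samples), unit="log2")
        ms = mt.build_modules(null)
        assert (ms.labels == mt.GREY).mean() >= 0.9

    def test_gene_order_permutation_invariance(self, rng):
        matrix, _, _ = simulate_module_structure(seed=5, n_modules=3)
        perm = rng.permutation(matrix.genes)
        shuffled = ExpressionMatrix(matrix.data.loc[perm], unit="log2")
        a = mt.build_modules(matrix).labels
        b = mt.build_modules(shuffled).labels
        # same partition up to label renaming
        df = pd.DataFrame({"a": a, "b": b.loc[a.index]})
        mapping = df.groupby("a")["b"].nunique()
        assert (mapping == 1).all()

    def test_anticorrelated_genes_split_under_signed_convention(self, rng):
        base = rng.normal(0, 1, (1, 12)).repeat(6, axis=0) + rng.normal(0, 0.05, (6, 12))
        data = np.vstack([base, -base]) + 10
        m = ExpressionMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(12)],
                                          columns=[f"s{i}" for i in range(12)]),
                             unit="log2")
        ms = mt.build_modules(m, mt.NetworkConfig(min_module_size=3))
        up = {ms.labels[f"g{i}"] for i in range(6)}
        down = {ms.labels[f"g{i}"] for i in range(6, 12)}
        assert up.isdisjoint(down)


class TestEigengene:
    def test_identical_genes_give_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        m = ExpressionMatrix(pd.DataFrame([profile + 1, profile * 2, profile + 4],
                                          index=["a", "b", "c"],
                                          columns=[f"s{i}" for i in range(4)]),
                             unit="log2")
        eig, explained = mt.module_eigengene(m, ["a", "b", "c"])
        r = np.corrcoef(eig, profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        assert explained == pytest.approx(1.0, abs=1e-9)

    def test_sign_oriented_with_mean_profile(self, rng):
        data = rng.normal(5, 1, (10, 8))
        m = ExpressionMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(10)],
                                          columns=[f"s{i}" for i in range(8)]),
                             unit="log2")
        eig, _ = mt.module_eigengene(m, m.genes)
        mean_profile = data.mean(axis=0)
        assert np.dot(eig, mean_profile - mean_profile.mean()) >= 0

    def test_explained_variance_matches_svd(self, rng):
        data = rng.normal(0, 1, (12, 9)) + 5
        m = ExpressionMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(12)],
                                          columns=[f"s{i}" for i in range(9)]),
                             unit="log2")
        _, explained = mt.module_eigengene(m, m.genes)
        z = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
        s = np.linalg.svd(z, compute_uv=False)
        assert explained == pytest.approx(s[0] ** 2 / (s ** 2).sum(), abs=1e-9)


class TestAnovaFilter:
    @staticmethod
    def _metas(n_groups=3, per_group=4):
        metas = []
        for g in range(n_groups):
            for r in range(per_group):
                metas.append(SampleMeta(f"g{g}r{r}", KaryotypeSpec(g + 1, 1)))
        return metas

    def test_constant_eigengene_fails(self):
        metas = self._metas()
        eigs = pd.DataFrame([[1.0] * 12], index=["M1"],
                            columns=[m.sample_id for m in metas])
        assert mt.anova_filter(eigs, metas) == []

    def test_f_statistic_matches_hand_computation(self):
        metas = self._metas(3, 3)
        values = np.array([1.0, 2.0, 1.5, 4.0, 4.5, 3.5, 8.0, 7.0, 9.0])
        eigs = pd.DataFrame([values], index=["M1"],
                            columns=[m.sample_id for m in metas])
        groups = values.reshape(3, 3)
        grand = values.mean()
        ss_between = sum(3 * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_manual = (ss_between / 2) / (ss_within / 6)
        from scipy import stats
        p_manual = stats.f.sf(f_manual, 2, 6)
        assert (mt.anova_filter(eigs, metas, alpha=0.05) == ["M1"]) == (p_manual < 0.05)
        assert p_manual < 0.05  # clearly separated groups

    def test_trending_module_passes(self):
        matrix, truth, metas = simulate_module_structure(
            seed=6, trend_assignment=["up"], n_modules=1,
            trend_log2_slope=1.0, latent_sd=0.3)
        ms = mt.build_modules(matrix, mt.NetworkConfig(min_module_size=10))
        eigs = mt.compute_eigengenes(matrix, ms)
        assert mt.anova_filter(eigs, metas) == ms.modules


class TestSupermodules:
    @staticmethod
    def _module_set(eigengenes: dict, samples):
        labels = {}
        for m in eigengenes:
            for i in range(30):
                labels[f"{m}_g{i}"] = m
        ms = mt.ModuleSet(labels=pd.Series(labels))
        ms.eigengenes = pd.DataFrame(eigengenes, index=samples).T
        return ms

    @staticmethod
    def _metas():
        return [SampleMeta(f"s{i}", KaryotypeSpec(1 + i % 4, 1)) for i in range(16)]

    def test_linear_eigengene_up_trend(self):
        metas = self._metas()
        n_x = np.array([m.karyotype.n_x for m in metas], dtype=float)
        ms = self._module_set({"M1": n_x}, [m.sample_id for m in metas])
        sms = mt.select_dosage_supermodules(ms, metas)
        assert ms.trend["M1"] == "up" and sms == {"SM1": ["M1"]}

    def test_similar_same_trend_modules_merge(self, rng):
        metas = self._metas()
        n_x = np.array([m.karyotype.n_x for m in metas], dtype=float)
        e1 = n_x + rng.normal(0, 0.15, 16)
        e2 = n_x + rng.normal(0, 0.15, 16)
        assert np.corrcoef(e1, e2)[0, 1] >= 0.75
        ms = self._module_set({"M1": e1, "M2": e2}, [m.sample_id for m in metas])
        sms = mt.select_dosage_supermodules(ms, metas)
        assert sms == {"SM1": ["M1", "M2"]}

    def test_non_monotone_profile_excluded(self):
        metas = self._metas()
        n_x = np.array([m.karyotype.n_x for m in metas], dtype=float)
        updown = np.where(n_x <= 2, n_x, 4.5 - n_x)  # rises then falls
        ms = self._module_set({"M1": updown}, [m.sample_id for m in metas])
        sms = mt.select_dosage_supermodules(ms, metas)
        assert ms.trend["M1"] == "flat" and sms == {}


def hypergeom_enumeration(N, K, n, k):
    """P[X >= k] by direct pmf summation with exact binomials."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / total


class TestHypergeomEnrich:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=3 -> (C(5,3)C(5,1) + C(5,4)C(5,0)) / C(10,4)
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g7"}
        (res,) = mt.hypergeom_enrich(query, {"t": term}, universe)
        expected = (math.comb(5, 3) * math.comb(5, 1)
                    + math.comb(5, 4)) / math.comb(10, 4)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(10)}
        (res,) = mt.hypergeom_enrich({"g0"}, {"t": {"g9"}}, universe)
        assert res.overlap == 0 and res.p_value == pytest.approx(1.0)

    def test_certain_event_gives_one(self):
        universe = {f"g{i}" for i in range(4)}
        (res,) = mt.hypergeom_enrich(universe, {"t": universe}, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term = set(rng.choice(sorted(universe), K, replace=False))
            query = set(rng.choice(sorted(universe), n, replace=False))
            (res,) = mt.hypergeom_enrich(query, {"t": term}, universe)
            k = len(query & term)
            assert res.p_value == pytest.approx(
                hypergeom_enumeration(N, K, n, k), abs=1e-12)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            mt.hypergeom_enrich(set(), {"t": {"a"}}, {"a"})


class TestGeneSetOverlap:
    def test_counts_and_percentage(self):
        universe = set("abcdefgh")
        res = mt.gene_set_overlap(set("abcd"), set("cde"), universe)
        assert res["overlap"] == 2 and res["percent_of_a"] == pytest.approx(50.0)

    def test_disjoint_sets(self):
        universe = set("abcdef")
        res = mt.gene_set_overlap(set("ab"), set("cd"), universe)
        assert res["overlap"] == 0 and res["percent_of_a"] == 0.0

    def test_p_matches_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(8)}
        b = {f"g{i}" for i in range(5, 15)}
        res = mt.gene_set_overlap(a, b, universe)
        assert res["p_value"] == pytest.approx(
            hypergeom_enumeration(20, 10, 8, len(a & b)), abs=1e-12)
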