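"""Dosage statistics: X:A ratio, male-median FC, loess, DEGs, trends."""

import numpy as np
import pandas as pd
import pytest

from xdosage import dosage
from xdosage.annotation import GeneRecord, RegionClass
from xdosage.io import ExpressionMatrix
from xdosage.simulate import (XXXXY, XXXY, XXY, XY, SimConfig,
                              simulate_annotation, simulate_bulk_cohort)


def _fpkm(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            unit="FPKM")


def _gene(gene_id, chrom, start=1_000_000):
    g = GeneRecord(gene_id, chrom, start, start + 1000)
    g.region_class = (RegionClass.AUTOSOME if chrom not in ("X", "Y")
                      else RegionClass.X_NONPAR)
    return g


class TestFilterExpressed:
    def test_cut_is_below_half_fpkm(self):
        m = _fpkm([[0.4, 0.4], [0.5, 0.5], [2.0, 2.0]],
                  ["low", "boundary", "high"], ["s1", "s2"])
        kept = dosage.filter_expressed(m)
        assert kept.genes == ["boundary", "high"]

    def test_all_expressed_unchanged(self):
        m = _fpkm([[1.0], [2.0]], ["a", "b"], ["s1"])
        assert dosage.filter_expressed(m).genes == ["a", "b"]

    def test_wrong_unit_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["s"]),
                             unit="counts")
        with pytest.raises(ValueError, match="FPKM"):
            dosage.filter_expressed(m)


def brute_force_xa(matrix, annotation, sample):
    """Direct restatement: MF per chromosome, then X over autosome average."""
    chrom_of = {g.gene_id: g.chrom for g in annotation}
    per_chrom = {}
    for gene in matrix.genes:
        per_chrom.setdefault(chrom_of[gene], []).append(matrix.data.loc[gene, sample])
    mf = {c: sum(v) / len(v) for c, v in per_chrom.items()}
    autosomes = [mf[c] for c in mf if c not in ("X", "Y")]
    return mf["X"] / (sum(autosomes) / len(autosomes))


class TestXaRatio:
    def test_uniform_matrix_gives_unity(self):
        genes = [_gene("x1", "X"), _gene("a1", "1"), _gene("a2", "2")]
        m = _fpkm(np.ones((3, 1)), ["x1", "a1", "a2"], ["s"])
        assert dosage.x_a_ratio(m, genes, "s").ratio == pytest.approx(1.0)

    def test_doubled_x_gives_two(self):
        genes = [_gene("x1", "X"), _gene("a1", "1"), _gene("a2", "2")]
        m = _fpkm([[2.0], [1.0], [1.0]], ["x1", "a1", "a2"], ["s"])
        assert dosage.x_a_ratio(m, genes, "s").ratio == pytest.approx(2.0)

    def test_matches_brute_force_and_scale_invariance(self, rng):
        chroms = [str(i) for i in range(1, 23)] + ["X"]
        genes = [_gene(f"g{i}", chroms[i % 23]) for i in range(200)]
        values = rng.lognormal(1, 1, (200, 3))
        m = _fpkm(values, [g.gene_id for g in genes], ["s1", "s2", "s3"])
        scaled_exact = _fpkm(values * 32.0, m.genes, m.samples)   # power of two
        scaled_any = _fpkm(values * 37.5, m.genes, m.samples)
        for s in m.samples:
            r = dosage.x_a_ratio(m, genes, s)
            assert r.ratio == pytest.approx(brute_force_xa(m, genes, s), abs=1e-12)
            assert dosage.x_a_ratio(scaled_exact, genes, s).ratio == r.ratio
            assert dosage.x_a_ratio(scaled_any, genes, s).ratio == \
                pytest.approx(r.ratio, rel=1e-12)

    def test_no_x_genes_rejected(self):
        genes = [_gene("a1", "1")]
        m = _fpkm([[1.0]], ["a1"], ["s"])
        with pytest.raises(ValueError):
            dosage.x_a_ratio(m, genes, "s")


class TestMaleMedianFc:
    @staticmethod
    def _setup(rng, n_genes=30):
        genes = [_gene(f"x{i}", "X", start=1_000_000 * (i + 1)) for i in range(n_genes)]
        values = rng.lognormal(1, 0.5, (n_genes, 5))
        m = _fpkm(values, [g.gene_id for g in genes],
                  ["ref1", "ref2", "ref3", "case1", "case2"])
        return genes, m

    def test_fc_against_median_profile(self, rng):
        genes, m = self._setup(rng)
        track = dosage.male_median_fc(m, genes, ["ref1", "ref2", "ref3"])
        mm = m.data[["ref1", "ref2", "ref3"]].median(axis=1)
        np.testing.assert_allclose(track.fc["case1"],
                                   m.data["case1"] / mm, rtol=1e-12)
        # odd reference count: each gene's median FC across refs is exactly 1
        ref_fc = track.fc[["ref1", "ref2", "ref3"]]
        np.testing.assert_allclose(ref_fc.median(axis=1), 1.0, rtol=1e-12)

    def test_simple_fold_change(self):
        genes = [_gene(f"x{i}", "X", start=1_000_000 * (i + 1)) for i in range(2)]
        m = _fpkm([[2.0, 2.0, 4.0], [1.0, 1.0, 1.0]],
                  ["x0", "x1"], ["r1", "r2", "c"])
        track = dosage.male_median_fc(m, genes, ["r1", "r2"])
        assert track.fc.loc["x0", "c"] == pytest.approx(2.0)

    def test_zero_median_genes_dropped(self):
        genes = [_gene(f"x{i}", "X", start=1_000_000 * (i + 1)) for i in range(2)]
        m = _fpkm([[0.0, 0.0, 1.0], [1.0, 1.0, 1.0]],
                  ["x0", "x1"], ["r1", "r2", "c"])
        track = dosage.male_median_fc(m, genes, ["r1", "r2"])
        assert track.gene_ids == ["x1"]

    def test_requires_two_references(self, rng):
        genes, m = self._setup(rng)
        with pytest.raises(ValueError):
            dosage.male_median_fc(m, genes, ["ref1"])


def brute_force_loess(x, y, span, degree, x0):
    """Per-point weighted polynomial fit, written independently via polyfit."""
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    if h == 0:
        return float(np.mean(y[d == 0]))
    w = np.where(d < h, (1 - (d / h) ** 3) ** 3, 0.0)
    mask = w > 0
    coeffs = np.polyfit(x[mask] - x0, y[mask], degree, w=np.sqrt(w[mask]))
    return float(np.polyval(coeffs, 0.0))


class TestLoess:
    def test_constant_track_smooths_to_zero_log2(self, rng):
        genes = [_gene(f"x{i}", "X", start=500_000 * (i + 1)) for i in range(20)]
        m = _fpkm(np.full((20, 3), 2.0), [g.gene_id for g in genes],
                  ["r1", "r2", "c"])
        track = dosage.male_median_fc(m, genes, ["r1", "r2"])
        curve = dosage.moving_average_x(track, "c")
        np.testing.assert_allclose(curve.smoothed, 0.0, atol=1e-9)

    def test_full_span_degree_one_recovers_line(self):
        x = np.linspace(0, 10, 30)
        y = 2.5 * x - 1.0
        fitted = dosage.loess_fit(x, y, span=1.0, degree=1)
        np.testing.assert_allclose(fitted, y, atol=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        x = np.sort(rng.uniform(0, 1.5e8, 200))
        y = rng.normal(0, 1, 200)
        fitted = dosage.loess_fit(x, y, span=0.45, degree=2)
        expected = [brute_force_loess(x, y, 0.45, 2, xi) for xi in x]
        np.testing.assert_allclose(fitted, expected, atol=1e-6)

    def test_too_few_points_rejected(self):
        genes = [_gene(f"x{i}", "X", start=500_000 * (i + 1)) for i in range(5)]
        m = _fpkm(np.ones((5, 3)), [g.gene_id for g in genes], ["r1", "r2", "c"])
        track = dosage.male_median_fc(m, genes, ["r1", "r2"])
        with pytest.raises(ValueError, match="10"):
            dosage.moving_average_x(track, "c")


class TestDegCalls:
    @pytest.mark.parametrize("lfc,fdr,expected", [
        (0.3, 0.01, "up"),
        (0.25, 0.01, "ns"),     # strict inequality at the log2 FC cut
        (-0.3, 0.01, "down"),
        (0.3, 0.05, "ns"),      # strict inequality at the FDR cut
    ])
    def test_thresholds(self, lfc, fdr, expected):
        table = pd.DataFrame({"log2_fc": [lfc], "fdr": [fdr]}, index=["g"])
        (call,) = dosage.call_degs(table)
        assert call.direction == expected

    def test_threshold_monotone_in_fdr(self, rng):
        table = pd.DataFrame({"log2_fc": rng.normal(0, 1, 200),
                              "fdr": rng.uniform(0, 1, 200)})
        called = None
        for cut in (0.2, 0.1, 0.05, 0.01):
            now = {c.gene_id for c in dosage.call_degs(table, fdr_cut=cut)
                   if c.direction != "ns"}
            if called is not None:
                assert now <= called
            called = now

    def test_intersection_requires_concordant_direction(self):
        a = [dosage.DegCall("a", 1, 0.01, "up"), dosage.DegCall("b", 1, 0.01, "up"),
             dosage.DegCall("c", 1, 0.01, "up")]
        b = [dosage.DegCall("b", 1, 0.01, "up"), dosage.DegCall("c", -1, 0.01, "down"),
             dosage.DegCall("d", 1, 0.01, "up")]
        assert dosage.intersect_degs(a, b) == ["b"]

    def test_invalid_fdr_rejected(self):
        table = pd.DataFrame({"log2_fc": [1.0], "fdr": [1.5]}, index=["g"])
        with pytest.raises(ValueError):
            dosage.call_degs(table)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(seed=8, noise_cv=0.1,
                    karyotype_panel=((XY, 4), (XXY, 4), (XXXY, 4), (XXXXY, 4)))
    annotation = simulate_annotation(cfg)
    matrix, metas, truth = simulate_bulk_cohort(cfg, annotation)
    return cfg, annotation, matrix, metas, truth


class TestDosageTrend:
    def test_constant_gene_is_flat(self):
        genes = [_gene("g", "1")]
        m = _fpkm(np.full((1, 8), 3.0), ["g"],
                  [f"s{i}" for i in range(8)])
        from xdosage.karyotype import KaryotypeSpec, SampleMeta
        metas = [SampleMeta(f"s{i}", KaryotypeSpec(1 + i % 4, 1)) for i in range(8)]
        (trend,) = dosage.classify_dosage_trend(m, metas, genes)
        assert trend.trend == "flat" and trend.slope == pytest.approx(0.0)

    def test_law_recovery(self, cohort):
        _, annotation, matrix, metas, truth = cohort
        trends = {t.gene_id: t for t in
                  dosage.classify_dosage_trend(matrix, metas, annotation)}
        law = truth["law"]
        par1 = [g for g in law[law == "par1"].index]
        frac_par1 = np.mean([trends[g].trend == "proportional" for g in par1])
        down = [g for g in law[law == "autosome_down"].index]
        frac_down = np.mean([trends[g].trend == "inverse" for g in down])
        flat = [g for g in law[law == "autosome_flat"].index]
        frac_flat_bad = np.mean([trends[g].trend != "flat" for g in flat])
        assert frac_par1 >= 0.95
        assert frac_down >= 0.95
        assert frac_flat_bad <= 0.05

    def test_slope_bias_under_five_percent(self, cohort):
        """Fitted slopes track the slopes of the noiseless expectation."""
        _, annotation, matrix, metas, truth = cohort
        trends = {t.gene_id: t for t in
                  dosage.classify_dosage_trend(matrix, metas, annotation)}
        noiseless = ExpressionMatrix(truth["expected"], unit="FPKM")
        true_trends = {t.gene_id: t for t in
                       dosage.classify_dosage_trend(noiseless, metas, annotation)}
        law = truth["law"]
        genes = list(law[law.isin(["autosome_up", "autosome_down"])].index)
        fitted = np.array([trends[g].slope for g in genes])
        expected = np.array([true_trends[g].slope for g in genes])
        bias = np.mean(fitted - expected) / np.mean(np.abs(expected))
        assert abs(bias) < 0.05

    def test_single_karyotype_rejected(self):
        genes = [_gene("g", "1")]
        m = _fpkm(np.ones((1, 4)), ["g"], [f"s{i}" for i in range(4)])
        from xdosage.karyotype import KaryotypeSpec, SampleMeta
        metas = [SampleMeta(f"s{i}", KaryotypeSpec(2, 1)) for i in range(4)]
        with pytest.raises(ValueError):
            dosage.classify_dosage_trend(m, metas, genes)


class TestCategorizeXDegs:
    def test_precedence_and_novel(self):
        par1 = GeneRecord("p1", "X", 0, 1000, xci_status="escape")
        par1.region_class = RegionClass.PAR1
        esc = GeneRecord("e1", "X", 50_000_000, 50_001_000, xci_status="escape")
        esc.region_class = RegionClass.X_NONPAR
        unk = GeneRecord("u1", "X", 60_000_000, 60_001_000, xci_status="unknown")
        unk.region_class = RegionClass.X_NONPAR
        aut = GeneRecord("a1", "3", 1000, 2000)
        aut.region_class = RegionClass.AUTOSOME
        degs = [dosage.DegCall(g, 1.0, 0.01, "up") for g in ("p1", "e1", "u1", "a1")]
        cats = dosage.categorize_x_degs(degs, [par1, esc, unk, aut])
        assert cats["PAR1"] == ["p1"]          # PAR1 overrides escape status
        assert cats["escape"] == ["e1"]
        assert cats["novel"] == ["u1"]
        assert all("a1" not in v for v in cats.values())
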