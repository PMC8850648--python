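"""Synthetic cohorts with the dosage structure the analysis assumes.

The generator encodes the dosage laws observed in sex-chromosome aneuploid
(47,XXY .. 49,XXXXY) pluripotent cells:

* PAR1 genes are expressed from every sex chromosome: expected expression
  scales with (n_x + n_y) / 2 relative to a euploid male.
* PAR2 genes are expressed but do not mirror dosage (flat).
* Non-PAR escape genes scale with the X count n_x.
* Inactive X genes are expressed from the single active X only (flat).
* XIST scales with the number of inactive Xs, (n_x - 1): zero in 46,XY.
* Autosomal genes are flat, except a configurable subset given a log-linear
  response to n_x (for trend-recovery testing).
* An "eroded" sample reactivates enough inactive non-PAR X genes to carry
  a 2-3x multiple of the baseline biallelic non-PAR X gene count.

Per-SNP allele counts are negative-binomial in depth with binomial allele
sampling: biallelic sites draw their reference-allele fraction from a
Beta(20, 20) centred on 0.5; monoallelic sites express the silenced allele
only through a small leak probability (sequencing error + leaky silencing).

Everything is driven by one seed; sub-streams are spawned per generator so
outputs are reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .annotation import GeneRecord, ParBoundaries, RegionClass, assign_region_class
from .io import AlleleCountRecord, ExpressionMatrix
from .karyotype import KaryotypeSpec, SampleMeta

__all__ = [
    "SimConfig",
    "DEFAULT_KARYOTYPE_PANEL",
    "simulate_annotation",
    "simulate_bulk_cohort",
    "simulate_allele_counts",
    "simulate_single_cell",
    "simulate_module_structure",
    "simulate_promoter_fasta",
    "write_whitelist_vcf",
]

XY = KaryotypeSpec(1, 1)
XX = KaryotypeSpec(2, 0)
XXY = KaryotypeSpec(2, 1)
XXXY = KaryotypeSpec(3, 1)
XXXXY = KaryotypeSpec(4, 1)

# cohort shape: male/female controls plus the three aneuploid karyotypes,
# 2-4 replicates per karyotype as in small iPSC cohorts
DEFAULT_KARYOTYPE_PANEL: tuple[tuple[KaryotypeSpec, int], ...] = (
    (XY, 4), (XX, 2), (XXY, 4), (XXXY, 4), (XXXXY, 4),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``noise_cv`` is the coefficient of variation of multiplicative
    log-normal replicate noise; ``depth_mean``/``depth_dispersion``
    parameterize negative-binomial SNP depths; ``monoallelic_leak`` is the
    probability that a read reports the silenced allele.
    """

    seed: int = 0
    n_genes_autosome: int = 400
    n_genes_x_nonpar: int = 200
    n_genes_par1: int = 15
    n_genes_par2: int = 3
    fraction_escape_nonpar: float = 0.10
    fraction_autosome_up: float = 0.10
    fraction_autosome_down: float = 0.10
    autosome_trend_log2_slope: float = 0.5
    karyotype_panel: tuple = DEFAULT_KARYOTYPE_PANEL
    base_mean_log: float = 3.0
    base_sd_log: float = 0.8
    x_base_scale: float = 0.6          # X genes expressed lower than autosomes
    noise_cv: float = 0.2
    snp_per_gene_mean: float = 3.0
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0      # NB shape; larger = closer to Poisson
    monoallelic_leak: float = 0.01
    biallelic_beta: tuple[float, float] = (20.0, 20.0)
    eroded_samples: dict = field(default_factory=dict)  # sample_id -> multiplier
    boundaries: ParBoundaries = field(default_factory=ParBoundaries)

    def __post_init__(self) -> None:
        for name in ("n_genes_autosome", "n_genes_x_nonpar", "n_genes_par1",
                     "n_genes_par2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_escape_nonpar", "fraction_autosome_up",
                     "fraction_autosome_down", "monoallelic_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for kt, _ in self.karyotype_panel:
            if kt.n_x < 1:
                raise ValueError("karyotypes with n_x = 0 are not supported")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic sub-stream derived from the global seed."""
        digest = sum(ord(c) * 131 ** i for i, c in enumerate(stream)) % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, digest)))


# expression law per gene class, as a multiplier of the gene's base level
def _law_factor(law: str, kt: KaryotypeSpec, slope: float = 0.5) -> float:
    if law == "par1":
        return kt.n_sex_chromosomes / 2.0
    if law == "escape":
        return float(kt.n_x)
    if law == "xist":
        return float(kt.n_x - 1)
    if law == "autosome_up":
        return float(2.0 ** (slope * (kt.n_x - 1)))
    if law == "autosome_down":
        return float(2.0 ** (-slope * (kt.n_x - 1)))
    # par2, inactive, autosome_flat
    return 1.0


def simulate_annotation(config: SimConfig) -> list[GeneRecord]:
    """Gene annotation covering all region classes, incl. an XIST gene.

    Non-PAR X genes carry literature-style xci_status labels: the escape
    fraction "escape", a small slice "unknown" (novel), the rest
    "inactive".
    """
    rng = config.rng("annotation")
    b = config.boundaries
    genes: list[GeneRecord] = []

    def add(gene_id: str, chrom: str, start: int, length: int, xci: str | None) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        rec = GeneRecord(gene_id=gene_id, chrom=chrom, start=int(start),
                         end=int(start + length), strand=strand, xci_status=xci)
        rec.region_class = assign_region_class(rec, b)
        genes.append(rec)

    # PAR1: spread within the first par1_span bp
    starts = np.sort(rng.choice(b.par1_span_bp - 20_000, config.n_genes_par1, replace=False))
    for i, s in enumerate(starts):
        add(f"PAR1_{i:03d}", "X", s, 10_000, "escape")
    # PAR2
    starts = np.sort(rng.choice(b.par2_span_bp - 20_000, config.n_genes_par2, replace=False))
    for i, s in enumerate(starts):
        add(f"PAR2_{i:03d}", "X", b.par2_start + s, 10_000, "escape")
    # non-PAR X body, XIST at ~73 Mb
    body_lo, body_hi = b.par1_span_bp + 100_000, b.par2_start - 200_000
    n_escape = int(round(config.fraction_escape_nonpar * config.n_genes_x_nonpar))
    n_unknown = max(1, config.n_genes_x_nonpar // 50)
    starts = np.sort(rng.choice(np.arange(body_lo, body_hi, 50_000),
                                config.n_genes_x_nonpar, replace=False))
    order = rng.permutation(config.n_genes_x_nonpar)
    status = np.array(["inactive"] * config.n_genes_x_nonpar, dtype=object)
    status[order[:n_escape]] = "escape"
    status[order[n_escape:n_escape + n_unknown]] = "unknown"
    for i, (s, st) in enumerate(zip(starts, status)):
        add(f"XNP_{i:03d}", "X", s, 30_000, str(st))
    add("XIST", "X", 73_000_000 + 7, 32_000, "escape")
    # autosomes spread over chr1..22
    for i in range(config.n_genes_autosome):
        chrom = str(1 + i % 22)
        add(f"AUT_{i:03d}", chrom, 1_000_000 + (i // 22) * 120_000, 40_000, None)
    return genes


def _assign_laws(config: SimConfig, annotation: list[GeneRecord]) -> pd.Series:
    """Map each gene to its dosage law."""
    rng = config.rng("laws")
    laws: dict[str, str] = {}
    autosome_ids = [g.gene_id for g in annotation
                    if g.region_class is RegionClass.AUTOSOME]
    n_up = int(round(config.fraction_autosome_up * len(autosome_ids)))
    n_down = int(round(config.fraction_autosome_down * len(autosome_ids)))
    shuffled = list(rng.permutation(autosome_ids))
    up = set(shuffled[:n_up])
    down = set(shuffled[n_up:n_up + n_down])
    for g in annotation:
        if g.gene_id == "XIST":
            laws[g.gene_id] = "xist"
        elif g.region_class is RegionClass.PAR1:
            laws[g.gene_id] = "par1"
        elif g.region_class is RegionClass.PAR2:
            laws[g.gene_id] = "par2"
        elif g.region_class is RegionClass.X_NONPAR:
            laws[g.gene_id] = "escape" if g.xci_status == "escape" else "inactive"
        elif g.gene_id in up:
            laws[g.gene_id] = "autosome_up"
        elif g.gene_id in down:
            laws[g.gene_id] = "autosome_down"
        else:
            laws[g.gene_id] = "autosome_flat"
    return pd.Series(laws, name="law")


def _sample_metas(config: SimConfig) -> list[SampleMeta]:
    metas = []
    for kt, n_reps in config.karyotype_panel:
        for r in range(n_reps):
            if kt.n_x == 1 and kt.n_y == 1:
                role = "control_male"
            elif kt.n_x == 2 and kt.n_y == 0:
                role = "control_female"
            else:
                role = "case"
            metas.append(SampleMeta(sample_id=f"{kt.label.replace(',', '_')}_r{r + 1}",
                                    karyotype=kt, cohort_role=role))
    return metas


def simulate_bulk_cohort(
    config: SimConfig,
    annotation: list[GeneRecord] | None = None,
) -> tuple[ExpressionMatrix, list[SampleMeta], dict]:
    """Bulk FPKM cohort under the dosage laws.

    Returns the FPKM matrix, the sample metadata, and a truth table with
    the per-gene law, base level, and the noiseless expected matrix.
    """
    if annotation is None:
        annotation = simulate_annotation(config)
    laws = _assign_laws(config, annotation)
    metas = _sample_metas(config)
    rng = config.rng("bulk")

    gene_ids = [g.gene_id for g in annotation]
    base = rng.lognormal(config.base_mean_log, config.base_sd_log, len(gene_ids))
    is_x = np.array([g.chrom == "X" for g in annotation])
    base = np.where(is_x, base * config.x_base_scale, base)

    expected = np.empty((len(gene_ids), len(metas)))
    for j, m in enumerate(metas):
        factors = np.array([
            _law_factor(laws[g], m.karyotype, config.autosome_trend_log2_slope)
            for g in gene_ids])
        expected[:, j] = base * factors
    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
    # mean-preserving multiplicative log-normal noise
    noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, expected.shape) if sigma > 0 else 1.0
    values = expected * noise

    sample_ids = [m.sample_id for m in metas]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids),
                              unit="FPKM")
    truth = {
        "law": laws,
        "base": pd.Series(base, index=gene_ids, name="base"),
        "expected": pd.DataFrame(expected, index=gene_ids, columns=sample_ids),
    }
    return matrix, metas, truth


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def _true_allelic_status(law: str, region: RegionClass, kt: KaryotypeSpec) -> str | None:
    """True biallelic/monoallelic status of a gene in one karyotype.

    Returns None when no heterozygous SNP is possible (hemizygous X in a
    single-X sample, XIST without an inactive X).
    """
    if region in (RegionClass.PAR1, RegionClass.PAR2):
        # PARs are diploid in every karyotype (shared with Y)
        return "biallelic" if kt.n_sex_chromosomes >= 2 else None
    if region is RegionClass.X_NONPAR:
        if kt.n_x < 2:
            return None
        if law == "xist":
            return "monoallelic"
        return "biallelic" if law == "escape" else "monoallelic"
    if region is RegionClass.AUTOSOME:
        return "biallelic"
    return None


def simulate_allele_counts(
    config: SimConfig,
    annotation: list[GeneRecord],
    sample_meta: list[SampleMeta],
) -> tuple[list[AlleleCountRecord], pd.DataFrame]:
    """Per-SNP allele counts with a per-gene/sample truth table.

    Eroded samples (``config.eroded_samples``) flip inactive non-PAR X
    genes to biallelic so their biallelic non-PAR X count reaches
    ``multiplier`` times the escape-gene baseline.
    """
    rng = config.rng("allele_counts")
    laws = _assign_laws(config, annotation)
    a_beta, b_beta = config.biallelic_beta
    nb_shape = config.depth_dispersion
    records: list[AlleleCountRecord] = []
    truth_rows: list[dict] = []

    inactive_nonpar = [g.gene_id for g in annotation
                      if g.region_class is RegionClass.X_NONPAR
                      and laws[g.gene_id] == "inactive"]
    n_escape = sum(1 for g in annotation
                   if g.region_class is RegionClass.X_NONPAR
                   and laws[g.gene_id] == "escape")

    bases = "ACGT"
    for m in sample_meta:
        eroded_mult = config.eroded_samples.get(m.sample_id)
        reactivated: set[str] = set()
        if eroded_mult:
            n_extra = int(round((eroded_mult - 1.0) * n_escape))
            n_extra = min(n_extra, len(inactive_nonpar))
            reactivated = set(rng.choice(inactive_nonpar, n_extra, replace=False))
        for g in annotation:
            status = _true_allelic_status(laws[g.gene_id], g.region_class, m.karyotype)
            if status is None:
                continue
            if g.gene_id in reactivated:
                status = "biallelic"
            n_snps = int(rng.poisson(config.snp_per_gene_mean))
            truth_rows.append({"sample_id": m.sample_id, "gene_id": g.gene_id,
                               "region_class": g.region_class.value,
                               "true_status": status, "n_snps": n_snps,
                               "eroded_reactivation": g.gene_id in reactivated})
            if n_snps == 0:
                continue
            positions = g.start + 1 + rng.choice(g.length, n_snps, replace=False)
            for pos in np.sort(positions):
                total = 1 + rng.poisson(rng.gamma(nb_shape,
                                                  max(config.depth_mean - 1, 0.1) / nb_shape))
                if status == "biallelic":
                    p_ref = rng.beta(a_beta, b_beta)
                else:
                    leak = config.monoallelic_leak
                    p_ref = leak if rng.random() < 0.5 else 1.0 - leak
                ref_count = int(rng.binomial(total, p_ref))
                ref_b = bases[int(rng.integers(4))]
                alt_b = bases[(bases.index(ref_b) + 1 + int(rng.integers(3))) % 4]
                records.append(AlleleCountRecord(
                    sample_id=m.sample_id, chrom=g.chrom, pos=int(pos),
                    ref=ref_b, alt=alt_b,
                    ref_count=ref_count, alt_count=int(total) - ref_count,
                    total_count=int(total),
                    gene_id=g.gene_id, is_xist=(g.gene_id == "XIST")))
    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_whitelist_vcf(records: list[AlleleCountRecord], path: str | Path) -> None:
    """Write the exome-confirmed variant whitelist as a minimal VCF.

    One PASS record per distinct site with INFO/DP set to the site's
    maximum observed depth across samples.
    """
    depth: dict[tuple[str, int, str, str], int] = {}
    for r in records:
        key = (r.chrom, r.pos, r.ref, r.alt)
        depth[key] = max(depth.get(key, 0), r.total_count)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for i in list(range(1, 23)) + ["X", "Y"]:
            fh.write(f"##contig=<ID={i}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (chrom, pos, ref, alt), dp in sorted(
                depth.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tDP={dp}\n")


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------

def simulate_single_cell(
    config: SimConfig,
    annotation: list[GeneRecord] | None = None,
    sample_meta: list[SampleMeta] | None = None,
    n_cells_per_sample: int = 200,
    sc_base_scale: float = 0.25,
    sc_dispersion: float = 2.0,
    n_phase_dependent: int = 2,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Per-cell negative-binomial counts under the karyotype dosage laws.

    Within a karyotype every gene's mean is a function of the karyotype
    alone, so escape/PAR expression is conditionally independent of the
    cell's realized XIST value — the null the XIST-independence tests
    assume. Cell-cycle phases {G1, S, G2M} are assigned independently of
    XIST; the first ``n_phase_dependent`` autosomal flat genes are made
    phase-dependent for power checks.
    """
    if n_cells_per_sample < 50:
        raise ValueError("n_cells_per_sample must be >= 50 for test stability")
    if annotation is None:
        annotation = simulate_annotation(config)
    if sample_meta is None:
        sample_meta = _sample_metas(config)
    rng = config.rng("single_cell")
    laws = _assign_laws(config, annotation)
    gene_ids = [g.gene_id for g in annotation]
    base = rng.lognormal(config.base_mean_log, config.base_sd_log, len(gene_ids))
    base = base * sc_base_scale
    phase_dependent = [gid for gid in gene_ids if laws[gid] == "autosome_flat"][:n_phase_dependent]
    phase_factor = {"G1": 1.0, "S": 1.6, "G2M": 2.2}

    X_blocks, obs_rows = [], []
    for m in sample_meta:
        factors = np.array([_law_factor(laws[g], m.karyotype,
                                        config.autosome_trend_log2_slope)
                            for g in gene_ids])
        mu = base * factors
        phases = rng.choice(["G1", "S", "G2M"], size=n_cells_per_sample,
                            p=[0.5, 0.3, 0.2])
        mu_cells = np.tile(mu, (n_cells_per_sample, 1))
        for gid in phase_dependent:
            j = gene_ids.index(gid)
            mu_cells[:, j] = mu[j] * np.array([phase_factor[p] for p in phases])
        lam = np.where(mu_cells > 0,
                       rng.gamma(sc_dispersion, 1.0, mu_cells.shape)
                       * mu_cells / sc_dispersion, 0.0)
        counts = rng.poisson(lam)
        X_blocks.append(counts)
        for c in range(n_cells_per_sample):
            obs_rows.append({"cell_id": f"{m.sample_id}_c{c + 1:04d}",
                             "sample_id": m.sample_id,
                             "karyotype": m.karyotype.label,
                             "n_x": m.karyotype.n_x,
                             "n_y": m.karyotype.n_y,
                             "phase": phases[c]})
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(X=np.vstack(X_blocks).astype(float), obs=obs,
                       var=pd.DataFrame(index=gene_ids))
    adata.var["law"] = [laws[g] for g in gene_ids]
    adata.var["phase_dependent"] = [g in set(phase_dependent) for g in gene_ids]
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "law": [laws[g] for g in gene_ids],
        "xist_independent": [laws[g] != "xist" for g in gene_ids],
        "phase_dependent": [g in set(phase_dependent) for g in gene_ids],
    })
    return adata, truth


# ---------------------------------------------------------------------------
# Module-structure generator
# ---------------------------------------------------------------------------

def simulate_module_structure(
    n_modules: int = 5,
    genes_per_module: int = 100,
    n_samples: int = 20,
    trend_assignment: list[str] | None = None,
    seed: int = 0,
    trend_log2_slope: float = 0.5,
    latent_sd: float = 1.0,
    gene_noise_sd: float = 0.4,
) -> tuple[ExpressionMatrix, pd.DataFrame, list[SampleMeta]]:
    """Block-correlated expression with module-level dosage trends.

    Samples cycle through X counts 1..4; each module's latent per-sample
    signal is an independent factor (sd ``latent_sd``) plus a dosage
    trend component (up: +slope*n_x, down: -slope*n_x, flat: none).
    The independent factor keeps distinct modules separable even when
    they share a trend, while within-module correlations stay >= ~0.7 by
    construction. Values sit on a log2-like scale shifted positive;
    truth labels give gene -> module and module -> trend.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 901)))
    if trend_assignment is None:
        trend_assignment = (["up", "down", "flat"] * n_modules)[:n_modules]
    if len(trend_assignment) != n_modules:
        raise ValueError("trend_assignment must name each module")
    panel = [KaryotypeSpec(1, 1), KaryotypeSpec(2, 1),
             KaryotypeSpec(3, 1), KaryotypeSpec(4, 1)]
    metas = []
    for s in range(n_samples):
        kt = panel[s % len(panel)]
        metas.append(SampleMeta(
            sample_id=f"S{s + 1:02d}_{kt.label.replace(',', '_')}",
            karyotype=kt,
            cohort_role="control_male" if kt.n_x == 1 else "case"))
    n_x = np.array([m.karyotype.n_x for m in metas], dtype=float)

    rows, gene_ids, truth_rows = [], [], []
    for mi, trend in enumerate(trend_assignment):
        latent = rng.normal(0, latent_sd, n_samples)
        if trend == "up":
            signal = trend_log2_slope * n_x + latent
        elif trend == "down":
            signal = -trend_log2_slope * n_x + latent
        elif trend == "flat":
            signal = latent
        else:
            raise ValueError(f"unknown trend {trend!r}")
        for gi in range(genes_per_module):
            loading = rng.uniform(0.9, 1.1)
            rows.append(loading * signal + rng.normal(0, gene_noise_sd, n_samples))
            gene_ids.append(f"M{mi + 1}_G{gi + 1:03d}")
            truth_rows.append({"gene_id": gene_ids[-1], "module": mi + 1,
                               "trend": trend})
    values = np.array(rows)
    values = values - values.min() + 4.0          # shift to a positive log2 scale
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=[m.sample_id for m in metas]),
        unit="log2")
    return matrix, pd.DataFrame(truth_rows).set_index("gene_id"), metas


# ---------------------------------------------------------------------------
# Promoter sequences with a planted motif
# ---------------------------------------------------------------------------

def simulate_promoter_fasta(
    gene_ids: list[str],
    planted_genes: set[str],
    consensus: str = "TGCGCATGCGCA",
    length: int = 2000,
    seed: int = 0,
    path: str | Path | None = None,
) -> dict[str, str]:
    """Random promoter sequences; ``planted_genes`` get the consensus embedded.

    Synthetic stand-in for promoter windows extracted from a reference
    genome; used to exercise the motif-enrichment path end to end.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7717)))
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for gid in gene_ids:
        seq = list(rng.choice(bases, size=length))
        if gid in planted_genes:
            pos = int(rng.integers(0, length - len(consensus)))
            seq[pos:pos + len(consensus)] = list(consensus)
        seqs[gid] = "".join(seq)
    if path is not None:
        with open(path, "w") as fh:
            for gid, seq in seqs.items():
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    return seqs
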