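"""Allele-specific expression: SNP/gene biallelic calling and erosion flagging.

The classification rules: a SNP is *biallelic* when its reference-allele
fraction (refCount / totalCount) lies within [0.1, 0.9] and *monoallelic*
when it falls below 0.1 or above 0.9. A gene is biallelic if one or more
of its SNPs is biallelic. Upstream site filters require a whitelist of
exome-confirmed variants (PASS, total reads > 10), read depth strictly
greater than six, exonic position, and unique gene mapping — XIST being
exempt from the last two (it is the one gene whose intronic/overlapping
SNPs are deliberately retained to assay Xi clonality).

"X erosion" — progressive loss of X inactivation in cultured pluripotent
cells — surfaces as a sample with a multiple (2-3x) of the cohort-typical
number of biallelically expressed non-PAR X genes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .annotation import GeneRecord, RegionClass
from .io import AlleleCountRecord

__all__ = [
    "SnpStatus",
    "SnpCall",
    "GeneAseCall",
    "AseSummary",
    "filter_variant_whitelist",
    "filter_sites",
    "classify_snp",
    "call_gene",
    "call_genes",
    "summarize_ase",
    "flag_erosion",
    "xist_allelic_check",
    "annotate_records",
]

log = logging.getLogger(__name__)

BIALLELIC_LOW = 0.1
BIALLELIC_HIGH = 0.9


class SnpStatus(str, Enum):
    BIALLELIC = "biallelic"
    MONOALLELIC = "monoallelic"
    FILTERED = "filtered"


@dataclass
class SnpCall:
    record: AlleleCountRecord
    ref_fraction: float
    status: SnpStatus


@dataclass
class GeneAseCall:
    gene_id: str
    sample_id: str
    n_informative: int
    n_biallelic: int
    status: str  # {biallelic, monoallelic, uninformative}
    region_class: RegionClass | None = None


@dataclass
class AseSummary:
    """Per-sample biallelic/monoallelic gene counts by region class."""

    sample_id: str
    counts: dict = field(default_factory=dict)   # (region_class, status) -> n genes
    eroded: bool = False
    xist_status: str = "uninformative"

    def count(self, region: RegionClass | str, status: str) -> int:
        key = region.value if isinstance(region, RegionClass) else str(region)
        return self.counts.get((key, status), 0)

    @property
    def biallelic_nonpar_x(self) -> int:
        return self.count(RegionClass.X_NONPAR, "biallelic")


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def filter_variant_whitelist(
    vcf_path: str,
    min_total_reads: int = 11,
    require_pass: bool = True,
) -> set[tuple[str, int]]:
    """Build the exome-variant whitelist from a filtered VCF.

    Keeps PASS records with total reads strictly greater than 10 (i.e.
    >= ``min_total_reads``). Depth is taken from INFO/DP, then the first
    sample's FORMAT/DP, then the sum of FORMAT/AD; records with no depth
    field are excluded with a warning. Positions are 1-based (chrom, pos).
    """
    from cyvcf2 import VCF
    from .annotation import normalize_chrom

    whitelist: set[tuple[str, int]] = set()
    for var in VCF(str(vcf_path)):
        if require_pass and var.FILTER is not None:   # cyvcf2: None == PASS
            continue
        depth = var.INFO.get("DP")
        if depth is None:
            try:
                fmt_dp = var.format("DP")
                depth = int(np.sum(fmt_dp[0])) if fmt_dp is not None else None
            except Exception:
                depth = None
        if depth is None:
            try:
                ad = var.format("AD")
                depth = int(np.sum(ad[0])) if ad is not None else None
            except Exception:
                depth = None
        if depth is None:
            log.warning("%s:%d: no depth field, record excluded", var.CHROM, var.POS)
            continue
        if int(depth) >= min_total_reads:
            whitelist.add((normalize_chrom(var.CHROM), var.POS))
    return whitelist


def filter_sites(
    records: list[AlleleCountRecord],
    whitelist: set[tuple[str, int]] | None = None,
    min_depth: int = 7,
    xist_exempt_intronic: bool = True,
) -> tuple[list[AlleleCountRecord], list[tuple[AlleleCountRecord, str]]]:
    """Partition records into kept vs filtered-with-primary-reason.

    Kept records satisfy, in order of precedence: position whitelisted
    (when a whitelist is given), total depth strictly greater than six
    (``>= min_depth``), exonic, and uniquely mapped to one gene. XIST is
    exempt from the unique-mapping filter and (by default) from the
    intronic filter as well.
    """
    from .annotation import normalize_chrom

    if whitelist is not None and len(whitelist) == 0:
        log.warning("empty variant whitelist: all records will be filtered")
    kept: list[AlleleCountRecord] = []
    filtered: list[tuple[AlleleCountRecord, str]] = []
    for rec in records:
        if whitelist is not None and (normalize_chrom(rec.chrom), rec.pos) not in whitelist:
            filtered.append((rec, "not_in_whitelist"))
        elif rec.total_count < min_depth:
            filtered.append((rec, "low_depth"))
        elif rec.intronic and not (rec.is_xist and xist_exempt_intronic):
            filtered.append((rec, "intronic"))
        elif rec.multi_gene and not rec.is_xist:
            filtered.append((rec, "multi_gene"))
        else:
            kept.append(rec)
    return kept, filtered


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_snp(
    record: AlleleCountRecord,
    low: float = BIALLELIC_LOW,
    high: float = BIALLELIC_HIGH,
) -> SnpCall:
    """Classify one SNP as biallelic/monoallelic by reference-allele fraction.

    Biallelic iff low <= refCount/totalCount <= high (bounds inclusive);
    monoallelic otherwise. Zero-depth records are returned as filtered.
    """
    if record.total_count == 0:
        return SnpCall(record, ref_fraction=float("nan"), status=SnpStatus.FILTERED)
    frac = record.ref_fraction
    status = SnpStatus.BIALLELIC if low <= frac <= high else SnpStatus.MONOALLELIC
    return SnpCall(record, ref_fraction=frac, status=status)


def call_gene(snp_calls: list[SnpCall], gene_id: str | None = None,
              sample_id: str | None = None) -> GeneAseCall:
    """Aggregate SNP calls of one gene/sample: biallelic iff >=1 biallelic SNP."""
    informative = [c for c in snp_calls if c.status is not SnpStatus.FILTERED]
    if gene_id is None:
        gene_id = informative[0].record.gene_id if informative else (gene_id or "NA")
    if sample_id is None:
        sample_id = informative[0].record.sample_id if informative else "NA"
    n_bi = sum(1 for c in informative if c.status is SnpStatus.BIALLELIC)
    if not informative:
        status = "uninformative"
    elif n_bi >= 1:
        status = "biallelic"
    else:
        status = "monoallelic"
    return GeneAseCall(gene_id=gene_id, sample_id=sample_id,
                       n_informative=len(informative), n_biallelic=n_bi, status=status)


def call_genes(records: list[AlleleCountRecord],
               annotation: list[GeneRecord] | None = None) -> list[GeneAseCall]:
    """SNP-classify and gene-aggregate a filtered record collection.

    Records must carry ``gene_id`` (see :func:`annotate_records`); records
    without one are ignored with a warning.
    """
    region_of = {g.gene_id: g.region_class for g in annotation} if annotation else {}
    by_key: dict[tuple[str, str], list[SnpCall]] = defaultdict(list)
    for rec in records:
        if rec.gene_id is None:
            log.warning("%s:%d has no gene assignment, ignored", rec.chrom, rec.pos)
            continue
        by_key[(rec.sample_id, rec.gene_id)].append(classify_snp(rec))
    calls = []
    for (sample_id, gene_id), snp_calls in sorted(by_key.items()):
        call = call_gene(snp_calls, gene_id=gene_id, sample_id=sample_id)
        call.region_class = region_of.get(gene_id)
        calls.append(call)
    return calls


def annotate_records(records: list[AlleleCountRecord],
                     annotation: list[GeneRecord]) -> list[AlleleCountRecord]:
    """Assign gene ids to records by position (1-based pos inside [start, end))."""
    by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in annotation:
        by_chrom[g.chrom].append(g)
    for rec in records:
        from .annotation import normalize_chrom
        hits = [g for g in by_chrom.get(normalize_chrom(rec.chrom), [])
                if g.start < rec.pos <= g.end]
        if len(hits) == 1:
            rec.gene_id = hits[0].gene_id
        elif len(hits) > 1:
            xist = [g for g in hits if g.gene_id.upper() == "XIST"]
            rec.multi_gene = True
            if xist:
                rec.gene_id, rec.is_xist = xist[0].gene_id, True
            else:
                rec.gene_id = hits[0].gene_id
        if rec.gene_id and rec.gene_id.upper() == "XIST":
            rec.is_xist = True
    return records


# ---------------------------------------------------------------------------
# Summaries, erosion, XIST
# ---------------------------------------------------------------------------

def summarize_ase(gene_calls: list[GeneAseCall],
                  annotation: list[GeneRecord] | None = None) -> dict[str, AseSummary]:
    """Per-sample counts of biallelic/monoallelic genes by region class."""
    region_of = {g.gene_id: g.region_class for g in annotation} if annotation else {}
    out: dict[str, AseSummary] = {}
    for call in gene_calls:
        if call.status == "uninformative":
            continue
        region = call.region_class or region_of.get(call.gene_id)
        if region is None:
            log.warning("gene %s absent from annotation; counted as 'unknown'", call.gene_id)
            region_key = "unknown"
        else:
            region_key = region.value
        summ = out.setdefault(call.sample_id, AseSummary(sample_id=call.sample_id))
        key = (region_key, call.status)
        summ.counts[key] = summ.counts.get(key, 0) + 1
    return out


def biallelic_frequency(gene_calls: list[GeneAseCall]) -> dict[str, float]:
    """Per-gene biallelic detection frequency across replicates, in percent.

    frequency = (replicates where biallelic) / (replicates informative) x 100.
    """
    informative: dict[str, int] = defaultdict(int)
    biallelic: dict[str, int] = defaultdict(int)
    for call in gene_calls:
        if call.status == "uninformative":
            continue
        informative[call.gene_id] += 1
        if call.status == "biallelic":
            biallelic[call.gene_id] += 1
    return {g: 100.0 * biallelic[g] / informative[g] for g in informative}


def flag_erosion(
    summaries: dict[str, AseSummary],
    multiplier_threshold: float = 2.0,
    min_biallelic: int = 30,
) -> dict[str, bool]:
    """Flag samples with an erosion-scale excess of biallelic non-PAR X genes.

    A sample is eroded iff its biallelic non-PAR X count is at least
    ``multiplier_threshold`` times the median of the *other* samples AND
    at least ``min_biallelic`` (the floor keeps ordinary escape-gene
    counts from tripping the multiplier when male controls pull the
    median down).
    """
    if len(summaries) < 3:
        raise ValueError("erosion flagging needs >= 3 samples for a reference distribution")
    counts = {sid: s.biallelic_nonpar_x for sid, s in summaries.items()}
    flags: dict[str, bool] = {}
    for sid, n in counts.items():
        others = [v for k, v in counts.items() if k != sid]
        med = float(np.median(others))
        flags[sid] = bool(n >= multiplier_threshold * med and n >= min_biallelic)
        summaries[sid].eroded = flags[sid]
    return flags


def xist_allelic_check(records: list[AlleleCountRecord]) -> str:
    """Allelic status of XIST itself: monoallelic XIST rules out mosaic XCI.

    Applies the same SNP/gene rules to records flagged ``is_xist``.
    Returns {monoallelic, biallelic, uninformative}; a biallelic result
    logs a mosaic-inactivation warning.
    """
    xist = [r for r in records if r.is_xist]
    call = call_gene([classify_snp(r) for r in xist], gene_id="XIST",
                     sample_id=xist[0].sample_id if xist else "NA")
    if call.status == "biallelic":
        log.warning("XIST is biallelic: possible mosaic X inactivation")
    return call.status


def par_vs_nonpar_test(gene_calls: list[GeneAseCall]) -> dict:
    """Mann-Whitney U on per-sample biallelic counts, PAR vs non-PAR X.

    Convenience report mirroring the display of biallelic counts by
    region; two-sided.
    """
    par: dict[str, int] = defaultdict(int)
    nonpar: dict[str, int] = defaultdict(int)
    samples = set()
    for c in gene_calls:
        if c.status != "biallelic" or c.region_class is None:
            continue
        samples.add(c.sample_id)
        if c.region_class in (RegionClass.PAR1, RegionClass.PAR2):
            par[c.sample_id] += 1
        elif c.region_class is RegionClass.X_NONPAR:
            nonpar[c.sample_id] += 1
    xs = [par[s] for s in sorted(samples)]
    ys = [nonpar[s] for s in sorted(samples)]
    if not samples or (all(v == xs[0] for v in xs) and all(v == ys[0] for v in ys) and xs[0] == ys[0]):
        return {"u_statistic": float("nan"), "p_value": float("nan"),
                "par_counts": xs, "nonpar_counts": ys}
    u, p = stats.mannwhitneyu(xs, ys, alternative="two-sided")
    return {"u_statistic": float(u), "p_value": float(p),
            "par_counts": xs, "nonpar_counts": ys}
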