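"""Promoter PWM scanning with a deficit threshold and Fisher coverage tests.

Promoters span -1,500..+500 bp around the TSS, strand-aware. Position
frequency matrices (JASPAR format) are converted to log-odds scores
against a background base composition; a window is a hit when its score
is within ``deficit`` x (score range) of the matrix maximum:

    score >= s_max - deficit * (s_max - s_min)

so deficit 0 accepts only consensus-scoring windows and deficit 1 accepts
everything. Both strands are scanned. Enrichment is at the gene level:
a gene is "bound" by a TF iff its promoter has >= 1 hit, and bound/unbound
counts in query vs background gene sets go into a two-sided Fisher's exact
test ("gene coverage" p-value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .annotation import GeneRecord

__all__ = [
    "Pwm",
    "PromoterWindow",
    "TfEnrichment",
    "read_jaspar_pfms",
    "extract_promoters",
    "scan_pwm",
    "coverage_fisher",
    "recurrent_tfs",
]

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
DEFAULT_DEFICIT = 0.15

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class Pwm:
    """A position weight matrix with its log-odds scoring form.

    ``probs`` is 4 x L over (A, C, G, T); built from counts with a
    per-cell pseudocount against a background base distribution
    (uniform by default).
    """

    tf_id: str
    probs: np.ndarray
    background: np.ndarray
    log_odds: np.ndarray
    s_max: float
    s_min: float

    @classmethod
    def from_counts(cls, tf_id: str, counts: np.ndarray,
                    pseudocount: float = 0.01,
                    background: np.ndarray | None = None) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("counts must be 4 x L over (A, C, G, T)")
        if background is None:
            background = np.full(4, 0.25)
        probs = counts + pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        lo = np.log2(probs / background[:, None])
        return cls(tf_id=tf_id, probs=probs, background=np.asarray(background),
                   log_odds=lo, s_max=float(lo.max(axis=0).sum()),
                   s_min=float(lo.min(axis=0).sum()))

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def threshold(self, deficit: float) -> float:
        if not 0.0 <= deficit <= 1.0:
            raise ValueError(f"deficit must lie in [0, 1], got {deficit}")
        return self.s_max - deficit * (self.s_max - self.s_min)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


def read_jaspar_pfms(path: str | Path, pseudocount: float = 0.01,
                     background: np.ndarray | None = None) -> list[Pwm]:
    """Read JASPAR-format PFM files (raw and 'jaspar' bracket dialects)."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        name = m.name or m.matrix_id or "motif"
        mid = m.matrix_id or name
        pwms.append(Pwm.from_counts(f"{mid}:{name}" if m.matrix_id else name,
                                    counts, pseudocount, background))
    return pwms


@dataclass
class PromoterWindow:
    gene_id: str
    sequence: str
    truncated: bool = False


def extract_promoters(
    annotation: list[GeneRecord],
    fasta_path: str | Path,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PromoterWindow]:
    """Strand-aware promoter windows (-upstream..+downstream around the TSS).

    Plus strand: [tss - upstream, tss + downstream); minus strand: the
    mirrored genomic window, reverse-complemented. Windows truncated at
    contig edges are flagged; genes on missing contigs are skipped with a
    warning.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    names = set(fasta.keys())

    def resolve(chrom: str) -> str | None:
        for candidate in (chrom, f"chr{chrom}"):
            if candidate in names:
                return candidate
        return None

    windows = []
    for g in annotation:
        contig = resolve(g.chrom)
        if contig is None:
            log.warning("gene %s: contig %s missing from FASTA, skipped", g.gene_id, g.chrom)
            continue
        clen = len(fasta[contig])
        tss = g.tss
        if g.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss + 1 - downstream, tss + 1 + upstream
        truncated = lo < 0 or hi > clen
        lo_c, hi_c = max(lo, 0), min(hi, clen)
        seq = str(fasta[contig][lo_c:hi_c])
        if g.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        windows.append(PromoterWindow(gene_id=g.gene_id, sequence=seq,
                                      truncated=truncated))
    return windows


def scan_pwm(sequence: str, pwm: Pwm, deficit: float = DEFAULT_DEFICIT
             ) -> list[tuple[int, str, float]]:
    """All hit windows of a PWM on both strands of a sequence.

    Returns (position, strand, score) for windows whose score meets the
    deficit threshold; windows containing non-ACGT characters are
    skipped. A PWM longer than the sequence yields no hits.
    """
    seq = sequence.upper()
    L = pwm.length
    n = len(seq)
    if L > n:
        return []
    thr = pwm.threshold(deficit)
    lo_f = pwm.log_odds
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    idx = np.arange(L)
    hits = []
    for pos in range(n - L + 1):
        window = codes[pos:pos + L]
        if (window < 0).any():
            continue
        score_f = float(lo_f[window, idx].sum())
        # reverse strand: score the reverse-complemented window forward, so
        # summation order matches s_max and consensus hits are float-exact
        score_r = float(lo_f[3 - window[::-1], idx].sum())
        # report the better strand; both can pass, one row per position/strand
        if score_f >= thr:
            hits.append((pos, "+", score_f))
        if score_r >= thr:
            hits.append((pos, "-", score_r))
    return hits


@dataclass
class TfEnrichment:
    tf_id: str
    query_bound: int
    query_total: int
    background_bound: int
    background_total: int
    enrichment: float         # log2 ratio of bound proportions
    p_value: float            # two-sided Fisher's exact
    significant: bool


def coverage_fisher(
    bound: dict[str, bool],
    query_genes: set[str],
    background_genes: set[str],
    tf_id: str = "TF",
    alpha: float = 0.05,
    allow_overlap: bool = False,
) -> TfEnrichment:
    """Gene-coverage Fisher test: bound/unbound x query/background.

    ``bound`` maps gene -> whether its promoter carries >= 1 hit. The
    enrichment is the log2 ratio of bound proportions (positive =
    over-represented in the query); +/-inf when one proportion is zero.
    """
    if not background_genes:
        raise ValueError("empty background gene set")
    if not allow_overlap and (query_genes & background_genes):
        raise ValueError("query and background overlap; pass allow_overlap=True to permit")
    qb = sum(1 for g in query_genes if bound.get(g, False))
    bb = sum(1 for g in background_genes if bound.get(g, False))
    qt, bt = len(query_genes), len(background_genes)
    table = [[qb, qt - qb], [bb, bt - bb]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    pq, pb = qb / qt if qt else 0.0, bb / bt
    if pq > 0 and pb > 0:
        enr = math.log2(pq / pb)
    elif pq == 0 and pb == 0:
        enr = 0.0
    else:
        enr = math.inf if pb == 0 else -math.inf
    return TfEnrichment(tf_id=tf_id, query_bound=qb, query_total=qt,
                        background_bound=bb, background_total=bt,
                        enrichment=enr, p_value=float(p),
                        significant=bool(p < alpha))


def recurrent_tfs(enrichments_per_supermodule: list[dict[str, TfEnrichment]],
                  min_supermodules: int = 7) -> list[str]:
    """TFs significantly over-represented in at least ``min_supermodules`` sets."""
    if not enrichments_per_supermodule:
        raise ValueError("no supermodule enrichments supplied")
    counts: dict[str, int] = {}
    for enr in enrichments_per_supermodule:
        for tf, e in enr.items():
            if e.significant and e.enrichment > 0:
                counts[tf] = counts.get(tf, 0) + 1
    return sorted(tf for tf, c in counts.items() if c >= min_supermodules)
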