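"""Genome/region model: PAR boundaries, gene records, region classification.

The pseudoautosomal regions PAR1 and PAR2 sit at the Xp and Xq termini
(~2.6 Mb and ~320 kb respectively) and are shared with the Y chromosome.
Genes there are expressed from every sex chromosome, so their dose follows
the *total* sex-chromosome count; non-PAR escape genes follow the X count;
inactive X genes are expressed from the single active X only.

Internal coordinates are 0-based half-open. GTF is read as 1-based closed,
BED as 0-based half-open; conversion happens at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

__all__ = [
    "RegionClass",
    "ParBoundaries",
    "GeneRecord",
    "normalize_chrom",
    "assign_region_class",
    "read_gene_annotation",
    "write_gene_bed",
]

log = logging.getLogger(__name__)

# hg-scale defaults: PAR1 ~2.6 Mb from Xp terminus, PAR2 ~320 kb from Xq terminus
DEFAULT_PAR1_SPAN = 2_600_000
DEFAULT_PAR2_SPAN = 320_000
DEFAULT_X_LENGTH = 155_270_560


class RegionClass(str, Enum):
    PAR1 = "PAR1"
    PAR2 = "PAR2"
    X_NONPAR = "X_NONPAR"
    Y_LINKED = "Y_LINKED"
    AUTOSOME = "AUTOSOME"


class XciStatus(str, Enum):
    """Literature X-inactivation annotation of a gene."""

    ESCAPE = "escape"
    INACTIVE = "inactive"
    VARIABLE = "variable"
    SUBJECT = "subject"   # reported as subject to XCI
    UNKNOWN = "unknown"   # novel: no previously described status


@dataclass(frozen=True)
class ParBoundaries:
    """Pseudoautosomal spans measured from the X-chromosome termini (bp)."""

    par1_span_bp: int = DEFAULT_PAR1_SPAN
    par2_span_bp: int = DEFAULT_PAR2_SPAN
    x_length_bp: int = DEFAULT_X_LENGTH

    def __post_init__(self) -> None:
        if self.par1_span_bp <= 0 or self.par2_span_bp <= 0:
            raise ValueError("PAR spans must be positive")
        if self.par1_span_bp + self.par2_span_bp >= self.x_length_bp:
            raise ValueError("PAR spans must not cover the whole X chromosome")

    @property
    def par2_start(self) -> int:
        return self.x_length_bp - self.par2_span_bp


def normalize_chrom(chrom: str) -> str:
    """Map 'chrX'/'X'/'x' style names onto bare upper-case names."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y"):
        return c.upper()
    return c


@dataclass
class GeneRecord:
    """A gene span with its sex-chromosome region class.

    Coordinates are 0-based half-open on the internal convention.
    ``xci_status`` is the literature X-inactivation annotation, if any.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    region_class: RegionClass | None = None
    xci_status: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        self.chrom = normalize_chrom(self.chrom)

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def assign_region_class(gene: GeneRecord, boundaries: ParBoundaries) -> RegionClass:
    """Classify a gene into {PAR1, PAR2, X_NONPAR, Y_LINKED, AUTOSOME}.

    A gene straddling a PAR boundary is classified by its start position,
    giving a single deterministic rule.
    """
    chrom = normalize_chrom(gene.chrom)
    if chrom == "Y":
        return RegionClass.Y_LINKED
    if chrom != "X":
        return RegionClass.AUTOSOME
    if gene.end > boundaries.x_length_bp:
        raise ValueError(
            f"{gene.gene_id}: end {gene.end} beyond X length {boundaries.x_length_bp}"
        )
    if gene.start < boundaries.par1_span_bp:
        return RegionClass.PAR1
    if gene.start >= boundaries.par2_start:
        return RegionClass.PAR2
    return RegionClass.X_NONPAR


class AnnotationParseError(ValueError):
    """Raised with the offending line number when a GTF/BED line is malformed."""


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


_KNOWN_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def read_gene_annotation(
    path: str | Path,
    boundaries: ParBoundaries | None = None,
    fmt: str | None = None,
) -> list[GeneRecord]:
    """Read gene spans from a GTF (ensembl dialect) or BED6 file.

    GTF 1-based closed coordinates are converted to internal 0-based
    half-open; BED is taken as-is. Every returned record has its
    ``region_class`` assigned. Records on unresolvable chromosomes are
    skipped with a warning.
    """
    path = Path(path)
    boundaries = boundaries or ParBoundaries()
    if fmt is None:
        fmt = "bed" if path.suffix.lower() in (".bed",) else "gtf"
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    if fields[2] != "gene":
                        continue
                    chrom = normalize_chrom(fields[0])
                    start = int(fields[3]) - 1          # 1-based closed -> 0-based
                    end = int(fields[4])                # closed end == half-open end
                    strand = fields[6]
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs.get("gene_id")
                    if gene_id is None:
                        raise ValueError("missing gene_id attribute")
                    xci = attrs.get("xci_status")
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 tab-separated BED6 fields")
                    chrom = normalize_chrom(fields[0])
                    start, end = int(fields[1]), int(fields[2])
                    gene_id, strand = fields[3], fields[5]
                    xci = None
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in _KNOWN_CHROMS:
                log.warning("%s:%d: unknown chromosome %r, record skipped", path, lineno, chrom)
                continue
            if gene_id in seen:
                raise AnnotationParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            rec = GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end,
                             strand=strand, xci_status=xci)
            rec.region_class = assign_region_class(rec, boundaries)
            genes.append(rec)
    return genes


def write_gene_bed(genes: list[GeneRecord], path: str | Path) -> None:
    """Write gene spans as BED6 (score column carries the region class)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t"
                f"{g.region_class.value if g.region_class else '.'}\t{g.strand}\n"
            )


def write_gene_gtf(genes: list[GeneRecord], path: str | Path) -> None:
    """Write gene spans as ensembl-dialect GTF gene lines (round-trippable)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.xci_status:
                attrs += f' xci_status "{g.xci_status}";'
            fh.write(
                f"{g.chrom}\txdosage\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
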