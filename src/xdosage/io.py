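"""Readers/writers for expression matrices, allele counts, and sample metadata.

Formats: genes×samples TSV (header row = sample ids), MatrixMarket MTX with
sidecar row/column name files, GATK ASEReadCounter-dialect TSV, and a YAML
sample-metadata file mapping sample_id -> karyotype label / cohort role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .karyotype import KaryotypeSpec, SampleMeta, parse_karyotype_label

__all__ = [
    "ExpressionMatrix",
    "AlleleCountRecord",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_allele_counts",
    "write_allele_counts",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gmt",
]

log = logging.getLogger(__name__)

VALID_UNITS = ("counts", "FPKM", "CPM", "log2")


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with a declared unit."""

    data: pd.DataFrame           # index: gene ids; columns: sample ids
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains NaN")
        if (vals < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = [g for g in self.data.index if g in set(gene_ids)]
        return ExpressionMatrix(self.data.loc[keep], unit=self.unit)


def read_expression_matrix(path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read a genes×samples TSV, or an MTX triplet file with sidecars.

    For ``m.mtx`` the row (gene) and column (sample) names are read from
    ``m.rows.txt`` / ``m.cols.txt`` next to it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        df = pd.DataFrame(np.asarray(mat), index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        sparse = scipy.sparse.coo_matrix(matrix.data.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        Path(str(path)[: -len(".mtx")] + ".rows.txt").write_text(
            "\n".join(matrix.genes) + "\n")
        Path(str(path)[: -len(".mtx")] + ".cols.txt").write_text(
            "\n".join(matrix.samples) + "\n")
    else:
        matrix.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Allele counts (ASEReadCounter dialect)
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


@dataclass
class AlleleCountRecord:
    """Per-SNP allele counts. Positions are 1-based (VCF convention)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    total_count: int
    gene_id: str | None = None
    intronic: bool = False
    multi_gene: bool = False
    is_xist: bool = False

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.total_count) < 0:
            raise ValueError("allele counts must be non-negative")
        if self.ref_count + self.alt_count > self.total_count:
            raise ValueError(
                f"{self.chrom}:{self.pos}: refCount+altCount "
                f"({self.ref_count}+{self.alt_count}) exceeds totalCount {self.total_count}"
            )

    @property
    def ref_fraction(self) -> float:
        """Reference allele counts divided by total counts."""
        if self.total_count == 0:
            raise ZeroDivisionError("total_count is zero")
        return self.ref_count / self.total_count


_ASE_REQUIRED = ["contig", "position", "refAllele", "altAllele",
                 "refCount", "altCount", "totalCount"]


def read_allele_counts(path: str | Path, sample_id: str | None = None) -> list[AlleleCountRecord]:
    """Read an ASEReadCounter-style TSV into allele-count records.

    Rows with non-ACGT alleles (e.g. 'N', indels) are excluded with a
    warning; refCount+altCount > totalCount raises. Optional columns
    sample_id, gene_id, intronic, multi_gene, is_xist are honored.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ASE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[AlleleCountRecord] = []
    for row in df.itertuples(index=False):
        ref, alt = str(row.refAllele).upper(), str(row.altAllele).upper()
        if ref not in _ACGT or alt not in _ACGT:
            log.warning("%s %s:%s: non-ACGT allele (%s/%s), record excluded",
                        path, row.contig, row.position, ref, alt)
            continue
        records.append(AlleleCountRecord(
            sample_id=str(getattr(row, "sample_id", sample_id or "sample")),
            chrom=str(row.contig),
            pos=int(row.position),
            ref=ref,
            alt=alt,
            ref_count=int(row.refCount),
            alt_count=int(row.altCount),
            total_count=int(row.totalCount),
            gene_id=(str(row.gene_id) if getattr(row, "gene_id", None) not in (None, np.nan) else None),
            intronic=bool(getattr(row, "intronic", False)),
            multi_gene=bool(getattr(row, "multi_gene", False)),
            is_xist=bool(getattr(row, "is_xist", False)),
        ))
    return records


def write_allele_counts(records: list[AlleleCountRecord], path: str | Path) -> None:
    rows = [{
        "contig": r.chrom, "position": r.pos,
        "refAllele": r.ref, "altAllele": r.alt,
        "refCount": r.ref_count, "altCount": r.alt_count, "totalCount": r.total_count,
        "sample_id": r.sample_id, "gene_id": r.gene_id or "",
        "intronic": int(r.intronic), "multi_gene": int(r.multi_gene),
        "is_xist": int(r.is_xist),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata (YAML)
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a YAML mapping sample_id -> {karyotype, cohort_role, clone_id}.

    A bare string value is shorthand for the karyotype label.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of sample_id -> metadata")
    metas: list[SampleMeta] = []
    for sample_id, entry in raw.items():
        if isinstance(entry, str):
            entry = {"karyotype": entry}
        kt = parse_karyotype_label(entry["karyotype"])
        metas.append(SampleMeta(
            sample_id=str(sample_id),
            karyotype=kt,
            cohort_role=entry.get("cohort_role", _default_role(kt)),
            clone_id=entry.get("clone_id"),
        ))
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return metas


def _default_role(kt: KaryotypeSpec) -> str:
    if kt.n_x == 1 and kt.n_y == 1:
        return "control_male"
    if kt.n_x == 2 and kt.n_y == 0:
        return "control_female"
    return "case"


def write_sample_metadata(metas: list[SampleMeta], path: str | Path) -> None:
    out = {m.sample_id: {"karyotype": m.karyotype.label,
                         "cohort_role": m.cohort_role,
                         **({"clone_id": m.clone_id} if m.clone_id else {})}
           for m in metas}
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file: term <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
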