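"""Bulk dosage statistics along and beyond the X chromosome.

Core quantities:

* ``MF`` (mean FPKM) per chromosome = sum(FPKM) / number of expressed genes
  on that chromosome; the X:A ratio is MF(X) divided by the unweighted mean
  of the per-autosome MFs. Dosage-compensated cells sit between 0.5 and 1.
* ``MM`` (male median) = per-gene median FPKM over healthy 46,XY reference
  samples; ``FC`` = FPKM / MM per sample, smoothed along the X by a loess
  fit (span 0.45, local quadratic, tricube weights) of log2 FC on gene
  position.
* Dosage-trend classification: OLS of log2(expr + 1) on the sex-chromosome
  covariate — total sex-chromosome count (n_x + n_y) for PAR genes, X count
  (n_x) otherwise — with Benjamini-Hochberg correction across genes.
* DEG thresholds: FDR < 0.05 and |log2 FC| > 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneRecord, RegionClass
from .io import ExpressionMatrix
from .karyotype import SampleMeta

__all__ = [
    "XaRatioResult",
    "FoldChangeTrack",
    "MovingAverageCurve",
    "DosageTrend",
    "DegCall",
    "filter_expressed",
    "x_a_ratio",
    "male_median_fc",
    "loess_fit",
    "moving_average_x",
    "welch_degs",
    "call_degs",
    "intersect_degs",
    "classify_dosage_trend",
    "categorize_x_degs",
]

log = logging.getLogger(__name__)

FPKM_EXPRESSED_CUT = 0.5
DEG_FDR_CUT = 0.05
DEG_LFC_CUT = 0.25
DEFAULT_LOESS_SPAN = 0.45


@dataclass
class XaRatioResult:
    sample_id: str
    mf_x: float
    mf_autosome_mean: float

    @property
    def ratio(self) -> float:
        return self.mf_x / self.mf_autosome_mean


@dataclass
class FoldChangeTrack:
    """Per-gene male-median fold changes with gene positions along X."""

    gene_ids: list[str]
    positions: np.ndarray              # gene start on X, bp
    male_median: np.ndarray            # MM per gene
    fc: pd.DataFrame                   # genes x samples, FPKM / MM


@dataclass
class MovingAverageCurve:
    positions: np.ndarray
    smoothed: np.ndarray               # loess-smoothed log2 FC (or FC)
    span: float
    log2: bool = True


@dataclass
class DosageTrend:
    gene_id: str
    covariate: str                     # {n_x, n_x_plus_n_y}
    slope: float
    p_value: float
    fdr: float
    trend: str                         # {proportional, inverse, flat}


@dataclass
class DegCall:
    gene_id: str
    log2_fc: float
    fdr: float
    direction: str                     # {up, down, ns}


# ---------------------------------------------------------------------------
# Expressed-gene filtering and X:A ratio
# ---------------------------------------------------------------------------

def filter_expressed(matrix: ExpressionMatrix, cut: float = FPKM_EXPRESSED_CUT,
                     per_sample: bool = False) -> ExpressionMatrix:
    """Drop genes below the FPKM expression cut (default: mean FPKM < 0.5).

    With ``per_sample=True`` a gene is kept if any single sample reaches
    the cut instead of the cross-sample mean.
    """
    if matrix.unit != "FPKM":
        raise ValueError(f"filter_expressed requires FPKM, got unit {matrix.unit!r}")
    if per_sample:
        keep = (matrix.data >= cut).any(axis=1)
    else:
        keep = matrix.data.mean(axis=1) >= cut
    return ExpressionMatrix(matrix.data.loc[keep], unit=matrix.unit)


def x_a_ratio(matrix: ExpressionMatrix, annotation: list[GeneRecord],
              sample_id: str) -> XaRatioResult:
    """X:A FPKM ratio = MF(X) / mean over autosomes of MF(autosome).

    MF per chromosome = sum(FPKM) / number of genes on that chromosome,
    computed on the expressed-gene-filtered matrix. Exactly invariant
    under global rescaling of the matrix.
    """
    chrom_of = {g.gene_id: g.chrom for g in annotation}
    col = matrix.data[sample_id]
    by_chrom: dict[str, list[float]] = {}
    for gene_id, value in col.items():
        chrom = chrom_of.get(gene_id)
        if chrom is None:
            continue
        by_chrom.setdefault(chrom, []).append(float(value))
    if "X" not in by_chrom:
        raise ValueError(f"{sample_id}: no expressed X-linked genes in matrix")
    autosome_mfs = [np.mean(v) for c, v in by_chrom.items() if c not in ("X", "Y")]
    if not autosome_mfs:
        raise ValueError(f"{sample_id}: no expressed autosomal genes in matrix")
    return XaRatioResult(sample_id=sample_id,
                         mf_x=float(np.mean(by_chrom["X"])),
                         mf_autosome_mean=float(np.mean(autosome_mfs)))


# ---------------------------------------------------------------------------
# Male-median fold change and loess moving average
# ---------------------------------------------------------------------------

def male_median_fc(matrix: ExpressionMatrix, annotation: list[GeneRecord],
                   reference_samples: list[str],
                   x_only: bool = True) -> FoldChangeTrack:
    """Fold change of each sample over the male-median reference profile.

    MM = per-gene median over 46,XY reference samples; FC = FPKM / MM.
    Genes with MM = 0 are dropped with a log entry. By default restricted
    to X-linked genes (the track is plotted along the X).
    """
    if len(reference_samples) < 2:
        raise ValueError("need >= 2 reference (46,XY) samples for a male median")
    missing = [s for s in reference_samples if s not in matrix.data.columns]
    if missing:
        raise ValueError(f"reference samples absent from matrix: {missing}")
    genes = [g for g in annotation if g.gene_id in matrix.data.index]
    if x_only:
        genes = [g for g in genes if g.chrom == "X"]
    genes.sort(key=lambda g: g.start)
    ids = [g.gene_id for g in genes]
    sub = matrix.data.loc[ids]
    mm = sub[reference_samples].median(axis=1)
    zero = mm == 0
    if zero.any():
        log.info("male_median_fc: dropping %d genes with male median 0", int(zero.sum()))
    keep = ~zero
    ids = [g for g, k in zip(ids, keep) if k]
    positions = np.array([g.start for g in genes])[keep.to_numpy()]
    fc = sub.loc[ids].div(mm[keep], axis=0)
    return FoldChangeTrack(gene_ids=ids, positions=positions,
                           male_median=mm[keep].to_numpy(), fc=fc)


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = DEFAULT_LOESS_SPAN,
              degree: int = 2, eval_x: np.ndarray | None = None) -> np.ndarray:
    """Locally weighted polynomial regression (loess).

    ``span`` is the fraction of observations in each local window;
    tricube weights on the distance to the k-th nearest neighbour,
    local polynomial of the given degree, no robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = len(x)
    if n < degree + 1:
        raise ValueError("not enough points for the local polynomial")
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    if eval_x is None:
        eval_x = x
    eval_x = np.asarray(eval_x, dtype=float)
    out = np.empty(len(eval_x))
    for i, x0 in enumerate(eval_x):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            # all k nearest points coincide with x0: weighted mean of ties
            out[i] = float(np.mean(y[d == 0]))
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        mask = w > 0
        # center on x0 and scale by the bandwidth to keep the local
        # polynomial basis well conditioned at genomic coordinate scale
        xm, ym, wm = (x[mask] - x0) / h, y[mask], w[mask]
        deg = min(degree, len(xm) - 1)
        basis = np.vander(xm, deg + 1, increasing=True)
        sw = np.sqrt(wm)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], ym * sw, rcond=None)
        out[i] = coef[0]                     # intercept == fit at x0
    return out


def moving_average_x(track: FoldChangeTrack, sample_id: str,
                     span: float = DEFAULT_LOESS_SPAN, degree: int = 2,
                     log2: bool = True) -> MovingAverageCurve:
    """Loess moving average of (log2) fold change along X gene positions."""
    if len(track.gene_ids) < 10:
        raise ValueError(
            f"moving average needs >= 10 X-linked genes, got {len(track.gene_ids)}; "
            "use a larger annotation/matrix")
    fc = track.fc[sample_id].to_numpy()
    yvals = np.log2(fc) if log2 else fc
    order = np.argsort(track.positions, kind="stable")
    x = track.positions[order].astype(float)
    y = yvals[order]
    smoothed = loess_fit(x, y, span=span, degree=degree)
    return MovingAverageCurve(positions=x, smoothed=smoothed, span=span, log2=log2)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def welch_degs(matrix: ExpressionMatrix, group_a: list[str],
               group_b: list[str]) -> pd.DataFrame:
    """Simple DE engine: Welch t-test on log2(CPM+1), BH-corrected.

    Returns a per-gene table with columns log2_fc (A minus B) and fdr,
    consumable by :func:`call_degs`. External DE output (e.g. from a
    count-model engine) can be fed to :func:`call_degs` directly instead.
    """
    data = matrix.data
    if matrix.unit == "counts":
        cpm = data / data.sum(axis=0) * 1e6
        logm = np.log2(cpm + 1)
    elif matrix.unit == "log2":
        logm = data
    else:
        logm = np.log2(data + 1)
    a, b = logm[group_a].to_numpy(), logm[group_b].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"log2_fc": lfc, "p_value": p, "fdr": fdr}, index=data.index)


def call_degs(table: pd.DataFrame, fdr_cut: float = DEG_FDR_CUT,
              lfc_cut: float = DEG_LFC_CUT) -> list[DegCall]:
    """Apply the DEG thresholds: FDR < 0.05 and log2 FC beyond +/-0.25.

    ``table`` needs columns log2_fc and fdr (gene ids in the index) —
    either from :func:`welch_degs` or from an external engine.
    """
    if ((table["fdr"] < 0) | (table["fdr"] > 1)).any():
        raise ValueError("fdr column must lie in [0, 1]")
    calls = []
    for gene_id, row in table.iterrows():
        if row["fdr"] < fdr_cut and row["log2_fc"] > lfc_cut:
            direction = "up"
        elif row["fdr"] < fdr_cut and row["log2_fc"] < -lfc_cut:
            direction = "down"
        else:
            direction = "ns"
        calls.append(DegCall(str(gene_id), float(row["log2_fc"]), float(row["fdr"]), direction))
    return calls


def intersect_degs(calls_a: list[DegCall], calls_b: list[DegCall]) -> list[str]:
    """Genes called in both comparisons with concordant direction."""
    dir_a = {c.gene_id: c.direction for c in calls_a if c.direction != "ns"}
    shared = [c.gene_id for c in calls_b
              if c.direction != "ns" and dir_a.get(c.gene_id) == c.direction]
    return sorted(shared)


# ---------------------------------------------------------------------------
# Dosage-trend classification
# ---------------------------------------------------------------------------

def classify_dosage_trend(
    matrix: ExpressionMatrix,
    sample_meta: list[SampleMeta],
    annotation: list[GeneRecord],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    covariate_override: str | None = None,
) -> list[DosageTrend]:
    """Per-gene trend vs sex-chromosome dose: proportional / inverse / flat.

    OLS of log2(expr + pseudocount) on the covariate — total sex-chromosome
    count for PAR genes, X count otherwise (override with
    ``covariate_override`` in {"n_x", "n_x_plus_n_y"}). BH correction
    across genes; trend is non-flat only when the corrected p < alpha.
    """
    meta = {m.sample_id: m for m in sample_meta}
    samples = [s for s in matrix.samples if s in meta]
    n_x = np.array([meta[s].karyotype.n_x for s in samples], dtype=float)
    n_xy = np.array([meta[s].karyotype.n_sex_chromosomes for s in samples], dtype=float)
    if len(set(zip(n_x, n_xy))) < 2:
        raise ValueError("dosage-trend classification needs >= 2 distinct karyotypes")
    region_of = {g.gene_id: g.region_class for g in annotation}
    logm = np.log2(matrix.data[samples].to_numpy(dtype=float) + pseudocount)

    rows = []
    pvals = []
    for i, gene_id in enumerate(matrix.genes):
        region = region_of.get(gene_id)
        if covariate_override is not None:
            cov_name = covariate_override
        elif region in (RegionClass.PAR1, RegionClass.PAR2):
            cov_name = "n_x_plus_n_y"
        else:
            cov_name = "n_x"
        cov = n_xy if cov_name == "n_x_plus_n_y" else n_x
        res = stats.linregress(cov, logm[i])
        p = res.pvalue if np.isfinite(res.pvalue) else 1.0
        rows.append((gene_id, cov_name, float(res.slope), float(p)))
        pvals.append(p)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    trends = []
    for (gene_id, cov_name, slope, p), fdr in zip(rows, fdrs):
        if fdr < alpha and slope > 0:
            trend = "proportional"
        elif fdr < alpha and slope < 0:
            trend = "inverse"
        else:
            trend = "flat"
        trends.append(DosageTrend(gene_id, cov_name, slope, p, float(fdr), trend))
    return trends


_XCI_CATEGORY = {
    "escape": "escape",
    "inactive": "inactive",
    "variable": "variable",
    "subject": "subject-to-XCI",
}


def categorize_x_degs(degs: list[DegCall], annotation: list[GeneRecord]) -> dict[str, list[str]]:
    """Bucket X-linked DEGs: PAR1, escape, inactive, variable, subject-to-XCI, novel.

    PAR1 membership overrides the literature XCI status; X-linked genes
    with no described status fall into "novel".
    """
    gene_of = {g.gene_id: g for g in annotation}
    out: dict[str, list[str]] = {k: [] for k in
                                 ("PAR1", "escape", "inactive", "variable",
                                  "subject-to-XCI", "novel")}
    for call in degs:
        if call.direction == "ns":
            continue
        g = gene_of.get(call.gene_id)
        if g is None or g.chrom != "X":
            continue
        if g.region_class is RegionClass.PAR1:
            out["PAR1"].append(call.gene_id)
        else:
            cat = _XCI_CATEGORY.get((g.xci_status or "unknown").lower(), "novel")
            out[cat].append(call.gene_id)
    return out
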