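"""Single-cell tests of XIST dosage and XIST/cell-cycle independence.

XIST dose mirrors the X count minus one across karyotypes (Kruskal-Wallis
across groups), while PAR and non-PAR escape genes track the number of Xs
without tracking a cell's realized XIST level: within a karyotype their
Pearson correlation with XIST should be indistinguishable from zero.
Independence is declared when the correlation test gives p > 0.05;
correlations are computed within karyotype only — pooling karyotypes would
induce spurious correlation through the shared dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneXistCorrelation",
    "normalize_cells",
    "xist_by_karyotype",
    "correlate_with_xist",
    "phase_independence",
]

log = logging.getLogger(__name__)

INDEPENDENCE_ALPHA = 0.05


@dataclass
class GeneXistCorrelation:
    gene_id: str
    karyotype: str
    r: float
    p_value: float
    n_cells: int
    verdict: str            # {correlated, independent, undefined}


def _gene_vector(adata: ad.AnnData, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    j = adata.var_names.get_loc(gene)
    col = adata.X[:, j]
    return np.asarray(col).ravel().astype(float)


def normalize_cells(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalize to the median library, then log2(x + 1).

    Cells with zero counts are dropped with a warning. Returns a new
    AnnData; raw counts are kept in ``layers['counts']``.
    """
    X = np.asarray(adata.X, dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    libs = X.sum(axis=1)
    zero = libs == 0
    if zero.any():
        log.warning("dropping %d zero-library cells", int(zero.sum()))
        adata = adata[~zero].copy()
        X, libs = X[~zero], libs[~zero]
    target = float(np.median(libs))
    scaled = X * (target / libs)[:, None]
    out = adata.copy()
    out.layers["counts"] = X
    out.X = np.log2(scaled + 1.0)
    return out


def xist_by_karyotype(adata: ad.AnnData, xist_gene: str = "XIST",
                      group_key: str = "karyotype") -> dict:
    """Per-karyotype XIST distribution summary plus a Kruskal-Wallis test."""
    xist = _gene_vector(adata, xist_gene)
    groups = adata.obs[group_key].astype(str)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 karyotype groups")
    per_group = []
    medians = {}
    for lab in labels:
        v = xist[(groups == lab).to_numpy()]
        if len(v) < 3:
            log.warning("karyotype group %s has < 3 cells", lab)
        per_group.append(v)
        medians[lab] = float(np.median(v))
    if all(np.all(v == per_group[0][0]) for v in per_group):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*per_group)
    return {"medians": medians, "h_statistic": float(h), "p_value": float(p),
            "group_sizes": {lab: int(len(v)) for lab, v in zip(labels, per_group)}}


def correlate_with_xist(
    adata: ad.AnnData,
    genes: list[str],
    xist_gene: str = "XIST",
    group_key: str = "karyotype",
    min_cells: int = 10,
    alpha: float = INDEPENDENCE_ALPHA,
) -> list[GeneXistCorrelation]:
    """Within-karyotype Pearson correlation of each gene with XIST.

    verdict = independent iff p > alpha; zero-variance genes (or a
    zero-variance XIST group, e.g. 46,XY) are flagged undefined.
    """
    xist = _gene_vector(adata, xist_gene)
    groups = adata.obs[group_key].astype(str)
    results: list[GeneXistCorrelation] = []
    for lab in sorted(groups.unique()):
        mask = (groups == lab).to_numpy()
        if mask.sum() < min_cells:
            log.warning("karyotype %s: only %d cells, skipped", lab, mask.sum())
            continue
        xg = xist[mask]
        xist_flat = np.std(xg) == 0
        for gene in genes:
            v = _gene_vector(adata, gene)[mask]
            if xist_flat or np.std(v) == 0:
                results.append(GeneXistCorrelation(gene, lab, float("nan"),
                                                   float("nan"), int(mask.sum()),
                                                   "undefined"))
                continue
            r, p = stats.pearsonr(xg, v)
            verdict = "independent" if p > alpha else "correlated"
            results.append(GeneXistCorrelation(gene, lab, float(r), float(p),
                                               int(mask.sum()), verdict))
    return results


def phase_independence(
    adata: ad.AnnData,
    genes: list[str],
    phase_key: str = "phase",
    min_cells_per_phase: int = 3,
    alpha: float = INDEPENDENCE_ALPHA,
) -> pd.DataFrame:
    """Kruskal-Wallis of each gene across cell-cycle phases {G1, S, G2M}.

    Returns a per-gene table (h, p_value, independent). Skipped with a
    warning when any phase has fewer than ``min_cells_per_phase`` cells.
    """
    phases = adata.obs[phase_key].astype(str)
    labels = [lab for lab in ("G1", "S", "G2M") if (phases == lab).any()]
    sizes = {lab: int((phases == lab).sum()) for lab in labels}
    if len(labels) < 2 or any(n < min_cells_per_phase for n in sizes.values()):
        log.warning("phase groups too small (%s); test skipped", sizes)
        return pd.DataFrame(columns=["gene_id", "h", "p_value", "independent"]
                            ).set_index("gene_id")
    rows = []
    for gene in genes:
        v = _gene_vector(adata, gene)
        per_phase = [v[(phases == lab).to_numpy()] for lab in labels]
        if all(np.std(g) == 0 for g in per_phase) and len({g[0] for g in per_phase}) == 1:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*per_phase)
        rows.append({"gene_id": gene, "h": float(h), "p_value": float(p),
                     "independent": bool(p > alpha)})
    return pd.DataFrame(rows).set_index("gene_id")
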