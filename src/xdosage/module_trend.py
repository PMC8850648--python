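"""Co-expression modules, dosage-trend supermodules, and set enrichment.

Module detection follows the weighted-correlation-network recipe: signed
adjacency a_ij = ((1 + cor_ij)/2)^beta with soft power beta (default 20),
signed topological-overlap dissimilarity, average-linkage hierarchical
clustering, and a deterministic static tree cut. Clusters below the
minimum size, or without internal correlation coherence, fall into the
unassigned "grey" bin. Modules are summarized by their eigengene (first
principal component of the standardized module submatrix), filtered by
one-way ANOVA across karyotypes, and grouped into "supermodules" when
their eigengenes are similar and share a monotone linear trend in the X
count. Gene-set enrichment uses the exact hypergeometric upper tail with
Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .karyotype import SampleMeta

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "EnrichmentResult",
    "filter_cpm",
    "build_modules",
    "module_eigengene",
    "anova_filter",
    "select_dosage_supermodules",
    "hypergeom_enrich",
    "gene_set_overlap",
]

log = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class NetworkConfig:
    soft_power: float = 20.0
    network_type: str = "signed"
    min_module_size: int = 30
    merge_dissimilarity: float = 0.25
    anova_alpha: float = 0.05
    cut_quantile: float = 0.99      # static tree cut at this merge-height quantile
    min_intra_cor: float = 0.3      # coherence gate: mean within-module correlation

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if self.network_type != "signed":
            raise ValueError("only the signed network type is implemented")


@dataclass
class ModuleSet:
    """Gene -> module labels plus per-module summaries."""

    labels: pd.Series                               # gene -> label ('grey' = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    anova_p: dict = field(default_factory=dict)
    trend: dict = field(default_factory=dict)       # module -> {up, down, flat}
    supermodule: dict = field(default_factory=dict)  # module -> supermodule id

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.labels) - {GREY},
                      key=lambda m: (-int((self.labels == m).sum()), m))

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def filter_cpm(matrix: ExpressionMatrix, min_cpm: float = 1.0,
               min_samples: int = 4) -> ExpressionMatrix:
    """Keep genes with CPM >= 1 in at least four samples."""
    if matrix.unit != "counts":
        raise ValueError(f"filter_cpm requires counts, got {matrix.unit!r}")
    if matrix.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {matrix.shape[1]}")
    cpm = matrix.data / matrix.data.sum(axis=0) * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.data.loc[keep], unit="counts")


def _signed_tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix for a (signed) adjacency with zero diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_modules(matrix: ExpressionMatrix, config: NetworkConfig | None = None) -> ModuleSet:
    """Detect co-expression modules via signed adjacency + TOM clustering.

    Static cut: average-linkage tree cut at the ``cut_quantile`` of merge
    heights; clusters smaller than ``min_module_size`` or with mean
    within-cluster correlation below ``min_intra_cor`` are sent to grey.
    Module labels are M1, M2, ... ordered by decreasing size.
    """
    config = config or NetworkConfig()
    data = matrix.data
    const = data.std(axis=1) == 0
    if const.any():
        log.warning("dropping %d constant gene rows before correlation", int(const.sum()))
        data = data.loc[~const]
    genes = list(data.index)
    n = len(genes)
    if n < 3 * config.min_module_size:
        raise ValueError("too few genes for module detection")
    if data.shape[1] < 8:
        raise ValueError("module detection needs >= 8 samples")
    cor = np.corrcoef(data.to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** config.soft_power
    tom = _signed_tom(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, config.cut_quantile))
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    labels = pd.Series(GREY, index=genes, dtype=object)
    clusters = []
    for cid in np.unique(raw):
        idx = np.where(raw == cid)[0]
        if len(idx) < config.min_module_size:
            continue
        sub = cor[np.ix_(idx, idx)]
        mean_cor = float((sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1)))
        if mean_cor < config.min_intra_cor:
            continue
        clusters.append(idx)
    clusters.sort(key=len, reverse=True)
    for mi, idx in enumerate(clusters, start=1):
        labels.iloc[idx] = f"M{mi}"
    return ModuleSet(labels=labels)


def module_eigengene(matrix: ExpressionMatrix, module_genes: list[str]
                     ) -> tuple[np.ndarray, float]:
    """First principal component of the standardized module submatrix.

    Returns (per-sample eigengene, fraction of variance explained); the
    eigengene is sign-oriented to correlate positively with the module's
    mean expression profile. Degenerate submatrices fall back to the mean
    profile with a warning.
    """
    if len(module_genes) < 3:
        raise ValueError("module must have >= 3 genes")
    sub = matrix.data.loc[module_genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    mean_profile = sub.mean(axis=0)
    if (sd == 0).all():
        log.warning("rank-deficient module submatrix; using mean profile")
        return mean_profile, 1.0
    keep = sd > 0
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    explained = float(s[0] ** 2 / (s ** 2).sum())
    centred = mean_profile - mean_profile.mean()
    if np.std(centred) > 0 and float(np.dot(eig, centred)) < 0:
        eig = -eig
    return eig, explained


def compute_eigengenes(matrix: ExpressionMatrix, module_set: ModuleSet) -> pd.DataFrame:
    """Eigengene table (modules x samples), stored on the ModuleSet."""
    rows = {}
    for module in module_set.modules:
        eig, _ = module_eigengene(matrix, module_set.genes_in(module))
        rows[module] = eig
    eigs = pd.DataFrame(rows, index=matrix.samples).T
    module_set.eigengenes = eigs
    return eigs


def anova_filter(eigengenes: pd.DataFrame, sample_meta: list[SampleMeta],
                 alpha: float = 0.05) -> list[str]:
    """One-way ANOVA of each eigengene across karyotype groups; pass iff p < alpha."""
    meta = {m.sample_id: m.karyotype.label for m in sample_meta}
    groups = pd.Series({s: meta[s] for s in eigengenes.columns})
    labels = groups.unique()
    if len(labels) < 2 or sum((groups == lab).sum() >= 2 for lab in labels) < 2:
        raise ValueError("ANOVA needs >= 2 karyotype groups with >= 2 samples each")
    passing = []
    for module, eig in eigengenes.iterrows():
        vals = [eig[groups[groups == lab].index].to_numpy() for lab in labels]
        vals = [v for v in vals if len(v) >= 2]
        if len(vals) < 2:
            log.warning("module %s skipped: degenerate group sizes", module)
            continue
        if all(np.std(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
            p = 1.0
        else:
            _, p = stats.f_oneway(*vals)
            p = 1.0 if np.isnan(p) else float(p)
        if p < alpha:
            passing.append(module)
    return passing


def _monotone(values: np.ndarray, increasing: bool) -> bool:
    diffs = np.diff(values)
    return bool(np.all(diffs >= 0) if increasing else np.all(diffs <= 0))


def select_dosage_supermodules(
    module_set: ModuleSet,
    sample_meta: list[SampleMeta],
    passing: list[str] | None = None,
    merge_dissimilarity: float = 0.25,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Label module trends vs n_x and merge similar same-trend modules.

    A module trends up/down when the linear regression of its eigengene
    on the X count is significant (p < alpha) and the per-karyotype group
    means are monotone in n_x; others are flat and excluded. Modules with
    eigengene correlation >= 1 - merge_dissimilarity and the same trend
    merge into one supermodule (SM1, SM2, ... by decreasing total size).
    """
    eigs = module_set.eigengenes
    if eigs.empty:
        raise ValueError("compute eigengenes before supermodule selection")
    if passing is None:
        passing = list(eigs.index)
    meta = {m.sample_id: m.karyotype.n_x for m in sample_meta}
    n_x = np.array([meta[s] for s in eigs.columns], dtype=float)
    trends: dict[str, str] = {}
    for module in passing:
        eig = eigs.loc[module].to_numpy()
        res = stats.linregress(n_x, eig)
        xs = np.unique(n_x)
        group_means = np.array([eig[n_x == x].mean() for x in xs])
        if res.pvalue < alpha and res.slope > 0 and _monotone(group_means, True):
            trends[module] = "up"
        elif res.pvalue < alpha and res.slope < 0 and _monotone(group_means, False):
            trends[module] = "down"
        else:
            trends[module] = "flat"
    module_set.trend = trends

    # merge same-trend modules whose eigengenes correlate above the threshold
    corr_cut = 1.0 - merge_dissimilarity
    directional = [m for m in passing if trends[m] != "flat"]
    parent = {m: m for m in directional}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for i, a in enumerate(directional):
        for b in directional[i + 1:]:
            if trends[a] != trends[b]:
                continue
            r = float(np.corrcoef(eigs.loc[a], eigs.loc[b])[0, 1])
            if r >= corr_cut:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for m in directional:
        groups.setdefault(find(m), []).append(m)
    sized = sorted(groups.values(),
                   key=lambda ms: (-sum(len(module_set.genes_in(m)) for m in ms),
                                   ms[0]))
    supermodules = {f"SM{i + 1}": sorted(ms) for i, ms in enumerate(sized)}
    module_set.supermodule = {m: sm for sm, ms in supermodules.items() for m in ms}
    return supermodules


# ---------------------------------------------------------------------------
# Exact set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term: str
    overlap: int          # k
    query_size: int       # n
    term_size: int        # K
    universe_size: int    # N
    p_value: float        # hypergeometric upper tail P[X >= k]
    adjusted_p: float     # Bonferroni


def hypergeom_enrich(query: set[str], term_sets: dict[str, set[str]],
                     universe: set[str]) -> list[EnrichmentResult]:
    """Exact hypergeometric over-representation of each term in the query.

    p = P[X >= k] for X ~ Hypergeometric(N, K, n); Bonferroni-adjusted
    across terms.
    """
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    results = []
    for term, genes in sorted(term_sets.items()):
        members = genes & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, p,
                                        min(1.0, p * len(term_sets))))
    return results


def gene_set_overlap(set_a: set[str], set_b: set[str], universe: set[str]) -> dict:
    """Overlap count, percentage of A, and hypergeometric enrichment p."""
    if not set_a or not set_b:
        raise ValueError("empty gene set")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_b), len(set_a)))
    return {"overlap": k, "percent_of_a": 100.0 * k / len(set_a), "p_value": p}
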