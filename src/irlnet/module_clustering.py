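"""Bidirectional hierarchical clustering of the co-regulation network.

The extracted lncRNA-mRNA network is rendered as an association matrix
(rows = lncRNAs, columns = mRNAs, entry = 1 - p for significant edges and 0
otherwise), both axes are clustered agglomeratively, and the
(row-cluster x column-cluster) block with the highest mean association is
reported as the insulin-resistance-associated module together with the RBPs
shared on its edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .triple_network import Irlmn, TripleNetwork


@dataclass
class HeatmapModule:
    lncrnas: list[str]
    mrnas: list[str]
    rbps: list[str]          # union of shared RBPs over in-module edges
    mean_score: float


def association_matrix(irlmn: Irlmn) -> pd.DataFrame:
    """Dense lncRNA x mRNA matrix of association scores in [0, 1].

    Significant edges score 1 - p (so smaller p means a stronger
    association); untested or non-significant pairs score 0.
    """
    if not irlmn.edges:
        raise ValueError("cannot build an association matrix from an empty network")
    rows = sorted(irlmn.lnc_nodes)
    cols = sorted(irlmn.mrna_nodes)
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for e in irlmn.edges:
        mat.loc[e.lncrna, e.mrna] = 1.0 - e.p
    return mat


def bicluster(
    mat: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Agglomerative clustering of rows and columns; returns both linkages
    and the matrix reordered by dendrogram leaf order.

    Defaults (Euclidean distance, complete linkage) follow the common
    heatmap convention; both are configurable.
    """
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("biclustering needs at least a 2 x 2 matrix")
    values = mat.to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        warnings.warn("association matrix is constant; dendrograms are degenerate")
    row_z = linkage(pdist(values, metric=metric), method=method)
    col_z = linkage(pdist(values.T, metric=metric), method=method)
    ordered = mat.iloc[leaves_list(row_z), leaves_list(col_z)]
    return row_z, col_z, ordered


def extract_module(
    row_z: np.ndarray,
    col_z: np.ndarray,
    mat: pd.DataFrame,
    n_row_clusters: int = 2,
    n_col_clusters: int = 2,
    irlmn: Irlmn | None = None,
) -> HeatmapModule:
    """Cut both dendrograms and return the block with the highest mean score.

    Blocks whose mean scores agree within a small tolerance (1e-3 on the
    0..1 association scale) count as tied; ties break toward the block
    with more cells, then toward the (row-cluster, col-cluster) label pair
    that sorts first.  The module's RBP list is the union of shared-RBP
    sets over the network edges inside the block (empty if the network is
    not supplied).
    """
    if n_row_clusters < 2 or n_col_clusters < 2:
        raise ValueError("cluster counts must be at least 2")
    row_lab = fcluster(row_z, t=n_row_clusters, criterion="maxclust")
    col_lab = fcluster(col_z, t=n_col_clusters, criterion="maxclust")
    values = mat.to_numpy(dtype=float)

    tol = 1e-3
    candidates: list[tuple[float, int, int, int]] = []   # score, size, rl, cl
    for rl in sorted(set(row_lab)):
        for cl in sorted(set(col_lab)):
            block = values[np.ix_(row_lab == rl, col_lab == cl)]
            candidates.append((float(block.mean()), block.size, rl, cl))
    top = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] >= top - tol]
    score, _, rl, cl = max(tied, key=lambda c: (c[1], -c[2], -c[3]))
    if score == 0.0:
        raise ValueError("no associated module: every block has zero mean score")

    lncrnas = sorted(mat.index[row_lab == rl])
    mrnas = sorted(mat.columns[col_lab == cl])
    rbps: set[str] = set()
    if irlmn is not None:
        in_rows, in_cols = set(lncrnas), set(mrnas)
        for e in irlmn.edges:
            if e.lncrna in in_rows and e.mrna in in_cols:
                rbps |= e.shared_rbps
    return HeatmapModule(
        lncrnas=lncrnas, mrnas=mrnas, rbps=sorted(rbps), mean_score=score
    )


def choose_cuts(
    row_z: np.ndarray,
    col_z: np.ndarray,
    mat: pd.DataFrame,
    max_cuts: int = 10,
) -> tuple[int, int]:
    """Choose the row and column cluster counts from the merge-height gaps
    of each dendrogram, considering cuts yielding 2..max_cuts clusters.
    Among cuts whose gap reaches at least half of the largest gap, the
    shallowest (fewest clusters) wins — deep cuts driven by single stray
    entries then lose to the dominant structural separation.  Association
    scores are nearly binary, so variance-ratio indices degenerate (pure
    blocks have zero within-variance and always reward deeper cuts); the
    dendrogram gap does not.  Falls back to 2 clusters on degenerate
    trees."""

    def best_k(z: np.ndarray) -> int:
        heights = z[:, 2]
        n_merges = len(heights)
        gaps: dict[int, float] = {}
        for i in range(n_merges - 1):
            k = n_merges - i            # clusters when cutting above merge i
            if 2 <= k <= max_cuts:
                gaps[k] = heights[i + 1] - heights[i]
        if not gaps or max(gaps.values()) <= 0:
            return 2
        cutoff = 0.5 * max(gaps.values())
        return min(k for k, g in gaps.items() if g >= cutoff)

    return best_k(row_z), best_k(col_z)


def module_rbp_table(module: HeatmapModule, net: TripleNetwork) -> pd.DataFrame:
    """Per-lncRNA binding proteins restricted to the module's mRNA partners.

    Mirrors the familiar three-column hub-lncRNA table: gene, type, binding
    proteins (comma-separated).
    """
    module_mrna_rbps: set[str] = set()
    for mr in module.mrnas:
        module_mrna_rbps |= net.mrna_to_rbp.get(mr, frozenset())
    rows = []
    for lnc in module.lncrnas:
        bound = net.lnc_to_rbp.get(lnc, frozenset()) & module_mrna_rbps
        rows.append({
            "gene": lnc,
            "type": "lncRNA",
            "binding_proteins": ",".join(sorted(bound)),
        })
    return pd.DataFrame(rows, columns=["gene", "type", "binding_proteins"])
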