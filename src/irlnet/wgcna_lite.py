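"""Weighted co-expression network analysis, implemented from first principles.

Pipeline: sample-outlier removal on a sample dendrogram; soft-threshold
power selection by the scale-free topology fit; unsigned adjacency
``a_ij = |cor(x_i, x_j)|^beta``; topological overlap similarity

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``k_i = sum_{u != i} a_iu``; average-linkage clustering of ``1 - TOM``
cut at a static height with a minimum module size; module eigengenes (first
principal component of the standardized member submatrix, sign-anchored);
eigengene-dissimilarity module merging; eigengene-trait correlation; and
intramodular connectivity (kWithin) for hub ranking.

Defaults follow the common operating point for small-cohort microarray
studies: beta = 15 at a scale-free fit target of R^2 = 0.75, minimum module
size 30, merge height 0.10, unsigned Pearson adjacency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class WgcnaParams:
    beta: float = 15.0
    r2_target: float = 0.75
    min_module_size: int = 30
    merge_height: float = 0.10
    max_branches: int = 30            # upper bound on the tree-cut scan
    outlier_cut_height: float | None = None   # None -> mean + 2.5 SD of merge heights

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.r2_target < 1 or not 0 < self.merge_height < 1:
            raise ValueError("r2_target and merge_height must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleAssignment:
    """Feature -> module labels with eigengenes and derived statistics."""

    labels: pd.Series                      # feature -> module name (grey = none)
    eigengenes: pd.DataFrame               # samples x modules, unit norm
    trait_stats: pd.DataFrame | None = None   # module -> (r2, p)
    k_within: pd.Series | None = None

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def remove_outlier_samples(
    matrix: pd.DataFrame,
    cut_height: float | None = None,
    min_branch_size: int = 3,
) -> tuple[list[str], list[str]]:
    """Drop samples on outlying branches of the sample dendrogram.

    Samples (columns) are clustered by average linkage on Euclidean
    distance and the tree is cut at ``cut_height`` (default: mean + 2.5 SD
    of the merge heights).  Branches smaller than ``min_branch_size`` at
    the cut are treated as abnormal and dropped; if every branch is small,
    the largest one is retained.  Returns (retained, dropped).
    """
    if matrix.shape[1] < 4:
        raise ValueError("outlier removal needs at least 4 samples")
    d = pdist(matrix.to_numpy().T, metric="euclidean")
    z = linkage(d, method="average")
    if cut_height is None:
        heights = z[:, 2]
        cut_height = float(heights.mean() + 2.5 * heights.std(ddof=0))
    clusters = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(clusters).value_counts()
    keep = set(sizes.index[sizes >= min_branch_size])
    if not keep:
        keep = {sizes.idxmax()}
    retained = [s for s, c in zip(matrix.columns, clusters) if c in keep]
    dropped = [s for s in matrix.columns if s not in set(retained)]
    if not retained:
        raise ValueError("outlier cut removed every sample")
    if dropped:
        log.info("removed %d outlier samples: %s", len(dropped), dropped)
    return retained, dropped


# ---------------------------------------------------------------------------
# adjacency / soft threshold / TOM
# ---------------------------------------------------------------------------

def _abs_correlation(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        log.warning("%d zero-variance features: correlations set to 0", zero_var.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[np.isnan(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.abs(c)


def adjacency(matrix: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|^beta with unit diagonal."""
    if matrix.shape[0] < 2:
        raise ValueError("adjacency needs at least 2 features")
    a = _abs_correlation(matrix) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) against log10 k over binned connectivity.

    Negative when the regression slope is positive (connectivity increasing
    with frequency is the opposite of scale-free topology).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    slope = np.polyfit(xs, ys, 1)[0]
    r2 = float(np.corrcoef(xs, ys)[0, 1] ** 2)
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    matrix: pd.DataFrame,
    beta_grid: tuple[float, ...] = tuple(range(1, 21)),
    r2_target: float = 0.75,
) -> tuple[float, pd.DataFrame]:
    """Smallest beta whose scale-free fit reaches the target (else argmax).

    Returns the chosen beta and the full fit table (beta, r2, mean_k, max_k).
    """
    if not beta_grid:
        raise ValueError("beta grid is empty")
    if matrix.shape[0] < 10:
        raise ValueError("soft-threshold fit needs at least 10 features")
    absc = _abs_correlation(matrix)
    rows = []
    for beta in beta_grid:
        a = absc**beta
        k = a.sum(axis=1) - 1.0
        rows.append({
            "beta": beta,
            "r2": scale_free_fit(k),
            "mean_k": float(k.mean()),
            "max_k": float(k.max()),
        })
    fit = pd.DataFrame(rows)
    reaching = fit[fit["r2"] >= r2_target]
    beta = float(reaching.iloc[0]["beta"]) if len(reaching) else float(
        fit.loc[fit["r2"].idxmax(), "beta"]
    )
    return beta, fit


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix (unit diagonal)."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1) - 1.0
    # shared-neighbor term: (A @ A)_ij includes u = i and u = j, each
    # contributing a_ij (diagonal is 1), so subtract 2 a_ij
    shared = a @ a - 2.0 * a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def detect_modules(tom: pd.DataFrame, params: WgcnaParams) -> pd.Series:
    """Branch detection on the average-linkage tree of 1 - TOM.

    The tree is scanned over increasingly deep cuts and the partition
    maximizing the number of branches with at least ``min_module_size``
    members wins (ties: the deepest such cut, so undersized side branches
    go grey instead of being absorbed into a neighbouring module).
    Features falling on undersized branches are grey.  Splitting is
    deliberately aggressive — a homogeneous branch larger than twice the
    minimum size may be subdivided — because the subsequent eigengene
    merge step re-fuses such fragments (their eigengenes are nearly
    collinear), while a fixed cut height cannot separate genuinely
    distinct branches whose merge heights vary with sampling noise.
    Modules are named M1, M2, ... in decreasing size order.
    """
    dis = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dis, 0.0)
    z = linkage(squareform(dis, checks=False), method="average")
    n = tom.shape[0]
    best_key: tuple[int, int, int] | None = None
    best_clusters: np.ndarray | None = None
    k_max = min(params.max_branches, max(2, n // params.min_module_size + 2), n)
    for k in range(1, k_max + 1):
        clusters = fcluster(z, t=k, criterion="maxclust")
        sizes = pd.Series(clusters).value_counts()
        n_big = int((sizes >= params.min_module_size).sum())
        key = (-n_big, -k)
        if best_key is None or key < best_key:
            best_key, best_clusters = key, clusters
    assert best_clusters is not None
    labels = pd.Series(GREY, index=tom.index, name="module")
    sizes = pd.Series(best_clusters).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    if not kept:
        warnings.warn("no branch reaches the minimum module size; all grey")
    for rank, c in enumerate(sorted(kept, key=lambda c: (-sizes[c], c)), start=1):
        labels.iloc[np.nonzero(best_clusters == c)[0]] = f"M{rank}"
    return _reassign_grey(tom, labels)


def _reassign_grey(tom: pd.DataFrame, labels: pd.Series,
                   support: float = 0.3) -> pd.Series:
    """Medoid-style rescue of unassigned features.

    A grey feature joins the module to which its mean topological overlap
    is highest, provided that overlap reaches ``support`` times the
    module's internal mean overlap; genuinely unconnected features stay
    grey.  This mirrors the partitioning-around-medoids stage of hybrid
    branch cutting and repairs fragments that the tree cut carved off a
    module."""
    modules = sorted(set(labels) - {GREY})
    if not modules:
        return labels
    t = tom.to_numpy(dtype=float)
    member_idx = {m: np.nonzero((labels == m).to_numpy())[0] for m in modules}
    internal = {}
    for m, idx in member_idx.items():
        sub = t[np.ix_(idx, idx)]
        internal[m] = (sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1))
    labels = labels.copy()
    for i in np.nonzero((labels == GREY).to_numpy())[0]:
        scores = {m: t[i, idx].mean() for m, idx in member_idx.items()}
        best = max(scores, key=scores.get)
        if internal[best] > 0 and scores[best] >= support * internal[best]:
            labels.iloc[i] = best
    return labels


def module_eigengene(matrix: pd.DataFrame, members) -> pd.Series:
    """First principal component of the standardized member submatrix.

    Unit norm over samples; sign anchored so that the average member
    correlation with the eigengene is positive.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("module eigengene needs at least 2 members")
    sub = matrix.loc[members].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    std = (sub - mu) / sd
    # first right singular vector = per-sample component scores
    _, _, vt = np.linalg.svd(std, full_matrices=False)
    eig = vt[0]
    cors = std @ eig / (np.linalg.norm(eig) * np.sqrt(std.shape[1]))
    if cors.mean() < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    return pd.Series(eig, index=matrix.columns)


def _eigengene_frame(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    modules = sorted(set(labels) - {GREY})
    data = {
        m: module_eigengene(matrix, labels.index[labels == m]) for m in modules
    }
    return pd.DataFrame(data, index=matrix.columns)


def merge_modules(
    labels: pd.Series, matrix: pd.DataFrame, merge_height: float = 0.10
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge modules whose eigengene dissimilarity (1 - cor)
    falls below ``merge_height``; eigengenes are recomputed after each
    merge until a fixed point is reached.  Returns (labels, eigengenes)."""
    labels = labels.copy()
    while True:
        eigs = _eigengene_frame(matrix, labels)
        modules = list(eigs.columns)
        if len(modules) < 2:
            return labels, eigs
        cor = np.corrcoef(eigs.to_numpy().T)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_height:
            return labels, eigs
        keep, absorb = sorted((modules[i], modules[j]))
        labels[labels == absorb] = keep
        log.info("merged module %s into %s (dissimilarity %.3f)",
                 absorb, keep, dis[i, j])


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Squared Pearson correlation and two-sided p per module eigengene.

    The trait (numeric, or a binary group encoded 0/1) must cover every
    retained sample; p comes from the t-distribution with n - 2 df.
    """
    trait = trait.loc[eigengenes.index].astype(float)
    if trait.std() == 0:
        raise ValueError("trait is constant across retained samples")
    rows = []
    for m in eigengenes.columns:
        r, p = pearsonr(eigengenes[m], trait)
        rows.append({"module": m, "r2": r**2, "p": p})
    return pd.DataFrame(rows, columns=["module", "r2", "p"]).set_index("module")


def hub_weights(
    adj: pd.DataFrame,
    labels: pd.Series,
    module: str,
    top_k: int | None = None,
    biotype: pd.Series | None = None,
    restrict_biotype: str | None = None,
) -> pd.DataFrame:
    """Intramodular connectivity ranking of a module's members.

    kWithin(f) = sum of f's adjacency to other members of its module.
    Optionally restrict the report to one biotype (e.g. the top lncRNA
    hubs) before truncating to ``top_k``.
    """
    if module == GREY:
        raise ValueError("grey is not a module")
    members = list(labels.index[labels == module])
    if not members:
        raise ValueError(f"module {module!r} has no members")
    sub = adj.loc[members, members].to_numpy(dtype=float)
    kw = sub.sum(axis=1) - 1.0          # exclude the unit self-adjacency
    out = pd.DataFrame({"feature": members, "module": module, "k_within": kw})
    if biotype is not None and restrict_biotype is not None:
        out = out[out["feature"].map(biotype) == restrict_biotype]
    out = out.sort_values(
        ["k_within", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_k is not None:
        if top_k > len(out):
            warnings.warn(
                f"top_k={top_k} exceeds the {len(out)} eligible members; returning all"
            )
        out = out.head(top_k)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_wgcna(
    matrix: pd.DataFrame,
    trait: pd.Series,
    params: WgcnaParams | None = None,
    remove_outliers: bool = True,
) -> tuple[ModuleAssignment, pd.DataFrame, list[str]]:
    """Full analysis; returns (assignment, adjacency, dropped samples)."""
    params = params or WgcnaParams()
    dropped: list[str] = []
    if remove_outliers:
        retained, dropped = remove_outlier_samples(
            matrix, cut_height=params.outlier_cut_height
        )
        matrix = matrix[retained]
    adj = adjacency(matrix, params.beta)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, params)
    if set(labels) == {GREY}:
        return (
            ModuleAssignment(labels=labels,
                             eigengenes=pd.DataFrame(index=matrix.columns)),
            adj, dropped,
        )
    labels, eigs = merge_modules(labels, matrix, params.merge_height)
    trait_stats = module_trait_correlation(eigs, trait)
    kw = pd.concat([
        hub_weights(adj, labels, m).set_index("feature")["k_within"]
        for m in eigs.columns
    ]) if len(eigs.columns) else pd.Series(dtype=float)
    return (
        ModuleAssignment(labels=labels, eigengenes=eigs,
                         trait_stats=trait_stats, k_within=kw),
        adj, dropped,
    )
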