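"""Signed weighted coexpression network and module detection.

The input is a genes × conditions matrix of log2 fold changes.  Pairwise
Spearman correlations are soft-thresholded into a signed adjacency
a_ij = ((1 + ρ_ij)/2)^β (β = 18 by default), combined into a topological
overlap matrix (TOM), and modules are obtained by average-linkage
hierarchical clustering of the TOM distance with a static quantile tree cut
— a deterministic stand-in for the dynamic hybrid tree-cut algorithm.
Clusters smaller than ``min_module_size`` are left unassigned ("grey");
modules are named by size rank with the conventional WGCNA color sequence
(largest = "turquoise").  Modules whose eigengenes are more similar than
``merge_cut_height`` (1 − cor) are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import DesignError, ParameterError

#: WGCNA's conventional module color order, by decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

UNASSIGNED = "grey"


@dataclass(frozen=True)
class NetworkParams:
    """Coexpression network parameters (defaults are the study's values)."""

    beta: float = 18.0
    min_module_size: int = 25
    merge_cut_height: float = 0.05
    edge_weight_cutoff: float = 0.2
    tree_cut: str = "gap"          # "gap" (largest-gap midpoint) or "quantile"
    tree_cut_quantile: float = 0.99

    def __post_init__(self):
        if self.beta < 1:
            raise ParameterError("beta must be >= 1")
        for name in ("merge_cut_height", "edge_weight_cutoff", "tree_cut_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1.1:
                raise ParameterError(f"{name} out of range: {v}")


def drop_zero_variance(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant rows (Spearman undefined) with a warning."""
    var = X.var(axis=1)
    bad = var == 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} zero-variance gene(s) before correlation")
        X = X.loc[~bad]
    return X


def signed_adjacency(X: pd.DataFrame, params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Signed soft-thresholded adjacency from Spearman correlation.

    a_ij = ((1 + ρ_ij)/2)^β with average-rank ties.  Requires >= 4 conditions.
    """
    if X.shape[1] < 4:
        raise DesignError("need >= 4 conditions for a coexpression network")
    X = drop_zero_variance(X)
    ranks = X.rank(axis=1).to_numpy(dtype=float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norm, norm)
    np.clip(rho, -1.0, 1.0, out=rho)
    adj = ((1.0 + rho) / 2.0) ** params.beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=X.index, columns=X.index)


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float) if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T):
        raise ParameterError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame,
    params: NetworkParams = NetworkParams(),
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage clustering of 1 − TOM with a static cut.

    The default cut is the midpoint of the largest gap between consecutive
    sorted merge heights: tight within-module merges happen well below the
    near-flat band where unrelated genes attach, so the widest gap separates
    the two regimes deterministically.  ``tree_cut="quantile"`` instead cuts
    at the ``tree_cut_quantile`` of merge heights.  Clusters below
    ``min_module_size`` are unassigned.  Returns (labels, linkage matrix);
    labels use WGCNA color names by descending module size.
    """
    genes = list(tom.index)
    n = len(genes)
    if n < 2:
        return pd.Series([UNASSIGNED] * n, index=genes, name="module"), np.empty((0, 4))
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize fp noise for squareform
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    if params.tree_cut == "quantile":
        cut = float(np.quantile(heights, params.tree_cut_quantile))
    else:
        hs = np.sort(heights)
        if hs[-1] - hs[0] <= 0:
            cut = hs[-1] + 1.0  # flat dendrogram: one cluster
        else:
            gaps = np.diff(hs)
            i = int(np.argmax(gaps))
            cut = float((hs[i] + hs[i + 1]) / 2.0)
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = _label_by_size(flat, genes, params.min_module_size)
    return labels, Z


def _label_by_size(flat: np.ndarray, genes: list, min_size: int) -> pd.Series:
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    keep.sort(key=lambda c: (-sizes[c], c))
    color = {c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
             for i, c in enumerate(keep)}
    out = [color.get(c, UNASSIGNED) for c in flat]
    return pd.Series(out, index=genes, name="module")


def module_eigengene(
    X: pd.DataFrame,
    modules: pd.Series,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """First principal component of each module's z-scored submatrix.

    Returns (eigengenes: modules × conditions with unit norm, variance
    explained per module).  The sign is oriented so the eigengene correlates
    non-negatively with the module's mean z-scored profile.  One-gene modules
    get that gene's z-profile.
    """
    eigengenes = {}
    varexp = {}
    for mod in sorted(set(modules) - {UNASSIGNED}):
        sub = X.loc[modules[modules == mod].index].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eigengenes[mod] = e / np.linalg.norm(e)
        varexp[mod] = float(s[0] ** 2 / (s ** 2).sum())
    E = pd.DataFrame(eigengenes, index=X.columns).T
    E.index.name = "module"
    return E, varexp


def relative_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Per-gene profile minus its row mean (expression relative to the mean)."""
    return X.sub(X.mean(axis=1), axis=0)


def merge_modules(
    X: pd.DataFrame,
    modules: pd.Series,
    merge_cut_height: float = 0.05,
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < cut height.

    1 − cor(E_a, E_b) < merge_cut_height triggers a merge (closest pair
    first); eigengenes are recomputed after every merge, so the result is
    independent of initial pair ordering.  Merged modules keep the name of
    the larger member; labels are re-ranked by size at the end.
    """
    modules = modules.copy()
    while True:
        mods = sorted(set(modules) - {UNASSIGNED})
        if len(mods) < 2:
            break
        E, _ = module_eigengene(X, modules)
        C = np.corrcoef(E.loc[mods].to_numpy())
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        a, b = mods[i], mods[j]
        big, small = (a, b) if (modules == a).sum() >= (modules == b).sum() else (b, a)
        modules[modules == small] = big
    # re-rank colors by final size
    flat, genes = modules.to_numpy(), list(modules.index)
    name_to_int = {m: i + 1 for i, m in enumerate(sorted(set(flat) - {UNASSIGNED}))}
    ints = np.array([name_to_int.get(m, 0) for m in flat])
    relabeled = _label_by_size(ints[ints > 0], [g for g, v in zip(genes, ints) if v > 0], 1)
    out = pd.Series(UNASSIGNED, index=genes, name="module")
    out.loc[relabeled.index] = relabeled
    return out


def export_network(
    tom: pd.DataFrame,
    modules: pd.Series,
    edge_weight_cutoff: float = 0.2,
    module: str | list[str] | None = None,
) -> tuple[pd.DataFrame, list]:
    """Weighted edge list (TOM >= cutoff) within the selected module(s).

    Returns (edges, nodes); isolated nodes are retained in ``nodes`` with no
    incident edge.  Each undirected edge appears once, endpoints sorted.
    """
    if module is None:
        selected = sorted(set(modules) - {UNASSIGNED})
    elif isinstance(module, str):
        selected = [module]
    else:
        selected = list(module)
    rows = []
    nodes = []
    for mod in selected:
        genes = list(modules[modules == mod].index)
        nodes.extend(genes)
        sub = tom.loc[genes, genes].to_numpy(dtype=float)
        iu, ju = np.triu_indices(len(genes), k=1)
        mask = sub[iu, ju] >= edge_weight_cutoff
        for a, b, w in zip(iu[mask], ju[mask], sub[iu, ju][mask]):
            g1, g2 = sorted((genes[a], genes[b]))
            rows.append((g1, g2, float(w), mod))
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "weight", "module"])
    return edges, nodes
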