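"""Stretched pseudotime, branch x decile stratification, and a simplified
MST-based bifurcation inference.

Stretched pseudotime maps every root-to-leaf path (P->U and P->L) onto
[0, 100] so that the path minimum is 0 and each path maximum is 100,
while cells shared by both paths (the progenitor segment) receive a
single common value.  This is achieved by a two-segment piecewise-linear
map: the progenitor segment [min, branch point] is scaled onto [0, S]
with S the branch point's global min-max position, and each leaf segment
onto [S, 100].  With a single path the map reduces to plain min-max
scaling.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_qc import NormalizedMatrix, scale_values

logger = logging.getLogger(__name__)

__all__ = ["stretch_pseudotime", "stratify_deciles", "infer_bifurcation"]

BRANCHES = ("P", "U", "L")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("path with all-equal raw pseudotime")
    return (x - lo) / (hi - lo) * 100.0


def stretch_pseudotime(meta: pd.DataFrame, raw_col: str = "pseudotime_raw",
                       branch_col: str = "branch") -> pd.DataFrame:
    """Return a copy of ``meta`` with a ``pseudotime_stretched`` column.

    Requires finite non-negative raw pseudotime.  Raises on a path whose
    raw pseudotime has no spread.
    """
    t = meta[raw_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("raw pseudotime must be finite")
    if np.any(t < 0):
        raise ValueError("raw pseudotime must be >= 0")
    branch = meta[branch_col].astype(str).to_numpy()
    out = meta.copy()

    present = [b for b in BRANCHES if (branch == b).any()]
    leaves = [b for b in ("U", "L") if b in present]
    has_p = "P" in present

    if len(present) <= 1 or (not has_p and len(leaves) == 1):
        # one path only
        out["pseudotime_stretched"] = _minmax(t)
        return out
    if not has_p:
        # two disconnected paths: scale each independently
        s = np.empty_like(t)
        for b in leaves:
            m = branch == b
            s[m] = _minmax(t[m])
        out["pseudotime_stretched"] = s
        return out
    if len(leaves) == 1:
        # single root-to-leaf path through P
        out["pseudotime_stretched"] = _minmax(t)
        return out

    # full bifurcation: two-segment map, shared P values on both paths
    p_mask = branch == "P"
    t0 = t.min()
    t_bp = t[p_mask].max()
    t_max = t.max()
    if t_max == t0:
        raise ValueError("path with all-equal raw pseudotime")
    s_bp = 100.0 * (t_bp - t0) / (t_max - t0)
    s = np.empty_like(t)
    if t_bp == t0:
        s[p_mask] = 0.0
    else:
        s[p_mask] = (t[p_mask] - t0) / (t_bp - t0) * s_bp
    for b in leaves:
        m = branch == b
        tb = t[m].max()
        if tb <= t_bp:
            raise ValueError(
                f"path P->{b} has no raw-pseudotime spread beyond the "
                "branch point")
        s[m] = s_bp + (t[m] - t_bp) / (tb - t_bp) * (100.0 - s_bp)
    out["pseudotime_stretched"] = s
    return out


def stratify_deciles(meta: pd.DataFrame, n_bins: int = 10,
                     branch_col: str = "branch",
                     time_col: str = "pseudotime_stretched") -> pd.DataFrame:
    """Bin cells of each branch into ``n_bins`` pseudotime quantile bins.

    Bins are balanced rank bins (occupancy differs by at most one cell
    within a branch) with ties broken by cell id for determinism.
    Returns a frame with columns cell_id, branch, decile, stratum.
    """
    rows = []
    for b, sub in meta.groupby(branch_col, sort=True):
        n = len(sub)
        if n < n_bins:
            raise ValueError(
                f"branch {b!r} has {n} cells < {n_bins} bins; "
                "lower the bin count")
        order = np.lexsort((sub["cell_id"].to_numpy(),
                            sub[time_col].to_numpy(dtype=float)))
        decile = np.empty(n, dtype=int)
        decile[order] = np.arange(n) * n_bins // n + 1
        rows.append(pd.DataFrame({
            "cell_id": sub["cell_id"].to_numpy(),
            "branch": b,
            "decile": decile,
        }))
    out = pd.concat(rows, ignore_index=True)
    out["stratum"] = out["branch"].astype(str) + "_" + out["decile"].astype(str)
    return out


def _mst_graph(centroids: np.ndarray) -> nx.Graph:
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    mst = minimum_spanning_tree(dist).toarray()
    g = nx.Graph()
    g.add_nodes_from(range(len(centroids)))
    for i, j in zip(*np.nonzero(mst)):
        g.add_edge(int(i), int(j), weight=float(dist[i, j]))
    return g


def _pick_root(g: nx.Graph, centroids: np.ndarray,
               pcs: np.ndarray, root_cell_mask: np.ndarray | None) -> int:
    if root_cell_mask is not None and root_cell_mask.any():
        anchor = pcs[root_cell_mask].mean(axis=0)
        return int(np.argmin(((centroids - anchor) ** 2).sum(axis=1)))
    # most distal leaf: endpoint of the weighted diameter
    ecc = {}
    for v in g.nodes:
        ecc[v] = max(nx.single_source_dijkstra_path_length(
            g, v, weight="weight").values())
    leaves = sorted(v for v in g.nodes if g.degree[v] == 1)
    if not leaves:
        leaves = sorted(g.nodes)
    return max(leaves, key=lambda v: (ecc[v], -v))


def _pick_branch_node(g: nx.Graph, root: int,
                      cells_per_node: np.ndarray) -> int | None:
    """Degree>=3 node whose two largest off-root subtrees are most balanced."""
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    best, best_key = None, None
    for v in g.nodes:
        if g.degree[v] < 3:
            continue
        h = g.copy()
        h.remove_node(v)
        comps = list(nx.connected_components(h))
        off = [c for c in comps if root not in c]
        if len(off) < 2:
            continue
        sizes = sorted((int(cells_per_node[list(c)].sum()) for c in off),
                       reverse=True)
        key = (min(sizes[0], sizes[1]), -dist[v])
        if best_key is None or key > best_key:
            best, best_key = v, key
    return best


def infer_bifurcation(nm: NormalizedMatrix, n_pcs: int = 15,
                      n_clusters: int = 12, n_top_genes: int = 2000,
                      root_cells=None, u_markers=None,
                      random_state: int = 0) -> pd.DataFrame:
    """Simplified bifurcation inference: PCA -> k-means -> MST.

    The root centroid is the one nearest the designated early cells (or
    the most distal leaf when unlabeled); the degree->=3 MST node on the
    path defines the branch point.  Cells map to P before it and to the
    two subtrees (U/L) after it; raw pseudotime is the tree geodesic from
    the root plus the cell's scalar projection onto its centroid's
    incoming edge.  Branch orientation: the side with higher mean
    expression of ``u_markers`` is called U when markers are supplied.
    """
    values = nm.values
    n_cells, n_genes = values.shape
    var = values.var(axis=0)
    top = np.argsort(var)[::-1][:min(n_top_genes, n_genes)]
    sub = NormalizedMatrix(values=values[:, top], gene_ids=nm.gene_ids[top],
                           cell_ids=nm.cell_ids, transform=nm.transform)
    z = scale_values(sub).values
    n_comp = min(n_pcs, min(z.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full",
              random_state=random_state).fit_transform(z)
    k = min(n_clusters, n_cells)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(pcs)
    labels = km.labels_
    centroids = km.cluster_centers_
    cells_per_node = np.bincount(labels, minlength=k)

    g = _mst_graph(centroids)
    root_mask = None
    if root_cells is not None:
        root_set = set(map(str, root_cells))
        root_mask = np.array([str(c) in root_set for c in nm.cell_ids])
    root = _pick_root(g, centroids, pcs, root_mask)

    bp = _pick_branch_node(g, root, cells_per_node)
    node_branch = np.full(k, "P", dtype=object)
    if bp is None:
        warnings.warn("no branch point found (tree has no degree->=3 node); "
                      "all cells assigned to P")
    else:
        h = g.copy()
        h.remove_node(bp)
        comps = list(nx.connected_components(h))
        off = sorted((c for c in comps if root not in c),
                     key=lambda c: (-int(cells_per_node[list(c)].sum()),
                                    min(c)))
        side_a, side_b = set(off[0]), set(off[1])
        for extra in off[2:]:
            # merge stray subtrees into the nearer main side
            ca = centroids[list(side_a)].mean(axis=0)
            cb = centroids[list(side_b)].mean(axis=0)
            ce = centroids[list(extra)].mean(axis=0)
            if ((ce - ca) ** 2).sum() <= ((ce - cb) ** 2).sum():
                side_a |= set(extra)
            else:
                side_b |= set(extra)
        # orientation
        u_side, l_side = side_a, side_b
        if u_markers is not None:
            marker_idx = [i for i, gid in enumerate(nm.gene_ids)
                          if str(gid) in set(map(str, u_markers))]
            if marker_idx:
                mean_a = values[np.isin(labels, list(side_a))][:, marker_idx].mean()
                mean_b = values[np.isin(labels, list(side_b))][:, marker_idx].mean()
                if mean_b > mean_a:
                    u_side, l_side = side_b, side_a
        node_branch[list(u_side)] = "U"
        node_branch[list(l_side)] = "L"

    # pseudotime: geodesic to the centroid plus projection on incoming edge
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    paths = nx.single_source_dijkstra_path(g, root, weight="weight")
    pt = np.empty(n_cells)
    for node in range(k):
        m = labels == node
        if not m.any():
            continue
        if node == root:
            nbrs = sorted(g.neighbors(root),
                          key=lambda v: -cells_per_node[v])
            ref = centroids[nbrs[0]] if nbrs else centroids[root] + 1.0
            direction = ref - centroids[root]
        else:
            parent = paths[node][-2]
            direction = centroids[node] - centroids[parent]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction
        proj = (pcs[m] - centroids[node]) @ direction
        pt[m] = dist[node] + proj
    pt -= pt.min()

    return pd.DataFrame({
        "cell_id": nm.cell_ids,
        "pseudotime_raw": pt,
        "branch": node_branch[labels],
    })
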