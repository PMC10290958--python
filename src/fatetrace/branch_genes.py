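"""Branch-dependent gene testing, significance/effect filtering and
kinetic clustering.

The test contrasts a full model ``expr ~ spline(t) + branch +
spline(t):branch`` against the reduced ``expr ~ spline(t)`` on U/L cells
only, via a likelihood ratio with a chi-square reference whose degrees
of freedom equal the parameter-count difference.  The default family is
gaussian-on-log expression (fully vectorized across genes); a
negative-binomial GLM per gene is available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "natural_spline_basis",
    "bh_qvalues",
    "avg_logfc",
    "fit_branch_test",
    "filter_branch_genes",
    "kinetic_clusters",
]


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Knots at ``df + 1`` equally spaced quantiles of ``x`` (boundary knots
    included).  Uses the standard reduced truncated-power construction,
    linear beyond the boundary knots.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("cannot build a spline basis on constant x")
    xs = (x - x.min()) / span
    if df == 1:
        return xs[:, None]
    n_knots = df + 1
    knots = np.quantile(xs, np.linspace(0, 1, n_knots))
    knots = np.unique(knots)
    while len(knots) < n_knots:  # degenerate quantiles: pad evenly
        knots = np.linspace(xs.min(), xs.max(), n_knots)
        break
    kK = knots[-1]
    kK1 = knots[-2]

    def d(k):
        return (np.clip(xs - k, 0, None) ** 3
                - np.clip(xs - kK, 0, None) ** 3) / (kK - k)

    dK1 = d(kK1)
    cols = [xs] + [d(knots[j]) - dK1 for j in range(len(knots) - 2)]
    return np.column_stack(cols)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _ul_subset(expr_values: np.ndarray, meta: pd.DataFrame,
               cell_ids: np.ndarray):
    meta_idx = meta.set_index("cell_id").loc[list(map(str, cell_ids))]
    branch = meta_idx["branch"].astype(str).to_numpy()
    t = meta_idx["pseudotime_stretched"].to_numpy(dtype=float)
    mask = np.isin(branch, ("U", "L"))
    return expr_values[mask], t[mask], branch[mask]


def avg_logfc(expr, meta: pd.DataFrame) -> pd.Series:
    """Per-gene mean over U cells minus mean over L cells (log space)."""
    values, gene_ids, cell_ids = _unpack(expr)
    y, _, branch = _ul_subset(values, meta, cell_ids)
    u = branch == "U"
    l = branch == "L"
    if not u.any() or not l.any():
        raise ValueError("both U and L branches must be non-empty")
    lfc = y[u].mean(axis=0) - y[l].mean(axis=0)
    return pd.Series(lfc, index=pd.Index(gene_ids, name="gene_id"))


def _unpack(expr):
    """Accept a NormalizedMatrix or (values, gene_ids, cell_ids)."""
    if hasattr(expr, "values") and hasattr(expr, "gene_ids"):
        return expr.values, expr.gene_ids, expr.cell_ids
    values, gene_ids, cell_ids = expr
    return np.asarray(values, float), np.asarray(gene_ids), np.asarray(cell_ids)


def fit_branch_test(expr, meta: pd.DataFrame, spline_df: int = 3,
                    family: str = "gaussian", q_max: float = 0.05,
                    lfc_min: float = 0.3, counts=None,
                    nb_alpha: float = 0.5) -> pd.DataFrame:
    """Likelihood-ratio test for branch-dependent expression per gene.

    P-branch cells are excluded; the contrast is strictly U versus L.
    Returns a frame with gene_id, lr, p, q, avg_logfc, significant and a
    kinetic_cluster placeholder.
    """
    if family not in ("gaussian", "nb"):
        raise ValueError(f"unknown family {family!r}")
    values, gene_ids, cell_ids = _unpack(expr)
    y, t, branch = _ul_subset(values, meta, cell_ids)
    n = len(t)
    if n == 0:
        raise ValueError("no U/L cells available")
    b = (branch == "U").astype(float)
    B = natural_spline_basis(t, spline_df)
    ones = np.ones((n, 1))
    X_red = np.hstack([ones, B])
    X_full = np.hstack([ones, B, b[:, None], B * b[:, None]])
    ddiff = X_full.shape[1] - X_red.shape[1]

    gene_var = y.var(axis=0)
    if family == "gaussian":
        lr, p = _gaussian_lrt(y, X_red, X_full, ddiff)
    else:
        lr, p = _nb_lrt(y, X_red, X_full, ddiff, counts, nb_alpha,
                        cell_ids, meta)
    zero = gene_var == 0
    if zero.any():
        logger.info("%d zero-variance genes set to p=1", int(zero.sum()))
        lr[zero] = 0.0
        p[zero] = 1.0

    q = bh_qvalues(p)
    u = b == 1
    lfc = y[u].mean(axis=0) - y[~u].mean(axis=0)
    res = pd.DataFrame({
        "gene_id": gene_ids,
        "lr": lr,
        "p": p,
        "q": q,
        "avg_logfc": lfc,
    })
    res["significant"] = (res["q"] < q_max) & (res["avg_logfc"].abs() > lfc_min)
    res["kinetic_cluster"] = pd.array([pd.NA] * len(res), dtype="Int64")
    return res


def _gaussian_lrt(y, X_red, X_full, ddiff):
    n = y.shape[0]
    qr_r, _ = np.linalg.qr(X_red)
    qr_f, _ = np.linalg.qr(X_full)
    yty = (y ** 2).sum(axis=0)
    rss_red = np.maximum(yty - ((qr_r.T @ y) ** 2).sum(axis=0), 1e-12)
    rss_full = np.maximum(yty - ((qr_f.T @ y) ** 2).sum(axis=0), 1e-12)
    lr = np.maximum(n * (np.log(rss_red) - np.log(rss_full)), 0.0)
    p = chi2.sf(lr, ddiff)
    return lr, p


def _nb_lrt(y, X_red, X_full, ddiff, counts, nb_alpha, cell_ids, meta):
    """Per-gene negative-binomial GLM likelihood ratio (slow path)."""
    import statsmodels.api as sm

    if counts is None:
        raise ValueError("family='nb' requires the raw counts matrix")
    cvals, _, c_cells = _unpack(counts)
    if hasattr(cvals, "toarray"):
        cvals = cvals.toarray()
    sub, _, _ = _ul_subset(np.asarray(cvals, dtype=float), meta, c_cells)
    libsize = sub.sum(axis=1)
    offset = np.log(np.maximum(libsize, 1.0))
    fam = sm.families.NegativeBinomial(alpha=nb_alpha)
    n_genes = sub.shape[1]
    lr = np.zeros(n_genes)
    p = np.ones(n_genes)
    for j in range(n_genes):
        yj = sub[:, j]
        if yj.var() == 0:
            continue
        try:
            llf_full = sm.GLM(yj, X_full, family=fam,
                              offset=offset).fit().llf
            llf_red = sm.GLM(yj, X_red, family=fam,
                             offset=offset).fit().llf
            lr[j] = max(2.0 * (llf_full - llf_red), 0.0)
            p[j] = chi2.sf(lr[j], ddiff)
        except Exception:  # noqa: BLE001 - non-convergence -> no call
            logger.warning("NB GLM failed for gene index %d; p set to 1", j)
            lr[j], p[j] = 0.0, 1.0
    return lr, p


def filter_branch_genes(results: pd.DataFrame, q_max: float = 0.05,
                        lfc_min: float = 0.3) -> list[str]:
    """Genes with q < q_max and |avg_logfc| > lfc_min (strict)."""
    keep = (results["q"] < q_max) & (results["avg_logfc"].abs() > lfc_min)
    return results.loc[keep, "gene_id"].tolist()


def kinetic_clusters(curveset, genes, k: int = 6) -> pd.Series:
    """Cluster per-gene (U|L) concatenated z-scored curves.

    Hierarchical clustering with correlation distance and average
    linkage, cut at ``k`` clusters.  Returns a gene_id -> cluster Series
    with clusters numbered from 1.
    """
    genes = list(genes)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    rows = []
    for gid in genes:
        c = curveset.get(gid)
        vec = np.concatenate([c.curve_u, c.curve_l])
        sd = vec.std()
        rows.append((vec - vec.mean()) / sd if sd > 0
                    else np.zeros_like(vec))
    mat = np.vstack(rows)
    if len(genes) == 1 or k == 1:
        return pd.Series(np.ones(len(genes), dtype=int),
                         index=pd.Index(genes, name="gene_id"))
    d = pdist(mat, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    z = linkage(d, method="average")
    ids = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(ids.astype(int), index=pd.Index(genes, name="gene_id"))
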