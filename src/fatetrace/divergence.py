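"""Per-branch expression smoothing along stretched pseudotime and
divergence-point calling.

Curves are Nadaraya-Watson kernel regressions (Gaussian kernel) of
log-normalized expression onto a shared grid over [0, 100].  A gene's
divergence point t* is the earliest grid point from which the gap
between the two branch curves keeps the same sign — and, in strict mode,
stays at least ``min_gap`` in magnitude — all the way to the end of the
grid.  Genes whose curves cross back are rejected as non-persistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BranchCurve",
    "BranchCurveSet",
    "DivergenceCall",
    "smooth_branch_curves",
    "detect_divergence",
    "detect_divergence_all",
    "annotate_gene_sets",
    "read_gene_list",
]


@dataclass
class BranchCurve:
    gene_id: str
    grid: np.ndarray
    curve_u: np.ndarray
    curve_l: np.ndarray
    supported_u: np.ndarray
    supported_l: np.ndarray
    curve_p: np.ndarray | None = None
    smoother: str = "nw-gaussian"


@dataclass
class DivergenceCall:
    gene_id: str
    favored_branch: str | None
    t_star: float | None
    persistent: bool
    max_gap: float

    def __post_init__(self):
        has_t = self.t_star is not None
        has_branch = self.favored_branch is not None
        if has_t != has_branch or has_t != self.persistent:
            raise ValueError(
                "t_star, favored_branch and persistent must be jointly "
                "present or jointly absent")


class BranchCurveSet:
    """Smoothed curves for many genes on one shared grid."""

    def __init__(self, grid, gene_ids, curves_u, curves_l,
                 supported_u, supported_l, curves_p=None,
                 smoother="nw-gaussian"):
        self.grid = np.asarray(grid, dtype=float)
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.curves_u = np.asarray(curves_u, dtype=float)
        self.curves_l = np.asarray(curves_l, dtype=float)
        self.supported_u = np.asarray(supported_u, dtype=bool)
        self.supported_l = np.asarray(supported_l, dtype=bool)
        self.curves_p = curves_p
        self.smoother = smoother
        self._index = {str(g): i for i, g in enumerate(self.gene_ids)}

    def __len__(self):
        return len(self.gene_ids)

    def get(self, gene_id) -> BranchCurve:
        i = self._index[str(gene_id)]
        return BranchCurve(
            gene_id=str(gene_id), grid=self.grid,
            curve_u=self.curves_u[:, i], curve_l=self.curves_l[:, i],
            supported_u=self.supported_u, supported_l=self.supported_l,
            curve_p=None if self.curves_p is None else self.curves_p[:, i],
            smoother=self.smoother)


def _nw_smooth(t: np.ndarray, y: np.ndarray, grid: np.ndarray,
               bandwidth: float):
    w = np.exp(-0.5 * ((grid[:, None] - t[None, :]) / bandwidth) ** 2)
    denom = w.sum(axis=1)
    denom = np.maximum(denom, 1e-300)
    curves = (w @ y) / denom[:, None]
    supported = np.array([np.any(np.abs(grid[i] - t) <= 3.0 * bandwidth)
                          for i in range(len(grid))])
    return curves, supported


def smooth_branch_curves(expr, meta: pd.DataFrame, genes=None,
                         grid_size: int = 100, bandwidth: float = 10.0,
                         min_cells: int = 20,
                         include_p: bool = False) -> BranchCurveSet:
    """Kernel-smooth per-branch expression onto a shared [0, 100] grid."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if hasattr(expr, "values") and hasattr(expr, "gene_ids"):
        values, gene_ids, cell_ids = expr.values, expr.gene_ids, expr.cell_ids
    else:
        values, gene_ids, cell_ids = expr
        values = np.asarray(values, dtype=float)
        gene_ids = np.asarray(gene_ids, dtype=object)
    if genes is not None:
        wanted = [str(g) for g in genes]
        pos = {str(g): i for i, g in enumerate(gene_ids)}
        idx = [pos[g] for g in wanted if g in pos]
        values = values[:, idx]
        gene_ids = np.asarray([gene_ids[i] for i in idx], dtype=object)

    meta_idx = meta.set_index("cell_id").loc[list(map(str, cell_ids))]
    branch = meta_idx["branch"].astype(str).to_numpy()
    t = meta_idx["pseudotime_stretched"].to_numpy(dtype=float)
    grid = np.linspace(0.0, 100.0, grid_size)

    out = {}
    branches = ["U", "L"] + (["P"] if include_p else [])
    for b in ("U", "L"):
        if (branch == b).sum() < min_cells:
            raise ValueError(
                f"branch {b!r} has fewer than {min_cells} cells")
    for b in branches:
        m = branch == b
        if b == "P" and m.sum() < min_cells:
            out["P"] = (None, None)
            continue
        out[b] = _nw_smooth(t[m], values[m], grid, bandwidth)

    return BranchCurveSet(
        grid=grid, gene_ids=gene_ids,
        curves_u=out["U"][0], curves_l=out["L"][0],
        supported_u=out["U"][1], supported_l=out["L"][1],
        curves_p=out.get("P", (None,))[0] if include_p else None)


def detect_divergence(curve: BranchCurve, min_gap: float = 0.25,
                      mode: str = "strict",
                      min_tail_points: int = 1) -> DivergenceCall:
    """Call the earliest maintained divergence point of one gene.

    strict mode: t* is the earliest supported grid point from which
    |curve_u - curve_l| >= min_gap with constant sign through the end of
    the grid.  sign-tail mode relaxes the magnitude requirement to the
    onset point only.  ``min_tail_points`` sets the minimum number of
    supported grid points the maintained tail must span.
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    if mode not in ("strict", "sign-tail"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_tail_points < 1:
        raise ValueError("min_tail_points must be >= 1")
    valid = curve.supported_u & curve.supported_l
    d = (curve.curve_u - curve.curve_l)[valid]
    g = curve.grid[valid]
    none_call = dict(gene_id=curve.gene_id, favored_branch=None, t_star=None,
                     persistent=False,
                     max_gap=float(np.abs(d).max()) if d.size else 0.0)
    if d.size == 0:
        return DivergenceCall(**none_call)
    s = np.sign(d[-1])
    if s == 0:
        return DivergenceCall(**none_call)
    sign_ok = np.sign(d) == s
    ok = sign_ok & (np.abs(d) >= min_gap) if mode == "strict" else sign_ok
    bad = np.nonzero(~ok)[0]
    start = 0 if bad.size == 0 else int(bad[-1]) + 1
    if mode == "sign-tail":
        # onset additionally requires |d| >= min_gap at t*
        cand = np.nonzero(np.abs(d[start:]) >= min_gap)[0]
        if cand.size == 0:
            return DivergenceCall(**none_call)
        start = start + int(cand[0])
    if len(d) - start < min_tail_points:
        return DivergenceCall(**none_call)
    return DivergenceCall(
        gene_id=curve.gene_id,
        favored_branch="U" if s > 0 else "L",
        t_star=float(g[start]),
        persistent=True,
        max_gap=float(np.abs(d[start:]).max()))


def detect_divergence_all(curveset: BranchCurveSet, min_gap: float = 0.25,
                          mode: str = "strict",
                          min_tail_points: int = 1) -> pd.DataFrame:
    calls = [detect_divergence(curveset.get(gid), min_gap=min_gap, mode=mode,
                               min_tail_points=min_tail_points)
             for gid in curveset.gene_ids]
    return pd.DataFrame({
        "gene_id": [c.gene_id for c in calls],
        "favored_branch": [c.favored_branch for c in calls],
        "t_star": [np.nan if c.t_star is None else c.t_star for c in calls],
        "persistent": [c.persistent for c in calls],
        "max_gap": [c.max_gap for c in calls],
    })


def annotate_gene_sets(calls: pd.DataFrame,
                       gene_lists: dict) -> dict:
    """Per named list: persistent calls sorted by ascending t*.

    Lists with no overlap among the scored genes yield an empty table and
    a warning.
    """
    out = {}
    scored = set(map(str, calls["gene_id"]))
    for name, genes in gene_lists.items():
        members = {str(g) for g in genes}
        if not members & scored:
            warnings.warn(f"gene list {name!r} has no overlap with the "
                          "scored genes")
            out[name] = calls.iloc[0:0].assign(list=name)
            continue
        sub = calls[calls["gene_id"].astype(str).isin(members)
                    & calls["persistent"]]
        sub = sub.sort_values(["t_star", "gene_id"]).reset_index(drop=True)
        sub = sub.assign(list=name)
        out[name] = sub
    return out


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
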