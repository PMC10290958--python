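"""Two-component signature deconvolution of stratum expression profiles.

Stratum profiles are per-gene means of the normalized data in non-log
space (mean of ``expm1`` over member cells).  The brown fraction of each
profile is the simplex-constrained least-squares solution of
``profile ~ f * brown + (1 - f) * white`` after restricting to shared
signature genes and scaling every profile and signature column to unit
sum.  The one-dimensional problem has the closed form
``f = clip(<p - w, b - w> / ||b - w||^2, 0, 1)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_qc import NormalizedMatrix, undo_log

logger = logging.getLogger(__name__)

__all__ = [
    "build_stratum_profiles",
    "read_signature",
    "estimate_fractions",
]


def build_stratum_profiles(nm: NormalizedMatrix,
                           strata: pd.DataFrame) -> pd.DataFrame:
    """Genes x strata matrix of non-log mean expression per stratum."""
    expr = undo_log(nm)
    pos = {str(c): i for i, c in enumerate(nm.cell_ids)}
    cols = {}
    for stratum, sub in strata.groupby("stratum", sort=True):
        idx = [pos[str(c)] for c in sub["cell_id"] if str(c) in pos]
        if not idx:
            logger.warning("stratum %s has no cells in the matrix; skipped",
                           stratum)
            continue
        cols[stratum] = expr[idx].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(nm.gene_ids, name="gene"))


def read_signature(path: str) -> pd.DataFrame:
    """Signature CSV with columns gene, brown, white."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    if df.shape[1] != 2:
        raise ValueError("signature must have exactly two profile columns")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature profiles must be non-negative")
    return df


def _unit_sum(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        raise ValueError("profile with non-positive total")
    return v / s


def estimate_fractions(profiles: pd.DataFrame,
                       signature: pd.DataFrame) -> pd.DataFrame:
    """Brown fraction per stratum by constrained least squares.

    Requires >= 2 signature genes present in the profiles and
    non-identical signature columns.
    """
    shared = profiles.index.intersection(signature.index)
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} signature genes present; need >= 2")
    sig = signature.loc[shared]
    brown = _unit_sum(sig.iloc[:, 0].to_numpy(dtype=float))
    white = _unit_sum(sig.iloc[:, 1].to_numpy(dtype=float))
    diff = brown - white
    denom = float(diff @ diff)
    if denom <= 1e-300 or np.allclose(brown, white):
        raise ValueError("signature columns are identical; unidentifiable")
    rows = []
    for stratum in profiles.columns:
        p = _unit_sum(profiles.loc[shared, stratum].to_numpy(dtype=float))
        f = float(np.clip((p - white) @ diff / denom, 0.0, 1.0))
        resid = float(np.linalg.norm(p - (f * brown + (1 - f) * white)))
        rows.append((stratum, f, resid))
    out = pd.DataFrame(rows, columns=["stratum", "brown_fraction",
                                      "residual"])
    return out
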