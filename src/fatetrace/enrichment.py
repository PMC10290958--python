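"""Cumulative-hypergeometric gene-set enrichment and the directional
z-score ``(up - down) / sqrt(count)``.

The enrichment p-value is the one-tailed probability of an intersection
at least as large as observed under a hypergeometric draw of the query
from the universe; q-values are Benjamini-Hochberg across terms.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .branch_genes import bh_qvalues

__all__ = ["hypergeom_enrich", "go_zscore", "term_zscore", "read_gmt"]


def hypergeom_enrich(query, terms: dict, universe) -> pd.DataFrame:
    """One-tailed hypergeometric enrichment of ``query`` in each term.

    ``terms`` maps term id -> gene collection; term genes are intersected
    with the universe, and the query must be a subset of the universe
    (extraneous query genes are dropped with a warning).
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query_set = {str(g) for g in query}
    if not query_set:
        raise ValueError("empty query")
    extra = query_set - universe
    if extra:
        warnings.warn(f"{len(extra)} query genes outside the universe were "
                      "dropped")
        query_set &= universe
        if not query_set:
            raise ValueError("no query genes inside the universe")
    M = len(universe)
    N = len(query_set)
    rows = []
    for term_id in sorted(terms):
        term_genes = {str(g) for g in terms[term_id]} & universe
        n = len(term_genes)
        k = len(term_genes & query_set)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((term_id, N, n, M, k, p))
    out = pd.DataFrame(rows, columns=["term", "query_size", "term_size",
                                      "universe_size", "overlap", "p"])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def go_zscore(up: int, down: int) -> float:
    """Directional score ``(up - down) / sqrt(up + down)``."""
    count = up + down
    if count <= 0:
        raise ValueError("z-score undefined for count = 0")
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    return (up - down) / math.sqrt(count)


def term_zscore(term_genes, logfc: pd.Series) -> float:
    """z-score of a term from per-gene log fold changes (U minus L).

    Genes with positive logFC count as up, negative as down; zero-logFC
    genes are excluded from the count.
    """
    members = [str(g) for g in term_genes if str(g) in logfc.index]
    vals = logfc.loc[members].to_numpy(dtype=float)
    up = int((vals > 0).sum())
    down = int((vals < 0).sum())
    return go_zscore(up, down)


def read_gmt(path: str) -> dict:
    """GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = [g for g in parts[2:] if g]
    return terms
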