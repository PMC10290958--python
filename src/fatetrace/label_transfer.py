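"""Joint embedding of a reference and a query dataset, and kNN label
transfer with vote-fraction confidences.

The shared space is a PCA fitted on the gene-intersected, log-normalized
and per-gene standardized concatenation of both datasets.  Labels move
from reference to query by Euclidean k-nearest-neighbour plurality vote;
the confidence is the fraction of the k neighbours voting the predicted
label, with ties broken in alphabetical label order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_qc import CountMatrix, NormalizedMatrix, normalize_log

__all__ = ["joint_embed", "knn_transfer"]


def _as_lognorm(data) -> NormalizedMatrix:
    if isinstance(data, NormalizedMatrix):
        return data
    if isinstance(data, CountMatrix):
        return normalize_log(data)
    raise TypeError("expected CountMatrix or NormalizedMatrix")


def joint_embed(reference, query, n_pcs: int = 50, min_shared: int = 200):
    """Embed reference and query into one PCA space over shared genes.

    Returns ``(ref_embedding, query_embedding)``.  Raises when fewer than
    ``min_shared`` genes are shared.
    """
    ref = _as_lognorm(reference)
    qry = _as_lognorm(query)
    ref_genes = {str(g): i for i, g in enumerate(ref.gene_ids)}
    qry_genes = {str(g): i for i, g in enumerate(qry.gene_ids)}
    shared = sorted(set(ref_genes) & set(qry_genes))
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {min_shared}")
    r = ref.values[:, [ref_genes[g] for g in shared]]
    q = qry.values[:, [qry_genes[g] for g in shared]]
    stacked = np.vstack([r, q])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    stacked = (stacked - mu) / sd
    n_comp = min(n_pcs, min(stacked.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    emb = pca.fit_transform(stacked)
    return emb[: r.shape[0]], emb[r.shape[0]:]


def knn_transfer(ref_embedding: np.ndarray, ref_labels, query_embedding:
                 np.ndarray, k: int = 15, query_ids=None,
                 return_votes: bool = False):
    """Transfer labels by Euclidean kNN plurality vote.

    Confidence is ``votes / k`` for the winning label; ties break in
    alphabetical label order.  With ``return_votes`` the full vote
    fraction matrix (rows sum to 1) is returned alongside.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ref_embedding = np.asarray(ref_embedding, dtype=float)
    query_embedding = np.asarray(query_embedding, dtype=float)
    ref_labels = np.asarray(ref_labels, dtype=object)
    if k > len(ref_embedding):
        raise ValueError("k exceeds the reference size")
    if query_ids is None:
        query_ids = [f"query{i:05d}" for i in range(len(query_embedding))]

    nn = NearestNeighbors(n_neighbors=k).fit(ref_embedding)
    _, idx = nn.kneighbors(query_embedding)
    classes = sorted({str(l) for l in ref_labels})
    class_pos = {c: i for i, c in enumerate(classes)}
    votes = np.zeros((len(query_embedding), len(classes)))
    for row, neighbors in enumerate(idx):
        for j in neighbors:
            votes[row, class_pos[str(ref_labels[j])]] += 1
    fractions = votes / k
    # plurality with alphabetical tie-break: classes are sorted, argmax
    # returns the first (alphabetically smallest) maximal label
    winner = np.argmax(fractions, axis=1)
    out = pd.DataFrame({
        "cell_id": list(query_ids),
        "label": [classes[w] for w in winner],
        "confidence": fractions[np.arange(len(winner)), winner],
    })
    if return_votes:
        vote_df = pd.DataFrame(fractions, columns=classes,
                               index=list(query_ids))
        return out, vote_df
    return out
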