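"""Count-matrix I/O, quality-control filtering, normalization and
covariate residualization.

Reads 10x-style Matrix Market triplet directories (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``, genes as rows) or dense CSV/TSV tables
(cells as rows).  QC removes cells by detected-gene count, UMI total and
mitochondrial fraction (strict inequalities), then genes expressed in
too few cells.  Normalization scales each cell to a common transcript
count and applies ``log1p``; residualization regresses out technical
covariates per gene by ordinary least squares.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "NormalizedMatrix",
    "read_counts",
    "write_counts_mtx",
    "qc_filter",
    "normalize_log",
    "undo_log",
    "residualize",
    "scale_values",
]


@dataclass
class CountMatrix:
    """Sparse cells x genes non-negative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito_flags: np.ndarray

    def __post_init__(self):
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene id count {len(self.gene_ids)} != matrix columns {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell id count {len(self.cell_ids)} != matrix rows {n_cells}"
            )
        if len(self.mito_flags) != n_genes:
            raise ValueError("mito flag length mismatch")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer count entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def umi_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.asarray((self.values > 0).sum(axis=1)).ravel()

    def mito_fractions(self) -> np.ndarray:
        """Mitochondrial UMI fraction per cell, on raw counts."""
        totals = self.umi_totals().astype(float)
        mito = np.asarray(
            self.values[:, self.mito_flags].sum(axis=1)
        ).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
        return frac


@dataclass
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 9000
    max_umis: int = 120000
    max_mito_fraction: float = 0.08
    min_cells_per_gene: int = 3
    apply_mito_filter: bool = True

    def __post_init__(self):
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for name in ("min_genes", "max_genes", "max_umis", "max_mito_fraction",
                     "min_cells_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_umis: int
    removed_high_mito: int
    removed_cells_total: int
    n_cells_kept: int
    removed_low_cell_genes: int
    n_genes_kept: int
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NormalizedMatrix:
    """Dense cells x genes real-valued expression with a transform tag.

    ``size_factors`` record the per-cell scaling applied before the log so
    that non-log profiles can be reconstructed.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    transform: str = "log-normalized"
    size_factors: np.ndarray | None = None
    target_sum: float = 1e4

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("dimension mismatch in NormalizedMatrix")


def read_counts(path: str, mito_prefix: str = "MT-") -> CountMatrix:
    """Read counts from an MTX triplet directory or a dense CSV/TSV.

    MTX directories follow the 10x layout: genes as matrix rows, one id
    per line in ``genes.tsv``/``barcodes.tsv``.  Dense tables have cells
    as rows with cell ids in the first column and gene ids as header.
    Mitochondrial genes are flagged by id prefix (default ``MT-``).
    """
    if os.path.isdir(path):
        mat = mmread(os.path.join(path, "matrix.mtx"))
        genes = pd.read_csv(
            os.path.join(path, "genes.tsv"), sep="\t", header=None
        )[0].astype(str).to_numpy()
        barcodes = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        )[0].astype(str).to_numpy()
        values = sp.csr_matrix(mat.T)
        if values.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {values.shape} does not match id files "
                f"({len(barcodes)} barcodes, {len(genes)} genes)"
            )
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = df.columns.astype(str).to_numpy()
        barcodes = df.index.astype(str).to_numpy()
        values = sp.csr_matrix(df.to_numpy())
    mito = np.array([g.startswith(mito_prefix) for g in genes])
    return CountMatrix(values=values, gene_ids=genes, cell_ids=barcodes,
                       mito_flags=mito)


def write_counts_mtx(cm: CountMatrix, outdir: str) -> None:
    """Write a CountMatrix as a 10x-style MTX triplet (genes as rows)."""
    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "matrix.mtx"),
            sp.coo_matrix(cm.values.T.astype(np.int64)))
    pd.Series(cm.gene_ids).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False,
        index=False)


def qc_filter(cm: CountMatrix,
              thresholds: QCThresholds | None = None
              ) -> tuple[CountMatrix, QCReport]:
    """Apply cell filters (strict inequalities), then the gene filter.

    Cells are removed when detected genes < ``min_genes`` or
    > ``max_genes``, UMIs > ``max_umis`` or, when ``apply_mito_filter``,
    mitochondrial fraction > ``max_mito_fraction``.  Genes expressed in
    fewer than ``min_cells_per_gene`` of the remaining cells are then
    removed.
    """
    th = thresholds or QCThresholds()
    n_genes_det = cm.genes_detected()
    umis = cm.umi_totals()
    mito = cm.mito_fractions()

    low = n_genes_det < th.min_genes
    high = n_genes_det > th.max_genes
    high_umi = umis > th.max_umis
    high_mito = (mito > th.max_mito_fraction) if th.apply_mito_filter \
        else np.zeros(cm.n_cells, dtype=bool)
    drop = low | high | high_umi | high_mito
    keep_cells = ~drop
    if not keep_cells.any():
        raise ValueError("QC removed all cells; check thresholds")

    sub = cm.values[keep_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= th.min_cells_per_gene

    out = CountMatrix(
        values=sub[:, keep_genes],
        gene_ids=cm.gene_ids[keep_genes],
        cell_ids=cm.cell_ids[keep_cells],
        mito_flags=cm.mito_flags[keep_genes],
    )
    report = QCReport(
        n_cells_in=cm.n_cells,
        n_genes_in=cm.n_genes,
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_umis=int(high_umi.sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_cells_total=int(drop.sum()),
        n_cells_kept=int(keep_cells.sum()),
        removed_low_cell_genes=int((~keep_genes).sum()),
        n_genes_kept=int(keep_genes.sum()),
        thresholds=asdict(th),
    )
    return out, report


def normalize_log(cm: CountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p."""
    totals = cm.umi_totals().astype(float)
    if np.any(totals <= 0):
        raise ValueError("zero-count cell encountered; run qc_filter first")
    size_factors = totals / target_sum
    dense = cm.values.toarray().astype(float)
    dense /= size_factors[:, None]
    np.log1p(dense, out=dense)
    return NormalizedMatrix(values=dense, gene_ids=cm.gene_ids,
                            cell_ids=cm.cell_ids, transform="log-normalized",
                            size_factors=size_factors, target_sum=target_sum)


def undo_log(nm: NormalizedMatrix) -> np.ndarray:
    """Return the non-log (expm1) normalized values."""
    return np.expm1(nm.values)


def residualize(nm: NormalizedMatrix, covariates: pd.DataFrame
                ) -> NormalizedMatrix:
    """OLS residuals of every gene against intercept + covariates.

    Constant covariate columns are dropped with a warning.  Residual
    means are ~0 by construction.
    """
    if len(covariates) != len(nm.cell_ids):
        raise ValueError("covariates not aligned to cells")
    cols = []
    names = []
    for name in covariates.columns:
        col = covariates[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            logger.warning("dropping constant covariate %r", name)
            continue
        cols.append(col)
        names.append(name)
    X = np.column_stack([np.ones(len(covariates))] + cols)
    beta, *_ = np.linalg.lstsq(X, nm.values, rcond=None)
    resid = nm.values - X @ beta
    return NormalizedMatrix(values=resid, gene_ids=nm.gene_ids,
                            cell_ids=nm.cell_ids, transform="residualized",
                            size_factors=nm.size_factors,
                            target_sum=nm.target_sum)


def scale_values(nm: NormalizedMatrix, clip: float = 10.0) -> NormalizedMatrix:
    """Per-gene z-score with symmetric clipping (for embeddings only)."""
    mu = nm.values.mean(axis=0)
    sd = nm.values.std(axis=0)
    sd[sd == 0] = 1.0
    z = (nm.values - mu) / sd
    np.clip(z, -clip, clip, out=z)
    return NormalizedMatrix(values=z, gene_ids=nm.gene_ids,
                            cell_ids=nm.cell_ids, transform="scaled",
                            size_factors=nm.size_factors,
                            target_sum=nm.target_sum)
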