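"""Quality control, log-normalization, and variable-gene selection.

Filter rules follow the strict readings of the standard criteria:

* genes expressed (count > 0) in fewer than 200 cells or more than 8,000
  cells are excluded (bounds inclusive on the retained side);
* cells with fewer than 200 or more than 8,000 detected genes are removed;
* cells with more than 30% mitochondrial counts are removed (exactly 30%
  is retained — the rule is strict "more than").

Normalization is the usual library-size scaling to ``scale_factor`` total
followed by ``ln(1 + x)``. Variable genes are ranked by a
variance-stabilizing (vst-style) score: a local-regression mean-variance
trend on raw counts in log10 space, counts standardized by the
trend-predicted standard deviation with clipping at ``sqrt(n_cells)``, and
the variance of the clipped values as the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import GeneMatrix
from .errors import ConfigError, EmptyResultError, InputError

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCParams:
    min_cells_per_gene: int = 200
    max_cells_per_gene: int = 8000
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 8000
    max_mito_frac: float = 0.30
    scale_factor: float = 10000.0
    n_variable_genes: int = 2000
    lowess_span: float = 0.3

    def validate(self) -> None:
        if not self.min_cells_per_gene < self.max_cells_per_gene:
            raise ConfigError("min_cells_per_gene must be < max_cells_per_gene")
        if not self.min_genes_per_cell < self.max_genes_per_cell:
            raise ConfigError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0.0 < self.max_mito_frac <= 1.0:
            raise ConfigError("max_mito_frac must be in (0, 1]")


def _require_nonempty(counts: GeneMatrix) -> None:
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise InputError("empty matrix")


def gene_qc_table(counts: GeneMatrix, params: QCParams = QCParams()) -> pd.DataFrame:
    """Per-gene QC table: cells-expressing count, pass flag, failure reason."""
    _require_nonempty(counts)
    params.validate()
    n_cells_expr = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    low = n_cells_expr < params.min_cells_per_gene
    high = n_cells_expr > params.max_cells_per_gene
    reason = np.where(low, "too_few_cells", np.where(high, "too_many_cells", ""))
    return pd.DataFrame(
        {
            "gene": counts.genes,
            "n_cells_expressed": n_cells_expr,
            "pass": ~(low | high),
            "reason": reason,
        }
    )


def filter_genes(counts: GeneMatrix, params: QCParams = QCParams()) -> GeneMatrix:
    """Drop genes expressed in too few or too many cells; order preserved."""
    table = gene_qc_table(counts, params)
    keep = table["pass"].to_numpy()
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return GeneMatrix(counts.X[keep, :], counts.genes[keep], counts.cells)


def cell_qc_table(
    counts: GeneMatrix,
    mito_genes=None,
    params: QCParams = QCParams(),
) -> pd.DataFrame:
    """Per-cell QC table: detected genes, mito fraction, pass flag, reason.

    ``mito_genes`` may be an explicit gene-name set; by default genes with
    the ``MT-`` prefix are used. A cell with zero total counts fails with
    reason ``zero_counts`` (its mitochondrial fraction is undefined).
    """
    _require_nonempty(counts)
    params.validate()
    if mito_genes is None:
        mito_genes = {g for g in counts.genes if g.startswith(DEFAULT_MITO_PREFIX)}
    else:
        mito_genes = set(mito_genes)
        unknown = mito_genes - set(counts.genes)
        if unknown:
            raise InputError(f"mito_genes not in gene universe: {sorted(unknown)[:10]}")

    detected = np.asarray((counts.X > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.X.sum(axis=0)).ravel().astype(float)
    mito_mask = counts.genes.isin(mito_genes)
    mito_total = np.asarray(counts.X[mito_mask, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.where(total > 0, total, 1.0), np.nan)

    zero = total == 0
    low = detected < params.min_genes_per_cell
    high = detected > params.max_genes_per_cell
    mito_bad = ~zero & (mito_frac > params.max_mito_frac)
    reason = np.where(
        zero,
        "zero_counts",
        np.where(
            low, "too_few_genes",
            np.where(high, "too_many_genes", np.where(mito_bad, "high_mito", "")),
        ),
    )
    if zero.any():
        logger.warning(
            "%d cell(s) with zero total counts removed (mito fraction undefined)",
            int(zero.sum()),
        )
    return pd.DataFrame(
        {
            "cell_id": counts.cells,
            "n_genes_detected": detected,
            "mito_frac": mito_frac,
            "pass": ~(zero | low | high | mito_bad),
            "reason": reason,
        }
    )


def filter_cells(
    counts: GeneMatrix,
    mito_genes=None,
    params: QCParams = QCParams(),
) -> GeneMatrix:
    """Drop low/high-complexity and high-mitochondrial cells."""
    table = cell_qc_table(counts, mito_genes, params)
    keep = table["pass"].to_numpy()
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell")
    return GeneMatrix(counts.X[:, keep], counts.genes, counts.cells[keep])


def apply_qc(
    counts: GeneMatrix,
    mito_genes=None,
    params: QCParams = QCParams(),
    order: tuple[str, str] = ("genes", "cells"),
    to_fixpoint: bool = False,
    max_iter: int = 3,
) -> GeneMatrix:
    """Apply gene and cell filters in ``order`` (default genes first).

    With ``to_fixpoint=True`` the pair is repeated until no further gene or
    cell is removed (at most ``max_iter`` rounds).
    """
    if set(order) != {"genes", "cells"}:
        raise ConfigError("order must be a permutation of ('genes', 'cells')")
    current = counts
    for _ in range(max_iter if to_fixpoint else 1):
        shape_before = (current.n_genes, current.n_cells)
        for step in order:
            if step == "genes":
                current = filter_genes(current, params)
            else:
                current = filter_cells(current, mito_genes, params)
        if (current.n_genes, current.n_cells) == shape_before:
            break
    return current


def normalize(counts: GeneMatrix, params: QCParams = QCParams()) -> GeneMatrix:
    """Log-normalize: ``ln(1 + scale_factor * count / cell_total)``.

    Strictly column-local; a zero-total cell is an error (filter first).
    """
    _require_nonempty(counts)
    total = np.asarray(counts.X.sum(axis=0)).ravel().astype(float)
    if (total == 0).any():
        raise InputError("zero-total cell present; run cell QC before normalize")
    scale = params.scale_factor / total
    X = counts.X.astype(float).multiply(scale[np.newaxis, :]).tocsr()
    X.data = np.log1p(X.data)
    return GeneMatrix(X, counts.genes, counts.cells)


def _vst_scores(counts: GeneMatrix, span: float) -> np.ndarray:
    """Standardized (clipped) variance per gene, computed on raw counts."""
    X = counts.X.tocsr().astype(float)
    n = counts.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean ** 2) * n / max(n - 1, 1)

    scores = np.zeros(counts.n_genes)
    fit_mask = (var > 0) & (mean > 0)
    if not fit_mask.any():
        return scores
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    if fit_mask.sum() < 3 or np.ptp(lx) == 0:
        fitted = ly  # too few points for a trend; use observed variance
    else:
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
    sd_pred = np.sqrt(10.0 ** fitted)
    sd_pred = np.maximum(sd_pred, 1e-12)

    clip = np.sqrt(n)
    idx = np.flatnonzero(fit_mask)
    sd_full = np.zeros(counts.n_genes)
    sd_full[idx] = sd_pred
    mean_fit = mean

    # sum of squared standardized values; zeros handled in closed form
    indptr = X.indptr
    nnz_per_gene = np.diff(indptr)
    rows = np.repeat(np.arange(counts.n_genes), nnz_per_gene)
    z_nz = (X.data - mean_fit[rows]) / np.where(sd_full[rows] > 0, sd_full[rows], 1.0)
    z_nz = np.minimum(z_nz, clip)
    ssq_nz = np.zeros(counts.n_genes)
    np.add.at(ssq_nz, rows, z_nz ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_zero = np.where(sd_full > 0, -mean_fit / np.where(sd_full > 0, sd_full, 1.0), 0.0)
    z_zero = np.minimum(z_zero, clip)
    n_zero = n - nnz_per_gene
    ssq = ssq_nz + n_zero * z_zero ** 2
    scores[idx] = ssq[idx] / max(n - 1, 1)
    return scores


def select_variable_genes(
    counts: GeneMatrix, params: QCParams = QCParams()
) -> list[str]:
    """Top ``n_variable_genes`` genes by vst-style standardized variance.

    Computed on raw counts (the score standardizes counts against a fitted
    mean-variance trend). Ties, including the all-constant case where every
    score is zero, break deterministically by gene identifier. If fewer
    genes than requested are present, all are returned (logged).
    """
    _require_nonempty(counts)
    params.validate()
    scores = _vst_scores(counts, params.lowess_span)
    order = sorted(
        range(counts.n_genes), key=lambda i: (-scores[i], counts.genes[i])
    )
    n = params.n_variable_genes
    if counts.n_genes <= n:
        logger.info(
            "only %d genes present (<= n_variable_genes=%d); returning all",
            counts.n_genes, n,
        )
        return [counts.genes[i] for i in order]
    return [counts.genes[i] for i in order[:n]]
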