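"""Wilcoxon rank-sum differential expression with case-control conventions.

The test is the two-sided Mann-Whitney/Wilcoxon rank-sum: tie- and
continuity-corrected normal approximation for the group sizes typical of
single-cell data, with the exact null distribution used automatically for
small tie-free groups (and available explicitly via ``exact=True``). The fold change is computed on
de-logged normalized means,

    log2fc = log2((mean(expm1(A)) + eps) / (mean(expm1(B)) + eps)),  eps = 1e-9,

and significance uses Bonferroni adjustment over the genes tested in the
call. A gene is called ``up`` when log2fc > 0.5 and adjusted p < 0.05,
``down`` when log2fc < -0.5 and adjusted p < 0.05 (strict inequalities),
otherwise ``ns``. Adjusted p-values of exactly zero are given a display
value of 1e-320 so that -log10 is finite on volcano plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneMatrix
from .errors import InputError

ZERO_P_DISPLAY = 1e-320
LFC_EPS = 1e-9
LFC_THRESHOLD = 0.5
ALPHA = 0.05


def _direction(log2fc: np.ndarray, p_adj: np.ndarray,
               lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA) -> np.ndarray:
    up = (log2fc > lfc_threshold) & (p_adj < alpha)
    down = (log2fc < -lfc_threshold) & (p_adj < alpha)
    return np.where(up, "up", np.where(down, "down", "ns"))


def wilcoxon_de(
    norm: GeneMatrix,
    cells_a,
    cells_b,
    genes=None,
    exact: bool = False,
    bonferroni_n: int | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test of group A versus group B.

    Parameters
    ----------
    norm
        Log-normalized expression matrix.
    cells_a, cells_b
        Disjoint cell-id collections, each with at least 3 cells.
    genes
        Genes to test (default: all genes in the matrix).
    exact
        Use the exact Mann-Whitney null distribution (group sizes <= 10).
    bonferroni_n
        Override the Bonferroni family size (default: number of genes
        tested in this call).

    Returns a DataFrame with columns ``gene``, ``log2fc``, ``p_value``,
    ``p_adj``, ``p_adj_display``, ``pct_a``, ``pct_b``, ``direction``,
    ``flagged`` (True where the gene was constant across both groups).
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if set(cells_a) & set(cells_b):
        raise InputError("groups must be disjoint")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise InputError("each group needs at least 3 cells")
    if exact and (len(cells_a) > 10 or len(cells_b) > 10):
        raise InputError("exact mode supported only for groups of <= 10 cells")
    if genes is None:
        genes = list(norm.genes)
    else:
        genes = list(genes)

    sub = norm.subset_genes(genes)
    A = sub.subset_cells(cells_a).to_dense()
    B = sub.subset_cells(cells_b).to_dense()

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2((mean_a + LFC_EPS) / (mean_b + LFC_EPS))

    constant = np.array(
        [np.ptp(np.concatenate([A[i], B[i]])) == 0 for i in range(len(genes))]
    )
    p = np.ones(len(genes))
    todo = ~constant
    if todo.any():
        # 'auto' = exact null distribution for small tie-free groups,
        # tie- and continuity-corrected normal approximation otherwise
        method = "exact" if exact else "auto"
        res = stats.mannwhitneyu(
            A[todo], B[todo], axis=1, alternative="two-sided",
            method=method, use_continuity=True,
        )
        p[todo] = np.minimum(res.pvalue, 1.0)
    log2fc = np.where(constant, 0.0, log2fc)

    n_tested = bonferroni_n if bonferroni_n is not None else len(genes)
    p_adj = np.minimum(p * n_tested, 1.0)
    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "p_value": p,
            "p_adj": p_adj,
            "p_adj_display": np.where(p_adj == 0.0, ZERO_P_DISPLAY, p_adj),
            "pct_a": (A > 0).mean(axis=1),
            "pct_b": (B > 0).mean(axis=1),
            "flagged": constant,
        }
    )
    out["direction"] = _direction(out["log2fc"].to_numpy(), out["p_adj"].to_numpy())
    return out


def filter_degs(
    results: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition significant genes into (up, down) by the strict thresholds."""
    if len(results) == 0:
        raise InputError("empty DE result table")
    direction = _direction(
        results["log2fc"].to_numpy(), results["p_adj"].to_numpy(),
        lfc_threshold, alpha,
    )
    up = results[direction == "up"].reset_index(drop=True)
    down = results[direction == "down"].reset_index(drop=True)
    return up, down


def consistent_degs(
    per_line_results: list[pd.DataFrame],
    min_lines: int = 3,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Genes significant with the identical direction in >= ``min_lines`` sets.

    Returns a DataFrame with columns ``gene``, ``direction``, ``n_lines``.
    """
    if len(per_line_results) < 2:
        raise InputError("need at least 2 line-level result sets")
    if min_lines > len(per_line_results):
        raise InputError(
            f"min_lines={min_lines} exceeds number of result sets "
            f"({len(per_line_results)})"
        )
    votes: dict[tuple[str, str], int] = {}
    for res in per_line_results:
        up, down = filter_degs(res, lfc_threshold, alpha)
        for g in up["gene"]:
            votes[(g, "up")] = votes.get((g, "up"), 0) + 1
        for g in down["gene"]:
            votes[(g, "down")] = votes.get((g, "down"), 0) + 1
    rows = [
        {"gene": g, "direction": d, "n_lines": n}
        for (g, d), n in votes.items()
        if n >= min_lines
    ]
    out = pd.DataFrame(rows, columns=["gene", "direction", "n_lines"])
    return out.sort_values(["direction", "gene"]).reset_index(drop=True)


def volcano_table(
    results: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Volcano-plot table: adds ``neg_log10_p_adj`` using the display rule.

    ``p_adj = 0`` maps to the display value 1e-320, hence -log10 = 320.
    Threshold annotations (``lfc_threshold``, ``alpha``) are carried as
    DataFrame attrs.
    """
    out = results.copy()
    display = np.where(
        out["p_adj"].to_numpy() == 0.0, ZERO_P_DISPLAY, out["p_adj"].to_numpy()
    )
    out["p_adj_display"] = display
    out["neg_log10_p_adj"] = -np.log10(display)
    out.attrs["lfc_threshold"] = lfc_threshold
    out.attrs["alpha"] = alpha
    return out
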