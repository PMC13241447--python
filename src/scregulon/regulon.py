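"""TF regulon construction, rank-recovery AUC activity, differential activity.

A *regulon* is a transcription factor (TF) together with the genes whose
expression Spearman-correlates with the TF above a threshold (one-sided,
rho > 0.1 by default), keeping only regulons with at least 10 targets.

Per-cell activity is the rank-recovery AUC (the AUCell statistic): genes
are ranked by descending expression within each cell, the cumulative count
of regulon genes recovered is accumulated down to a maximum rank (5% of
the total gene count), and the area under this step curve is normalised by
the maximal achievable area, giving a score in [0, 1]. Ties — ubiquitous
because of scRNA-seq zeros — are broken by a single seeded permutation
shared across all cells, so scores are bit-reproducible.

Differential activity between groups uses two-sided Wilcoxon rank-sum
tests with Benjamini-Hochberg FDR across regulons; per regulon a log2 fold
change and a percent change of mean activity are reported, and a direction
(increased/decreased) is assigned only below the FDR threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneMatrix
from .errors import ConfigError, EmptyResultError, InputError

logger = logging.getLogger(__name__)

ACT_LFC_EPS = 1e-6


@dataclass(frozen=True)
class RegulonParams:
    min_tf_frac: float = 0.05
    rho_threshold: float = 0.1
    min_targets: int = 10
    max_rank_frac: float = 0.05
    fdr_threshold: float = 0.05
    tie_seed: int = 0
    absolute_rho: bool = False  # |rho| mode for sensitivity analysis
    max_rank_floor: bool = False  # floor instead of ceil for maxRank

    def validate(self) -> None:
        for name in ("min_tf_frac", "rho_threshold", "max_rank_frac", "fdr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.min_targets < 1:
            raise ConfigError("min_targets must be >= 1")


@dataclass
class Regulon:
    """A TF with its predicted targets and their correlation values."""

    tf: str
    targets: list[str]
    rho: dict[str, float] = field(default_factory=dict)
    cardiac: bool = False

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise InputError(f"TF {self.tf} appears in its own target list")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class ActivityMatrix:
    """Regulons x cells AUC scores in [0, 1]."""

    values: pd.DataFrame  # index: regulon (TF) names, columns: cell ids

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and ((v < 0) | (v > 1)).any():
            raise InputError("activity values outside [0, 1]")

    @property
    def regulons(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


def expressed_tfs(
    norm: GeneMatrix, tf_list, params: RegulonParams = RegulonParams()
) -> list[str]:
    """TFs present in the matrix and expressed in >= ``min_tf_frac`` of cells.

    The boundary is inclusive: a TF detected in exactly 5% of cells passes.
    """
    params.validate()
    tf_list = list(tf_list)
    if not tf_list:
        raise InputError("empty TF list")
    present = [tf for tf in tf_list if tf in norm.genes]
    absent = set(tf_list) - set(present)
    if absent:
        logger.warning("%d TF(s) absent from the matrix", len(absent))
    if not present:
        raise EmptyResultError("no TF from the list is present in the matrix")
    idx = norm.genes.get_indexer(present)
    frac = np.asarray((norm.X[idx, :] > 0).sum(axis=1)).ravel() / norm.n_cells
    passing = [tf for tf, f in zip(present, frac) if f >= params.min_tf_frac]
    if not passing:
        raise EmptyResultError("no TF passes the expression-fraction filter")
    return passing


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Average ranks of each row across columns (Spearman convention)."""
    return stats.rankdata(X, axis=1)


def build_regulons(
    norm: GeneMatrix, tfs, params: RegulonParams = RegulonParams()
) -> list[Regulon]:
    """Predict targets per TF by Spearman correlation over all cells.

    For each TF, Spearman's rho (average-rank tie handling) is computed
    between the TF's normalized expression and every other gene; genes with
    rho > ``rho_threshold`` (or |rho| in absolute mode) become targets.
    Regulons with fewer than ``min_targets`` targets are dropped, as are
    TFs with constant expression (rho undefined).
    """
    params.validate()
    tfs = list(tfs)
    if not tfs:
        raise InputError("empty TF list")
    missing = [t for t in tfs if t not in norm.genes]
    if missing:
        raise InputError(f"TFs not in matrix: {missing[:10]}")

    X = norm.to_dense()
    ranks = _rank_rows(X)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    gene_ok = norms > 0

    regulons: list[Regulon] = []
    gene_arr = np.asarray(norm.genes)
    for tf in tfs:
        ti = norm.genes.get_loc(tf)
        if not gene_ok[ti]:
            logger.warning("TF %s has constant expression; dropped", tf)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = ranks @ ranks[ti] / (norms * norms[ti])
        rho[~gene_ok] = np.nan
        rho[ti] = np.nan  # the TF never targets itself
        crit = np.abs(rho) if params.absolute_rho else rho
        sel = np.flatnonzero(np.nan_to_num(crit, nan=-np.inf) > params.rho_threshold)
        if len(sel) < params.min_targets:
            continue
        targets = [str(g) for g in gene_arr[sel]]
        regulons.append(
            Regulon(tf=tf, targets=targets,
                    rho={str(gene_arr[i]): float(rho[i]) for i in sel})
        )
    return regulons


def _max_rank(n_genes: int, params: RegulonParams) -> int:
    raw = params.max_rank_frac * n_genes
    rank = math.floor(raw) if params.max_rank_floor else math.ceil(raw)
    if rank < 1:
        raise InputError(f"maxRank < 1 for {n_genes} genes")
    return rank


def aucell_scores(
    norm: GeneMatrix, regulons: list[Regulon], params: RegulonParams = RegulonParams()
) -> ActivityMatrix:
    """Rank-recovery AUC of every regulon in every cell.

    Per cell, all G genes are ranked by descending expression, with ties
    broken by one fixed permutation drawn from ``tie_seed`` (identical in
    every cell). With maxRank = ceil(``max_rank_frac`` * G),

        raw AUC = sum_{k=1..maxRank} hits(k),   hits(k) = #targets ranked <= k,

    and the reported AUC divides by the maximal achievable raw AUC,
    sum_{k=1..maxRank} min(k, |targets|). The scored set is the target list
    (the TF itself is excluded by construction).
    """
    params.validate()
    G = norm.n_genes
    max_rank = _max_rank(G, params)
    for reg in regulons:
        missing = set(reg.targets) - set(norm.genes)
        if missing:
            raise InputError(
                f"regulon {reg.tf}: targets not in matrix: {sorted(missing)[:10]}"
            )
        if reg.size > G:
            raise InputError(f"regulon {reg.tf} larger than the gene universe")

    tie_break = np.random.default_rng(params.tie_seed).permutation(G)
    X = norm.to_dense()
    ranks = np.empty((G, norm.n_cells), dtype=np.int32)
    arange = np.arange(1, G + 1, dtype=np.int32)
    for c in range(norm.n_cells):
        order = np.lexsort((tie_break, -X[:, c]))
        ranks[order, c] = arange

    values = np.empty((len(regulons), norm.n_cells))
    ks = np.arange(1, max_rank + 1)
    for i, reg in enumerate(regulons):
        idx = norm.genes.get_indexer(reg.targets)
        r = ranks[idx, :]
        contrib = np.clip(max_rank - r + 1, 0, None).sum(axis=0)
        denom = np.minimum(ks, reg.size).sum()
        values[i] = contrib / denom
    df = pd.DataFrame(values, index=[r.tf for r in regulons], columns=norm.cells)
    return ActivityMatrix(df)


def differential_activity(
    act: ActivityMatrix,
    ann: pd.DataFrame,
    params: RegulonParams = RegulonParams(),
    group_col: str = "group",
    control_label: str = "control",
    case_label: str = "case",
    cardiac: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Wilcoxon differential activity of each regulon, case vs control.

    Returns a DataFrame with columns ``regulon``, ``mean_control``,
    ``mean_case``, ``log2fc``, ``pct_change``, ``p_value``, ``fdr``,
    ``direction``, ``cardiac``, ``flagged``. Direction is assigned only
    when fdr < ``params.fdr_threshold``.
    """
    params.validate()
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann
    groups = ann.loc[act.cells, group_col]
    ctrl_cells = act.cells[groups.to_numpy() == control_label]
    case_cells = act.cells[groups.to_numpy() == case_label]
    if len(ctrl_cells) < 3 or len(case_cells) < 3:
        raise InputError("both groups need at least 3 cells")

    A = act.values[case_cells].to_numpy()
    B = act.values[ctrl_cells].to_numpy()
    mean_case = A.mean(axis=1)
    mean_control = B.mean(axis=1)
    constant = np.array([np.ptp(np.concatenate([a, b])) == 0 for a, b in zip(A, B)])
    p = np.ones(len(act.regulons))
    todo = ~constant
    if todo.any():
        res = stats.mannwhitneyu(
            A[todo], B[todo], axis=1, alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        p[todo] = np.minimum(res.pvalue, 1.0)

    fdr = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2((mean_case + ACT_LFC_EPS) / (mean_control + ACT_LFC_EPS))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            mean_control > 0,
            100.0 * (mean_case - mean_control) / mean_control,
            np.nan,
        )
    sig = fdr < params.fdr_threshold
    direction = np.where(
        sig & (mean_case > mean_control), "increased",
        np.where(sig & (mean_case < mean_control), "decreased", "ns"),
    )
    cardiac = cardiac or {}
    return pd.DataFrame(
        {
            "regulon": act.regulons,
            "mean_control": mean_control,
            "mean_case": mean_case,
            "log2fc": log2fc,
            "pct_change": pct,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "cardiac": [bool(cardiac.get(r, False)) for r in act.regulons],
            "flagged": constant,
        }
    ).reset_index(drop=True)


def cardiac_regulons(regulons: list[Regulon], cardiac_sets: dict[str, list[str]]) -> list[Regulon]:
    """Mark and return regulons whose TF belongs to any supplied gene set."""
    if not cardiac_sets:
        raise InputError("empty gene-set collection")
    members = set()
    for genes in cardiac_sets.values():
        members.update(genes)
    out = []
    for reg in regulons:
        reg.cardiac = reg.tf in members
        if reg.cardiac:
            out.append(reg)
    return out


def summarize_direction(
    diff: pd.DataFrame,
    subset: str = "all",
    fdr_threshold: float = 0.05,
) -> dict:
    """Counts and percentages of significantly increased/decreased regulons.

    Percentages are over significant regulons, rounded to one decimal.
    With zero significant regulons the percentages are reported as None.
    ``subset`` is ``all`` or ``cardiac``.
    """
    if subset == "cardiac":
        diff = diff[diff["cardiac"]]
    elif subset != "all":
        raise InputError("subset must be 'all' or 'cardiac'")
    sig = diff[diff["fdr"] < fdr_threshold]
    n_sig = len(sig)
    n_dec = int((sig["direction"] == "decreased").sum())
    n_inc = int((sig["direction"] == "increased").sum())
    out = {
        "n_regulons": int(len(diff)),
        "n_significant": n_sig,
        "n_decreased": n_dec,
        "n_increased": n_inc,
        "pct_decreased": round(100.0 * n_dec / n_sig, 1) if n_sig else None,
        "pct_increased": round(100.0 * n_inc / n_sig, 1) if n_sig else None,
    }
    return out
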