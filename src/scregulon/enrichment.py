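"""Hypergeometric over-representation analysis of gene lists.

For a query of n genes drawn from a background of N genes, and a term with
K background members of which k overlap the query, the classic p-value is
the hypergeometric upper tail P[X >= k]; the conservative EASE variant
(available by flag) removes one overlapping gene from the tail, i.e. uses
P[X >= k - 1] computed on k - 1. Fold enrichment is (k/n) / (K/N).
Benjamini-Hochberg FDR is applied across all tested terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)


def enrich(
    query,
    background,
    sets: dict[str, list[str]],
    ease: bool = False,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set for over-representation in ``query``.

    ``query`` must be a subset of ``background``; each set is intersected
    with the background before testing, and sets with no background member
    are skipped. Returns a DataFrame with columns ``term``, ``k``, ``n``,
    ``K``, ``N``, ``fold_enrichment``, ``p_value``, ``fdr``,
    ``significant``, sorted by ascending p.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise InputError("query and background must be non-empty")
    if not query <= background:
        raise InputError(
            f"query contains genes outside the background: "
            f"{sorted(query - background)[:10]}"
        )
    N, n = len(background), len(query)
    rows = []
    for term, members in sets.items():
        term_bg = set(members) & background
        K = len(term_bg)
        if K == 0:
            logger.warning("term %r has no background member; skipped", term)
            continue
        k = len(term_bg & query)
        k_tail = max(k - 1, 0) if ease else k
        # P[X >= k_tail] for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k_tail - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": (k / n) / (K / N),
                "p_value": p,
            }
        )
    if not rows:
        raise InputError("no testable term (all empty after background intersection)")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["p_value", "term"]).reset_index(drop=True)


def top_pathways(
    results: pd.DataFrame,
    top_n: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Top ``top_n`` significant terms by ascending FDR.

    Ties break by ascending p-value, then term identifier. Fewer than
    ``top_n`` significant terms simply returns what exists.
    """
    sig = results[results["fdr"] < fdr_threshold]
    sig = sig.sort_values(["fdr", "p_value", "term"], kind="mergesort")
    return sig.head(top_n).reset_index(drop=True)


def top_pathways_per_regulon(
    per_regulon_results: dict[str, pd.DataFrame],
    top_n: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply :func:`top_pathways` per regulon; adds a ``regulon`` column."""
    frames = []
    for reg, res in per_regulon_results.items():
        top = top_pathways(res, top_n, fdr_threshold)
        if len(top):
            top = top.copy()
            top.insert(0, "regulon", reg)
            frames.append(top)
    if not frames:
        return pd.DataFrame(
            columns=["regulon", "term", "k", "n", "K", "N",
                     "fold_enrichment", "p_value", "fdr", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def categorize(
    terms: pd.DataFrame,
    category_map: dict[str, str],
) -> pd.DataFrame:
    """Map retained terms to functional categories with -log10(FDR) weights.

    ``terms`` is a table with ``term`` and ``fdr`` columns (optionally
    ``regulon``); unmapped terms get category ``unassigned`` with a
    warning. The output is circos-ready: one link row per term with its
    category and weight.
    """
    out = terms.copy()
    cats = [category_map.get(t) for t in out["term"]]
    n_missing = sum(c is None for c in cats)
    if n_missing:
        logger.warning("%d term(s) missing from the category map", n_missing)
    out["category"] = [c if c is not None else "unassigned" for c in cats]
    fdr = out["fdr"].to_numpy(dtype=float)
    out["weight"] = -np.log10(np.clip(fdr, 1e-320, None))
    return out
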