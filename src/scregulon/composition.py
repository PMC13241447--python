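"""Cluster-composition quantification and per-cluster chi-square testing.

Each cluster is tested with a 2x2 Pearson chi-square (in-cluster vs
not-in-cluster, unit A vs unit B) without continuity correction, and
Benjamini-Hochberg FDR adjustment is applied across all clusters in one
comparison. Separate comparisons (e.g. pooled case group, and each case
line against the control pool) are corrected independently.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)


def cluster_proportions(ann: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-unit cluster proportions; rows (units) sum to 1.

    ``by`` is the annotation column defining units (``group`` or ``line``).
    """
    if by not in ann.columns:
        raise InputError(f"annotation has no column {by!r}")
    bad = ann["cluster"].isna()
    if bad.any():
        offenders = ann.loc[bad, "cell_id"].tolist()
        raise InputError(f"cells without cluster label: {offenders[:10]}")
    counts = pd.crosstab(ann[by], ann["cluster"])
    return counts.div(counts.sum(axis=1), axis=0)


def composition_test(
    ann: pd.DataFrame,
    unit_a: str,
    unit_b: str,
    by: str = "group",
    fdr_threshold: float = 0.05,
    continuity: bool = False,
) -> pd.DataFrame:
    """Per-cluster 2x2 chi-square comparison of units A and B.

    Returns a DataFrame with columns ``cluster``, ``prop_a``, ``prop_b``,
    ``diff_pp`` (percentage points, B minus A), ``chi2_stat``, ``p_value``,
    ``fdr``, ``significant``. Clusters absent from both units are skipped
    with a warning; a 2x2 table with a zero expected count gets p = 1.
    """
    if by not in ann.columns:
        raise InputError(f"annotation has no column {by!r}")
    in_a = ann[ann[by] == unit_a]
    in_b = ann[ann[by] == unit_b]
    if len(in_a) == 0 or len(in_b) == 0:
        raise InputError(f"unit {unit_a!r} or {unit_b!r} has no cells")

    clusters = sorted(set(ann["cluster"].unique()))
    n_a, n_b = len(in_a), len(in_b)
    rows = []
    for c in clusters:
        a_in = int((in_a["cluster"] == c).sum())
        b_in = int((in_b["cluster"] == c).sum())
        if a_in == 0 and b_in == 0:
            logger.warning("cluster %r absent from both units; skipped", c)
            continue
        table = np.array([[a_in, n_a - a_in], [b_in, n_b - b_in]], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected == 0).any():
            logger.warning("cluster %r has a zero expected count; p set to 1", c)
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = chi2_contingency(table, correction=continuity)
        prop_a, prop_b = a_in / n_a, b_in / n_b
        rows.append(
            {
                "cluster": c,
                "prop_a": prop_a,
                "prop_b": prop_b,
                "diff_pp": (prop_b - prop_a) * 100.0,
                "chi2_stat": float(chi2),
                "p_value": float(p),
            }
        )
    if not rows:
        raise InputError("no cluster present in either unit")
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out
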