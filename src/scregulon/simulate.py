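"""Synthetic case-control scRNA-seq generator with planted regulon structure.

The generator emulates the design of a pooled case-control iPSC-cardiomyocyte
experiment: several case lines compared against a pooled control, cells
falling into clusters with group-specific proportions, and transcription
factors (TFs) whose per-cell latent activity drives a block of target genes.

Mechanism, per cell:

1. a cluster is drawn from the group-specific cluster proportions;
2. each TF gets a latent activity ``a_t ~ Normal(0, 1)``; in case cells
   ``shift_size`` is subtracted from ``a_t`` for every shifted TF;
3. the log-mean of each TF gene and of each of its targets is
   ``baseline + coupling_strength * a_t``; background genes keep their
   baseline (cluster marker genes additionally get a cluster offset);
4. per-gene expression weights ``exp(log-mean)`` are normalised to sum to
   one (softmax), scaled by the cell's library size, and counts are drawn
   from a negative binomial with shared dispersion;
5. a designated mitochondrial gene block receives a per-cell mitochondrial
   fraction of the library.

Everything planted (regulon membership, shifted TFs and their direction,
per-gene expected effects, cluster proportions, deliberately QC-failing
cells) is returned as :class:`GroundTruth` so downstream stages can be
scored against a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GeneMatrix
from .errors import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults are desk-scale: 3,000 genes, 40 TFs with 25 targets each,
    4 control + 4 case lines at 500 cells per line, 14 clusters.
    """

    n_genes: int = 3000
    n_tfs: int = 40
    targets_per_tf: int = 25
    n_control_lines: int = 4
    n_case_lines: int = 4
    cells_per_line: int = 500
    n_clusters: int = 14
    cluster_props_control: tuple | None = None
    cluster_props_case: tuple | None = None
    coupling_strength: float = 1.5
    shift_frac: float = 0.5
    shift_size: float = 1.0
    libsize_mean: float = 5000.0
    libsize_shape: float = 0.35  # lognormal sigma of library size
    nb_dispersion: float = 2.0  # NB size; var = mu + mu^2/size
    mito_frac_mean: float = 0.05
    mito_frac_sd: float = 0.02
    n_mito_genes: int = 10
    outlier_cell_frac: float = 0.0
    seed: int = 0

    def resolved_props(self) -> tuple[np.ndarray, np.ndarray]:
        """Control and case cluster proportions with defaults filled in."""
        if self.cluster_props_control is None:
            ctrl = _default_props(self.n_clusters)
        else:
            ctrl = np.asarray(self.cluster_props_control, dtype=float)
        if self.cluster_props_case is None:
            case = _default_case_props(ctrl)
        else:
            case = np.asarray(self.cluster_props_case, dtype=float)
        return ctrl, case

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "targets_per_tf", "n_control_lines",
                     "n_case_lines", "cells_per_line", "n_clusters"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        need = self.n_tfs * (self.targets_per_tf + 1) + self.n_mito_genes
        if need > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {self.n_tfs} TFs with "
                f"{self.targets_per_tf} targets each plus {self.n_mito_genes} "
                f"mitochondrial genes (need >= {need})"
            )
        ctrl, case = self.resolved_props()
        for name, p in (("cluster_props_control", ctrl), ("cluster_props_case", case)):
            if len(p) != self.n_clusters:
                raise ConfigError(f"{name} must have length n_clusters={self.n_clusters}")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.shift_frac <= 1.0:
            raise ConfigError("shift_frac must be in [0, 1]")
        if self.coupling_strength < 0:
            raise ConfigError("coupling_strength must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not 0.0 <= self.outlier_cell_frac < 1.0:
            raise ConfigError("outlier_cell_frac must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a simulated dataset."""

    regulon_membership: dict[str, list[str]]
    shifted_tfs: set[str]
    true_direction: dict[str, str]  # TF -> {"decreased", "increased", "null"}
    de_genes: dict[str, float]  # gene -> expected log-mean change in case cells
    cluster_props: dict[str, np.ndarray]  # group -> proportions
    qc_fail_cells: dict[str, str] = field(default_factory=dict)  # barcode -> reason

    def to_record(self) -> dict:
        """JSON-serialisable representation."""
        return {
            "regulon_membership": self.regulon_membership,
            "shifted_tfs": sorted(self.shifted_tfs),
            "true_direction": self.true_direction,
            "de_genes": self.de_genes,
            "cluster_props": {k: list(map(float, v)) for k, v in self.cluster_props.items()},
            "qc_fail_cells": self.qc_fail_cells,
        }


def _default_props(k: int) -> np.ndarray:
    # mildly decreasing cluster sizes, akin to graph-clustering output
    p = 0.85 ** np.arange(k)
    return p / p.sum()


def _default_case_props(ctrl: np.ndarray) -> np.ndarray:
    # enrich one cluster at the expense of another, as case-control
    # compositions typically differ in a couple of clusters
    case = ctrl.copy()
    k = len(case)
    if k >= 4:
        delta = 0.4 * case[3]
        case[3] -= delta
        case[1] += delta
    elif k >= 2:
        delta = 0.2 * case[0]
        case[0] -= delta
        case[1] += delta
    return case


def _gene_names(cfg: SimulationConfig) -> tuple[pd.Index, np.ndarray, np.ndarray, np.ndarray]:
    """Gene universe layout: [TFs][targets][background][mito]."""
    n_t = cfg.n_tfs * cfg.targets_per_tf
    n_bg = cfg.n_genes - cfg.n_tfs - n_t - cfg.n_mito_genes
    tf_idx = np.arange(cfg.n_tfs)
    tg_idx = np.arange(cfg.n_tfs, cfg.n_tfs + n_t)
    bg_idx = np.arange(cfg.n_tfs + n_t, cfg.n_tfs + n_t + n_bg)
    names = (
        [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
        + [f"TG{i + 1:05d}" for i in range(n_t)]
        + [f"BG{i + 1:05d}" for i in range(n_bg)]
        + [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    )
    return pd.Index(names), tf_idx, tg_idx, bg_idx


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GeneMatrix, pd.DataFrame, GroundTruth]:
    """Generate a case-control count matrix, annotation, and ground truth.

    Returns
    -------
    counts
        Integer :class:`GeneMatrix` (genes x cells).
    annotation
        DataFrame with columns ``cell_id``, ``line``, ``group``, ``cluster``.
    truth
        :class:`GroundTruth` recording every planted effect.

    The same ``config`` (including its seed) always yields bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    genes, tf_idx, tg_idx, bg_idx = _gene_names(cfg)
    n_nonmito = cfg.n_genes - cfg.n_mito_genes
    tf_names = list(genes[tf_idx])

    # fixed per-gene baselines; regulon genes are moderately expressed so
    # that rank correlations are informative (a target that is almost never
    # detected carries no correlation signal)
    baseline = np.empty(n_nonmito)
    baseline[tf_idx] = rng.normal(1.0, 0.5, size=len(tf_idx))
    baseline[tg_idx] = rng.normal(0.5, 0.75, size=len(tg_idx))
    baseline[bg_idx] = rng.normal(0.0, 1.0, size=len(bg_idx))

    # parent TF of every gene (-1 = none); TF genes couple to their own activity
    parent = np.full(n_nonmito, -1, dtype=int)
    parent[tf_idx] = np.arange(cfg.n_tfs)
    for t in range(cfg.n_tfs):
        lo = cfg.n_tfs + t * cfg.targets_per_tf
        parent[lo:lo + cfg.targets_per_tf] = t

    # cluster marker offsets live on dedicated background genes so cluster
    # structure cannot masquerade as TF-target correlation
    n_markers = min(10, max(0, len(bg_idx) // max(cfg.n_clusters, 1)))
    marker_offset = np.zeros((cfg.n_clusters, n_nonmito))
    if n_markers > 0:
        pool = rng.permutation(bg_idx)
        for c in range(cfg.n_clusters):
            chosen = pool[c * n_markers:(c + 1) * n_markers]
            marker_offset[c, chosen] = 1.0

    # mito block weights (relative within the block)
    mito_w = np.exp(rng.normal(0.0, 0.3, size=cfg.n_mito_genes))
    mito_w /= mito_w.sum()

    n_shift = int(round(cfg.shift_frac * cfg.n_tfs))
    shifted = np.sort(rng.choice(cfg.n_tfs, size=n_shift, replace=False))
    shifted_mask = np.zeros(cfg.n_tfs, dtype=bool)
    shifted_mask[shifted] = True

    props_ctrl, props_case = cfg.resolved_props()
    mu_ln = np.log(cfg.libsize_mean) - cfg.libsize_shape ** 2 / 2.0

    lines = [("CTRL%d" % (i + 1), "control") for i in range(cfg.n_control_lines)]
    lines += [("CASE%d" % (i + 1), "case") for i in range(cfg.n_case_lines)]

    blocks: list[sp.csr_matrix] = []
    ann_rows: list[tuple[str, str, str, int]] = []
    qc_fail: dict[str, str] = {}

    for line, group in lines:
        n = cfg.cells_per_line
        props = props_case if group == "case" else props_ctrl
        clusters = rng.choice(cfg.n_clusters, size=n, p=props)
        libsize = rng.lognormal(mu_ln, cfg.libsize_shape, size=n)
        mito_f = np.clip(
            rng.normal(cfg.mito_frac_mean, cfg.mito_frac_sd, size=n), 0.0, 0.15
        )

        # deliberately QC-failing cells: half starved libraries, half high-mito
        n_out = int(round(cfg.outlier_cell_frac * n))
        out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
        barcodes = [f"{line}_{i + 1:04d}" for i in range(n)]
        for j, ci in enumerate(out_idx):
            if j % 2 == 0:
                libsize[ci] = 60.0
                qc_fail[barcodes[ci]] = "low_count"
            else:
                mito_f[ci] = 0.5
                qc_fail[barcodes[ci]] = "high_mito"

        activity = rng.normal(0.0, 1.0, size=(n, cfg.n_tfs))
        if group == "case" and cfg.shift_size != 0.0 and n_shift > 0:
            activity[:, shifted_mask] -= cfg.shift_size

        # log-mean per (cell, nonmito gene)
        logm = np.broadcast_to(baseline, (n, n_nonmito)).copy()
        has_parent = parent >= 0
        logm[:, has_parent] += cfg.coupling_strength * activity[:, parent[has_parent]]
        logm += marker_offset[clusters, :]

        w = np.exp(logm)
        w /= w.sum(axis=1, keepdims=True)
        mu = w * (libsize * (1.0 - mito_f))[:, None]
        mu_mito = np.outer(libsize * mito_f, mito_w)
        mu_all = np.concatenate([mu, mu_mito], axis=1)  # cells x genes

        r = cfg.nb_dispersion
        p_nb = r / (r + mu_all)
        counts = rng.negative_binomial(r, p_nb).astype(np.int32)
        blocks.append(sp.csr_matrix(counts.T))  # genes x cells
        ann_rows += [
            (barcodes[i], line, group, int(clusters[i])) for i in range(n)
        ]

    X = sp.hstack(blocks, format="csr")
    cells = pd.Index([r[0] for r in ann_rows])
    counts_mat = GeneMatrix(X, genes, cells)
    annotation = pd.DataFrame(ann_rows, columns=["cell_id", "line", "group", "cluster"])

    if cfg.shift_size > 0:
        shift_dir = "decreased"
    elif cfg.shift_size < 0:
        shift_dir = "increased"
    else:
        shift_dir = "null"
    membership = {
        tf_names[t]: [
            str(genes[cfg.n_tfs + t * cfg.targets_per_tf + j])
            for j in range(cfg.targets_per_tf)
        ]
        for t in range(cfg.n_tfs)
    }
    true_direction = {
        tf_names[t]: (shift_dir if shifted_mask[t] else "null")
        for t in range(cfg.n_tfs)
    }
    de_genes: dict[str, float] = {}
    effect = -cfg.coupling_strength * cfg.shift_size
    if effect != 0.0:
        for t in shifted:
            de_genes[tf_names[t]] = effect
            for g in membership[tf_names[t]]:
                de_genes[g] = effect
    truth = GroundTruth(
        regulon_membership=membership,
        shifted_tfs={tf_names[t] for t in shifted} if shift_dir != "null" else set(),
        true_direction=true_direction,
        de_genes=de_genes,
        cluster_props={"control": props_ctrl, "case": props_case},
        qc_fail_cells=qc_fail,
    )
    return counts_mat, annotation, truth


def simulate_null_dataset(
    config: SimulationConfig,
) -> tuple[GeneMatrix, pd.DataFrame, GroundTruth]:
    """Matched null dataset: no group shifts, identical cluster proportions.

    The regulon structure (TF-target coupling) is kept so the regulon
    pipeline still produces regulons; only group differences are removed.
    Every TF's true direction is ``null``.
    """
    config.validate()
    ctrl, _ = config.resolved_props()
    null_cfg = dataclasses.replace(
        config,
        shift_frac=0.0,
        shift_size=0.0,
        cluster_props_control=tuple(ctrl),
        cluster_props_case=tuple(ctrl),
    )
    return simulate_dataset(null_cfg)
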