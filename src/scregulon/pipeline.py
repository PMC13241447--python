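"""End-to-end pipeline runner: simulate/read -> QC -> composition -> DE ->
regulons -> enrichment, with deterministic, header-stamped TSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import composition_test
from .containers import GeneMatrix
from .dge import consistent_degs, filter_degs, volcano_table, wilcoxon_de
from .enrichment import categorize, enrich, top_pathways_per_regulon
from .errors import ConfigError
from .io import (
    read_annotation,
    read_gene_list,
    read_gmt,
    read_matrix,
    write_annotation,
    write_json,
    write_matrix,
    write_table,
)
from .qc import QCParams, apply_qc, cell_qc_table, gene_qc_table, normalize, select_variable_genes
from .regulon import (
    RegulonParams,
    aucell_scores,
    build_regulons,
    differential_activity,
    expressed_tfs,
    summarize_direction,
)
from .simulate import SimulationConfig, simulate_dataset, simulate_null_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are left intact on disk."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is set (inputs are generated) or ``matrix_dir`` /
    ``annotation`` / ``tf_list`` point at existing files.
    """

    out_dir: str = "results"
    simulate: SimulationConfig | None = None
    simulate_null: bool = False
    matrix_dir: str | None = None
    annotation: str | None = None
    tf_list: str | None = None
    gmt: str | None = None  # enrichment collection
    cardiac_gmt: str | None = None  # sets defining cardiac TFs
    category_map: str | None = None  # JSON term -> category
    qc: QCParams = field(default_factory=QCParams)
    regulon: RegulonParams = field(default_factory=RegulonParams)
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    min_lines: int = 3
    control_label: str = "control"
    case_label: str = "case"
    write_matrices: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimulationConfig(**d["simulate"])
        if "qc" in d:
            d["qc"] = QCParams(**d["qc"])
        if "regulon" in d:
            d["regulon"] = RegulonParams(**d["regulon"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # output location does not affect results
        payload = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _meta(config: PipelineConfig) -> dict:
    return {
        "package": "scregulon",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to disk).

    Stage order: simulate (optional) -> qc -> composition -> dge (pooled and
    per line) -> regulon build/score/diff/summary -> enrichment. Identical
    config and inputs produce byte-identical TSV bodies.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)
    manifest: dict = {"stages": {}, **meta}
    t0 = time.time()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.start = time.time()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = round(time.time() - self.start, 3)
                logger.info("stage %s: done in %.2fs", name, manifest["stages"][name])

        return _Ctx()

    # --- inputs -----------------------------------------------------------
    with stage("inputs"):
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            gen = simulate_null_dataset if config.simulate_null else simulate_dataset
            counts, ann, truth = gen(sim_cfg)
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            if config.write_matrices:
                write_matrix(sim_dir, counts)
            write_annotation(sim_dir / "annotation.tsv", ann)
            write_json(sim_dir / "ground_truth.json", truth.to_record())
            tf_names = sorted(truth.regulon_membership)
            with open(sim_dir / "tf_list.txt", "w") as fh:
                fh.write("\n".join(tf_names) + "\n")
        else:
            if not (config.matrix_dir and config.annotation and config.tf_list):
                raise ConfigError(
                    "matrix_dir, annotation and tf_list are required when not simulating"
                )
            counts = read_matrix(config.matrix_dir)
            ann = read_annotation(config.annotation)
            tf_names = read_gene_list(config.tf_list)
            truth = None

    # --- qc ---------------------------------------------------------------
    with stage("qc"):
        write_table(out / "qc_genes.tsv", gene_qc_table(counts, config.qc), meta)
        write_table(out / "qc_cells.tsv", cell_qc_table(counts, None, config.qc), meta)
        filtered = apply_qc(counts, None, config.qc, order=("genes", "cells"))
        norm = normalize(filtered, config.qc)
        hvg = select_variable_genes(filtered, config.qc)
        write_table(out / "variable_genes.tsv", pd.DataFrame({"gene": hvg}), meta)
        ann = ann[ann["cell_id"].isin(set(filtered.cells))].reset_index(drop=True)
        if config.write_matrices:
            write_matrix(out / "filtered", filtered)

    case_lines = sorted(ann.loc[ann["group"] == config.case_label, "line"].unique())

    # --- composition ------------------------------------------------------
    with stage("composition"):
        pooled = composition_test(ann, config.control_label, config.case_label, by="group")
        write_table(out / "composition_pooled.tsv", pooled, meta)
        for line in case_lines:
            unit = ann.copy()
            unit["unit"] = unit.apply(
                lambda r: "control_pool" if r["group"] == config.control_label else r["line"],
                axis=1,
            )
            unit = unit[(unit["unit"] == "control_pool") | (unit["unit"] == line)]
            res = composition_test(unit, "control_pool", line, by="unit")
            write_table(out / f"composition_{line}.tsv", res, meta)

    # --- differential expression -----------------------------------------
    with stage("dge"):
        ctrl_cells = ann.loc[ann["group"] == config.control_label, "cell_id"]
        case_cells = ann.loc[ann["group"] == config.case_label, "cell_id"]
        pooled_de = wilcoxon_de(norm, case_cells, ctrl_cells)
        write_table(out / "dge_pooled.tsv", volcano_table(pooled_de), meta)
        per_line = []
        for line in case_lines:
            line_cells = ann.loc[ann["line"] == line, "cell_id"]
            res = wilcoxon_de(norm, line_cells, ctrl_cells)
            per_line.append(res)
            write_table(out / f"dge_{line}.tsv", volcano_table(res), meta)
        if len(per_line) >= 2:
            consistent = consistent_degs(
                per_line, min(config.min_lines, len(per_line)),
                config.lfc_threshold, config.alpha,
            )
        else:
            up, down = filter_degs(pooled_de, config.lfc_threshold, config.alpha)
            consistent = pd.DataFrame(
                {
                    "gene": list(up["gene"]) + list(down["gene"]),
                    "direction": ["up"] * len(up) + ["down"] * len(down),
                    "n_lines": 1,
                }
            )
        write_table(out / "dge_consistent.tsv", consistent, meta)

    # --- regulons ---------------------------------------------------------
    with stage("regulon"):
        tfs = expressed_tfs(norm, [t for t in tf_names if t in norm.genes], config.regulon)
        regulons = build_regulons(norm, tfs, config.regulon)
        cardiac_map: dict[str, bool] = {}
        if config.cardiac_gmt:
            cardiac_sets = read_gmt(config.cardiac_gmt)
            members = {g for genes in cardiac_sets.values() for g in genes}
            for reg in regulons:
                reg.cardiac = reg.tf in members
        cardiac_map = {reg.tf: reg.cardiac for reg in regulons}
        reg_table = pd.DataFrame(
            {
                "tf": [r.tf for r in regulons],
                "n_targets": [r.size for r in regulons],
                "cardiac": [r.cardiac for r in regulons],
                "targets": [",".join(r.targets) for r in regulons],
                "rho": [",".join(f"{r.rho[t]:.4f}" for t in r.targets) for r in regulons],
            }
        )
        write_table(out / "regulons.tsv", reg_table, meta)
        act = aucell_scores(norm, regulons, config.regulon)
        act_df = act.values.reset_index(names="regulon")
        write_table(out / "activity.tsv", act_df, meta)
        diff = differential_activity(
            act, ann, config.regulon,
            control_label=config.control_label, case_label=config.case_label,
            cardiac=cardiac_map,
        )
        write_table(out / "activity_diff.tsv", diff, meta)
        summary = {
            "all": summarize_direction(diff, "all", config.regulon.fdr_threshold),
            "cardiac": summarize_direction(diff, "cardiac", config.regulon.fdr_threshold),
        }
        write_json(out / "activity_summary.json", summary)

    # --- enrichment -------------------------------------------------------
    if config.gmt:
        with stage("enrichment"):
            sets = read_gmt(config.gmt)
            background = list(norm.genes)
            for direction in ("up", "down"):
                degs = consistent.loc[consistent["direction"] == direction, "gene"]
                degs = [g for g in degs if g in norm.genes]
                if not degs:
                    continue
                res = enrich(degs, background, sets)
                write_table(out / f"enrichment_degs_{direction}.tsv", res, meta)
            per_reg = {}
            for reg in regulons:
                if config.cardiac_gmt and not reg.cardiac:
                    continue
                targets = [g for g in reg.targets if g in norm.genes]
                if targets:
                    per_reg[reg.tf] = enrich(targets, background, sets)
            if per_reg:
                top = top_pathways_per_regulon(per_reg)
                write_table(out / "enrichment_regulons_top.tsv", top, meta)
                if config.category_map:
                    with open(config.category_map) as fh:
                        cmap = json.load(fh)
                    links = categorize(top, cmap)
                    write_table(out / "regulon_category_links.tsv", links, meta)

    manifest["runtime_s"] = round(time.time() - t0, 3)
    write_json(out / "manifest.json", manifest)
    return manifest
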