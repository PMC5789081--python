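"""Configuration-driven orchestration of the full analysis.

The pipeline sequences: per-condition differential expression against the
time-matched control -> DE-set bookkeeping and cross-condition overlap ->
knowledge-guided clustering with optimal-K selection -> per-cluster TF
enrichment (and optional pathway/signature analyses) -> transcriptional
cascade assembly and export. Every output is a plain TSV; a JSON manifest
records the seed, the configuration echo and per-stage timings.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cascade import build_cascade, export_cascade
from .clustering import build_profiles, select_optimal_k, write_clustering, write_score_curve
from .differential import (DEConfig, condition_overlap, de_sets,
                           run_de_timecourse, write_de_table)
from .enrichment import (cluster_direction_test, pathway_ora,
                         signature_overlap, tf_enrichment_per_cluster)
from .errors import ConfigError, DataError
from .io import read_expression, read_gene_sets, read_tf_kb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; loadable from a flat YAML file."""

    expression: str = ""
    sample_sheet: str = ""
    kb: str = ""
    out_dir: str = "results"
    max_rank: int = 2
    pathways_gmt: str | None = None
    signatures_gmt: str | None = None
    external_stats: str | None = None  # TSV: gene, log2FC
    min_set_size: int = 30
    control: str = "control"
    cluster_condition: str = "both"
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    early_times: tuple[float, ...] = (2.0, 4.0, 8.0)
    late_times: tuple[float, ...] = (24.0,)
    k_range: tuple[int, ...] = tuple(range(2, 13))
    methods: tuple[str, ...] = ("hierarchical",)
    alpha: float = 0.05
    score_method: str = "mean_neglogp"
    strict_tf_filter: bool = True
    universe_size: int = 41220
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("early_times", "late_times", "k_range", "methods"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("expression", "sample_sheet", "kb"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"config is missing required path: {name}")
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        for name in ("pathways_gmt", "signatures_gmt", "external_stats"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    def de_config(self) -> DEConfig:
        return DEConfig(lfc_threshold=self.lfc_threshold,
                        fdr_threshold=self.fdr_threshold,
                        early_times=tuple(self.early_times),
                        late_times=tuple(self.late_times))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing outputs under config.out_dir.

    Returns the manifest dict. Any stage failure aborts with the stage name;
    the partial manifest (stages completed so far) is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "outputs": [],
    }
    stage_t0 = [time.perf_counter()]

    def done(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = round(time.perf_counter() - stage_t0[0], 3)
        manifest["outputs"] += [str(p.relative_to(out)) for p in paths]
        stage_t0[0] = time.perf_counter()

    def write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    current_stage = "load_inputs"
    try:
        expr = read_expression(config.expression, config.sample_sheet)
        kb = read_tf_kb(config.kb, max_rank=config.max_rank)
        pathways = (read_gene_sets(config.pathways_gmt, config.min_set_size)
                    if config.pathways_gmt else None)
        signatures = (read_gene_sets(config.signatures_gmt, config.min_set_size)
                      if config.signatures_gmt else None)
        done(current_stage)

        current_stage = "differential_expression"
        decfg = config.de_config()
        treatments = [c for c in expr.samples.conditions if c != config.control]
        if config.cluster_condition not in treatments:
            raise ConfigError(
                f"cluster_condition {config.cluster_condition!r} not among "
                f"treatment conditions {treatments}")
        de_tables: dict[str, pd.DataFrame] = {}
        de_paths = []
        for cond in treatments:
            det = run_de_timecourse(expr, cond, config.control, decfg)
            de_tables[cond] = det
            p = out / f"de_{cond}.tsv"
            write_de_table(det, p)
            de_paths.append(p)
        done(current_stage, *de_paths)

        current_stage = "de_sets_and_overlap"
        focal = de_tables[config.cluster_condition]
        sets = de_sets(focal, decfg)
        sets_path = out / "de_sets.tsv"
        rows = [{"set": "union", "n": len(sets["union"]),
                 "genes": ",".join(sorted(sets["union"]))},
                {"set": "early", "n": len(sets["early"]),
                 "genes": ",".join(sorted(sets["early"]))},
                {"set": "late", "n": len(sets["late"]),
                 "genes": ",".join(sorted(sets["late"]))}]
        for t, s in sorted(sets["per_time"].items()):
            rows.append({"set": f"t{t:g}h", "n": len(s),
                         "genes": ",".join(sorted(s))})
        pd.DataFrame(rows).to_csv(sets_path, sep="\t", index=False)
        overlap_paths = []
        if len(de_tables) >= 2:
            pair_rows = []
            for t in sorted(focal["time_h"].unique()):
                ov = condition_overlap(de_tables, t)
                pw = ov["pairwise"].copy()
                pw.insert(0, "time_h", t)
                pair_rows.append(pw)
            ov_path = out / "condition_overlap.tsv"
            pd.concat(pair_rows, ignore_index=True).to_csv(
                ov_path, sep="\t", index=False, float_format="%.10g")
            overlap_paths.append(ov_path)
        done(current_stage, sets_path, *overlap_paths)

        current_stage = "clustering"
        if not sets["union"]:
            raise DataError("no DE genes in the focal condition; nothing to cluster")
        profiles = build_profiles(focal, sets["union"])
        curve, clustering = select_optimal_k(
            profiles, kb, config.k_range, methods=config.methods,
            alpha=config.alpha, seed=config.seed,
            score_method=config.score_method)
        curve_path = out / "score_curve.tsv"
        memb_path = out / "cluster_membership.tsv"
        write_score_curve(curve, curve_path)
        write_clustering(clustering, memb_path)
        done(current_stage, curve_path, memb_path)

        current_stage = "tf_enrichment"
        enr = tf_enrichment_per_cluster(clustering, kb, alpha=config.alpha)
        enr_path = out / "tf_enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.10g")
        done(current_stage, enr_path)

        extra_paths = []
        if pathways is not None:
            current_stage = "pathway_ora"
            background = set(focal["gene"])
            for label, gene_list in (("early", sets["early"]),
                                     ("late", sets["late"])):
                if not gene_list:
                    continue
                ora = pathway_ora(gene_list, pathways, background,
                                  fdr=config.fdr_threshold)
                p = out / f"pathway_ora_{label}.tsv"
                ora.to_csv(p, sep="\t", index=False, float_format="%.10g")
                extra_paths.append(p)
            done(current_stage, *extra_paths)
            extra_paths = []

        if signatures is not None:
            current_stage = "signature_overlap"
            union_sets = {cond: de_sets(det, decfg)["union"]
                          for cond, det in de_tables.items()}
            sig = signature_overlap(union_sets, signatures,
                                    universe_size=config.universe_size)
            p = out / "signature_overlap.tsv"
            sig.to_csv(p, sep="\t", index=False, float_format="%.10g")
            done(current_stage, p)

        if config.external_stats is not None:
            current_stage = "direction_test"
            ext = pd.read_csv(config.external_stats, sep="\t")
            if not {"gene", "log2FC"}.issubset(ext.columns):
                raise DataError("external stats TSV needs columns gene, log2FC")
            series = ext.set_index("gene")["log2FC"]
            direction = cluster_direction_test(clustering, series)
            p = out / "cluster_direction.tsv"
            direction.to_csv(p, sep="\t", index=False, float_format="%.10g")
            done(current_stage, p)

        current_stage = "cascade"
        cascade = build_cascade(clustering, focal, enr, kb,
                                alpha=config.alpha,
                                strict_tf_filter=config.strict_tf_filter)
        paths = export_cascade(cascade, out / "cascade", fmt="edge-tsv")
        paths += export_cascade(cascade, out / "cascade", fmt="sif")
        done(current_stage, *paths)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        write_manifest()
        logger.error("pipeline stage %r failed: %s", current_stage, exc)
        raise

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    write_manifest()
    return manifest
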