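"""Pipeline orchestration: config validation, staged execution, manifest.

``run_pipeline`` executes, for every case condition against the control:
differential RNA, differential ATAC, peak annotation, DEG/DAR
integration (correlation scores + Pareto ranking), TF activity, CERNO
enrichment, GWAS-variant overlap and drug-target overlap. Every stage
writes a TSV; a JSON manifest records the config hash, seed and
per-stage row counts. Reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, integration, peaks, tf_activity
from .io_formats import (
    load_counts,
    load_drug_targets,
    load_enhancer_links,
    load_gene_sets_gmt,
    load_intervals_bed,
    load_regulons,
    load_variants,
    extract_tss_from_gtf,
)

logger = logging.getLogger("epinteg")

_PATH_KEYS = (
    "rna_counts", "atac_counts", "samples", "peaks_bed", "enhancers_bed",
    "genes_gtf", "links", "regulons", "variants", "gene_sets", "drug_targets",
)
_OPTIONAL_PATHS = ("regulons", "variants", "gene_sets", "drug_targets")

# q-value floor before the signed inverse-normal transform (q = 0 is infinite)
Q_FLOOR = 1e-12


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths + analysis parameters)."""

    paths: dict[str, str]
    outdir: str
    control: str = "NDC"
    fdr_level: float = 0.05
    promoter_window: tuple[int, int] = (-1500, 500)
    cerno_min_size: int = 5
    pareto_objectives: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError(f"fdr_level must be in (0,1), got {self.fdr_level}")
        up, down = self.promoter_window
        if not (up < 0 < down):
            raise ValueError(
                f"promoter_window must satisfy upstream < 0 < downstream, got {self.promoter_window}"
            )
        if self.pareto_objectives not in (2, 3):
            raise ValueError("pareto_objectives must be 2 or 3")
        unknown = set(self.paths) - set(_PATH_KEYS)
        if unknown:
            raise ValueError(f"unknown path key(s): {sorted(unknown)}")
        for key in _PATH_KEYS:
            if key not in self.paths and key not in _OPTIONAL_PATHS:
                raise ValueError(f"missing required path: {key}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and normalize a YAML pipeline config; reject unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"paths", "outdir", "control", "fdr_level", "promoter_window",
             "cerno_min_size", "pareto_objectives", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "paths" not in raw or "outdir" not in raw:
        raise ValueError(f"{path}: config needs 'paths' and 'outdir'")
    kwargs = dict(raw)
    if "promoter_window" in kwargs:
        kwargs["promoter_window"] = tuple(kwargs["promoter_window"])
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> int:
    df.to_csv(path, sep="\t", float_format="%.10g",
              index=index_label is not None, index_label=index_label)
    return len(df)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every case condition; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "fdr_level": config.fdr_level,
        "stages": {},
    }
    mpath = outdir / "manifest.json"

    def record(stage: str, rows: int, t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "complete", "rows": int(rows),
            "elapsed_s": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %-14s complete rows=%d", stage, rows)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "incomplete", "error": str(exc)}
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    p = {k: Path(v) for k, v in config.paths.items()}
    for key, path in p.items():
        if not path.exists():
            raise FileNotFoundError(f"input {key!r} missing: {path}")

    stage = "load"
    try:
        rna = load_counts(p["rna_counts"], p["samples"])
        atac = load_counts(p["atac_counts"], p["samples"])
        peak_ivs = load_intervals_bed(p["peaks_bed"])
        enhancer_ivs = load_intervals_bed(p["enhancers_bed"])
        gene_models = extract_tss_from_gtf(p["genes_gtf"])
        links = load_enhancer_links(p["links"])
        regulon_table = load_regulons(p["regulons"]) if "regulons" in p else None
        variants = load_variants(p["variants"]) if "variants" in p else None
        gene_sets = load_gene_sets_gmt(p["gene_sets"]) if "gene_sets" in p else None
        network = load_drug_targets(p["drug_targets"]) if "drug_targets" in p else None
    except Exception as exc:
        fail(stage, exc)
        raise StageError(stage, exc) from exc

    cases = [c for c in rna.condition_levels() if c != config.control]
    if not cases:
        exc = ValueError(f"no case conditions besides control {config.control!r}")
        fail("load", exc)
        raise StageError("load", exc)

    regulons = (tf_activity.regulons_from_table(regulon_table)
                if regulon_table is not None else None)

    for case in cases:
        tag = case
        try:
            stage = f"diff-rna[{tag}]"
            t0 = time.monotonic()
            rna_res = differential.run_differential(
                rna, case, config.control, fdr_level=config.fdr_level
            )
            record(stage, _write_tsv(rna_res, outdir / f"diff_rna_{tag}.tsv", "feature_id"), t0)

            stage = f"diff-atac[{tag}]"
            t0 = time.monotonic()
            atac_res = differential.run_differential(
                atac, case, config.control, fdr_level=config.fdr_level
            )
            record(stage, _write_tsv(atac_res, outdir / f"diff_atac_{tag}.tsv", "feature_id"), t0)

            stage = f"annotate[{tag}]"
            t0 = time.monotonic()
            annotated = peaks.annotate_peaks(
                [iv for iv in peak_ivs if iv.id in atac_res.index],
                gene_models, enhancer_ivs, links,
                window=config.promoter_window, diff=atac_res,
            )
            record(stage, _write_tsv(peaks.annotation_table(annotated),
                                     outdir / f"annotation_{tag}.tsv"), t0)

            stage = f"integrate[{tag}]"
            t0 = time.monotonic()
            gene_peaks = integration.intersect_deg_dar(rna_res, annotated, config.fdr_level)
            chosen = integration.prioritize_peaks(gene_peaks)
            n_rows = 0
            records = None
            if len(chosen) >= 3:
                try:
                    records = integration.correlation_scores(rna_res, chosen)
                    n_rows = _write_tsv(records, outdir / f"integrated_{tag}.tsv", "gene_id")
                except ValueError as err:
                    logger.warning("integrate[%s]: %s", tag, err)
            record(stage, n_rows, t0)

            stage = f"pareto[{tag}]"
            t0 = time.monotonic()
            sig_annotated = [ap for ap in annotated
                             if ap.diff is not None and ap.diff["q"] < config.fdr_level]
            n_rows = 0
            ranked_table = None
            if sig_annotated:
                try:
                    z_table = integration.build_z_table(
                        rna_res, sig_annotated, objectives=config.pareto_objectives
                    )
                    ranked_table = integration.pareto_rank(z_table)
                    n_rows = _write_tsv(ranked_table, outdir / f"pareto_{tag}.tsv", "gene_id")
                except ValueError as err:
                    logger.warning("pareto[%s]: %s", tag, err)
            record(stage, n_rows, t0)

            stage = f"tf-activity[{tag}]"
            t0 = time.monotonic()
            n_rows = 0
            if regulons is not None:
                scores = pd.Series(
                    differential.signed_quantile_score(
                        rna_res["q"].clip(lower=Q_FLOOR), rna_res["log2fc"]
                    ),
                    index=rna_res.index,
                )
                tf_rows = tf_activity.score_regulons(scores, regulons)
                n_rows = _write_tsv(tf_rows, outdir / f"tf_activity_{tag}.tsv")
            record(stage, n_rows, t0)

            stage = f"enrich[{tag}]"
            t0 = time.monotonic()
            n_rows = 0
            if gene_sets is not None:
                ranked = enrichment.RankedList(list(rna_res.index),
                                               rna_res["msd"].to_numpy())
                rows = enrichment.cerno_test(ranked, gene_sets, config.cerno_min_size)
                rows.insert(0, "ranking", "msd")
                frames = [rows]
                if ranked_table is not None:
                    pr = integration.integrate_and_enrich(ranked_table, gene_sets,
                                                          config.cerno_min_size)
                    pr.insert(0, "ranking", "pareto")
                    frames.append(pr)
                all_rows = pd.concat(frames, ignore_index=True)
                n_rows = _write_tsv(all_rows, outdir / f"enrichment_{tag}.tsv")
            record(stage, n_rows, t0)

            stage = f"gwas-overlap[{tag}]"
            t0 = time.monotonic()
            n_rows = 0
            if variants is not None:
                dars = [ap for ap in annotated
                        if ap.diff is not None and ap.diff["q"] < config.fdr_level]
                overlap = peaks.intersect_variants(variants, dars)
                n_rows = _write_tsv(overlap, outdir / f"gwas_overlap_{tag}.tsv")
            record(stage, n_rows, t0)

            stage = f"drug-overlap[{tag}]"
            t0 = time.monotonic()
            n_rows = 0
            if network is not None and records is not None:
                cats = integration.categorize_genes(records)
                hits = integration.drug_target_overlap(cats, network)
                n_rows = _write_tsv(hits, outdir / f"drug_overlap_{tag}.tsv")
            record(stage, n_rows, t0)
        except Exception as exc:
            fail(stage, exc)
            raise StageError(stage, exc) from exc

    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
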