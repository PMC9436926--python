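"""End-to-end orchestration: stages, configuration, manifest and logging.

A run directory is populated stage by stage (synthetic data -> clinical
statistics -> covariance maps -> expression prep -> region-specific
expression -> imaging-transcriptomics -> enrichment); every stage reads
its inputs from and writes its outputs to the run directory, so partial
re-runs by stage name are possible, and a manifest records the config and
a content hash of every output for reproducibility checks.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .ahba import (SampleQCRules, match_samples_to_vertices, qc_samples,
                   select_probes)
from .clinical import run_clinical_stage
from .covariance import map_covariance, summarize_map
from .enrichment import (GeneSetCollection, PsiTable, compute_psi,
                         csea_enrich, csea_summary, hypergeom_enrich)
from .imagingtx import assemble_design, fit_mixed_per_gene, rank_and_slice
from .regionexpr import run_region_expression
from .simulate import (CohortConfig, ExpressionConfig, SurfaceBundle,
                       SurfaceConfig, generate_dataset, write_dataset)
from .stats import InvalidArgumentError

log = logging.getLogger("bftx")

STAGES = ("simulate", "clinical", "covariance", "ahba_prep",
          "region_expression", "imaging_tx", "enrichment")

BF_CENTERS = {"NBM": (-18.0, -2.0, -12.0), "Ch1-3": (0.0, 2.0, -9.0)}


class DependencyError(RuntimeError):
    """An upstream stage output is missing."""


@dataclass
class RunConfig:
    """Declarative run configuration; defaults are the study conditions."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)
    surface: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    fdr_q: float = 0.10
    match_cutoff_mm: float = 10.0
    bf_qc_radius_mm: float = 15.0
    decile: float = 0.10
    fdr_grid: tuple = (0.10, 0.05, 0.01)
    seed_regions: tuple = ("NBM_L", "Ch1-3")
    covariance_structures: tuple = ("cortex-L", "hippocampus")
    target_regions: tuple = ("Ch1-3", "NBM")
    imaging_seed_region: str = "NBM_L"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _require(outdir: Path, name: str, stage: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise DependencyError(
            f"stage '{stage}' requires missing upstream output {name}")
    return p


def _load_surface(cfg: RunConfig, outdir: Path, stage: str) -> SurfaceBundle:
    vertices = bio.read_tsv(_require(outdir, "surface_vertices.tsv", stage))
    qt1 = bio.read_matrix_tsv(_require(outdir, "surface_qt1.tsv", stage))
    return SurfaceBundle(vertices=vertices, qt1=qt1,
                         config=SurfaceConfig(**cfg.surface))


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    data = generate_dataset(CohortConfig(**cfg.cohort),
                            SurfaceConfig(**cfg.surface),
                            ExpressionConfig(**cfg.expression),
                            seed=cfg.seed)
    write_dataset(data, outdir)


def stage_clinical(cfg: RunConfig, outdir: Path) -> None:
    subjects = bio.read_tsv(_require(outdir, "subjects.tsv", "clinical"))
    roi = bio.read_tsv(_require(outdir, "roi_measures.tsv", "clinical"))
    results = run_clinical_stage(subjects, roi)
    bio.write_tsv(results, outdir / "clinical_results.tsv")


def stage_covariance(cfg: RunConfig, outdir: Path) -> None:
    surface = _load_surface(cfg, outdir, "covariance")
    roi = bio.read_tsv(_require(outdir, "roi_measures.tsv", "covariance"))
    for seed_region in cfg.seed_regions:
        cov = map_covariance(surface, roi, seed_region=seed_region,
                             fdr_q=cfg.fdr_q)
        for structure, g in cov.groupby("structure"):
            if structure not in cfg.covariance_structures:
                continue
            bio.write_tsv(g, outdir / f"covariance_{seed_region}_{structure}.tsv")
        bio.write_tsv(summarize_map(cov),
                      outdir / f"covariance_summary_{seed_region}.tsv")


def stage_ahba_prep(cfg: RunConfig, outdir: Path) -> None:
    expression = bio.read_matrix_tsv(_require(outdir, "expression.tsv",
                                              "ahba_prep"))
    probes = bio.read_tsv(_require(outdir, "probes.tsv", "ahba_prep"))
    samples = bio.read_tsv(_require(outdir, "samples.tsv", "ahba_prep"))
    vertices = bio.read_tsv(_require(outdir, "surface_vertices.tsv",
                                     "ahba_prep"))
    gene_expr, mapping, dropped = select_probes(probes, expression)
    rules = SampleQCRules(bounding_spheres={
        lab: (BF_CENTERS[lab], cfg.bf_qc_radius_mm) for lab in BF_CENTERS})
    samples_qc, qc_log = qc_samples(samples, rules)
    qc_log["genes_dropped_no_passing_probe"] = dropped
    # left cortex only by default: only a minority of donors sample the
    # right hemisphere, so cross-hemisphere matches are not meaningful
    cortical = samples_qc[(samples_qc.structure_label == "cortex")
                          & (samples_qc.x < 0)]
    matches, match_summary = match_samples_to_vertices(
        cortical, vertices, max_distance_mm=cfg.match_cutoff_mm)
    qc_log["match_summary"] = match_summary
    bio.write_matrix_tsv(gene_expr, outdir / "gene_expression.tsv",
                         index_name="gene")
    bio.write_tsv(mapping, outdir / "probe_gene_mapping.tsv")
    bio.write_tsv(samples_qc, outdir / "samples_qc.tsv")
    bio.write_tsv(matches, outdir / "matches.tsv")
    bio.write_json(qc_log, outdir / "qc_log.json")


def stage_region_expression(cfg: RunConfig, outdir: Path) -> None:
    gene_expr = bio.read_matrix_tsv(_require(outdir, "gene_expression.tsv",
                                             "region_expression"))
    samples = bio.read_tsv(_require(outdir, "samples_qc.tsv",
                                    "region_expression"))
    for region in cfg.target_regions:
        stats = run_region_expression(gene_expr, samples, region)
        bio.write_tsv(stats, outdir / f"region_stats_{region}.tsv")
        for thr, genes in stats.attrs["fdr_lists"].items():
            name = f"genes_{region}_fdr{int(round(thr * 100))}.txt"
            (outdir / name).write_text("\n".join(genes) + "\n")


def stage_imaging_tx(cfg: RunConfig, outdir: Path) -> None:
    seed_region = cfg.imaging_seed_region
    cov = bio.read_tsv(_require(outdir,
                                f"covariance_{seed_region}_cortex-L.tsv",
                                "imaging_tx"))
    matches = bio.read_tsv(_require(outdir, "matches.tsv", "imaging_tx"))
    gene_expr = bio.read_matrix_tsv(_require(outdir, "gene_expression.tsv",
                                             "imaging_tx"))
    samples = bio.read_tsv(_require(outdir, "samples_qc.tsv", "imaging_tx"))
    design = assemble_design(cov, matches, gene_expr, samples)
    stats = fit_mixed_per_gene(design)
    sliced = rank_and_slice(stats, decile=cfg.decile,
                            fdr_thresholds=tuple(cfg.fdr_grid))
    bio.write_tsv(sliced["stats"], outdir / "imaging_gene_stats.tsv")
    (outdir / "top10.txt").write_text("\n".join(sliced["top"]) + "\n")
    (outdir / "bottom10.txt").write_text("\n".join(sliced["bottom"]) + "\n")
    bio.write_json({"fdr_counts": {str(k): v for k, v in
                                   sliced["fdr_counts"].items()},
                    "n_design_rows": len(design)},
                   outdir / "imaging_tx_summary.json")


def stage_enrichment(cfg: RunConfig, outdir: Path) -> None:
    gene_expr = bio.read_matrix_tsv(_require(outdir, "gene_expression.tsv",
                                             "enrichment"))
    universe = list(gene_expr.index)
    disease = bio.read_gmt(_require(outdir, "disease_sets.gmt", "enrichment"))
    collection = GeneSetCollection(sets=disease, universe=universe,
                                   source="synthetic_disease_sets")
    profiles = bio.read_matrix_tsv(_require(outdir, "cell_profiles.tsv",
                                            "enrichment"))
    psi = compute_psi(profiles, seed=cfg.seed)
    bio.write_matrix_tsv(psi.values, outdir / "psi_table.tsv",
                         index_name="gene")

    frames, grids = [], []
    for region in cfg.target_regions:
        path = _require(outdir, f"genes_{region}_fdr10.txt", "enrichment")
        genes = [g for g in path.read_text().splitlines() if g]
        res = hypergeom_enrich(genes, collection, fdr_alpha=cfg.fdr_q)
        res.insert(0, "query", f"{region}_fdr10")
        frames.append(res)
        grid = csea_enrich(genes, psi, universe, fdr_alpha=cfg.fdr_q)
        grid.insert(0, "query", f"{region}_fdr10")
        grids.append(grid)
    for name in ("top10", "bottom10"):
        p = outdir / f"{name}.txt"
        if p.exists():
            genes = [g for g in p.read_text().splitlines() if g]
            grid = csea_enrich(genes, psi, universe, fdr_alpha=cfg.fdr_q)
            grid.insert(0, "query", f"imaging_{name}")
            grids.append(grid)
    bio.write_tsv(pd.concat(frames, ignore_index=True),
                  outdir / "enrichment_results.tsv")
    grid_all = pd.concat(grids, ignore_index=True)
    bio.write_tsv(grid_all, outdir / "csea_grid.tsv")
    summaries = []
    for query, g in grid_all.groupby("query"):
        s = csea_summary(g)
        s.insert(0, "query", query)
        summaries.append(s)
    bio.write_tsv(pd.concat(summaries, ignore_index=True),
                  outdir / "csea_summary.tsv")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "clinical": stage_clinical,
    "covariance": stage_covariance,
    "ahba_prep": stage_ahba_prep,
    "region_expression": stage_region_expression,
    "imaging_tx": stage_imaging_tx,
    "enrichment": stage_enrichment,
}


def run_pipeline(config: RunConfig | None = None, outdir: str | Path = "run",
                 stages: list[str] | None = None) -> dict:
    """Execute pipeline stages in dependency order; returns the manifest."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(stages) if stages is not None else list(STAGES)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise InvalidArgumentError(f"unknown stages: {sorted(unknown)}")
    wanted = [s for s in STAGES if s in wanted]

    cfg.to_yaml(outdir / "run_config.yaml")
    manifest: dict = {"config": asdict(cfg), "stages": {}, "files": {}}
    for stage in wanted:
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        _STAGE_FUNCS[stage](cfg, outdir)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.1fs", stage,
                 manifest["stages"][stage]["seconds"])
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = bio.sha256_file(p)
    bio.write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# input validation (report-only)

_SCHEMAS = {
    "subjects.tsv": ["subject_id", "group", "age", "sex", "smoking", "cast",
                     "choline", "choline_crlb", "icv"],
    "roi_measures.tsv": ["subject_id", "region", "metric", "value"],
    "surface_vertices.tsv": ["vertex_id", "structure", "hemisphere",
                             "x", "y", "z"],
    "probes.tsv": ["probe_id", "gene", "qc_pass", "rnaseq_r"],
    "samples.tsv": ["sample_id", "donor_id", "structure_label", "x", "y", "z"],
}


def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Schema and sanity checks per input file; never raises, only reports."""
    report: dict = {"files": {}, "ok": True}
    for name, path in paths.items():
        entry: dict = {"path": str(path), "findings": []}
        path = Path(path)
        if not path.exists():
            entry["findings"].append("file missing")
        elif path.stat().st_size == 0:
            entry["findings"].append("empty file")
        else:
            try:
                df = bio.read_tsv(path)
            except Exception as exc:  # noqa: BLE001 - report, don't raise
                df = None
                entry["findings"].append(f"unreadable: {exc}")
            if df is not None:
                required = _SCHEMAS.get(name, [])
                missing = [c for c in required if c not in df.columns]
                if missing:
                    entry["findings"].append(f"missing columns: {missing}")
                id_col = required[0] if required else None
                if id_col and id_col in df.columns and name != "roi_measures.tsv":
                    dup = df[id_col].duplicated().sum()
                    if dup:
                        entry["findings"].append(
                            f"{dup} duplicate values in {id_col}")
                if df.empty:
                    entry["findings"].append("no data rows")
                entry["n_rows"] = int(len(df))
        entry["ok"] = not entry["findings"]
        report["ok"] &= entry["ok"]
        report["files"][name] = entry
    # cross-file coordinate-frame sanity
    if {"samples.tsv", "surface_vertices.tsv"} <= set(paths):
        try:
            s = bio.read_tsv(paths["samples.tsv"])
            v = bio.read_tsv(paths["surface_vertices.tsv"])
            span_s = s[["x", "y", "z"]].abs().to_numpy().max()
            span_v = v[["x", "y", "z"]].abs().to_numpy().max()
            shared = 0.2 < (span_s / span_v) < 5.0
            report["coordinate_frame_shared"] = bool(shared)
            if not shared:
                report["ok"] = False
        except Exception:
            report["coordinate_frame_shared"] = None
    return report
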