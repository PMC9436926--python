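"""Expression preprocessing: probe QC and probe-to-gene collapsing, sample
QC, and coordinate-based assignment of expression samples to surface
vertices.

Sample-to-vertex matching assigns each cortical sample to its nearest
vertex by Euclidean distance, removes samples farther than a configurable
cutoff (10 mm by default), and where several samples share a vertex keeps
only the closest one, so matching is one-to-one among retained records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import InvalidArgumentError


def select_probes(probes: pd.DataFrame, expression: pd.DataFrame):
    """Collapse probes to one per gene: among QC-passing probes, keep the
    probe with the highest correlation to RNA-seq.

    Returns ``(gene_expression, mapping, dropped_genes)`` where
    `gene_expression` is genes x samples, `mapping` records the chosen
    probe per gene, and `dropped_genes` lists genes with no passing probe.
    """
    required = {"probe_id", "gene", "qc_pass", "rnaseq_r"}
    if probes.empty:
        raise InvalidArgumentError("empty probe table")
    if not required <= set(probes.columns):
        raise InvalidArgumentError(
            f"probe table missing columns: {required - set(probes.columns)}")
    passing = probes[probes.qc_pass.astype(bool)]
    # deterministic arg-max: highest rnaseq_r, ties broken by probe_id
    passing = passing.sort_values(["gene", "rnaseq_r", "probe_id"],
                                  ascending=[True, False, True],
                                  kind="mergesort")
    chosen = passing.drop_duplicates("gene", keep="first")
    dropped = sorted(set(probes.gene) - set(chosen.gene))
    gene_expr = expression.loc[chosen.probe_id]
    gene_expr.index = pd.Index(chosen.gene, name="gene")
    mapping = chosen[["gene", "probe_id", "rnaseq_r"]].reset_index(drop=True)
    return gene_expr, mapping, dropped


@dataclass
class SampleQCRules:
    """Declarative sample QC: label allow-list, per-label coordinate
    bounding spheres, and an explicit exclusion list."""

    allowed_labels: list[str] | None = None
    bounding_spheres: dict = field(default_factory=dict)  # label -> (center, radius_mm)
    exclude_ids: list[str] = field(default_factory=list)


def qc_samples(samples: pd.DataFrame, rules: SampleQCRules | None = None):
    """Apply declarative QC rules; returns (filtered, exclusion_log).

    The log counts removals per rule and lists removed sample ids. An
    exclusion id absent from the table produces a warning entry, not an
    error.
    """
    for col in ("sample_id", "structure_label", "x", "y", "z"):
        if col not in samples.columns:
            raise InvalidArgumentError(f"sample table missing column {col}")
    rules = rules or SampleQCRules()
    df = samples.copy()
    log: dict = {"n_input": len(df), "removed": {}, "warnings": []}

    if rules.allowed_labels is not None:
        bad = ~df.structure_label.isin(rules.allowed_labels)
        log["removed"]["label_not_allowed"] = sorted(df.loc[bad, "sample_id"])
        df = df[~bad]
    for label, (center, radius) in rules.bounding_spheres.items():
        sub = df.structure_label == label
        d = np.sqrt(((df.loc[sub, ["x", "y", "z"]].to_numpy(float)
                      - np.asarray(center, float)) ** 2).sum(axis=1))
        bad_ids = df.loc[sub, "sample_id"][d > radius]
        log["removed"][f"out_of_region_{label}"] = sorted(bad_ids)
        df = df[~df.sample_id.isin(bad_ids)]
    if rules.exclude_ids:
        known = set(df.sample_id)
        missing = [i for i in rules.exclude_ids if i not in known]
        for i in missing:
            log["warnings"].append(f"exclusion id not present: {i}")
        hits = [i for i in rules.exclude_ids if i in known]
        log["removed"]["explicit_exclusion"] = sorted(hits)
        df = df[~df.sample_id.isin(hits)]
    log["n_retained"] = len(df)
    log["counts_by_label"] = df.structure_label.value_counts().to_dict()
    return df.reset_index(drop=True), log


def match_samples_to_vertices(samples: pd.DataFrame, vertices: pd.DataFrame,
                              max_distance_mm: float = 10.0,
                              cutoff_before_dedup: bool = True,
                              structures: tuple = ("cortex-L",)):
    """Assign each sample to its nearest vertex, one-to-one after QC.

    Steps: (1) restrict vertices to `structures` (left cortex by default,
    since only a minority of donors sample the right hemisphere);
    (2) nearest vertex per sample by Euclidean distance; (3) remove
    samples beyond `max_distance_mm` (before vertex dedup by default);
    (4) where several samples share a vertex, retain the closest,
    breaking exact ties by lowest vertex_id then lowest sample_id.

    Returns ``(matches, summary)``: `matches` has one row per input sample
    with (vertex_id, distance, retained, removal_reason); `summary`
    reports retained counts and the distance distribution.
    """
    verts = vertices[vertices.structure.isin(structures)]
    if verts.empty:
        raise InvalidArgumentError("empty vertex set after structure filter")
    vcoord = verts[["x", "y", "z"]].to_numpy(float)
    vids = verts.vertex_id.to_numpy()
    scoord = samples[["x", "y", "z"]].to_numpy(float)
    tree = cKDTree(vcoord)
    dist, j = tree.query(scoord, k=1)
    # deterministic tie-break: among equidistant vertices pick lowest vertex_id
    for i in range(len(samples)):
        cand = tree.query_ball_point(scoord[i], dist[i] + 1e-9)
        if len(cand) > 1:
            ids = sorted((vids[c] for c in cand
                          if abs(np.linalg.norm(vcoord[c] - scoord[i])
                                 - dist[i]) <= 1e-9))
            j[i] = np.where(vids == ids[0])[0][0]

    matches = pd.DataFrame({
        "sample_id": samples.sample_id.to_numpy(),
        "vertex_id": vids[j],
        "distance": dist,
        "retained": True,
        "removal_reason": "none",
    })

    def _apply_cutoff(m):
        over = m.retained & (m.distance > max_distance_mm)
        m.loc[over, ["retained", "removal_reason"]] = [False, "over_distance"]

    def _dedup(m):
        live = m[m.retained].sort_values(
            ["vertex_id", "distance", "sample_id"], kind="mergesort")
        dup = live.duplicated("vertex_id", keep="first")
        losers = live.loc[dup, "sample_id"]
        sel = m.sample_id.isin(losers)
        m.loc[sel, ["retained", "removal_reason"]] = [False, "duplicate_vertex"]

    if cutoff_before_dedup:
        _apply_cutoff(matches)
        _dedup(matches)
    else:
        _dedup(matches)
        _apply_cutoff(matches)

    kept = matches[matches.retained]
    summary = {
        "n_samples": len(matches),
        "n_retained": int(matches.retained.sum()),
        "n_over_distance": int((matches.removal_reason == "over_distance").sum()),
        "n_duplicate_vertex": int((matches.removal_reason == "duplicate_vertex").sum()),
        "mean_distance": float(kept.distance.mean()) if len(kept) else np.nan,
        "sd_distance": float(kept.distance.std(ddof=1)) if len(kept) > 1 else np.nan,
        "min_distance": float(kept.distance.min()) if len(kept) else np.nan,
        "max_distance": float(kept.distance.max()) if len(kept) else np.nan,
        "cutoff_mm": max_distance_mm,
        "cutoff_before_dedup": cutoff_before_dedup,
    }
    return matches, summary
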