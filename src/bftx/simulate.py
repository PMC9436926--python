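"""Synthetic cohort, imaging, MRS and atlas-style expression data.

The generator emulates the statistical structure of a first-episode
psychosis (FEP) case-control study of basal forebrain (BF) cholinergic
nuclei, plus a six-donor post-mortem microarray atlas, so that every
downstream analysis stage can be exercised and validated end-to-end
without any external data:

* a clinical cohort (default 56 FEP / 29 HC) with age, sex, smoking,
  cannabis (CAST), clinical scores (YMRS, PANSS-8 negative, CDS),
  cognition (DSST, trail making) and dACC MRS choline;
* per-subject BF microstructure (qT1, AxD, RD) for Ch1-3 and left/right
  NBM, with a planted case-control effect in Ch1-3 driven by a shared
  latent demyelination factor (so qT1/AxD/RD move together);
* choline coupled to left-NBM qT1 in controls and decoupled in patients;
* cortical/subcortical surface vertex clouds whose per-subject qT1 carries
  a latent projection field tied to the subject's BF microstructure;
* an expression bundle (probes x samples) with donor batch effects,
  BF-enriched genes, genes spatially coupled to the projection field,
  probe-level QC structure, and two planted QC cases (one mislabelled BF
  sample, one cortical sample displaced > 10 mm from every vertex);
* cell-type mean-expression profiles and disease gene sets (GMT) for the
  enrichment stage.

All ground-truth parameters are recorded in a :class:`GroundTruth` object
serialised next to the data, and every generator is deterministic given
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import InvalidArgumentError
from . import io as bio

REGIONS = ("Ch1-3", "NBM_L", "NBM_R")
METRICS = ("qt1", "axd", "rd")

# physical scales: qT1 in ms, diffusivities in 1e-3 mm^2/s
_SCALES = {
    "qt1": (1650.0, 60.0),
    "axd": (1.05, 0.06),
    "rd": (0.70, 0.05),
}

SUBCORTICAL = ("hippocampus", "amygdala", "striatum", "thalamus",
               "globus_pallidum")


@dataclass
class CohortConfig:
    """Cohort sizes, covariate distributions and planted effects.

    Effects are standardized (in units of the metric's total SD).
    """

    n_fep: int = 56
    n_hc: int = 29
    # planted case-control effects per (region, metric); Ch1-3 qT1 and AxD
    # elevated in FEP, RD follows the same latent demyelination factor
    effect_ch13_qt1: float = 0.62
    effect_ch13_axd: float = 0.65
    effect_ch13_rd: float = 0.50
    effect_nbm_qt1: float = 0.0
    effect_nbm_axd: float = 0.0
    # within-region latent loading tying qt1/axd/rd together
    metric_latent_rho: float = 0.5
    # choline coupling: corr(choline, NBM_L qT1) in HC, zero in FEP
    hc_coupling_r: float = -0.5
    fep_coupling_r: float = 0.0
    choline_group_effect: float = 0.0
    # clinical couplings inside FEP
    ymrs_qt1_r: float = 0.45
    panss_axd_r: float = 0.36
    # covariate-group associations (FEP smoke and use cannabis more)
    smoking_rate_fep: float = 0.30
    smoking_rate_hc: float = 0.0
    # calibrated so the expected CAST group-difference t is ~5.6 at 56/29
    cast_lambda_fep: float = 1.3
    cast_lambda_hc: float = 0.3
    choline_mean: float = 1.60
    choline_sd: float = 0.25
    crlb_mean: float = 1.88
    crlb_sd: float = 0.52
    # available-case structure for cognition
    n_missing_trails_fep: int = 18
    n_missing_trails_hc: int = 4
    n_missing_dsst_fep: int = 1


@dataclass
class SurfaceConfig:
    """Vertex clouds and the latent projection field."""

    n_vertices_per_hemi: int = 2000
    n_subcortical_per_structure: int = 100
    field_strength_ms: float = 12.0   # qT1 change per unit latent at |field|=1
    subject_mean_sd_ms: float = 8.0
    noise_sd_ms: float = 10.0
    smooth_bandwidth_mm: float = 20.0
    latent_region: str = "NBM_L"
    latent_metric: str = "qt1"


@dataclass
class ExpressionConfig:
    """Microarray-style bundle: donors, samples, probes, planted genes."""

    n_genes: int = 2000
    n_donors: int = 6
    cortical_samples_per_donor: int = 60       # left hemisphere, all donors
    right_samples_per_donor: int = 20          # only the last 2 donors
    nbm_sample_counts: tuple = (3, 2, 2, 2)    # donors 1-4 -> 9 NBM samples
    ch13_sample_counts: tuple = (3, 2, 2, 2)   # 9 Ch1-3, one mislabelled
    donor_sd_log2: float = 0.5
    noise_sd_log2: float = 0.5
    gene_base_mean: float = 6.0
    gene_base_sd: float = 1.0
    n_bf_enriched: int = 30
    bf_effect_log2: float = 1.0                # ~2 SD of noise: strong marker
    n_field_coupled: int = 30
    field_slope_log2: float = 1.0
    second_probe_frac: float = 0.3
    qc_fail_frac: float = 0.10
    displaced_sample_offset_mm: float = 15.0


@dataclass
class GroundTruth:
    """Planted parameters, serialised alongside generated data."""

    seed: int
    effects: dict = field(default_factory=dict)
    hc_coupling_r: float = 0.0
    fep_coupling_r: float = 0.0
    clinical_couplings: dict = field(default_factory=dict)
    bf_enriched_genes: list = field(default_factory=list)
    field_coupled_genes: list = field(default_factory=list)
    cell_markers: dict = field(default_factory=dict)
    donor_effects: dict = field(default_factory=dict)
    mislabelled_sample: str | None = None
    displaced_sample: str | None = None
    field_summary: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        bio.write_json(asdict(self), path)


def _positive_int(rng, mean_latent, scale, base):
    v = np.rint(base + scale * mean_latent)
    return np.clip(v, 0, None)


def generate_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Generate the clinical cohort and ROI microstructure tables.

    Returns ``(subjects, roi, truth)`` where `subjects` is one row per
    participant, `roi` is a tidy (subject_id, region, metric, value) table
    in physical units, and `truth` records every planted parameter.
    """
    cfg = config or CohortConfig()
    if cfg.n_fep < 3 or cfg.n_hc < 3:
        raise InvalidArgumentError("group sizes must be >= 3")
    for name, val in asdict(cfg).items():
        if name.startswith("effect") and not np.isfinite(val):
            raise InvalidArgumentError(f"non-finite effect size: {name}")
    rng = np.random.default_rng(seed)
    n = cfg.n_fep + cfg.n_hc
    fep = np.concatenate([np.ones(cfg.n_fep), np.zeros(cfg.n_hc)])
    subject_id = [f"S{i:03d}" for i in range(n)]

    age = np.where(fep == 1, rng.normal(22.3, 4.3, n), rng.normal(21.7, 3.5, n))
    age = np.clip(age, 16, 40)
    sex = np.where(
        rng.random(n) < np.where(fep == 1, 43 / 56, 18 / 29), "M", "F")
    smoking = (rng.random(n) < np.where(fep == 1, cfg.smoking_rate_fep,
                                        cfg.smoking_rate_hc)).astype(int)
    cast = rng.poisson(np.where(fep == 1, cfg.cast_lambda_fep,
                                cfg.cast_lambda_hc))
    icv = rng.normal(1.5e6, 1.3e5, n) + np.where(sex == "M", 6e4, -6e4)

    # latent demyelination factor per region (shared across metrics)
    effects = {
        ("Ch1-3", "qt1"): cfg.effect_ch13_qt1,
        ("Ch1-3", "axd"): cfg.effect_ch13_axd,
        ("Ch1-3", "rd"): cfg.effect_ch13_rd,
        ("NBM_L", "qt1"): cfg.effect_nbm_qt1,
        ("NBM_L", "axd"): cfg.effect_nbm_axd,
        ("NBM_L", "rd"): 0.0,
        ("NBM_R", "qt1"): cfg.effect_nbm_qt1,
        ("NBM_R", "axd"): cfg.effect_nbm_axd,
        ("NBM_R", "rd"): 0.0,
    }
    rho = cfg.metric_latent_rho
    z = {}
    for region in REGIONS:
        latent = rng.normal(size=n)
        for metric in METRICS:
            eps = rng.normal(size=n)
            d = effects[(region, metric)]
            z[(region, metric)] = (d * fep + np.sqrt(rho) * latent
                                   + np.sqrt(1 - rho) * eps)

    rows = []
    for (region, metric), zval in z.items():
        mu, sd = _SCALES[metric]
        for i in range(n):
            rows.append((subject_id[i], region, metric, mu + sd * zval[i]))
    roi = pd.DataFrame(rows, columns=["subject_id", "region", "metric",
                                      "value"])

    # choline: coupled to NBM_L qT1 in HC, decoupled in FEP
    q = z[("NBM_L", "qt1")]
    qc = (q - q.mean()) / q.std()
    slope = np.where(fep == 1, cfg.fep_coupling_r, cfg.hc_coupling_r)
    resid_sd = np.sqrt(np.clip(1 - slope ** 2, 0.05, 1.0))
    chol_z = (slope * qc + resid_sd * rng.normal(size=n)
              + cfg.choline_group_effect * fep
              + 0.10 * (age - age.mean()) / age.std())
    choline = cfg.choline_mean + cfg.choline_sd * chol_z
    crlb = np.clip(rng.normal(cfg.crlb_mean, cfg.crlb_sd, n), 0.8, None)

    # clinical scores: FEP only; YMRS tracks NBM_L qT1, PANSS-neg tracks AxD
    a = z[("NBM_L", "axd")]
    ac = (a - a.mean()) / a.std()
    ymrs_lat = cfg.ymrs_qt1_r * qc + np.sqrt(1 - cfg.ymrs_qt1_r ** 2) * \
        rng.normal(size=n)
    panss_lat = cfg.panss_axd_r * ac + np.sqrt(1 - cfg.panss_axd_r ** 2) * \
        rng.normal(size=n)
    ymrs = np.where(fep == 1, _positive_int(rng, ymrs_lat, 5.0, 8.0), np.nan)
    panss = np.where(fep == 1, _positive_int(rng, panss_lat, 4.0, 7.0), np.nan)
    cds = np.where(fep == 1, rng.poisson(3.7, n).astype(float), np.nan)

    dsst = np.where(fep == 1, rng.normal(51.8, 14.0, n),
                    rng.normal(68.7, 11.3, n))
    trails = np.where(fep == 1, np.exp(rng.normal(np.log(80), 0.5, n)),
                      np.exp(rng.normal(np.log(53), 0.28, n)))

    subjects = pd.DataFrame({
        "subject_id": subject_id,
        "group": np.where(fep == 1, "FEP", "HC"),
        "age": age, "sex": sex, "smoking": smoking, "cast": cast,
        "ymrs": ymrs, "panss8_neg": panss, "cds": cds,
        "dsst": dsst, "trails": trails,
        "choline": choline, "choline_crlb": crlb, "icv": icv,
    })
    # available-case missingness in cognition
    fep_idx = subjects.index[subjects.group == "FEP"]
    hc_idx = subjects.index[subjects.group == "HC"]
    miss = rng.choice(fep_idx, size=min(cfg.n_missing_trails_fep,
                                        len(fep_idx)), replace=False)
    subjects.loc[miss, "trails"] = np.nan
    miss = rng.choice(hc_idx, size=min(cfg.n_missing_trails_hc,
                                       len(hc_idx)), replace=False)
    subjects.loc[miss, "trails"] = np.nan
    miss = rng.choice(fep_idx, size=min(cfg.n_missing_dsst_fep,
                                        len(fep_idx)), replace=False)
    subjects.loc[miss, "dsst"] = np.nan

    truth = GroundTruth(
        seed=seed,
        effects={f"{r}:{m}": v for (r, m), v in effects.items()},
        hc_coupling_r=cfg.hc_coupling_r,
        fep_coupling_r=cfg.fep_coupling_r,
        clinical_couplings={"ymrs~NBM_L.qt1": cfg.ymrs_qt1_r,
                            "panss8_neg~NBM_L.axd": cfg.panss_axd_r},
    )
    return subjects, roi, truth


def roi_wide(roi: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy ROI table to one row per subject, columns region.metric."""
    w = roi.pivot_table(index="subject_id", columns=["region", "metric"],
                        values="value")
    w.columns = [f"{r}.{m}" for r, m in w.columns]
    return w.reset_index()


# ---------------------------------------------------------------------------
# surfaces


def _sphere_points(rng, n, radii, center, hemisphere=None):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * np.asarray(radii) + np.asarray(center)
    if hemisphere == "L":
        pts[:, 0] = -np.abs(pts[:, 0] - center[0]) + center[0]
    elif hemisphere == "R":
        pts[:, 0] = np.abs(pts[:, 0] - center[0]) + center[0]
    return pts


def _projection_field(coords: np.ndarray) -> np.ndarray:
    """Smooth latent field: positive frontal lobe, weaker negative occipital."""
    c_front = np.array([-20.0, 55.0, 20.0])
    c_back = np.array([-20.0, -75.0, 10.0])
    f = (np.exp(-np.sum((coords - c_front) ** 2, axis=1) / (2 * 30.0 ** 2))
         - 0.6 * np.exp(-np.sum((coords - c_back) ** 2, axis=1) / (2 * 30.0 ** 2)))
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _smooth_noise(rng, coords, n_subjects, bandwidth):
    """Spatially correlated noise via a Gaussian-kernel covariance."""
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    K = np.exp(-d2 / (2 * bandwidth ** 2)) + 1e-6 * np.eye(len(coords))
    L = np.linalg.cholesky(K)
    return rng.normal(size=(n_subjects, len(coords))) @ L.T


@dataclass
class SurfaceBundle:
    vertices: pd.DataFrame          # vertex_id, structure, hemisphere, x,y,z, field, label
    qt1: pd.DataFrame               # subjects x vertices (index subject_id)
    config: SurfaceConfig


def generate_surfaces(subjects: pd.DataFrame, roi: pd.DataFrame,
                      config: SurfaceConfig | None = None,
                      seed: int = 0) -> SurfaceBundle:
    """Per-subject vertex-wise qT1 carrying the latent projection field.

    Vertex qT1 = subject offset + field(vertex) * subject BF latent +
    spatially smooth noise, where the BF latent is the subject's z-scored
    seed-region qT1, so seed-to-vertex covariance recovers the field.
    """
    cfg = config or SurfaceConfig()
    if cfg.n_vertices_per_hemi < 10:
        raise InvalidArgumentError("need >= 10 vertices per hemisphere")
    rng = np.random.default_rng(seed)
    w = roi_wide(roi).set_index("subject_id").loc[subjects.subject_id]
    latent = w[f"{cfg.latent_region}.{cfg.latent_metric}"].to_numpy()
    latent = (latent - latent.mean()) / latent.std()
    n_subj = len(subjects)

    frames = []
    radii = (65.0, 85.0, 60.0)
    for hemi, cx in (("L", -35.0), ("R", 35.0)):
        pts = _sphere_points(rng, cfg.n_vertices_per_hemi, radii,
                             (cx, -10.0, 15.0), hemisphere=hemi)
        frames.append(pd.DataFrame({
            "structure": f"cortex-{hemi}", "hemisphere": hemi,
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}))
    centers = {"hippocampus": (-28, -24, -12), "amygdala": (-24, -4, -18),
               "striatum": (-20, 8, 2), "thalamus": (-10, -18, 8),
               "globus_pallidum": (-16, -2, -2)}
    for s in SUBCORTICAL:
        pts = rng.normal(centers[s], (6, 10, 6),
                         size=(cfg.n_subcortical_per_structure, 3))
        frames.append(pd.DataFrame({
            "structure": s, "hemisphere": "L",
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}))
    vertices = pd.concat(frames, ignore_index=True)
    vertices.insert(0, "vertex_id", [f"V{i:05d}" for i in range(len(vertices))])
    coords = vertices[["x", "y", "z"]].to_numpy()
    fld = _projection_field(coords)
    vertices["field"] = fld
    # coarse anatomical labels for map summaries
    lab = np.where(vertices.y > 30, "frontal",
                   np.where(vertices.y < -45, "occipital", "central"))
    lab = np.where(vertices.structure.str.startswith("cortex"), lab,
                   vertices.structure)
    vertices["label"] = lab

    subj_off = rng.normal(0, cfg.subject_mean_sd_ms, n_subj)
    base = 2000.0
    qt1 = (base + subj_off[:, None]
           + cfg.field_strength_ms * np.outer(latent, fld))
    for s in vertices.structure.unique():
        idx = np.where(vertices.structure.to_numpy() == s)[0]
        qt1[:, idx] += cfg.noise_sd_ms * _smooth_noise(
            rng, coords[idx], n_subj, cfg.smooth_bandwidth_mm)
    qt1 = pd.DataFrame(qt1, index=pd.Index(subjects.subject_id,
                                           name="subject_id"),
                       columns=vertices.vertex_id)
    return SurfaceBundle(vertices=vertices, qt1=qt1, config=cfg)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionBundle:
    expression: pd.DataFrame     # probes x samples, log2 intensity
    probes: pd.DataFrame         # probe_id, gene, qc_pass, rnaseq_r
    samples: pd.DataFrame        # sample_id, donor_id, structure_label, x,y,z
    config: ExpressionConfig


def _displace_inward(coord, all_coords, min_dist):
    """Pull a point toward the centroid of the reference cloud until it is
    > min_dist from every reference point (the planted over-distance QC
    case). The reference cloud is a (hemi)spherical shell, so its centroid
    lies well inside it."""
    centroid = all_coords.mean(axis=0)
    p = coord.copy()
    for frac in np.linspace(0.0, 1.0, 51):
        cand = coord * (1 - frac) + centroid * frac
        d = np.sqrt(((all_coords - cand) ** 2).sum(axis=1)).min()
        if d > min_dist:
            return cand
    raise RuntimeError("could not displace sample beyond cutoff")


def generate_expression(surface: SurfaceBundle,
                        config: ExpressionConfig | None = None,
                        seed: int = 0,
                        truth: GroundTruth | None = None) -> ExpressionBundle:
    """Atlas-style expression with donor effects and planted gene structure."""
    cfg = config or ExpressionConfig()
    if cfg.n_donors < 2:
        raise InvalidArgumentError("need >= 2 donors")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    bf_genes = list(rng.choice(genes, cfg.n_bf_enriched, replace=False))
    rest = [g for g in genes if g not in set(bf_genes)]
    field_genes = list(rng.choice(rest, cfg.n_field_coupled, replace=False))
    donors = [f"D{i+1}" for i in range(cfg.n_donors)]
    donor_eff = dict(zip(donors, rng.normal(0, cfg.donor_sd_log2,
                                            cfg.n_donors)))

    verts = surface.vertices
    cortexL = verts[verts.structure == "cortex-L"]
    cortexR = verts[verts.structure == "cortex-R"]
    cortL_coords = cortexL[["x", "y", "z"]].to_numpy()

    srows = []
    for d in donors:
        pick = rng.choice(len(cortexL), cfg.cortical_samples_per_donor,
                          replace=False)
        for j in pick:
            v = cortexL.iloc[j]
            jit = rng.normal(0, 1.0, 3)
            srows.append((d, "cortex", v.x + jit[0], v.y + jit[1],
                          v.z + jit[2], v.field))
    for d in donors[-2:]:
        pick = rng.choice(len(cortexR), cfg.right_samples_per_donor,
                          replace=False)
        for j in pick:
            v = cortexR.iloc[j]
            jit = rng.normal(0, 1.0, 3)
            srows.append((d, "cortex", v.x + jit[0], v.y + jit[1],
                          v.z + jit[2], v.field))
    bf_center = {"NBM": np.array([-18.0, -2.0, -12.0]),
                 "Ch1-3": np.array([0.0, 2.0, -9.0])}
    for label, counts in (("NBM", cfg.nbm_sample_counts),
                          ("Ch1-3", cfg.ch13_sample_counts)):
        for d, k in zip(donors[:4], counts):
            for _ in range(k):
                c = bf_center[label] + rng.normal(0, 2.0, 3)
                srows.append((d, label, c[0], c[1], c[2], 0.0))
    samples = pd.DataFrame(srows, columns=["donor_id", "structure_label",
                                           "x", "y", "z", "field"])
    samples.insert(0, "sample_id",
                   [f"A{i:04d}" for i in range(len(samples))])

    # planted QC case 1: one Ch1-3 sample mislabelled / misplaced (far from BF)
    ch13_ids = samples.index[samples.structure_label == "Ch1-3"]
    mis = ch13_ids[-1]
    samples.loc[mis, ["x", "y", "z"]] = (40.0, -60.0, 30.0)
    mislabelled_id = samples.loc[mis, "sample_id"]

    # planted QC case 2: one left-cortical sample > cutoff from every vertex
    cort_ids = samples.index[(samples.structure_label == "cortex")
                             & (samples.x < 0)]
    disp = cort_ids[0]
    newc = _displace_inward(samples.loc[disp, ["x", "y", "z"]].to_numpy(float),
                            cortL_coords, cfg.displaced_sample_offset_mm)
    samples.loc[disp, ["x", "y", "z"]] = newc
    displaced_id = samples.loc[disp, "sample_id"]

    # expression matrix at gene level, then expand to probes
    n_s = len(samples)
    base = rng.normal(cfg.gene_base_mean, cfg.gene_base_sd, cfg.n_genes)
    expr = np.tile(base[:, None], (1, n_s))
    expr += np.array([donor_eff[d] for d in samples.donor_id])[None, :]
    is_bf = samples.structure_label.isin(["NBM", "Ch1-3"]).to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    for g in bf_genes:
        expr[gidx[g], is_bf] += cfg.bf_effect_log2
    is_cort = (samples.structure_label == "cortex").to_numpy()
    fvals = samples.field.to_numpy()
    for g in field_genes:
        expr[gidx[g], is_cort] += cfg.field_slope_log2 * fvals[is_cort]
    expr += rng.normal(0, cfg.noise_sd_log2, expr.shape)

    # probes: one primary per gene; a fraction of genes get a weaker second
    # probe; qc failures planted at probe level
    prows, pexpr = [], []
    for i, g in enumerate(genes):
        r1 = rng.uniform(0.5, 0.95)
        prows.append((f"P{i:04d}_1", g, True, r1))
        pexpr.append(expr[i])
        if rng.random() < cfg.second_probe_frac:
            r2 = rng.uniform(0.1, r1)
            prows.append((f"P{i:04d}_2", g, True, r2))
            pexpr.append(expr[i] + rng.normal(0, 0.3, n_s))
    probes = pd.DataFrame(prows, columns=["probe_id", "gene", "qc_pass",
                                          "rnaseq_r"])
    fail = rng.random(len(probes)) < cfg.qc_fail_frac
    probes["qc_pass"] = ~fail
    expression = pd.DataFrame(np.asarray(pexpr),
                              index=pd.Index(probes.probe_id, name="probe_id"),
                              columns=samples.sample_id)

    if truth is not None:
        truth.bf_enriched_genes = bf_genes
        truth.field_coupled_genes = field_genes
        truth.donor_effects = {k: float(v) for k, v in donor_eff.items()}
        truth.mislabelled_sample = str(mislabelled_id)
        truth.displaced_sample = str(displaced_id)
        truth.field_summary = {
            "field_strength_ms": surface.config.field_strength_ms,
            "max_abs_field": float(np.abs(surface.vertices.field).max()),
        }
    return ExpressionBundle(expression=expression, probes=probes,
                            samples=samples.drop(columns="field"),
                            config=cfg)


# ---------------------------------------------------------------------------
# cell-type profiles and disease sets for the enrichment stage

CELL_TYPES = ("cholinergic_neurons", "oligodendrocytes", "astrocytes",
              "cortical_neurons", "microglia")


def generate_cell_type_profiles(genes: list[str], truth: GroundTruth,
                                seed: int = 0, markers_per_type: int = 40,
                                marker_boost: float = 2.5) -> pd.DataFrame:
    """Mean expression per (gene, cell type) with planted marker structure.

    The planted BF-enriched genes are markers of cholinergic neurons and
    half of the field-coupled genes are oligodendrocyte markers, so the
    downstream cell-type enrichment recovers them.
    """
    rng = np.random.default_rng(seed)
    n = len(genes)
    prof = rng.normal(6.0, 0.6, size=(n, len(CELL_TYPES)))
    gidx = {g: i for i, g in enumerate(genes)}
    markers: dict[str, list[str]] = {}
    chol = [g for g in truth.bf_enriched_genes if g in gidx]
    oligo = [g for g in truth.field_coupled_genes if g in gidx]
    oligo = oligo[: len(oligo) // 2]
    taken = set(chol) | set(oligo)
    pool = [g for g in genes if g not in taken]
    rng.shuffle(pool)
    for ct in CELL_TYPES:
        if ct == "cholinergic_neurons":
            mk = list(chol)
        elif ct == "oligodendrocytes":
            mk = list(oligo)
        else:
            mk, pool = pool[:markers_per_type], pool[markers_per_type:]
        extra_needed = markers_per_type - len(mk)
        if extra_needed > 0:
            mk, pool = mk + pool[:extra_needed], pool[extra_needed:]
        for g in mk:
            prof[gidx[g], CELL_TYPES.index(ct)] += marker_boost
        markers[ct] = mk
    truth.cell_markers = markers
    return pd.DataFrame(prof, index=pd.Index(genes, name="gene"),
                        columns=list(CELL_TYPES))


def generate_disease_sets(genes: list[str], truth: GroundTruth,
                          seed: int = 0) -> dict[str, list[str]]:
    """GMT-style disease gene sets; the schizophrenia-like set is seeded
    with planted BF-enriched genes so BF expression shows real overlap."""
    rng = np.random.default_rng(seed)
    bf = list(truth.bf_enriched_genes)
    other = [g for g in genes if g not in set(bf)]
    rng.shuffle(other)
    sets = {
        "schizophrenia_like": bf[:20] + other[:60],
        "depression_like": bf[20:28] + other[60:115],
        "control_set_1": other[115:165],
        "control_set_2": other[165:215],
    }
    return {k: sorted(v) for k, v in sets.items()}


# ---------------------------------------------------------------------------
# one-call dataset plus on-disk serialisation


def generate_dataset(cohort_cfg: CohortConfig | None = None,
                     surface_cfg: SurfaceConfig | None = None,
                     expr_cfg: ExpressionConfig | None = None,
                     seed: int = 0) -> dict:
    """Generate every synthetic input the pipeline consumes."""
    subjects, roi, truth = generate_cohort(cohort_cfg, seed=seed)
    surface = generate_surfaces(subjects, roi, surface_cfg, seed=seed + 1)
    bundle = generate_expression(surface, expr_cfg, seed=seed + 2, truth=truth)
    profiles = generate_cell_type_profiles(
        sorted(bundle.probes.gene.unique()), truth, seed=seed + 3)
    disease = generate_disease_sets(sorted(bundle.probes.gene.unique()),
                                    truth, seed=seed + 4)
    return {"subjects": subjects, "roi": roi, "surface": surface,
            "expression": bundle, "cell_profiles": profiles,
            "disease_sets": disease, "truth": truth}


def write_dataset(data: dict, outdir: str | Path) -> None:
    """Serialise a generated dataset to TSV/GMT/JSON under `outdir`."""
    outdir = Path(outdir)
    bio.write_tsv(data["subjects"], outdir / "subjects.tsv")
    bio.write_tsv(data["roi"], outdir / "roi_measures.tsv")
    bio.write_tsv(data["surface"].vertices, outdir / "surface_vertices.tsv")
    bio.write_matrix_tsv(data["surface"].qt1, outdir / "surface_qt1.tsv",
                         index_name="subject_id")
    bio.write_matrix_tsv(data["expression"].expression,
                         outdir / "expression.tsv", index_name="probe_id")
    bio.write_tsv(data["expression"].probes, outdir / "probes.tsv")
    bio.write_tsv(data["expression"].samples, outdir / "samples.tsv")
    bio.write_matrix_tsv(data["cell_profiles"], outdir / "cell_profiles.tsv",
                         index_name="gene")
    bio.write_gmt(data["disease_sets"], outdir / "disease_sets.gmt")
    data["truth"].to_json(outdir / "ground_truth.json")
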