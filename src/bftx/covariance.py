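"""Seed-to-brain structural covariance mapping.

Correlates a basal-forebrain seed's per-subject qT1 with every cortical or
subcortical vertex across subjects (pooled over groups by default), with
Benjamini-Hochberg FDR computed within each structure separately and a
p < 0.05 subthreshold fallback flag for maps where nothing survives
q < 0.10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (InsufficientDataError, InvalidArgumentError, bh_fdr,
                    t_tail_p_vec)
from .simulate import SurfaceBundle, roi_wide


def _pearson_seed_vs_matrix(seed: np.ndarray, mat: np.ndarray):
    """Pearson r of one vector against every column; complete rows only."""
    xc = seed - seed.mean()
    mc = mat - mat.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum())
    sm = np.sqrt((mc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ mc) / (sx * sm)
    return r


def map_covariance(surface: SurfaceBundle, roi: pd.DataFrame,
                   seed_region: str = "NBM_L", metric: str = "qt1",
                   structures: list[str] | None = None,
                   fdr_q: float = 0.10, subthreshold_p: float = 0.05,
                   max_missing_frac: float = 0.20,
                   groups: list[str] | None = None,
                   subjects: pd.DataFrame | None = None,
                   residualize: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-vertex correlation of a BF seed with every surface unit.

    Returns one row per vertex with (r, p, q, passes_fdr,
    subthreshold_flag); q-values are computed within each structure only.
    `groups` optionally restricts to a diagnosis subset (requires
    `subjects`); `residualize` optionally regresses given covariate columns
    out of both seed and vertex values first.
    """
    w = roi_wide(roi).set_index("subject_id")
    common = w.index.intersection(surface.qt1.index)
    if groups is not None:
        if subjects is None:
            raise InvalidArgumentError("groups filter requires subjects table")
        keep = subjects.loc[subjects.group.isin(groups), "subject_id"]
        common = common.intersection(pd.Index(keep))
    if len(common) < 5:
        raise InsufficientDataError(
            f"only {len(common)} overlapping subjects")
    seed = w.loc[common, f"{seed_region}.{metric}"].to_numpy(float)
    qt1 = surface.qt1.loc[common]
    verts = surface.vertices.set_index("vertex_id").loc[qt1.columns]
    if structures is not None:
        keep_v = verts.structure.isin(structures)
        verts, qt1 = verts[keep_v], qt1.loc[:, keep_v.to_numpy()]

    if residualize is not None:
        import statsmodels.api as sm
        Z = sm.add_constant(residualize.loc[common].to_numpy(float))
        H = Z @ np.linalg.pinv(Z)
        seed = seed - H @ seed
        qt1 = pd.DataFrame(qt1.to_numpy() - H @ qt1.to_numpy(),
                           index=qt1.index, columns=qt1.columns)

    mat = qt1.to_numpy(float)
    n = mat.shape[0]
    frac_missing = np.mean(~np.isfinite(mat), axis=0)
    usable = frac_missing <= max_missing_frac
    constant = np.nanstd(mat, axis=0) == 0
    usable &= ~constant

    r = np.full(mat.shape[1], np.nan)
    complete = np.isfinite(mat).all(axis=0) & np.isfinite(seed).all()
    if complete.any():
        r[usable & complete] = _pearson_seed_vs_matrix(
            seed, mat[:, usable & complete])
    # per-vertex complete-pairs fallback where values are missing
    for j in np.where(usable & ~complete)[0]:
        col = mat[:, j]
        k = np.isfinite(col) & np.isfinite(seed)
        if k.sum() >= 5 and np.ptp(col[k]) > 0:
            r[j] = np.corrcoef(seed[k], col[k])[0, 1]

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.clip(1 - r ** 2, 1e-300, None))
    p = np.where(np.isfinite(r), t_tail_p_vec(np.where(np.isfinite(t), t, 0.0),
                                              df), np.nan)
    p = np.where(np.isfinite(r) & (np.abs(r) >= 1.0), 0.0, p)

    out = pd.DataFrame({
        "seed": seed_region, "metric": metric,
        "unit_id": verts.index, "structure": verts.structure.to_numpy(),
        "label": verts.label.to_numpy(),
        "r": r, "p": p, "df": df, "n_used": n,
    })
    out["q"] = np.nan
    for s, idx in out.groupby("structure").groups.items():
        pv = out.loc[idx, "p"]
        ok = pv.notna().to_numpy()
        if ok.any():
            out.loc[idx[ok], "q"] = bh_fdr(pv[ok].to_numpy()).q
    out["passes_fdr"] = out.q < fdr_q
    out["subthreshold_flag"] = (~out.passes_fdr) & (out.p < subthreshold_p)
    out.attrs["n_excluded_constant"] = int(constant.sum())
    out.attrs["n_excluded_missing"] = int((frac_missing > max_missing_frac).sum())
    return out.reset_index(drop=True)


def summarize_map(cov_map: pd.DataFrame,
                  atlas_labels: pd.Series | dict | None = None,
                  top_n: int = 10) -> pd.DataFrame:
    """Per-label mean r, counts of FDR-passing units, and top units.

    `atlas_labels` maps unit_id -> label; defaults to the map's own
    `label` column. Labels must cover all units.
    """
    df = cov_map.copy()
    if atlas_labels is not None:
        lab = pd.Series(atlas_labels)
        missing = set(df.unit_id) - set(lab.index)
        if missing:
            raise InvalidArgumentError(
                f"{len(missing)} units without a label, e.g. "
                f"{sorted(missing)[:3]}")
        df["label"] = lab.loc[df.unit_id].to_numpy()
    rows = []
    for label, g in df.groupby("label", sort=True):
        gs = g.sort_values(["r", "unit_id"], ascending=[False, True])
        rows.append({
            "label": label,
            "n_units": len(g),
            "mean_r": g.r.mean(),
            "n_passing_fdr": int(g.passes_fdr.sum()),
            "n_subthreshold": int(g.subthreshold_flag.sum()),
            "top_units": ",".join(gs.unit_id.head(top_n)),
        })
    return pd.DataFrame(rows).sort_values("mean_r", ascending=False,
                                          kind="mergesort").reset_index(drop=True)
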