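"""Region-specific expression via per-gene linear models and
empirical-Bayes moderated t-statistics.

For every gene, expression is regressed on donor indicator variables plus
an indicator of the target region (vs all other sampled regions pooled).
Per-gene residual variances are then shrunk toward a pooled prior by
fitting a scaled-F model to the ensemble of variances with the classical
method-of-moments equations on log variances (digamma/trigamma moments),
yielding prior degrees of freedom d0 and prior variance s0^2. The
moderated t uses posterior variance

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

with total degrees of freedom d_g + d0, then Benjamini-Hochberg FDR and a
signed significance rank score -log10(p) * sign(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

from .stats import (InsufficientDataError, InvalidArgumentError, bh_fdr,
                    t_tail_p_vec)


@dataclass
class ModerationHyperparams:
    """Prior degrees of freedom and prior variance of the variance ensemble."""

    d0: float          # may be inf
    s0_sq: float


@dataclass
class GeneModelFits:
    """Per-gene OLS results for the donor + region design."""

    genes: list
    beta: np.ndarray        # region coefficient (log2 units)
    s_g_sq: np.ndarray      # residual variance
    d_g: int                # residual df (shared design)
    v_region: float         # unscaled coefficient variance factor
    degenerate: np.ndarray  # zero-residual-variance flag
    n_samples: int
    donors: list


def restrict_to_bf_donors(samples: pd.DataFrame,
                          bf_labels: tuple = ("Ch1-3", "NBM")) -> pd.DataFrame:
    """Keep all samples from donors that sampled every BF label."""
    ok = None
    for lab in bf_labels:
        d = set(samples.loc[samples.structure_label == lab, "donor_id"])
        ok = d if ok is None else ok & d
    return samples[samples.donor_id.isin(sorted(ok))].reset_index(drop=True)


def fit_gene_models(gene_expression: pd.DataFrame, samples: pd.DataFrame,
                    target_region: str,
                    contrast_region: str | None = None) -> GeneModelFits:
    """Per-gene OLS of expression on donor indicators + region indicator.

    All genes share one design (intercept, donor dummies, target-region
    indicator), so the fit is a single matrix solve. `contrast_region`
    switches from target-vs-rest to a pairwise contrast restricted to the
    two regions.
    """
    samp = samples[samples.sample_id.isin(gene_expression.columns)]
    if contrast_region is not None:
        samp = samp[samp.structure_label.isin([target_region,
                                               contrast_region])]
    donors = sorted(samp.donor_id.unique())
    if len(donors) < 2:
        raise InvalidArgumentError("need >= 2 donors")
    if target_region not in set(samp.structure_label):
        raise InvalidArgumentError(f"no samples labelled {target_region}")
    E = gene_expression[samp.sample_id].to_numpy(float)
    n = len(samp)
    donor_dummies = pd.get_dummies(samp.donor_id, drop_first=True).astype(float)
    region = (samp.structure_label == target_region).astype(float).to_numpy()
    X = np.column_stack([np.ones(n), donor_dummies.to_numpy(), region])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise InvalidArgumentError(
            "design rank deficient: a donor's samples may all lie in the "
            "target region")
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    B = E @ pinv.T                     # genes x params
    resid = E - B @ X.T
    d_g = n - X.shape[1]
    if d_g < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    s_g_sq = (resid ** 2).sum(axis=1) / d_g
    beta = B[:, -1]
    # zero residual variance up to floating point, relative to signal scale
    scale = np.maximum((E ** 2).mean(axis=1), 1e-300)
    degenerate = s_g_sq <= 1e-12 * scale
    return GeneModelFits(genes=list(gene_expression.index), beta=beta,
                         s_g_sq=s_g_sq, d_g=d_g,
                         v_region=float(XtX_inv[-1, -1]),
                         degenerate=degenerate, n_samples=n, donors=donors)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/y (monotone)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_moderation(s_g_sq, d_g) -> ModerationHyperparams:
    """Fit (d0, s0^2) by matching moments of log residual variances to a
    scaled-F model.

    With z_g = log(s_g^2), E[z_g] = log(s0^2) + digamma(d_g/2) -
    log(d_g/2) + [log adjustment from the prior] and Var[z_g] =
    trigamma(d_g/2) + trigamma(d0/2); the excess of the observed variance
    of z over its expected sampling variance identifies d0 via the inverse
    trigamma, and the mean identifies s0^2. When the observed variance
    does not exceed the sampling variance, d0 = inf and every posterior
    variance equals s0^2.
    """
    s2 = np.asarray(s_g_sq, dtype=float)
    d = np.broadcast_to(np.asarray(d_g, dtype=float), s2.shape)
    ok = (s2 > 0) & (d >= 1)
    s2, d = s2[ok], d[ok]
    if s2.size < 10:
        raise InsufficientDataError(
            f"need >= 10 positive variances, got {s2.size}")
    if np.all(s2 <= 0):
        raise InvalidArgumentError("all residual variances are zero")
    z = np.log(s2)
    e = z - digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1)
    expected = np.mean(polygamma(1, d / 2))
    excess = evar - expected
    if excess <= 0:
        # no excess dispersion: all genes share one variance, estimated by
        # the pooled (arithmetic) mean
        return ModerationHyperparams(d0=np.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2))
    return ModerationHyperparams(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(fits: GeneModelFits, hyper: ModerationHyperparams,
                fdr_thresholds: tuple = (0.10, 0.05, 0.01)) -> pd.DataFrame:
    """Moderated t-statistics, p, q and the signed rank score per gene.

    Degenerate genes (zero residual variance) are reported NA. Returns a
    frame in input gene order; frame.attrs carries the FDR-passing gene
    lists at each threshold and the hyperparameters used.
    """
    if not (np.isfinite(hyper.s0_sq) and hyper.s0_sq > 0):
        raise InvalidArgumentError(f"invalid prior variance {hyper.s0_sq}")
    if not (hyper.d0 >= 0):
        raise InvalidArgumentError(f"invalid prior df {hyper.d0}")
    d0, s0 = hyper.d0, hyper.s0_sq
    d_g = float(fits.d_g)
    if np.isinf(d0):
        s_post = np.full_like(fits.s_g_sq, s0)
        df_total = np.inf
    else:
        s_post = (d0 * s0 + d_g * fits.s_g_sq) / (d0 + d_g)
        df_total = d_g + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits.beta / np.sqrt(s_post * fits.v_region)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = t_tail_p_vec(t_mod, df_total)
    bad = fits.degenerate | ~np.isfinite(t_mod)
    t_mod = np.where(bad, np.nan, t_mod)
    p = np.where(bad, np.nan, p)
    q = np.full_like(p, np.nan)
    if (~bad).any():
        q[~bad] = bh_fdr(p[~bad]).q
    with np.errstate(divide="ignore"):
        rank_score = np.where(np.isfinite(p),
                              -np.log10(np.clip(p, 1e-300, None))
                              * np.sign(t_mod), np.nan)
    out = pd.DataFrame({
        "gene": fits.genes,
        "beta": fits.beta,
        "s_g_sq": fits.s_g_sq,
        "s_post_sq": s_post,
        "t_mod": t_mod,
        "df_total": df_total,
        "p": p,
        "q": q,
        "rank_score": rank_score,
        "degenerate": bad,
    })
    out.attrs["hyper"] = {"d0": d0, "s0_sq": s0}
    out.attrs["fdr_lists"] = {
        thr: out.loc[(out.q < thr) & ~out.degenerate, "gene"].tolist()
        for thr in fdr_thresholds
    }
    return out


def run_region_expression(gene_expression: pd.DataFrame,
                          samples: pd.DataFrame, target_region: str,
                          restrict_donors: bool = True) -> pd.DataFrame:
    """Full region-specific expression stage for one BF contrast."""
    samp = restrict_to_bf_donors(samples) if restrict_donors else samples
    fits = fit_gene_models(gene_expression, samp, target_region)
    keep = ~fits.degenerate
    hyper = estimate_moderation(fits.s_g_sq[keep],
                                np.full(keep.sum(), fits.d_g))
    return moderated_t(fits, hyper)
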