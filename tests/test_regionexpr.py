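"""Tests of per-gene region models and empirical-Bayes moderation,
including an independent cross-check against the reference R
implementation of moderated t-statistics."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bftx.regionexpr import (GeneModelFits, ModerationHyperparams,
                             estimate_moderation, fit_gene_models,
                             moderated_t, restrict_to_bf_donors,
                             run_region_expression)
from bftx.stats import InsufficientDataError, InvalidArgumentError


def _fixture(rng, n_genes=60, noise=0.4, shift=1.0):
    """3 donors x (2 BF regions + cortex), 18 samples."""
    rows = []
    for d in ("D1", "D2", "D3"):
        for lab, k in (("Ch1-3", 2), ("NBM", 2), ("cortex", 2)):
            for i in range(k):
                rows.append((f"{d}_{lab}_{i}", d, lab, 0.0, 0.0, 0.0))
    samples = pd.DataFrame(rows, columns=["sample_id", "donor_id",
                                          "structure_label", "x", "y", "z"])
    donor_eff = {"D1": 0.0, "D2": 0.5, "D3": -0.3}
    base = rng.normal(5, 1, n_genes)
    E = np.tile(base[:, None], (1, len(samples)))
    E += np.array([donor_eff[d] for d in samples.donor_id])
    target = (samples.structure_label == "Ch1-3").to_numpy()
    E[:10, target] += shift
    if noise:
        E += rng.normal(0, noise, E.shape)
    expr = pd.DataFrame(E, index=pd.Index([f"g{i}" for i in range(n_genes)],
                                          name="gene"),
                        columns=samples.sample_id)
    return expr, samples


class TestFitGeneModels:
    def test_noiseless_planted_shift_recovered_exactly(self, rng):
        expr, samples = _fixture(rng, noise=0.0, shift=1.0)
        fits = fit_gene_models(expr, samples, "Ch1-3")
        assert np.allclose(fits.beta[:10], 1.0, atol=1e-10)
        assert np.allclose(fits.beta[10:], 0.0, atol=1e-10)
        assert fits.degenerate.all()  # zero residual variance everywhere

    def test_matches_independent_ols_oracle(self, rng):
        """Region coefficients equal per-gene statsmodels OLS fits."""
        import statsmodels.formula.api as smf
        expr, samples = _fixture(rng, n_genes=12)
        fits = fit_gene_models(expr, samples, "Ch1-3")
        for i, g in enumerate(expr.index):
            df = samples.copy()
            df["y"] = expr.loc[g].to_numpy()
            df["region"] = (df.structure_label == "Ch1-3").astype(float)
            m = smf.ols("y ~ C(donor_id) + region", data=df).fit()
            assert fits.beta[i] == pytest.approx(m.params["region"],
                                                 abs=1e-10)
            assert fits.s_g_sq[i] == pytest.approx(m.mse_resid, rel=1e-10)

    def test_restrict_to_bf_donors(self, rng):
        expr, samples = _fixture(rng)
        extra = pd.DataFrame([("X1", "D9", "cortex", 0, 0, 0)],
                             columns=samples.columns)
        wide = pd.concat([samples, extra], ignore_index=True)
        out = restrict_to_bf_donors(wide)
        assert "D9" not in set(out.donor_id)

    def test_rank_deficient_design_raises(self, rng):
        expr, samples = _fixture(rng)
        # only target-region samples left: region indicator == intercept
        bad = samples[samples.structure_label == "Ch1-3"]
        with pytest.raises(InvalidArgumentError):
            fit_gene_models(expr[bad.sample_id], bad, "Ch1-3")


class TestEstimateModeration:
    def test_recovers_known_hyperparameters(self):
        """Variances drawn from the scaled model with d0=4, s0^2=0.05."""
        rng = np.random.default_rng(99)
        d0, s0, d_g, m = 4.0, 0.05, 10, 5000
        for rep in range(3):
            prior = d0 * s0 / rng.chisquare(d0, m)     # gene-level variances
            s2 = prior * rng.chisquare(d_g, m) / d_g   # sampled variances
            hyper = estimate_moderation(s2, np.full(m, d_g))
            assert hyper.d0 == pytest.approx(d0, rel=0.25)
            assert hyper.s0_sq == pytest.approx(s0, rel=0.10)

    def test_identical_variances_give_infinite_d0(self):
        hyper = estimate_moderation(np.full(100, 0.3), np.full(100, 8))
        assert np.isinf(hyper.d0)
        assert hyper.s0_sq == pytest.approx(0.3)

    def test_too_few_genes_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_moderation([0.1, 0.2], [5, 5])


def _fits_for_moderation(rng, n=200):
    beta = rng.normal(0, 1, n)
    s2 = 0.05 * rng.chisquare(8, n) / 8
    return GeneModelFits(genes=[f"g{i}" for i in range(n)], beta=beta,
                         s_g_sq=s2, d_g=8, v_region=0.5,
                         degenerate=np.zeros(n, bool), n_samples=14,
                         donors=["D1", "D2"])


class TestModeratedT:
    def test_d0_zero_limit_equals_ordinary_t(self, rng):
        fits = _fits_for_moderation(rng)
        out = moderated_t(fits, ModerationHyperparams(d0=0.0, s0_sq=1.0))
        ordinary = fits.beta / np.sqrt(fits.s_g_sq * fits.v_region)
        assert np.allclose(out.t_mod, ordinary)

    def test_d0_infinite_limit_shares_one_variance(self, rng):
        fits = _fits_for_moderation(rng)
        out = moderated_t(fits, ModerationHyperparams(d0=np.inf, s0_sq=0.07))
        assert np.allclose(out.s_post_sq, 0.07)

    def test_interpolation_between_gene_and_prior_variance(self, rng):
        fits = _fits_for_moderation(rng)
        hyper = ModerationHyperparams(d0=4.0, s0_sq=0.05)
        out = moderated_t(fits, hyper)
        lo = np.minimum(fits.s_g_sq, hyper.s0_sq)
        hi = np.maximum(fits.s_g_sq, hyper.s0_sq)
        assert ((out.s_post_sq >= lo - 1e-12)
                & (out.s_post_sq <= hi + 1e-12)).all()
        nz = fits.beta != 0
        assert (np.sign(out.t_mod[nz]) == np.sign(fits.beta[nz])).all()

    def test_rank_score_matches_signed_p_ordering(self, rng):
        fits = _fits_for_moderation(rng)
        out = moderated_t(fits, ModerationHyperparams(d0=4.0, s0_sq=0.05))
        by_rank = out.sort_values("rank_score", ascending=False)
        signed = out.copy()
        signed["key"] = list(zip(-np.sign(signed.t_mod),
                                 np.where(signed.t_mod > 0, signed.p,
                                          -signed.p)))
        by_signed = signed.sort_values("key")
        assert list(by_rank.gene) == list(by_signed.gene)

    def test_invalid_hyper_raises(self, rng):
        fits = _fits_for_moderation(rng)
        with pytest.raises(InvalidArgumentError):
            moderated_t(fits, ModerationHyperparams(d0=4.0, s0_sq=np.nan))


def test_full_stage_recovers_planted_genes(small_dataset):
    from bftx.ahba import select_probes
    b = small_dataset["expression"]
    truth = small_dataset["truth"]
    ge, _, _ = select_probes(b.probes, b.expression)
    stats = run_region_expression(ge, b.samples, "Ch1-3")
    fdr10 = set(stats.attrs["fdr_lists"][0.10])
    planted = set(truth.bf_enriched_genes) & set(ge.index)
    assert len(fdr10 & planted) / len(planted) >= 0.8


_R_SCRIPT = """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
expr <- as.matrix(read.csv(args[1], row.names=1, check.names=FALSE))
design <- as.matrix(read.csv(args[2], row.names=1, check.names=FALSE))
fit <- lmFit(expr, design)
fit <- eBayes(fit)
out <- data.frame(gene=rownames(expr),
                  t=fit$t[, "region"],
                  p=fit$p.value[, "region"],
                  d0=fit$df.prior,
                  s0=fit$s2.prior)
write.csv(out, args[3], row.names=FALSE)
"""


def test_moderated_t_matches_limma_reference(rng, tmp_path):
    """Independent oracle: the reference R implementation produces the
    same hyperparameters, moderated t and p on a shared fixture."""
    expr, samples = _fixture(rng, n_genes=80, noise=0.5)
    # heterogeneous gene variances so the prior df d0 is finite
    scale = np.sqrt(0.4 * rng.chisquare(4, len(expr)) / 4)
    centred = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
    expr = pd.DataFrame(expr.to_numpy().mean(axis=1, keepdims=True)
                        + centred * scale[:, None],
                        index=expr.index, columns=expr.columns)
    donor_dummies = pd.get_dummies(samples.donor_id, drop_first=True)
    design = pd.DataFrame({"Intercept": 1.0}, index=samples.sample_id)
    for c in donor_dummies.columns:
        design[c] = donor_dummies[c].to_numpy().astype(float)
    design["region"] = (samples.structure_label == "Ch1-3"
                        ).to_numpy().astype(float)
    expr.to_csv(tmp_path / "expr.csv")
    design.to_csv(tmp_path / "design.csv")
    (tmp_path / "mod.R").write_text(_R_SCRIPT)
    subprocess.run(["Rscript", tmp_path / "mod.R", tmp_path / "expr.csv",
                    tmp_path / "design.csv", tmp_path / "out.csv"],
                   check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv")

    fits = fit_gene_models(expr, samples, "Ch1-3")
    hyper = estimate_moderation(fits.s_g_sq, np.full(len(expr), fits.d_g))
    ours = moderated_t(fits, hyper)
    assert hyper.d0 == pytest.approx(ref.d0.iloc[0], rel=1e-6)
    assert hyper.s0_sq == pytest.approx(ref.s0.iloc[0], rel=1e-6)
    assert np.allclose(ours.t_mod, ref.t, rtol=1e-6)
    assert np.allclose(ours.p, ref.p, rtol=1e-6)
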