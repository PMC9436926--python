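"""Tests of the per-gene random-intercept model and decile ranking,
including grid-search and statsmodels oracles for the REML fit."""

import numpy as np
import pandas as pd
import pytest

from bftx.imagingtx import (assemble_design, fit_mixed_per_gene,
                            fit_random_intercept, rank_and_slice,
                            reml_criterion, _group_indices)
from bftx.stats import InvalidArgumentError


def _sim(rng, slope=0.3, donor_sd=0.2, resid_sd=0.3, n_donors=6,
         per_donor=30):
    donors = pd.Series(np.repeat([f"D{i}" for i in range(n_donors)],
                                 per_donor))
    x = rng.normal(size=len(donors))
    u = dict(zip(donors.unique(), rng.normal(0, donor_sd, n_donors)))
    y = slope * x + donors.map(u).to_numpy() + rng.normal(0, resid_sd,
                                                          len(donors))
    return y, x, donors


class TestRandomIntercept:
    def test_zero_donor_variance_falls_back_to_ols(self, rng):
        donors = pd.Series(np.repeat([f"D{i}" for i in range(6)], 30))
        x = rng.normal(size=len(donors))
        e = rng.normal(0, 0.3, len(donors))
        # within-donor centred noise: no between-donor variance at all, so
        # the REML optimum sits at the zero boundary
        e -= pd.Series(e).groupby(donors).transform("mean").to_numpy()
        y = 0.3 * x + e
        fit = fit_random_intercept(y, x, donors)
        b_ols = np.polyfit(x, y, 1)[0]
        assert fit["slope"] == pytest.approx(b_ols, abs=1e-6)
        assert fit["singular"]
        assert fit["donor_variance"] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_over_replicates(self):
        """Planted slope 0.3 with donor sd 0.2: the mean REML slope over
        200 replicates is within +/-0.03 of truth."""
        rng = np.random.default_rng(55)
        slopes = [fit_random_intercept(*_sim(rng))["slope"]
                  for _ in range(200)]
        assert np.mean(slopes) == pytest.approx(0.3, abs=0.03)

    def test_matches_grid_search_oracle(self, rng):
        """Profiled REML equals a brute-force grid over the variance ratio
        to 1e-3."""
        for _ in range(10):
            y, x, donors = _sim(rng, donor_sd=float(rng.uniform(0.05, 0.5)),
                                per_donor=12)
            fit = fit_random_intercept(y, x, donors)
            X = np.column_stack([np.ones(len(y)), x])
            groups = _group_indices(donors)
            grid = np.arange(0.0, 5.0, 1e-3)
            crits = [reml_criterion(l, y, X, groups)[0] for l in grid]
            lam_star = grid[int(np.argmin(crits))]
            assert abs(fit["lam"] - lam_star) <= 1.5e-3

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent oracle: statsmodels MixedLM REML slope and variance
        components agree."""
        import statsmodels.formula.api as smf
        y, x, donors = _sim(rng, donor_sd=0.3, per_donor=20)
        fit = fit_random_intercept(y, x, donors)
        df = pd.DataFrame({"y": y, "x": x, "donor": donors})
        m = smf.mixedlm("y ~ x", df, groups="donor").fit(reml=True)
        assert fit["slope"] == pytest.approx(m.params["x"], rel=1e-4)
        assert fit["residual_variance"] == pytest.approx(m.scale, rel=1e-3)
        assert fit["donor_variance"] == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-4)

    def test_scaling_equivariance(self, rng):
        y, x, donors = _sim(rng)
        f1 = fit_random_intercept(y, x, donors)
        f2 = fit_random_intercept(y, 10.0 * x, donors)
        assert f2["slope"] == pytest.approx(f1["slope"] / 10.0, rel=1e-9)
        assert f2["t"] == pytest.approx(f1["t"], rel=1e-9)

    def test_lrt_option(self, rng):
        y, x, donors = _sim(rng, slope=0.08)
        wald = fit_random_intercept(y, x, donors)
        lrt = fit_random_intercept(y, x, donors, test="lrt")
        assert lrt["p"] < 0.05 and wald["p"] < 0.05
        assert abs(lrt["p"] - wald["p"]) / wald["p"] > 1e-4

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(InvalidArgumentError):
            fit_random_intercept(np.zeros(4), np.arange(4.0),
                                 pd.Series(["a", "a", "b", "b"]))


def _design_fixture(rng, n_genes=8):
    cov = pd.DataFrame({"unit_id": [f"V{i}" for i in range(5)],
                        "r": rng.uniform(-0.5, 0.5, 5)})
    matches = pd.DataFrame({
        "sample_id": [f"A{i}" for i in range(6)],
        "vertex_id": [f"V{i}" for i in range(6)],
        "distance": 1.0,
        "retained": [True] * 5 + [False],
        "removal_reason": ["none"] * 5 + ["over_distance"]})
    samples = pd.DataFrame({"sample_id": [f"A{i}" for i in range(6)],
                            "donor_id": ["D1", "D1", "D2", "D2", "D3", "D3"]})
    expr = pd.DataFrame(rng.normal(size=(n_genes, 6)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"A{i}" for i in range(6)])
    return cov, matches, expr, samples


class TestAssembleDesign:
    def test_rows_are_retained_matches_with_vertex_r(self, rng):
        cov, matches, expr, samples = _design_fixture(rng)
        design = assemble_design(cov, matches, expr, samples)
        assert len(design) == 5
        rmap = cov.set_index("unit_id").r
        assert np.allclose(design.r, rmap.loc[design.vertex_id])
        assert set(design.columns) >= {"sample_id", "vertex_id", "donor_id",
                                       "r", "g0"}

    def test_vertex_missing_from_map_dropped_and_counted(self, rng):
        cov, matches, expr, samples = _design_fixture(rng)
        cov = cov.iloc[:-1]  # V4 unmapped
        design = assemble_design(cov, matches, expr, samples)
        assert len(design) == 4
        assert design.attrs["n_dropped_unmapped"] == 1

    def test_duplicate_vertex_is_integrity_error(self, rng):
        cov, matches, expr, samples = _design_fixture(rng)
        matches.loc[1, "vertex_id"] = "V0"
        with pytest.raises(InvalidArgumentError):
            assemble_design(cov, matches, expr, samples)

    def test_no_retained_matches_is_explicit_error(self, rng):
        cov, matches, expr, samples = _design_fixture(rng)
        matches["retained"] = False
        with pytest.raises(InvalidArgumentError):
            assemble_design(cov, matches, expr, samples)


class TestScan:
    def test_donor_zscore_flag_changes_fit_but_not_validity(self, rng):
        y, x, donors = _sim(rng, per_donor=10)
        design = pd.DataFrame({"sample_id": range(len(y)),
                               "vertex_id": range(len(y)),
                               "donor_id": donors, "r": y, "g0": x,
                               "g1": rng.normal(size=len(y))})
        plain = fit_mixed_per_gene(design, genes=["g0", "g1"])
        zed = fit_mixed_per_gene(design, genes=["g0", "g1"],
                                 donor_zscore=True)
        assert plain.p.notna().all() and zed.p.notna().all()
        assert plain.slope.iloc[0] != pytest.approx(zed.slope.iloc[0])

    def test_rank_and_slice_deciles(self, rng):
        stats = pd.DataFrame({"gene": [f"g{i}" for i in range(10)],
                              "t": np.arange(10.0),
                              "p": np.linspace(0.9, 0.01, 10)})
        stats["q"] = stats.p
        out = rank_and_slice(stats)
        assert out["top"] == ["g9"] and out["bottom"] == ["g0"]
        flags = out["stats"].set_index("gene").decile_flag
        assert flags["g9"] == "top10" and flags["g0"] == "bottom10"
        assert (flags.drop(["g9", "g0"]) == "none").all()

    def test_decile_sets_are_rank_consistent(self, small_dataset, rng):
        stats = pd.DataFrame({"gene": [f"g{i:03d}" for i in range(50)],
                              "t": rng.normal(size=50)})
        stats["p"] = 0.5
        stats["q"] = 0.5
        out = rank_and_slice(stats)
        s = out["stats"]
        top_min = s.loc[s.decile_flag == "top10", "t"].min()
        none_max = s.loc[s.decile_flag == "none", "t"].max()
        none_min = s.loc[s.decile_flag == "none", "t"].min()
        bot_max = s.loc[s.decile_flag == "bottom10", "t"].max()
        assert top_min >= none_max >= none_min >= bot_max

    def test_empty_stats_raises(self):
        with pytest.raises(InvalidArgumentError):
            rank_and_slice(pd.DataFrame())


def test_end_to_end_field_gene_recovery(small_dataset):
    """Genes planted to track the projection field land in the top decile
    of the imaging-transcriptomic ranking."""
    from bftx.ahba import match_samples_to_vertices, select_probes
    from bftx.covariance import map_covariance
    b = small_dataset["expression"]
    surf = small_dataset["surface"]
    truth = small_dataset["truth"]
    ge, _, _ = select_probes(b.probes, b.expression)
    cortical = b.samples[(b.samples.structure_label == "cortex")
                         & (b.samples.x < 0)]
    matches, _ = match_samples_to_vertices(cortical, surf.vertices)
    cov = map_covariance(surf, small_dataset["roi"], seed_region="NBM_L",
                         structures=["cortex-L"])
    design = assemble_design(cov, matches, ge, b.samples)
    stats = fit_mixed_per_gene(design)
    out = rank_and_slice(stats)
    planted = set(truth.field_coupled_genes) & set(ge.index)
    assert len(set(out["top"]) & planted) / len(planted) >= 0.8
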