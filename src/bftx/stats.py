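"""Deterministic statistical kernels shared by every analysis stage.

Every printed test in the pipeline reduces to one of the primitives here:
t-distribution tail probabilities, Pearson correlation tests, ordinary
least squares with covariates, a two-group interaction (slope-difference)
model, Levene/Brown-Forsythe variance tests, and multiple-testing
procedures (Benjamini-Hochberg step-up FDR and Bonferroni families).

All tests are two-sided unless stated otherwise, and missing data are
handled by listwise deletion per model with the used sample size reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class InvalidArgumentError(ValueError):
    """Raised when a kernel receives arguments outside its domain."""


class UndefinedCorrelationError(InvalidArgumentError):
    """Raised when a correlation is requested on a constant vector."""


class CollinearityError(InvalidArgumentError):
    """Raised when a design matrix is rank deficient; names the columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class InsufficientDataError(InvalidArgumentError):
    """Raised when too few observations remain after listwise deletion."""


@dataclass
class TestResult:
    """A single hypothesis test: estimate, statistic, df and p-value."""

    estimate: float
    statistic: float
    df: float
    p: float
    two_sided: bool = True
    term: str | None = None
    n_used: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise InvalidArgumentError(f"p-value out of [0, 1]: {self.p}")

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "estimate": self.estimate,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "n_used": self.n_used,
        }


@dataclass
class AdjustedPValues:
    """BH step-up q-values plus the Bonferroni threshold for one family."""

    p_raw: np.ndarray
    q: np.ndarray
    p_bonf_threshold: float
    n_tests: int


@dataclass
class OLSResult:
    """Per-term tests and a model summary for one least-squares fit."""

    terms: list[TestResult]
    r_squared: float
    adj_r_squared: float
    df_resid: int
    n_used: int
    params: pd.Series = field(repr=False, default=None)

    def term(self, name: str) -> TestResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def t_tail_p(statistic: float, df: float, two_sided: bool = True) -> float:
    """Tail probability of a t statistic.

    Returns ``P(|T_df| >= |statistic|)`` when two-sided, else the
    upper-tail ``P(T_df >= statistic)``.
    """
    if not np.isfinite(statistic):
        raise InvalidArgumentError(f"non-finite statistic: {statistic}")
    if not df >= 1:
        raise InvalidArgumentError(f"df must be >= 1, got {df}")
    if two_sided:
        return float(2.0 * sps.t.sf(abs(statistic), df))
    return float(sps.t.sf(statistic, df))


def t_tail_p_vec(statistic: np.ndarray, df, two_sided: bool = True) -> np.ndarray:
    """Vectorised :func:`t_tail_p` (no per-element validation)."""
    statistic = np.asarray(statistic, dtype=float)
    if two_sided:
        return 2.0 * sps.t.sf(np.abs(statistic), df)
    return sps.t.sf(statistic, df)


def pearson_r_test(x, y) -> TestResult:
    """Pearson correlation with the exact t-based test (df = n - 2).

    Pairs with a missing value in either vector are dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    # guard |r| = 1 exactly (zero residual variance)
    if abs(r) >= 1.0:
        return TestResult(estimate=np.sign(r), statistic=np.inf * np.sign(r),
                          df=df, p=0.0, n_used=n)
    t = r * np.sqrt(df / (1.0 - r * r))
    return TestResult(estimate=r, statistic=float(t), df=df,
                      p=t_tail_p(t, df), n_used=n)


def _design_matrix(design: pd.DataFrame, add_intercept: bool) -> pd.DataFrame:
    X = design.copy()
    for col in X.columns:
        if X[col].dtype == object or isinstance(X[col].dtype, pd.CategoricalDtype):
            X[col] = pd.factorize(X[col])[0].astype(float)
        elif X[col].dtype == bool:
            X[col] = X[col].astype(float)
    if add_intercept:
        X.insert(0, "Intercept", 1.0)
    return X.astype(float)


def _rank_deficient_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Identify columns that do not add rank, scanning left to right."""
    bad = []
    rank = 0
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def ols_fit(y, design: pd.DataFrame, add_intercept: bool = True) -> OLSResult:
    """Ordinary least squares with per-predictor t tests.

    Rows with any missing value (in `y` or any predictor) are dropped
    listwise; the used n is reported on every term.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise InvalidArgumentError("y and design have different lengths")
    X = _design_matrix(design, add_intercept)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(
            f"n = {n} observations for {p} parameters after listwise deletion"
        )
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < p:
        raise CollinearityError(_rank_deficient_columns(Xv, list(X.columns)))
    import statsmodels.api as sm

    fit = sm.OLS(y, Xv).fit()
    df_resid = int(fit.df_resid)
    terms = [
        TestResult(
            estimate=float(fit.params[j]),
            statistic=float(fit.tvalues[j]),
            df=df_resid,
            p=t_tail_p(float(fit.tvalues[j]), df_resid),
            term=str(X.columns[j]),
            n_used=n,
        )
        for j in range(p)
    ]
    return OLSResult(
        terms=terms,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        df_resid=df_resid,
        n_used=n,
        params=pd.Series(fit.params, index=X.columns),
    )


def interaction_model(y, x, group, covariates: pd.DataFrame | None = None) -> TestResult:
    """Test of the x-by-group product term in ``y ~ x + group + x:group + covariates``.

    `group` is binary (0/1 or bool). Detects whether two distinct groups
    are present among complete cases.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(group, dtype=float)
    design = pd.DataFrame({"x": x, "group": g, "x:group": x * g})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            design[c] = np.asarray(_design_matrix(cov[[c]], False)[c], dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = np.isfinite(yv) & np.isfinite(design.to_numpy()).all(axis=1)
    if len(np.unique(g[keep & np.isfinite(g)])) < 2:
        raise InvalidArgumentError("both groups must be present")
    res = ols_fit(yv, design)
    return res.term("x:group")


def levene_test(values, group, center: str = "median") -> TestResult:
    """Levene's test for equal variances across two groups.

    The default centre is the group median (Brown-Forsythe variant);
    ``center='mean'`` gives the classical Levene test.
    """
    values = np.asarray(values, dtype=float)
    g = np.asarray(group)
    keep = np.isfinite(values)
    values, g = values[keep], g[keep]
    levels = pd.unique(g)
    if len(levels) < 2:
        raise InvalidArgumentError("need two groups")
    samples = [values[g == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise InvalidArgumentError("each group needs >= 2 observations")
    stat, p = sps.levene(*samples, center=center)
    df = len(values) - len(levels)
    return TestResult(estimate=float(stat), statistic=float(stat), df=df,
                      p=float(p), n_used=len(values))


def bh_fdr(p_raw, alpha: float = 0.05) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p_raw must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return AdjustedPValues(p_raw=p, q=q, p_bonf_threshold=alpha / p.size,
                           n_tests=p.size)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise InvalidArgumentError("n_tests must be >= 1")
    return alpha / n_tests


def two_sample_t_from_summary(mean1: float, sd1: float, n1: int,
                              mean2: float, sd2: float, n2: int,
                              welch: bool = False) -> TestResult:
    """Two-sample t test from summary statistics (pooled or Welch)."""
    if min(n1, n2) < 2 or sd1 < 0 or sd2 < 0:
        raise InvalidArgumentError("need n >= 2 per group, non-negative sds")
    diff = mean1 - mean2
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if welch:
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = diff / se
    return TestResult(estimate=diff, statistic=float(t), df=float(df),
                      p=t_tail_p(float(t), df), n_used=n1 + n2)


def results_to_frame(results: dict[str, TestResult]) -> pd.DataFrame:
    """Serialize named TestResults to a tidy frame."""
    rows = []
    for analysis_id, r in results.items():
        d = r.to_dict()
        d["analysis_id"] = analysis_id
        rows.append(d)
    return pd.DataFrame(rows)[
        ["analysis_id", "term", "estimate", "statistic", "df", "p", "n_used"]
    ]
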