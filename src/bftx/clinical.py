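"""Clinical-sample analyses: MRS group comparison, structure-MRS coupling
and decoupling, case-control microstructure, clinical and cognitive
correlates, and radial-diffusivity sensitivity analyses.

Conventions
-----------
* Multiple-testing families are explicit: 3 tests for case-control and
  structure-MRS regions (Bonferroni p < 0.05/3), 8 for clinical
  correlations (p < 0.05/8 = 6.25e-3) and 12 for cognitive correlations
  (p < 0.05/12 ~ 4.17e-3).
* Region order is fixed as (Ch1-3, NBM_L, NBM_R) for deterministic output.
* Each analysis drops incomplete rows listwise and reports its used n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (TestResult, InvalidArgumentError, bonferroni_threshold,
                    interaction_model, levene_test, ols_fit, pearson_r_test)
from .simulate import REGIONS, roi_wide


@dataclass
class AnalysisPlan:
    """Declares one analysis: outcome, predictor, covariates and its
    multiple-testing family."""

    outcome: str
    predictor_of_interest: str
    covariates: list[str] = field(default_factory=list)
    subset: str | None = None            # group filter ("HC", "FEP" or None)
    correction_family: str = "none"
    n_tests_in_family: int = 1
    note: str = ""

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni_threshold(self.n_tests_in_family)


def _merged(subjects: pd.DataFrame, roi: pd.DataFrame) -> pd.DataFrame:
    df = subjects.merge(roi_wide(roi), on="subject_id", how="inner")
    df["diagnosis"] = (df.group == "FEP").astype(float)
    df["sex_m"] = (df.sex == "M").astype(float)
    return df


def _row(analysis_id, region, metric, res: TestResult, family_n: int,
         plan_note: str = "") -> dict:
    thr = bonferroni_threshold(family_n)
    return {"analysis_id": analysis_id, "region": region, "metric": metric,
            "term": res.term, "estimate": res.estimate,
            "statistic": res.statistic, "df": res.df, "p": res.p,
            "n_used": res.n_used, "p_bonf_family": family_n,
            "bonf_threshold": thr, "significant": res.p < thr,
            "note": plan_note}


def mrs_group_comparison(subjects: pd.DataFrame, roi: pd.DataFrame | None = None
                         ) -> TestResult:
    """Diagnosis effect on dACC choline, adjusting for age, sex, smoking
    and cannabis use."""
    df = subjects.copy()
    df["diagnosis"] = (df.group == "FEP").astype(float)
    df["sex_m"] = (df.sex == "M").astype(float)
    for g in ("HC", "FEP"):
        if df.loc[df.group == g, "choline"].notna().sum() < 2:
            raise InvalidArgumentError(f"group {g} lacks choline data")
    res = ols_fit(df.choline,
                  df[["diagnosis", "age", "sex_m", "smoking", "cast"]])
    return res.term("diagnosis")


def structure_mrs_coupling(subjects: pd.DataFrame, roi: pd.DataFrame,
                           group: str = "HC", metric: str = "qt1",
                           covariates: tuple = ("age", "sex_m", "cast"),
                           ) -> pd.DataFrame:
    """Choline-microstructure correlation per BF region within one group.

    Reports the raw Pearson test and the covariate-adjusted coefficient
    test (choline ~ region value + covariates), Bonferroni family of 3.
    """
    df = _merged(subjects, roi)
    df = df[df.group == group]
    if df.choline.notna().sum() < 5:
        raise InvalidArgumentError("fewer than 5 subjects with choline")
    rows = []
    for region in REGIONS:
        col = f"{region}.{metric}"
        raw = pearson_r_test(df[col], df.choline)
        raw.term = "pearson_r"
        rows.append(_row(f"coupling_{group}_{metric}", region, metric, raw, 3))
        adj = ols_fit(df.choline, df[[col, *covariates]]).term(col)
        rows.append(_row(f"coupling_{group}_{metric}_adjusted", region,
                         metric, adj, 3))
    return pd.DataFrame(rows)


def decoupling_test(subjects: pd.DataFrame, roi: pd.DataFrame,
                    metric: str = "qt1") -> pd.DataFrame:
    """Diagnosis-by-microstructure interaction on choline, per region.

    Covariates are age and sex only: smoking and cannabis are excluded by
    design because the control group contains (almost) no smokers and the
    groups differ strongly in cannabis use.
    """
    df = _merged(subjects, roi)
    rows = []
    note = "smoking/CAST excluded: no HC smokers, groups differ in cannabis"
    for region in REGIONS:
        col = f"{region}.{metric}"
        res = interaction_model(df.choline, df[col], df.diagnosis,
                                df[["age", "sex_m"]])
        rows.append(_row(f"decoupling_{metric}", region, metric, res, 3, note))
    return pd.DataFrame(rows)


def case_control_microstructure(subjects: pd.DataFrame, roi: pd.DataFrame,
                                metric: str = "qt1",
                                include_icv: bool = False) -> pd.DataFrame:
    """Diagnosis effect per region, adjusting for age, sex, CAST and
    smoking (optionally ICV); Levene's variance test reported per region."""
    df = _merged(subjects, roi)
    covs = ["age", "sex_m", "cast", "smoking"] + (["icv"] if include_icv else [])
    rows = []
    suffix = "_icv" if include_icv else ""
    for region in REGIONS:
        col = f"{region}.{metric}"
        res = ols_fit(df[col], df[["diagnosis", *covs]]).term("diagnosis")
        rows.append(_row(f"case_control_{metric}{suffix}", region, metric,
                         res, 3))
        lev = levene_test(df[col], df.group)
        lev.term = "levene_F"
        rows.append(_row(f"levene_{metric}{suffix}", region, metric, lev, 3))
    return pd.DataFrame(rows)


def clinical_correlates(subjects: pd.DataFrame, roi: pd.DataFrame,
                        regions: tuple = ("NBM_L", "Ch1-3"),
                        metrics: tuple = ("qt1", "axd"),
                        scores: tuple = ("ymrs", "panss8_neg")) -> pd.DataFrame:
    """Clinical-score correlations within FEP, raw and adjusted for CAST
    and smoking; 8-test Bonferroni family (2 regions x 2 metrics x 2 scores)."""
    df = _merged(subjects, roi)
    df = df[df.group == "FEP"]
    family = len(regions) * len(metrics) * len(scores)
    rows = []
    for score in scores:
        if df[score].notna().sum() < 5:
            raise InvalidArgumentError(f"fewer than 5 non-missing {score}")
        for region in regions:
            for metric in metrics:
                col = f"{region}.{metric}"
                raw = pearson_r_test(df[col], df[score])
                raw.term = "pearson_r"
                rows.append(_row(f"clinical_{score}", region, metric, raw,
                                 family))
                adj = ols_fit(df[score], df[[col, "cast", "smoking"]]).term(col)
                rows.append(_row(f"clinical_{score}_adjusted", region, metric,
                                 adj, family))
    return pd.DataFrame(rows)


def cognitive_correlates(subjects: pd.DataFrame, roi: pd.DataFrame,
                         metrics: tuple = ("qt1", "axd"),
                         scores: tuple = ("dsst", "trails")) -> pd.DataFrame:
    """Cognition-microstructure correlations per group on available cases;
    12-test Bonferroni family (2 scores x 3 regions x 2 metrics)."""
    df = _merged(subjects, roi)
    family = len(scores) * len(REGIONS) * len(metrics)
    rows = []
    for grp in ("FEP", "HC"):
        sub = df[df.group == grp]
        for score in scores:
            for region in REGIONS:
                for metric in metrics:
                    col = f"{region}.{metric}"
                    res = pearson_r_test(sub[col], sub[score])
                    res.term = "pearson_r"
                    rows.append(_row(f"cognitive_{grp}_{score}", region,
                                     metric, res, family))
    return pd.DataFrame(rows)


def posthoc_cognitive_and_rd(subjects: pd.DataFrame, roi: pd.DataFrame
                             ) -> pd.DataFrame:
    """Post hoc battery: cognitive correlations plus the radial-diffusivity
    re-run of coupling, decoupling, case-control and clinical analyses."""
    parts = [
        cognitive_correlates(subjects, roi),
        structure_mrs_coupling(subjects, roi, group="HC", metric="rd"),
        decoupling_test(subjects, roi, metric="rd"),
        case_control_microstructure(subjects, roi, metric="rd"),
        clinical_correlates(subjects, roi, metrics=("rd",)),
    ]
    return pd.concat(parts, ignore_index=True)


def run_clinical_stage(subjects: pd.DataFrame, roi: pd.DataFrame) -> pd.DataFrame:
    """Run the full clinical battery and return one tidy results table."""
    mrs = mrs_group_comparison(subjects)
    rows = [_row("mrs_group_comparison", "dACC", "choline", mrs, 1)]
    parts = [pd.DataFrame(rows)]
    for grp in ("HC", "FEP"):
        parts.append(structure_mrs_coupling(subjects, roi, group=grp))
    parts.append(decoupling_test(subjects, roi))
    for metric in ("qt1", "axd"):
        parts.append(case_control_microstructure(subjects, roi, metric=metric))
        parts.append(case_control_microstructure(subjects, roi, metric=metric,
                                                 include_icv=True))
    parts.append(clinical_correlates(subjects, roi))
    parts.append(posthoc_cognitive_and_rd(subjects, roi))
    return pd.concat(parts, ignore_index=True)
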