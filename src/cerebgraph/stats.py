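"""Covariate-adjusted group comparison, FDR control, and brain–behavior
correlations.

Group differences in each nodal graph measure are tested with a general
linear model ``metric ~ intercept + group + age + sex + mean_rms``; the
group coefficient is the covariate-adjusted difference in the metric's own
units (the reported effect size), tested two-sided. p-values are corrected
across nodes within each metric by Benjamini–Hochberg FDR (the per-metric
family is the common convention for nodal statistics; a single pooled
family is available via ``family="pooled"``).

Exploratory Pearson correlations between metrics and cognitive scores are
reported with 95% confidence intervals from the Fisher z transform,
``tanh(atanh(r) +/- 1.96 / sqrt(n - 3))``, and are deliberately not
multiplicity-corrected by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparisonResult:
    label: str                      # node or "__network__"
    metric: str
    adjusted_group_difference: float  # group coefficient, metric units
    t_statistic: float
    p_value: float
    q_value: float = float("nan")
    direction: str = ""             # "patients_lower" | "patients_higher"

    def __post_init__(self):
        if not np.isnan(self.q_value) and self.q_value < self.p_value - 1e-12:
            raise ValueError("q_value cannot be below p_value")


@dataclass
class CorrelationResult:
    metric: str
    score: str
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (-1 - 1e-9 <= self.ci_low <= self.r + 1e-9
                and self.r - 1e-9 <= self.ci_high <= 1 + 1e-9):
            raise ValueError("CI must bracket r within [-1, 1]")


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def glm_group_comparison(metrics: pd.DataFrame, subjects: pd.DataFrame,
                         family: str = "per_metric") -> pd.DataFrame:
    """GLM group comparison of every (node, metric) cell, with FDR.

    Parameters
    ----------
    metrics : DataFrame
        Long format with columns ``subject_id, label, metric, value`` —
        one row per subject, node (or ``__network__``) and measure.
    subjects : DataFrame
        One row per subject with ``subject_id, group, age, sex, mean_rms``;
        ``group`` coded ``patient``/``control``, ``sex`` ``F``/``M``.
    family : str
        FDR family: ``"per_metric"`` (correct across nodes within each
        metric; default) or ``"pooled"`` (one family over all tests).

    Returns a DataFrame of :class:`GroupComparisonResult` fields.
    """
    if family not in ("per_metric", "pooled"):
        raise ValueError("family must be 'per_metric' or 'pooled'")
    sub = subjects.set_index("subject_id")
    counts = sub["group"].value_counts()
    if counts.get("patient", 0) < 2 or counts.get("control", 0) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for (metric, label), cell in metrics.groupby(["metric", "label"], sort=True):
        cell = cell.set_index("subject_id")
        y = cell["value"].astype(float)
        covars = sub.loc[y.index]
        design = pd.DataFrame({
            "group": (covars["group"] == "patient").astype(float),
            "age": covars["age"].astype(float),
            "sex": (covars["sex"] == "M").astype(float),
            "mean_rms": covars["mean_rms"].astype(float),
        }, index=y.index)
        # a covariate with no variance carries no information: drop it
        degenerate = [c for c in ("age", "sex", "mean_rms")
                      if design[c].std() == 0]
        if degenerate:
            warnings.warn(f"dropping constant covariates {degenerate}")
            design = design.drop(columns=degenerate)
        x = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            corr = design.corr().abs()
            collinear = [c for c in design.columns
                         if (corr.loc[c].drop(c) > 1 - 1e-10).any()]
            raise ValueError(f"singular design for {label}/{metric}; "
                             f"collinear columns: {collinear}")
        fit = sm.OLS(y, x).fit()
        coef = float(fit.params["group"])
        rows.append({
            "label": label, "metric": metric,
            "adjusted_group_difference": coef,
            "t_statistic": float(fit.tvalues["group"]),
            "p_value": float(fit.pvalues["group"]),
            "direction": "patients_lower" if coef < 0 else "patients_higher",
        })
    out = pd.DataFrame(rows)
    if family == "pooled":
        out["q_value"] = fdr_bh(out["p_value"].to_numpy())
    else:
        out["q_value"] = np.nan
        for metric, idx in out.groupby("metric").groups.items():
            out.loc[idx, "q_value"] = fdr_bh(out.loc[idx, "p_value"].to_numpy())
    return out[["label", "metric", "adjusted_group_difference",
                "t_statistic", "p_value", "q_value", "direction"]]


def pearson_with_ci(x, y, metric: str = "", score: str = "") -> CorrelationResult:
    """Pearson r with two-sided p (t transform) and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need two equal-length samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:  # numerically perfect: CI collapses
        r = float(np.sign(r))
        lo = hi = r
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(metric=metric, score=score, r=r, n=n,
                             p_value=float(p),
                             ci_low=float(lo), ci_high=float(hi))


def demographics_tests(subjects: pd.DataFrame) -> dict:
    """Group comparability checks: age (Bartlett + t-test) and sex (chi-square).

    Returns a dict with ``age_bartlett_p``, ``age_t``, ``age_p``,
    ``sex_chi2``, ``sex_p`` and the per-group summaries.
    """
    groups = subjects.groupby("group")
    if not {"patient", "control"} <= set(groups.groups):
        raise ValueError("both groups must be present")
    age_p = groups.get_group("patient")["age"].to_numpy(float)
    age_c = groups.get_group("control")["age"].to_numpy(float)
    if len(age_p) == 0 or len(age_c) == 0:
        raise ValueError("empty group")
    if np.array_equal(np.sort(age_p), np.sort(age_c)):
        bart_p, t_stat, t_p = 1.0, 0.0, 1.0
    else:
        bart_p = float(sps.bartlett(age_p, age_c).pvalue)
        t = sps.ttest_ind(age_p, age_c)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    table = pd.crosstab(subjects["group"], subjects["sex"])
    if table.shape[1] < 2:  # single-sex cohort: no association testable
        chi2, chi_p = 0.0, 1.0
    else:
        chi2_res = sps.chi2_contingency(table.to_numpy(), correction=False)
        chi2, chi_p = float(chi2_res.statistic), float(chi2_res.pvalue)
    return {
        "age_bartlett_p": bart_p,
        "age_t": t_stat,
        "age_p": t_p,
        "sex_chi2": chi2,
        "sex_p": chi_p,
        "age_mean_by_group": groups["age"].mean().to_dict(),
        "sex_counts": {g: table.loc[g].to_dict() for g in table.index},
    }
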