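"""Cohort construction and group statistics.

Implements the menopause-timing cohort logic: subjects are first split at
a reference menopause age (51 years, the U.S. average), the overlap of the
two groups' age-at-MRI ranges is found, subjects scanned outside that
overlap are excluded to decouple menopause timing from age at scan, and
the remainder is cut into equal-size tertiles (earlier / intermediate /
later menopause) by age at menopause.

All metric comparisons first regress the linear effect of age at MRI out
of the metric ("age adjustment"); group tests are classical pooled-variance
two-sample t tests, the across-tertile trend is a linear regression on the
ordinal group code, and no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CollinearityError

__all__ = [
    "StatResult",
    "GROUP_ORDER",
    "assign_groups",
    "residualize_age",
    "two_sample_t",
    "anova_oneway",
    "ordinal_trend",
    "correlate",
    "wave_memory_model",
    "exclude_missing_scores",
    "headline_report",
    "DEFAULT_SPLIT_AGE",
]

DEFAULT_SPLIT_AGE = 51.0
GROUP_ORDER = ("earlier", "intermediate", "later")


@dataclass
class StatResult:
    """One statistical test: name, statistic, p, point estimate, sizes."""

    test: str
    statistic: float
    pvalue: float
    estimate: float
    n: tuple
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic,
             "pvalue": self.pvalue, "estimate": self.estimate,
             "n": list(self.n)}
        d.update({k: v for k, v in self.extras.items()})
        return d


def assign_groups(phenotypes: pd.DataFrame,
                  split_age: float = DEFAULT_SPLIT_AGE,
                  n_groups: int = 3) -> pd.DataFrame:
    """Apply the split / overlap-exclusion / tertile pipeline.

    Returns a copy of the table with ``included`` (bool) and ``group``
    (earlier/intermediate/later or NA) columns, plus the overlap bounds in
    ``DataFrame.attrs``. Rows already flagged ``excluded`` (abnormal
    phenotype responses) never enter the computation. The assignment is
    deterministic and invariant to input row order: tertile cutting sorts
    by (age at menopause, subject id), and when the retained count is not
    divisible by ``n_groups`` the earlier tertiles get the extra subjects.
    """
    df = phenotypes.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    valid = df.loc[~df["excluded"]]
    early = valid["age_at_menopause"] < split_age
    if early.any() and (~early).any():
        lo = max(valid.loc[early, "age_at_mri"].min(),
                 valid.loc[~early, "age_at_mri"].min())
        hi = min(valid.loc[early, "age_at_mri"].max(),
                 valid.loc[~early, "age_at_mri"].max())
    else:
        # degenerate split (everyone on one side): no overlap to enforce
        lo, hi = -np.inf, np.inf
    in_overlap = valid["age_at_mri"].between(lo, hi)
    retained = valid.loc[in_overlap].sort_values(
        ["age_at_menopause", "subject_id"], kind="stable")
    groups = np.array_split(retained["subject_id"].to_numpy(), n_groups)
    label_of = {}
    for name, ids in zip(GROUP_ORDER[:n_groups], groups):
        for sid in ids:
            label_of[sid] = name
    df["included"] = df["subject_id"].isin(retained["subject_id"])
    df["group"] = df["subject_id"].map(label_of)
    df.attrs["mri_age_overlap"] = (float(lo), float(hi))
    df.attrs["n_excluded_overlap"] = int(len(valid) - len(retained))
    return df


def residualize_age(values: Sequence[float], ages: Sequence[float]) -> np.ndarray:
    """Residuals of an OLS fit of the values on (intercept, age)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.shape != x.shape:
        raise ValueError("values and ages must align")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided pooled-variance two-sample t test; estimate = mean(x)-mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return StatResult("two_sample_t", float(t), float(p),
                      float(x.mean() - y.mean()), (x.size, y.size))


def anova_oneway(groups: Sequence[Sequence[float]]) -> StatResult:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f, p = stats.f_oneway(*arrays)
    grand = np.concatenate(arrays).mean()
    between = float(np.ptp([a.mean() for a in arrays]))
    return StatResult("anova_oneway", float(f), float(p), between,
                      tuple(a.size for a in arrays),
                      extras={"grand_mean": float(grand)})


def ordinal_trend(metric: Sequence[float], group_labels: Sequence[str],
                  order: Sequence[str] = GROUP_ORDER,
                  predictor: Optional[Sequence[float]] = None) -> StatResult:
    """Linear trend of a metric across ordered groups.

    The default predictor codes the groups ordinally (1, 2, 3); passing
    ``predictor`` (e.g. raw menopause age) switches to that continuous
    variable instead. Reports the slope and its two-sided p.
    """
    metric = np.asarray(metric, dtype=float)
    labels = np.asarray(group_labels)
    if predictor is None:
        code = {g: i + 1 for i, g in enumerate(order)}
        x = np.array([code[g] for g in labels], dtype=float)
    else:
        x = np.asarray(predictor, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("trend predictor is constant")
    res = stats.linregress(x, metric)
    sizes = tuple(int((labels == g).sum()) for g in order)
    tstat = float(res.slope / res.stderr) if res.stderr > 0 else 0.0
    pvalue = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return StatResult("ordinal_trend", tstat, pvalue, float(res.slope), sizes,
                      extras={"slope": float(res.slope)})


def correlate(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with a two-sided p-value.

    A constant input leaves the correlation undefined; NaNs are returned
    rather than warning, so degenerate cells in batch reports stay quiet.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult("pearson", np.nan, np.nan, np.nan, (x.size,))
    res = stats.pearsonr(x, y)
    return StatResult("pearson", float(res.statistic), float(res.pvalue),
                      float(res.statistic), (x.size,))


def wave_memory_model(activation: Sequence[float], age: Sequence[float],
                      score: Sequence[float]) -> StatResult:
    """Linear model: propagation intensity ~ age at MRI + task score.

    Reports the task-score coefficient and its p-value. A rank-deficient
    design (collinear predictors) raises :class:`CollinearityError`
    instead of silently dropping a term.
    """
    import statsmodels.api as sm

    y = np.asarray(activation, dtype=float)
    X = np.column_stack([np.asarray(age, dtype=float),
                         np.asarray(score, dtype=float)])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("age and score predictors are collinear")
    fit = sm.OLS(y, design).fit()
    return StatResult("wave_memory_ols", float(fit.tvalues[2]),
                      float(fit.pvalues[2]), float(fit.params[2]),
                      (y.size,),
                      extras={"age_coef": float(fit.params[1]),
                              "age_pvalue": float(fit.pvalues[1]),
                              "r_squared": float(fit.rsquared)})


def exclude_missing_scores(records: pd.DataFrame, score_name: str,
                           sentinel: float = 999.0) -> pd.DataFrame:
    """Drop rows whose score is missing (NaN) or carries the 999 sentinel."""
    col = records[score_name]
    keep = col.notna() & (col != sentinel)
    return records.loc[keep].copy()


def headline_report(metrics: pd.DataFrame,
                    coupling_col: str = "coupling",
                    amplitude_col: str = "amplitude",
                    count_col: str = "bottom_up_count",
                    score_col: str = "psmt_score") -> Dict[str, StatResult]:
    """The cohort-level statistics battery on a subject metrics table.

    Expects one row per included subject with columns ``group``,
    ``age_at_mri`` and the named metric columns (missing columns are
    skipped). Age adjustment is performed over all included subjects
    before any comparison; the wave-count/memory correlation is evaluated
    within the earlier group after dropping missing scores.
    """
    df = metrics.loc[metrics["group"].notna()].copy()
    out: Dict[str, StatResult] = {}
    by_group = {g: df.loc[df["group"] == g] for g in GROUP_ORDER}
    out["age_anova"] = anova_oneway(
        [by_group[g]["age_at_mri"].to_numpy(float) for g in GROUP_ORDER])
    for name, col in (("coupling", coupling_col), ("amplitude", amplitude_col)):
        if col not in df.columns:
            continue
        adj = residualize_age(df[col].to_numpy(float),
                              df["age_at_mri"].to_numpy(float))
        adj = pd.Series(adj, index=df.index)
        out[f"{name}_earlier_vs_later"] = two_sample_t(
            adj[df["group"] == "earlier"], adj[df["group"] == "later"])
        out[f"{name}_trend"] = ordinal_trend(adj, df["group"])
    if score_col in df.columns:
        scored = exclude_missing_scores(df, score_col)
        adj_score = residualize_age(scored[score_col].to_numpy(float),
                                    scored["age_at_mri"].to_numpy(float))
        adj_score = pd.Series(adj_score, index=scored.index)
        out["memory_earlier_vs_later"] = two_sample_t(
            adj_score[scored["group"] == "earlier"],
            adj_score[scored["group"] == "later"])
        if count_col in df.columns:
            early = scored.loc[scored["group"] == "earlier"]
            adj_cnt = residualize_age(early[count_col].to_numpy(float),
                                      early["age_at_mri"].to_numpy(float))
            out["wave_count_vs_memory_earlier"] = correlate(
                adj_cnt, adj_score[early.index])
    if "mfd" in df.columns:
        out["mfd_earlier_vs_later"] = two_sample_t(
            df.loc[df["group"] == "earlier", "mfd"],
            df.loc[df["group"] == "later", "mfd"])
    return out
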