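"""Longitudinal group statistics on ROI summaries.

The analysis mirrors standard longitudinal neuroimaging practice: per
metric and region, change over one year is first screened with a paired
t-test; screened metrics are then fitted with a covariate-adjusted
linear mixed model (random subject intercept, maximum likelihood),

    value ~ time + age + sex + lesion_load + dmt  +  (1 | subject),

whose time fixed effect is the adjusted annual change.  Lesion load is a
time-varying covariate (percent of intracranial volume at each visit).
Mixed-model p-values are corrected with Benjamini-Hochberg FDR within
each region's metric family.  Goodness of fit is summarised with the
Nakagawa marginal R^2,

    R2_marginal = s2_fixed / (s2_fixed + s2_random + s2_residual),

where s2_fixed is the variance of the fixed-effect linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "PairedTestResult",
    "LmmResult",
    "paired_t",
    "fit_lmm",
    "fdr_adjust",
    "change_correlation",
    "subgroup_welch",
    "marginal_r2",
    "longitudinal_analysis",
]

DEFAULT_COVARIATES = ("age", "sex", "lesion_load", "dmt")


@dataclass
class PairedTestResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float


@dataclass
class LmmResult:
    beta_time: float
    se: float
    t: float
    df: float
    p: float
    sigma2_fixed: float
    sigma2_random: float
    sigma2_resid: float
    marginal_r2: float
    converged: bool
    q: float = np.nan


def paired_t(values_t1, values_t2) -> PairedTestResult:
    """Two-sided paired t-test on per-subject values at two timepoints."""
    v1 = np.asarray(values_t1, dtype=float)
    v2 = np.asarray(values_t2, dtype=float)
    if v1.shape != v2.shape or v1.size < 2:
        raise ValueError("need >= 2 paired values of equal length")
    d = v2 - v1
    sd = float(d.std(ddof=1))
    res = stats.ttest_rel(v2, v1)
    t = float(res.statistic)
    if sd == 0 and d.mean() != 0:
        t = np.inf if d.mean() > 0 else -np.inf
    return PairedTestResult(
        n=int(v1.size),
        mean_diff=float(d.mean()),
        sd_diff=sd,
        t=t,
        df=int(v1.size - 1),
        p=float(res.pvalue),
    )


def marginal_r2(sigma2_fixed: float, sigma2_random: float, sigma2_resid: float) -> float:
    """Nakagawa marginal R^2 from variance components."""
    total = sigma2_fixed + sigma2_random + sigma2_resid
    if total <= 0:
        raise ValueError("variance components must sum to a positive total")
    return sigma2_fixed / total


def fit_lmm(
    data: pd.DataFrame,
    value_col: str = "value",
    time_col: str = "time",
    subject_col: str = "subject",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra_terms: tuple[str, ...] = (),
) -> LmmResult:
    """Random-intercept LMM of a metric on time plus confounders (ML fit).

    ``extra_terms`` allows interaction terms (e.g. ``"time:dmt"``); none
    are included by default.  Non-convergence is reported via the
    ``converged`` flag, never silently swallowed into estimates.
    """
    cols = [value_col, time_col, subject_col, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = data[cols].dropna().copy()
    terms = [time_col, *covariates, *extra_terms]
    formula = f"{value_col} ~ " + " + ".join(terms)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        model = MixedLM.from_formula(formula, groups=df[subject_col], data=df)
        fit = model.fit(reml=False)

    beta = float(fit.params[time_col])
    se = float(fit.bse[time_col])
    p = float(fit.pvalues[time_col])
    s2_rand = float(np.asarray(fit.cov_re)[0, 0])
    s2_resid = float(fit.scale)
    fixed_pred = np.asarray(fit.model.exog @ fit.fe_params)
    s2_fixed = float(np.var(fixed_pred, ddof=1))
    n_obs = int(fit.nobs)
    k_fe = len(fit.fe_params)
    return LmmResult(
        beta_time=beta,
        se=se,
        t=beta / se if se > 0 else np.nan,
        df=float(n_obs - k_fe),
        p=p,
        sigma2_fixed=s2_fixed,
        sigma2_random=s2_rand,
        sigma2_resid=s2_resid,
        marginal_r2=marginal_r2(s2_fixed, s2_rand, s2_resid),
        converged=bool(fit.converged),
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def change_correlation(deltas_a, deltas_b) -> tuple[float, float, float]:
    """Pearson correlation of per-subject changes: returns (r, r^2, p)."""
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired changes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(r) ** 2, float(p)


def subgroup_welch(changes, labels) -> tuple[float, float, float]:
    """Welch's t-test of changes between two labelled subgroups.

    Returns (t, Satterthwaite df, two-sided p).
    """
    changes = np.asarray(changes, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups.size}")
    x = changes[labels == groups[0]]
    y = changes[labels == groups[1]]
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Staged per-region analysis over a tidy cohort table
# ---------------------------------------------------------------------------


def _wide_pairs(table: pd.DataFrame, metric: str, region: str) -> pd.DataFrame:
    sub = table[(table["metric"] == metric) & (table["region"] == region)]
    wide = sub.pivot_table(index="subject", columns="time", values="mean")
    wide = wide.dropna()
    if wide.shape[1] != 2:
        raise ValueError(f"need exactly two timepoints for {metric}/{region}")
    return wide


def longitudinal_analysis(
    table: pd.DataFrame,
    metrics: tuple[str, ...],
    regions: tuple[str, ...],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    gate_with_paired_t: bool = True,
    extra_terms: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-t screening plus FDR-corrected mixed models per region.

    ``table`` is tidy: one row per subject x time x region x metric with a
    ``mean`` value column and covariate columns.  Mixed models are fitted
    only for metrics whose paired t passes the screening threshold (as is
    conventional, to keep the FDR family minimal); the family for FDR is
    the set of fitted metrics within each region.

    Returns ``(paired_df, lmm_df)``.
    """
    paired_rows, lmm_rows = [], []
    for region in regions:
        for metric in metrics:
            wide = _wide_pairs(table, metric, region)
            times = sorted(wide.columns)
            res = paired_t(wide[times[0]], wide[times[1]])
            paired_rows.append(
                {"region": region, "metric": metric, **res.__dict__}
            )
            if gate_with_paired_t and res.p >= alpha:
                continue
            sub = table[(table["metric"] == metric) & (table["region"] == region)]
            data = sub.rename(columns={"mean": "value"})
            lmm = fit_lmm(data, covariates=covariates, extra_terms=extra_terms)
            lmm_rows.append({"region": region, "metric": metric, **lmm.__dict__})

    paired_df = pd.DataFrame(paired_rows)
    lmm_df = pd.DataFrame(lmm_rows)
    if not lmm_df.empty:
        lmm_df["q"] = np.nan
        for region in regions:
            idx = lmm_df["region"] == region
            if idx.any():
                lmm_df.loc[idx, "q"] = fdr_adjust(lmm_df.loc[idx, "p"].to_numpy())
    return paired_df, lmm_df


def significance_pattern(
    paired_df: pd.DataFrame, lmm_df: pd.DataFrame, alpha: float = 0.05
) -> dict[tuple[str, str], str]:
    """Direction-of-change pattern: '+', '-' for FDR-significant, '0' otherwise.

    A metric screened out at the paired-t stage, or with FDR-corrected
    q >= alpha, counts as no change ('0').
    """
    pattern: dict[tuple[str, str], str] = {}
    for _, row in paired_df.iterrows():
        pattern[(row["region"], row["metric"])] = "0"
    for _, row in lmm_df.iterrows():
        if row["q"] < alpha:
            pattern[(row["region"], row["metric"])] = "+" if row["beta_time"] > 0 else "-"
    return pattern
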