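"""Cohort-level statistics: normality-gated group tests with FDR, effect
sizes, covariate adjustment, correlations, multiple regression, and
bootstrap causal mediation.

Test selection follows a Shapiro-Wilk gate per variable per group at
alpha = 0.05: Student's t when both groups pass, Mann-Whitney U otherwise
(a disagreement between groups falls through to the nonparametric test).
Multiple comparisons are corrected with the Benjamini-Hochberg false
discovery rate step-up, applied independently within declared families.
"Age- and sex-adjusted" values are residuals from a least-squares fit on
age and sex, re-centred on the grand mean.

Mediation uses the product-of-coefficients estimator: with mediator model
``m ~ x + covariates`` (slope a) and outcome model ``y ~ x + m + covariates``
(slopes: direct effect and b), the indirect effect is a*b, its uncertainty
from case-resampled bootstrap replicates with a percentile confidence
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .signal_models import arterial_oxygen_content

__all__ = [
    "GroupComparisonResult", "MediationResult", "RegressionResult",
    "CorrelationResult", "PhiResult",
    "cohen_d", "cohen_d_from_samples", "mann_whitney_r", "phi_2x2", "bh_fdr",
    "compare_groups", "adjust_age_sex", "correlate", "fit_regression",
    "mediate_bootstrap", "prepare_cohort",
]

NORMALITY_ALPHA = 0.05


# --------------------------------------------------------------------------
# effect sizes

def cohen_d(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d = (mean2 - mean1) / pooled SD, (n-1)-weighted pooling.

    The sign convention follows the column order: positive when group 2 has
    the larger mean.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("cohen_d requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("standard deviations must be non-negative")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DomainError("pooled SD is zero; d undefined")
    return float((mean2 - mean1) / pooled)


def cohen_d_from_samples(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohen_d(a.mean(), a.std(ddof=1), a.size,
                   b.mean(), b.std(ddof=1), b.size)


def mann_whitney_r(a, b) -> tuple[float, float]:
    """Rank-biserial-style effect r = |Z|/sqrt(N) for the Mann-Whitney U test.

    Z uses the normal approximation with tie correction. Returns ``(r, z)``;
    degenerate samples (zero-variance rank distribution) give r = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 0.0
    z = (u1 - mu) / np.sqrt(var)
    return float(abs(z) / np.sqrt(n)), float(z)


class PhiResult(NamedTuple):
    phi: float
    chi2: float
    p: float


def phi_2x2(table, continuity: bool = True) -> PhiResult:
    """Cramér's phi for a 2x2 table: sqrt(chi^2 / N), optional Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DomainError("phi_2x2 needs a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DomainError("zero margin; phi undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    return PhiResult(float(np.sqrt(chi2 / t.sum())), float(chi2), float(p))


# --------------------------------------------------------------------------
# multiple testing

def bh_fdr(p_values, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, per declared family.

    ``families`` is an optional sequence of hashable labels, one per p value;
    adjustment is applied independently within each label. Adjusted values
    are order-preserving within a family and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p values must lie in [0, 1]")
    if families is None:
        return multipletests(p, method="fdr_bh")[1]
    fam = np.asarray(families, dtype=object)
    if fam.shape != p.shape:
        raise DomainError("families must match p_values in length")
    adjusted = np.empty_like(p)
    for label in pd.unique(fam):
        idx = fam == label
        adjusted[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adjusted


# --------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparisonResult:
    variable: str | None
    test: str                      # "t" | "mann_whitney" | "degenerate"
    statistic: float
    p_raw: float
    effect_name: str               # "cohen_d" | "rank_r"
    effect_value: float
    n1: int
    n2: int
    family: str | None = None
    p_fdr: float | None = None
    note: str | None = None


def _shapiro_normal(x, alpha: float) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    try:
        return stats.shapiro(x).pvalue > alpha
    except Exception:
        return False


def compare_groups(a, b, variable: str | None = None,
                   family: str | None = None,
                   alpha_normality: float = NORMALITY_ALPHA) -> GroupComparisonResult:
    """Shapiro-Wilk-gated two-group comparison with effect size.

    Both groups normal -> Student's t (pooled variance) with Cohen's d
    (sign: group b minus group a); otherwise Mann-Whitney U with
    r = |Z|/sqrt(N). Identical constant samples are degenerate: reported
    with p = 1 and zero effect.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise DomainError("compare_groups needs >= 3 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return GroupComparisonResult(variable, "degenerate", 0.0, 1.0,
                                     "rank_r", 0.0, a.size, b.size, family,
                                     note="zero variance in both groups")
    if _shapiro_normal(a, alpha_normality) and _shapiro_normal(b, alpha_normality):
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparisonResult(variable, "t", float(res.statistic),
                                     float(res.pvalue), "cohen_d",
                                     cohen_d_from_samples(a, b),
                                     a.size, b.size, family)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    r, z = mann_whitney_r(a, b)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return GroupComparisonResult(variable, "mann_whitney", float(res.statistic),
                                 p, "rank_r", r, a.size, b.size, family)


# --------------------------------------------------------------------------
# adjustment, correlation, regression

def adjust_age_sex(values, age, sex) -> np.ndarray:
    """Residualize a variable on age and sex, re-adding the grand mean."""
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if np.isnan(y).any() or np.isnan(age).any() or np.isnan(sex).any():
        raise DomainError("adjust_age_sex requires complete cases")
    design = np.column_stack([np.ones_like(y), age, sex])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("constant or collinear covariates; adjustment is "
                      "degenerate (minimum-norm fit)", stacklevel=2)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef + y.mean()


class CorrelationResult(NamedTuple):
    method: str            # "pearson" | "spearman"
    r: float
    p: float
    n: int


def correlate(x, y, alpha_normality: float = NORMALITY_ALPHA) -> CorrelationResult:
    """Pearson when both variables pass the normality gate, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DomainError("correlate needs >= 3 complete pairs")
    if _shapiro_normal(x, alpha_normality) and _shapiro_normal(y, alpha_normality):
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p), x.size)
    r, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), float(p), x.size)


@dataclass
class RegressionResult:
    table: pd.DataFrame            # per predictor: b, beta, ci_low, ci_high, p, partial_r, vif
    r_squared: float
    n: int
    outcome: str
    model: object = field(repr=False, default=None)


def fit_regression(data: pd.DataFrame, outcome: str,
                   predictors: Sequence[str]) -> RegressionResult:
    """Ordinary least squares of ``outcome`` on a preselected covariate set.

    Complete cases only. Returns unstandardised and standardised
    coefficients, 95% CIs, p values, partial correlations (from the t
    statistics) and variance inflation factors. A rank-deficient design
    raises, naming the collinear columns.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    cols = [outcome, *predictors]
    df = data[cols].dropna()
    n = len(df)
    if n <= len(predictors) + 1:
        raise DomainError("too few complete cases for the design")
    y = df[outcome].to_numpy(dtype=float)
    X = df[list(predictors)].to_numpy(dtype=float)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(exog, j + 1, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(X[:, j]).max())):
                bad.append(predictors[j])
        raise DomainError(f"singular design; collinear predictors: {bad}")
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = y.std(ddof=1)
    df_resid = fit.df_resid
    rows = {}
    for j, name in enumerate(predictors):
        k = j + 1
        t = fit.tvalues[k]
        rows[name] = {
            "b": fit.params[k],
            "beta": fit.params[k] * X[:, j].std(ddof=1) / sd_y,
            "ci_low": ci[k, 0],
            "ci_high": ci[k, 1],
            "p": fit.pvalues[k],
            "partial_r": t / np.sqrt(t ** 2 + df_resid),
            "vif": variance_inflation_factor(exog, k),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return RegressionResult(table=table, r_squared=float(fit.rsquared),
                            n=n, outcome=outcome, model=fit)


# --------------------------------------------------------------------------
# mediation

@dataclass
class MediationResult:
    a_path: float
    b_path: float
    direct: float
    total: float
    indirect: float
    ci_low: float
    ci_high: float
    p_indirect: float
    proportion_mediated: float
    n: int
    n_boot: int
    seed: int | None
    boot_indirect: np.ndarray = field(repr=False, default=None)


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def mediate_bootstrap(x, mediator, y, covariates=None, n_boot: int = 1000,
                      seed: int | None = None, ci: float = 0.95) -> MediationResult:
    """Bootstrap product-of-coefficients mediation (percentile CI).

    ``covariates`` is an optional (n, k) array (e.g. age and sex) entered in
    every model. The indirect effect a*b is recomputed on ``n_boot``
    case-resampled replicates; the CI is the (2.5th, 97.5th) percentile pair
    at the default level and the two-sided p value is the percentile
    bootstrap sign test. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if m.size != n or y.size != n:
        raise DomainError("x, mediator, y must have equal length")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, np.newaxis]
        if C.shape[0] != n:
            raise DomainError("covariates must have one row per case")
    stack = [x, m, y] + ([C[:, j] for j in range(C.shape[1])] if C is not None else [])
    if any(np.isnan(v).any() for v in stack):
        raise DomainError("mediate_bootstrap requires complete cases")
    if n < 20:
        raise DomainError("mediation requires n >= 20 complete cases")
    if np.ptp(m) == 0:
        raise DomainError("zero-variance mediator")

    ones = np.ones(n)
    cov_cols = [C[:, j] for j in range(C.shape[1])] if C is not None else []
    X_med = np.column_stack([ones, x, *cov_cols])
    X_out = np.column_stack([ones, x, m, *cov_cols])
    X_tot = X_med

    a = _ols_coef(X_med, m)[1]
    out_coef = _ols_coef(X_out, y)
    direct, b = out_coef[1], out_coef[2]
    total = _ols_coef(X_tot, y)[1]
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        a_i = _ols_coef(X_med[idx], m[idx])[1]
        b_i = _ols_coef(X_out[idx], y[idx])[2]
        boot[i] = a_i * b_i
    lo, hi = np.percentile(boot, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    p = 2 * min((boot <= 0).mean(), (boot >= 0).mean())
    p = float(min(max(p, 1.0 / n_boot), 1.0))
    prop = float(indirect / total) if total != 0 else float("nan")
    return MediationResult(a_path=float(a), b_path=float(b),
                           direct=float(direct), total=float(total),
                           indirect=float(indirect), ci_low=float(lo),
                           ci_high=float(hi), p_indirect=p,
                           proportion_mediated=prop, n=n, n_boot=n_boot,
                           seed=seed, boot_indirect=boot)


# --------------------------------------------------------------------------
# cohort table preparation

def prepare_cohort(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Fill missing hemoglobin/saturation with group means; compute CaO2.

    Mirrors the handling of sparse hematology in clinical tables: missing
    hemoglobin or oxygen saturation values are substituted with the mean of
    the subject's group before arterial oxygen content is derived.
    """
    df = table.copy()
    for col in ("hemoglobin", "oxygen_saturation"):
        if col in df:
            df[col] = df.groupby(group_col)[col].transform(
                lambda s: s.fillna(s.mean()))
    if {"hemoglobin", "oxygen_saturation"} <= set(df.columns):
        df["cao2"] = arterial_oxygen_content(
            df["hemoglobin"].to_numpy(), df["oxygen_saturation"].to_numpy())
    return df
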