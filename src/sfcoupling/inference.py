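"""Covariate-adjusted two-group inference with family-wise error control.

The statistical machinery mirrors a conventional case-control connectome
analysis: each feature is residualized on age, sex and education by
ordinary least squares; the residuals are routed by Shapiro-Wilk normality
(both groups p > 0.05 -> independent two-sample t-test, otherwise
Mann-Whitney U; categorical variables -> chi-squared) with two-tailed
p-values throughout; family-wise error across a feature family is
controlled either by Bonferroni or by a max-statistic label-permutation
(Westfall-Young) procedure.  Partial correlations between brain features
and cognitive scores correlate the covariate residuals of both variables,
rank-transformed first for the Spearman variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisConfig

__all__ = [
    "ComparisonResult",
    "PartialCorrelationResult",
    "residualize",
    "route_test",
    "fwe_correct",
    "compare_groups",
    "partial_correlation",
    "comparison_table",
]

_COVARIATES = ("age", "sex", "education")


@dataclass
class ComparisonResult:
    """One feature's two-group comparison."""

    feature: str
    test_used: str
    statistic: float
    p_raw: float
    p_fwe: float | None = None
    direction: int = 0  # sign of (VCI - HC) adjusted difference
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        if self.p_fwe is not None and self.p_fwe < self.p_raw - 1e-12:
            raise ValueError("p_fwe must be >= p_raw")


@dataclass
class PartialCorrelationResult:
    region: str
    score: str
    rho_partial: float
    p_raw: float
    method: str
    n: int
    p_fwe: float | None = None
    pearson_rho: float = np.nan
    spearman_rho: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.rho_partial) and abs(self.rho_partial) > 1 + 1e-12:
            raise ValueError("|rho_partial| must be <= 1")


def design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """[intercept, age, sex(0/1), education] design from a covariate table."""
    missing = [c for c in _COVARIATES if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing column(s) {missing}")
    if covariates[list(_COVARIATES)].isna().any().any():
        raise ValueError("missing covariate values; drop incomplete subjects first")
    sex = covariates["sex"]
    if sex.dtype == object:
        sex = sex.map({"male": 1.0, "female": 0.0})
        if sex.isna().any():
            raise ValueError("sex column must contain 'male'/'female' (or 0/1)")
    x = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(float),
            sex.to_numpy(float),
            covariates["education"].to_numpy(float),
        ]
    )
    return x


def residualize(outcome: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of an outcome on [intercept, age, sex, education]."""
    y = np.asarray(outcome, dtype=float)
    x = design_matrix(covariates)
    if len(y) != x.shape[0]:
        raise ValueError("outcome and covariates have different lengths")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ("intercept",) + _COVARIATES
        keep = []
        for j in range(x.shape[1]):
            cols = keep + [j]
            if np.linalg.matrix_rank(x[:, cols]) == len(cols):
                keep.append(j)
        collinear = [names[j] for j in range(x.shape[1]) if j not in keep]
        raise ValueError(f"rank-deficient design: collinear column(s) {collinear}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _shapiro_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk routing rule: p > alpha counts as normal."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or np.all(values == values[0]):
        return False
    with np.errstate(all="ignore"):
        p = stats.shapiro(values).pvalue
    return bool(p > alpha)


def route_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    kind: str = "continuous",
    feature: str = "",
) -> ComparisonResult:
    """Normality-routed two-group test (two-tailed).

    Continuous: both groups Shapiro-Wilk p > 0.05 -> independent t-test,
    otherwise Mann-Whitney U.  Categorical: chi-squared on the 2xk table.
    Group a is taken as VCI and group b as HC for the direction sign.
    """
    a = np.asarray(values_a)
    b = np.asarray(values_b)
    if kind == "categorical":
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        if len(levels) < 2:
            raise ValueError(f"feature {feature or '<categorical>'}: only one category level")
        table = np.array(
            [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]], dtype=float
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ComparisonResult(
            feature=feature, test_used="chi_squared", statistic=float(chi2), p_raw=float(p),
            direction=0, n_a=a.size, n_b=b.size,
        )
    a = a.astype(float)
    b = b.astype(float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"feature {feature or '<continuous>'}: each group needs >= 3 values for routing")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        raise ValueError(f"feature {feature or '<continuous>'}: all values identical in both groups")
    direction = int(np.sign(a.mean() - b.mean()))
    if _shapiro_normal(a) and _shapiro_normal(b):
        res = stats.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            feature=feature, test_used="t", statistic=float(res.statistic), p_raw=float(res.pvalue),
            direction=direction, n_a=a.size, n_b=b.size,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        feature=feature, test_used="mann_whitney", statistic=float(res.statistic), p_raw=float(res.pvalue),
        direction=direction, n_a=a.size, n_b=b.size,
    )


def _t_statistics(x: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t per feature column."""
    n1 = int(is_a.sum())
    n2 = x.shape[0] - n1
    a = x[is_a]
    b = x[~is_a]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def maxT_null_distribution(
    residuals: np.ndarray,
    is_group_a: np.ndarray,
    permutations: int,
    rng: np.random.Generator,
    rank_based: bool = False,
) -> np.ndarray:
    """Null distribution of max |t| over features under label permutation."""
    x = np.asarray(residuals, dtype=float)
    if rank_based:
        x = stats.rankdata(x, axis=0)
    n = x.shape[0]
    null_max = np.empty(permutations)
    for p in range(permutations):
        perm = rng.permutation(n)
        null_max[p] = np.max(np.abs(_t_statistics(x[perm], is_group_a)))
    return null_max


def fwe_correct(
    results: list[ComparisonResult],
    method: str = "permutation_maxT",
    residuals: np.ndarray | None = None,
    is_group_a: np.ndarray | None = None,
    permutations: int = 1000,
    seed: int = 0,
    rank_based: bool = False,
) -> list[ComparisonResult]:
    """Attach family-wise-error-adjusted p-values to a feature family.

    ``bonferroni``: p_fwe = min(1, m * p_raw).  ``permutation_maxT``: group
    labels are permuted within the residualized feature matrix; each
    feature's p_fwe is the fraction of permutations whose maximum |t| over
    features reaches that feature's observed |t| (add-one estimator).
    """
    if not results:
        raise ValueError("empty feature family")
    m = len(results)
    if method == "bonferroni":
        for r in results:
            r.p_fwe = min(1.0, m * r.p_raw)
        return results
    if method != "permutation_maxT":
        raise ValueError(f"unknown FWE method {method!r}")
    if residuals is None or is_group_a is None:
        raise ValueError("permutation_maxT requires the residualized feature matrix and group labels")
    x = np.asarray(residuals, dtype=float)
    if x.shape[1] != m:
        raise ValueError(f"residual matrix has {x.shape[1]} features for {m} results")
    is_a = np.asarray(is_group_a, dtype=bool)
    rng = np.random.default_rng(seed)
    xs = stats.rankdata(x, axis=0) if rank_based else x
    observed = np.abs(_t_statistics(xs, is_a))
    null_max = maxT_null_distribution(x, is_a, permutations, rng, rank_based=rank_based)
    for j, r in enumerate(results):
        exceed = int(np.sum(null_max >= observed[j] - 1e-12))
        r.p_fwe = max((1 + exceed) / (permutations + 1), r.p_raw)
    return results


def compare_groups(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    config: AnalysisConfig | None = None,
    family: str = "features",
) -> list[ComparisonResult]:
    """Covariate-adjusted two-group comparison of a feature family.

    ``features``: one row per subject, one column per feature, indexed by
    subject_id.  ``manifest``: columns group, age, sex, education, indexed
    by subject_id.  Each feature is residualized on the covariates, the
    residuals are routed by normality, and FWE correction is applied across
    the family.  Subjects with missing covariates or a missing feature
    value are dropped listwise within the family (reported via n_a/n_b).
    """
    config = config or AnalysisConfig()
    common = features.index.intersection(manifest.index)
    feats = features.loc[common]
    man = manifest.loc[common]
    complete = (
        man[list(_COVARIATES)].notna().all(axis=1)
        & man["group"].notna()
        & feats.notna().all(axis=1)
    )
    feats = feats.loc[complete]
    man = man.loc[complete]
    if feats.empty:
        raise ValueError("no complete-case subjects for group comparison")
    for col in feats.columns:
        if feats[col].nunique() <= 1:
            raise ValueError(f"feature {col!r} is constant across subjects")
    is_vci = (man["group"] == "VCI").to_numpy()
    n_vci, n_hc = int(is_vci.sum()), int((~is_vci).sum())
    if n_vci < 3 or n_hc < 3:
        raise ValueError(f"need >= 3 complete-case subjects per group (got VCI={n_vci}, HC={n_hc})")
    resid = np.column_stack([residualize(feats[col].to_numpy(float), man) for col in feats.columns])
    results = []
    for j, col in enumerate(feats.columns):
        results.append(route_test(resid[is_vci, j], resid[~is_vci, j], kind="continuous", feature=str(col)))
    results = fwe_correct(
        results,
        method=config.fwe_method,
        residuals=resid,
        is_group_a=is_vci,
        permutations=config.permutations,
        seed=config.seed,
    )
    return results


def comparison_table(results: list[ComparisonResult], family: str = "") -> pd.DataFrame:
    """Tidy one-row-per-feature table of comparison results."""
    columns = ["family", "feature", "test", "statistic", "p_raw", "p_fwe", "direction", "n_vci", "n_hc"]
    if not results:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "family": family,
                "feature": r.feature,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_fwe": r.p_fwe,
                "direction": r.direction,
                "n_vci": r.n_a,
                "n_hc": r.n_b,
            }
            for r in results
        ]
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame,
    method: str = "auto",
    region: str = "",
    score: str = "",
) -> PartialCorrelationResult:
    """Partial correlation of x and y given age, sex, education.

    Correlates the OLS covariate residuals of both variables; for the
    Spearman variant both variables are rank-transformed first.  With
    ``method="auto"`` the variant is routed by Shapiro-Wilk on the raw
    variables (both normal -> Pearson, else Spearman); both variants are
    always computed and stored.  p-values use the t approximation with
    n - k - 2 degrees of freedom (k = 3 covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = len(_COVARIATES)
    if n <= k + 2:
        raise ValueError(f"partial correlation needs n > {k + 2}, got {n}")

    def _partial(xv: np.ndarray, yv: np.ndarray) -> float:
        rx = residualize(xv, covariates)
        ry = residualize(yv, covariates)
        sx, sy = rx.std(), ry.std()
        if sx == 0 or sy == 0:
            return np.nan
        return float(np.corrcoef(rx, ry)[0, 1])

    r_pearson = _partial(x, y)
    r_spearman = _partial(stats.rankdata(x), stats.rankdata(y))
    if method == "auto":
        method_used = "pearson" if (_shapiro_normal(x) and _shapiro_normal(y)) else "spearman"
    elif method in ("pearson", "spearman"):
        method_used = method
    else:
        raise ValueError(f"unknown method {method!r}")
    r = r_pearson if method_used == "pearson" else r_spearman
    df = n - k - 2
    if np.isfinite(r) and abs(r) < 1:
        tstat = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(tstat), df))
    elif np.isfinite(r):
        p = 0.0
    else:
        p = np.nan
    return PartialCorrelationResult(
        region=region, score=score, rho_partial=r, p_raw=p, method=method_used, n=n,
        pearson_rho=r_pearson, spearman_rho=r_spearman,
    )
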