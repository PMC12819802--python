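"""Covariate-adjusted group contrasts, multiplicity control, correlations.

The group contrast fits, per feature, the linear model
``feature ~ intercept + group + covariates`` by least squares and reports
the t statistic and two-sided p for the group coefficient; with no
covariates this reduces exactly to the classic pooled-variance two-sample
t-test. Family-wise control across features uses a max-|t| permutation
null (group labels permuted, model refitted per draw); per-feature
discovery control uses Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int


def _design(groups: np.ndarray, covariates: np.ndarray | None,
            baseline: str | None = None
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build [intercept, group indicator, covariates]; returns the design,
    the 0/1 group indicator, and column names for error reporting.

    ``baseline`` names the reference level (indicator 0); default is the
    first level in sorted order.
    """
    levels = list(np.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    if baseline is not None:
        if baseline not in levels:
            raise ValueError(f"baseline {baseline!r} not among groups {levels}")
        levels = [baseline] + [lv for lv in levels if lv != baseline]
    indicator = (groups == levels[1]).astype(float)
    cols = [np.ones(len(groups)), indicator]
    names = ["intercept", f"group[{levels[1]}]"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(groups):
            cov = cov.T
        if cov.shape[0] != len(groups):
            raise ValueError("covariate rows must match the number of subjects")
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"covariate{j}")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify which added column breaks full rank
        for j in range(2, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                raise ValueError(f"design is rank deficient at column {names[j]!r}")
        raise ValueError("design is rank deficient (group confounded with intercept)")
    return x, indicator, names


def _group_t(features: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized OLS t statistic for the group column (index 1)."""
    y = np.atleast_2d(np.asarray(features, dtype=float))
    if y.shape[0] != x.shape[0]:
        raise ValueError("feature rows must match the number of subjects")
    n, p = x.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough subjects for the requested model")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se, df


def adjusted_group_contrast(features: np.ndarray, groups,
                            covariates: np.ndarray | None = None,
                            feature_names: list[str] | None = None,
                            baseline: str | None = None) -> pd.DataFrame:
    """Per-feature covariate-adjusted two-group contrast.

    Parameters
    ----------
    features : (n_subjects, n_features) array
    groups : length-n label vector with exactly two levels; the t statistic
        is for the non-baseline level minus the baseline (default baseline:
        first level in sorted order).
    covariates : optional (n_subjects, n_covariates) array

    Returns a DataFrame with columns ``feature, t, p, df, n_<level>``.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    counts = {lv: int((groups == lv).sum()) for lv in levels}
    if min(counts.values()) < 3:
        raise ValueError(f"each group needs at least 3 subjects, got {counts}")
    x, _, _ = _design(groups, covariates, baseline)
    t, df = _group_t(features, x)
    p = 2 * sps.t.sf(np.abs(t), df)
    names = feature_names or [f"f{i}" for i in range(len(t))]
    out = pd.DataFrame({"feature": names, "t": t, "p": p, "df": df})
    for lv in levels:
        out[f"n_{lv}"] = counts[lv]
    return out


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_bh_by_network(p_values: np.ndarray, networks) -> np.ndarray:
    """BH applied separately within each network's feature set."""
    p = np.asarray(p_values, dtype=float)
    networks = np.asarray(networks)
    q = np.empty_like(p)
    for name in np.unique(networks):
        mask = networks == name
        q[mask] = fdr_bh(p[mask])
    return q


def maxstat_permutation(features: np.ndarray, groups,
                        covariates: np.ndarray | None = None,
                        n_perm: int = 999, seed: int = 0,
                        baseline: str | None = None) -> np.ndarray:
    """Family-wise corrected p per feature via the max-|t| permutation null.

    Group labels are permuted ``n_perm`` times, the covariate-adjusted t is
    recomputed for every feature, and each observed |t| is referred to the
    null distribution of the permutation maxima:
    ``p_corr = (1 + #{max_null >= |t_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    x, _, _ = _design(groups, covariates, baseline)
    t_obs, _ = _group_t(features, x)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(groups))
        xb, _, _ = _design(groups[perm], covariates, baseline)
        tb, _ = _group_t(features, xb)
        max_null[b] = np.abs(tb).max()
    exceed = (max_null[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)
    return (1.0 + exceed) / (n_perm + 1.0)


def correlate_clinical(feature: np.ndarray, clinical: np.ndarray,
                       method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(clinical, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 5:
        raise ValueError(f"need at least 5 paired observations, got {len(x)}")
    if x.std() < 1e-14 or y.std() < 1e-14:
        raise ValueError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p=float(p), n=len(x))


def choose_correlation_method(x: np.ndarray, y: np.ndarray,
                              alpha: float = 0.05) -> str:
    """Normality screen: Spearman if either vector fails Shapiro-Wilk."""
    for v in (x, y):
        if sps.shapiro(np.asarray(v, dtype=float)).pvalue < alpha:
            return "spearman"
    return "pearson"
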