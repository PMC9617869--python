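"""Group inference: permutation tests with FDR control, demographic tests,
and covariate-adjusted Spearman correlations with symptom ratings.

Dynamic features are compared between groups with a label-permutation test
on the difference of group means (two-sided, add-one p estimator), with
Benjamini-Hochberg FDR correction applied within declared families: the
state characteristics form one family, and each nodal-metric map is its
own family.  Symptom correlations use Spearman partial correlation with
age, sex (0/1) and education as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "PartialCorrResult",
    "permutation_test",
    "fdr_bh",
    "spearman_partial",
    "chi_square_2x2",
    "two_sample_t",
    "compare_groups",
    "demographics_table",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_perm: float
    n_perm: int


@dataclass(frozen=True)
class PartialCorrResult:
    rho: float
    p: float
    n: int
    covariates: tuple[str, ...]
    undefined: bool = False


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    statistic: str = "mean_diff",
) -> PermutationResult:
    """Two-sided label-permutation test.

    The statistic is the difference of group means (a minus b) by default;
    ``statistic='t'`` uses the pooled t statistic instead.  p is the
    add-one estimator (#{|perm| >= |observed|} + 1) / (n_perm + 1), so it
    is never exactly zero.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if statistic not in ("mean_diff", "t"):
        raise ValueError("statistic must be 'mean_diff' or 't'")
    rng = rng if rng is not None else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size

    def stat(x_a: np.ndarray, x_b: np.ndarray, axis: int = -1) -> np.ndarray:
        d = x_a.mean(axis=axis) - x_b.mean(axis=axis)
        if statistic == "mean_diff":
            return d
        va = x_a.var(axis=axis, ddof=1)
        vb = x_b.var(axis=axis, ddof=1)
        nb = n - na
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        return np.where(se > 0, d / np.where(se > 0, se, 1.0), 0.0)

    observed = float(stat(a, b))
    # vectorized shuffles: argsort of uniform keys gives independent
    # permutations per row
    keys = rng.random((n_perm, n))
    idx = np.argsort(keys, axis=1)
    perm = pooled[idx]
    perm_stat = stat(perm[:, :na], perm[:, na:])
    count = int(np.sum(np.abs(perm_stat) >= np.abs(observed) - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(observed_diff=observed, p_perm=p, n_perm=n_perm)


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
) -> PartialCorrResult:
    """Spearman partial correlation of x and y given covariates.

    x and y are rank-transformed (average ranks for ties), residualized on
    the covariates (with intercept) by least squares, and the Pearson
    correlation of the residuals is returned with a t-approximation p
    (df = n - #covariates - 2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = tuple(covariates.columns)
            Z = covariates.to_numpy(float)
        else:
            Z = np.asarray(covariates, float)
            if Z.ndim == 1:
                Z = Z[:, None]
    ncov = Z.shape[1]
    if n <= ncov + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    names = tuple(covariate_names) if covariate_names else tuple(
        f"cov{i}" for i in range(ncov)
    )
    if rx.std() == 0 or ry.std() == 0:
        return PartialCorrResult(np.nan, np.nan, n, names, undefined=True)
    design = np.column_stack([np.ones(n), Z])
    resid_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    resid_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    sx, sy = resid_x.std(), resid_y.std()
    if sx == 0 or sy == 0:
        return PartialCorrResult(np.nan, np.nan, n, names, undefined=True)
    rho = float(np.dot(resid_x - resid_x.mean(), resid_y - resid_y.mean())
                / (n * sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - ncov - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(rho=rho, p=p, n=n, covariates=names)


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity
    correction."""
    T = np.asarray(table, float)
    if T.shape != (2, 2) or np.any(T < 0):
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = stats.chi2_contingency(T, correction=False)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    features: pd.DataFrame,
    groups: Sequence[str],
    families: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> pd.DataFrame:
    """Permutation group comparison per feature column, FDR within
    families.

    ``families`` maps family label -> feature columns; unlisted columns
    form a catch-all family.  Group a = patients, b = controls (observed
    diff is patient minus control).
    """
    groups = np.asarray(groups)
    is_a = groups == "patient"
    is_b = groups == "control"
    if not is_a.any() or not is_b.any():
        raise ValueError("need both patients and controls")
    rng = np.random.default_rng(seed)
    rows = []
    fam_of = {}
    if families:
        for fam, cols in families.items():
            for c in cols:
                fam_of[c] = fam
    for col in features.columns:
        v = features[col].to_numpy(float)
        ok = np.isfinite(v)
        a, b = v[is_a & ok], v[is_b & ok]
        res = permutation_test(a, b, n_perm=n_perm, rng=rng, statistic=statistic)
        rows.append(
            {
                "feature": col,
                "family": fam_of.get(col, "other"),
                "mean_patient": a.mean(),
                "sd_patient": a.std(ddof=1) if a.size > 1 else np.nan,
                "mean_control": b.mean(),
                "sd_control": b.std(ddof=1) if b.size > 1 else np.nan,
                "observed_diff": res.observed_diff,
                "p_perm": res.p_perm,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for fam in out["family"].unique():
        mask = out["family"] == fam
        out.loc[mask, "p_fdr"] = fdr_bh(out.loc[mask, "p_perm"].to_numpy())
    return out


def demographics_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Case-control demographic tests: chi-square for sex, pooled t for
    age and education."""
    pat = metadata[metadata["group"] == "patient"]
    con = metadata[metadata["group"] == "control"]
    rows = []
    if "sex" in metadata.columns and metadata["sex"].nunique() == 2:
        tab = [
            [int((g["sex"] == s).sum()) for s in sorted(metadata["sex"].unique())]
            for g in (pat, con)
        ]
        stat, p = chi_square_2x2(tab)
        rows.append({"characteristic": "sex", "test": "chi_square",
                     "statistic": stat, "p": p})
    for col in ("age", "education"):
        if col in metadata.columns:
            stat, p = two_sample_t(pat[col], con[col])
            rows.append({"characteristic": col, "test": "two_sample_t",
                         "statistic": stat, "p": p})
    return pd.DataFrame(rows)
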