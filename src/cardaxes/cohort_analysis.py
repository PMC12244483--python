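"""Cohort-level statistics of axis metrics.

Covers the quality-control and inference machinery shared by the axis
analyses: the +/-3 SD z-score exclusion rule (meshes by sphericity index,
ECGs by per-lead QRS amplitude), mean-centred Levene variance tests,
Mann-Whitney U location tests, multivariable OLS with per-SD standardized
coefficients and VIF collinearity checks, confounder residualisation, and
Bonferroni-controlled univariate association scans of axis metrics against
many phenotype columns.

Missing values are handled by listwise deletion per analysis, never imputed;
each report records the n actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from cardaxes.errors import UsageError


def bsa_du_bois(height_cm: np.ndarray, weight_kg: np.ndarray) -> np.ndarray:
    """Body surface area (m^2), Du Bois & Du Bois formula."""
    return 0.007184 * np.asarray(height_cm, float) ** 0.725 * np.asarray(
        weight_kg, float
    ) ** 0.425


def zscore_qc_mask(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Inclusion mask: |v - mean| <= k * SD over the finite values.

    The population mean/SD are computed from the finite entries only;
    non-finite entries are excluded. With zero spread everything finite is
    included. This single rule backs mesh sphericity QC, per-lead QRS
    amplitude QC (a subject fails if any lead fails) and generic metric
    outlier removal.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise UsageError("values must be 1D")
    finite = np.isfinite(v)
    if finite.sum() < 10:
        raise UsageError("need at least 10 finite values for a population rule")
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    if sd == 0:
        return finite.copy()
    return finite & (np.abs(v - mean) <= k * sd)


def qrs_amplitude_qc(amplitudes: pd.DataFrame, k: float = 3.0) -> pd.Series:
    """Per-subject inclusion from a subjects x leads amplitude table:
    a subject is excluded if any lead amplitude fails the +/- k SD rule."""
    masks = {lead: zscore_qc_mask(amplitudes[lead].to_numpy(), k) for lead in amplitudes}
    include = np.logical_and.reduce(list(masks.values()))
    return pd.Series(include, index=amplitudes.index, name="include")


def variance_homogeneity(*groups: Sequence[float]) -> tuple[float, float]:
    """Levene's test with mean centring (the classical, not Brown-Forsythe,
    variant). Returns (statistic, p)."""
    if len(groups) < 2:
        raise UsageError("need at least two groups")
    clean = [np.asarray(g, dtype=float) for g in groups]
    for g in clean:
        if len(g) < 2:
            raise UsageError("each group needs at least 2 values")
    if all(np.ptp(g) == 0 for g in clean) and len({g[0] for g in clean}) == 1:
        return 0.0, float("nan")  # all-constant input: p undefined
    stat, p = st.levene(*clean, center="mean")
    return float(stat), float(p)


def location_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact permutation null when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction
    (no continuity correction, so identical samples give p = 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise UsageError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    exact_ok = len(combined) <= 20 and len(np.unique(combined)) == len(combined)
    if exact_ok:
        res = st.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = st.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class RegressionReport:
    """Standardized multivariable OLS summary."""

    response: str
    n_used: int
    r_squared: float
    coefficients: pd.DataFrame  # index = predictor; beta_std, ci_low, ci_high, p, vif
    binary_predictors: list[str] = field(default_factory=list)


def standardized_regression(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    binary: Iterable[str] = ("sex",),
) -> RegressionReport:
    """OLS of a response (native scale, e.g. degrees) on scale-free predictors.

    Continuous predictors are divided by their SD so each coefficient reads
    "change in response per SD of predictor", enabling direct comparison of
    effect strengths. Binary predictors (by default ``sex``, coded
    0 = female / 1 = male) are left unscaled so their coefficient reads
    "male compared to female". Rows with any missing value are dropped
    (listwise deletion); VIFs come from auxiliary regressions on the design.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise UsageError(f"table missing columns {missing_cols}")
    data = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(data) <= len(predictors) + 1:
        raise UsageError("not enough complete rows for the regression")

    binary = [b for b in binary if b in predictors]
    X = pd.DataFrame(index=data.index)
    for p in predictors:
        col = data[p].to_numpy(dtype=float)
        if p in binary:
            X[p] = col
        else:
            sd = col.std(ddof=1)
            if sd == 0:
                raise UsageError(f"predictor {p!r} is constant")
            X[p] = col / sd
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise UsageError(
            f"singular design: predictors {predictors} are perfectly collinear"
        )
    fit = sm.OLS(data[response].to_numpy(dtype=float), design).fit()

    conf = fit.conf_int(alpha=0.05)
    Xmat = design.to_numpy()
    rows = {}
    for j, p in enumerate(design.columns):
        if p == "const":
            continue
        rows[p] = {
            "beta_std": fit.params[p],
            "ci_low": conf.loc[p, 0],
            "ci_high": conf.loc[p, 1],
            "p_value": fit.pvalues[p],
            "vif": variance_inflation_factor(Xmat, j),
        }
    return RegressionReport(
        response=response,
        n_used=len(data),
        r_squared=float(fit.rsquared),
        coefficients=pd.DataFrame(rows).T,
        binary_predictors=binary,
    )


def deconfound(
    columns: pd.DataFrame,
    confounders: pd.DataFrame,
    interaction: tuple[str, str] | None = ("sex", "age"),
) -> pd.DataFrame:
    """Residualise each column against the confounder design (with intercept).

    The default design is age, sex, sex*age, height, weight - the
    ``interaction`` pair adds its product column if both factors are
    present. Residuals are exactly orthogonal to every confounder. Constant
    columns come back as zeros.
    """
    idx = columns.index.intersection(confounders.index)
    Y = columns.loc[idx].to_numpy(dtype=float)
    C = confounders.loc[idx].copy()
    if interaction is not None and all(f in C.columns for f in interaction):
        a, b = interaction
        C[f"{a}_x_{b}"] = C[a] * C[b]
    design = sm.add_constant(C.to_numpy(dtype=float), has_constant="add")
    if not np.all(np.isfinite(design)):
        raise UsageError("confounder columns must be complete for included rows")
    beta, *_ = np.linalg.lstsq(design, np.where(np.isfinite(Y), Y, 0.0), rcond=None)
    resid = Y - design @ beta
    # restore NaNs from the input and zero out constant columns
    resid[~np.isfinite(Y)] = np.nan
    const = np.nanstd(Y, axis=0) == 0
    resid[:, const] = 0.0
    return pd.DataFrame(resid, index=idx, columns=columns.columns)


def clean_phenotypes(
    phenotypes: pd.DataFrame,
    modal_fraction: float = 0.95,
    dedup_r: float = 0.9999,
) -> pd.DataFrame:
    """Apply the two scan pre-cleaning rules.

    Drops a column when its modal value covers >= ``modal_fraction`` of its
    non-missing rows (near-constant, uninformative), then greedily removes
    near-duplicate columns with |r| > ``dedup_r``, keeping the first.
    """
    keep = []
    for c in phenotypes.columns:
        col = phenotypes[c].dropna()
        if len(col) == 0:
            continue
        if col.value_counts().iloc[0] / len(col) >= modal_fraction:
            continue
        keep.append(c)
    pruned = phenotypes[keep]
    if len(keep) > 1:
        corr = pruned.corr().abs().to_numpy()
        drop = set()
        for i in range(len(keep)):
            if i in drop:
                continue
            for j in range(i + 1, len(keep)):
                if j not in drop and corr[i, j] > dedup_r:
                    drop.add(j)
        pruned = pruned[[c for k, c in enumerate(keep) if k not in drop]]
    return pruned


def association_scan(
    metrics: pd.DataFrame,
    phenotypes: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.05,
    min_n: int = 10,
) -> pd.DataFrame:
    """Univariate correlation scan with Bonferroni family-wise control.

    ``metrics`` are the deconfounded axis columns; ``phenotypes`` should be
    pre-cleaned with :func:`clean_phenotypes`. Each (metric, phenotype)
    pair is tested on its pairwise-complete rows; pairs with fewer than
    ``min_n`` complete rows or zero variance are flagged as untestable
    (NaN p) rather than silently returned. The significance threshold is
    alpha / (n_metrics * n_phenotypes).
    """
    if method not in ("pearson", "spearman"):
        raise UsageError(f"unknown correlation method {method!r}")
    idx = metrics.index.intersection(phenotypes.index)
    n_tests = metrics.shape[1] * phenotypes.shape[1]
    if n_tests == 0:
        raise UsageError("nothing to test")
    threshold = alpha / n_tests
    rows = []
    for m in metrics.columns:
        mv = metrics.loc[idx, m].to_numpy(dtype=float)
        for p in phenotypes.columns:
            pv = phenotypes.loc[idx, p].to_numpy(dtype=float)
            ok = np.isfinite(mv) & np.isfinite(pv)
            n = int(ok.sum())
            if n < min_n or np.std(mv[ok]) == 0 or np.std(pv[ok]) == 0:
                rows.append((m, p, np.nan, np.nan, n, False, False))
                continue
            if method == "pearson":
                r, pval = st.pearsonr(mv[ok], pv[ok])
            else:
                r, pval = st.spearmanr(mv[ok], pv[ok])
            rows.append((m, p, float(r), float(pval), n, pval < threshold, True))
    out = pd.DataFrame(
        rows, columns=["metric", "phenotype", "r", "p", "n", "significant", "testable"]
    )
    out.attrs.update(
        {
            "n_tests": n_tests,
            "bonferroni_threshold": threshold,
            "n_significant": int(out["significant"].sum()),
        }
    )
    return out
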