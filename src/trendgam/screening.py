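"""Global-overview statistics: autoscaled PCA, Pearson correlations and the
per-timepoint t-test comparator with Benjamini-Hochberg FDR control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def pivot_wide(data: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long time-course table to samples x metabolites.

    Rows are indexed by (day, replicate, group); any missing cell after the
    pivot is an error (the screening statistics need a complete matrix).
    """
    wide = data.pivot_table(
        index=["day", "replicate", "group"],
        columns="metabolite",
        values="concentration",
        aggfunc="first",
    )
    if wide.isna().any().any():
        missing = [
            (idx, col)
            for col in wide.columns
            for idx in wide.index[wide[col].isna()]
        ]
        raise ValueError(f"missing cells after pivot (first 10): {missing[:10]}")
    wide.columns.name = None
    return wide


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-center and scale every column to unit variance (ddof=1)."""
    sd = matrix.std(axis=0, ddof=1)
    zero = sd.index[(sd == 0) | sd.isna()].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class PCAResult:
    scores: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)
    variance_explained: np.ndarray  # percent, all components, sums to 100

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of an autoscaled matrix via SVD.

    ``variance_explained`` covers all ``min(n-1, p)``-rank components (it
    sums to 100) even when only the first ``n_components`` score/loading
    columns are returned.  Loading signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    rank = min(n, p)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds min(dims)={rank}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # reproducible orientation: largest-|loading| entry positive per component
    for i in range(rank):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    varexp = 100.0 * s**2 / (s**2).sum()
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=matrix.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=matrix.columns, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=varexp)


def correlation_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every column pair with two-sided p-values.

    p-values come from the t transform ``t = r sqrt((n-2)/(1-r^2))``.
    Constant columns produce NaN correlations (flagged by the caller's NaN
    check) rather than an error.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("correlation needs at least 3 rows")
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = X - X.mean(axis=0)
        cov = (Xc.T @ Xc) / (n - 1)
        r = cov / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    # |r| == 1 gives tstat = +/-inf and hence p = 0; NaN r propagates to NaN p
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pvals, 0.0)
    cols = matrix.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(pvals, index=cols, columns=cols),
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def pointwise_tests(
    data: pd.DataFrame, metabolite: str, alpha: float = 0.01
) -> pd.DataFrame:
    """Welch two-sample t-test of treated vs control at each day, with BH-FDR
    adjustment across days.

    Days where either group has fewer than 2 replicates get NaN p-values and
    are excluded from the adjustment.  ``significant`` flags adjusted
    p < ``alpha``.
    """
    sub = data.loc[data["metabolite"] == metabolite]
    if sub.empty:
        raise ValueError(f"no observations for metabolite '{metabolite}'")
    rows = []
    for day, grp in sub.groupby("day", sort=True):
        a = grp.loc[grp["group"] == "control", "concentration"].to_numpy(dtype=float)
        b = grp.loc[grp["group"] == "treated", "concentration"].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append({"day": day, "n_control": a.size, "n_treated": b.size,
                         "t_statistic": np.nan, "p_raw": np.nan})
            continue
        if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(b, a, equal_var=False)
            if np.isnan(p):  # zero variance in both groups, equal means
                t, p = 0.0, 1.0
        rows.append({"day": day, "n_control": a.size, "n_treated": b.size,
                     "t_statistic": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    table.loc[table["p_adjusted"].isna(), "significant"] = False
    return table


@dataclass
class ComparisonReport:
    """Joint per-timepoint vs trend-model report for one metabolite."""

    metabolite: str
    trend_fit: object = field(repr=False)  # TrendFit
    pointwise: pd.DataFrame = field(repr=False)
    pointwise_significant_days: list[float]
    band_excludes_zero_days: list[float]

    @property
    def n_pointwise_significant(self) -> int:
        return len(self.pointwise_significant_days)

    @property
    def n_band_excludes_zero(self) -> int:
        return len(self.band_excludes_zero_days)


def compare_gam_vs_pointwise(
    data: pd.DataFrame,
    metabolite: str,
    k: int = 10,
    family: str = "gamma-log",
    alpha: float = 0.01,
    elicitation_day: float | None = None,
) -> ComparisonReport:
    """Contrast the per-day t-test verdicts with the differential-smoother
    band of the trend model.

    A day 'detected' by the trend model is a treated-range observed day where
    the differential smoother's 95% band excludes zero.
    """
    from trendgam.trend import fit_trend_model
    from trendgam.gam import confidence_band

    tf = fit_trend_model(
        data, metabolite, k=k, family=family, elicitation_day=elicitation_day
    )
    table = pointwise_tests(data, metabolite, alpha=alpha)
    days = np.unique(
        data.loc[
            (data["metabolite"] == metabolite) & (data["group"] == "treated"), "day"
        ].to_numpy(dtype=float)
    )
    band = confidence_band(tf.fit, "s_diff", days)
    excludes = (band["lower"] > 0) | (band["upper"] < 0)
    return ComparisonReport(
        metabolite=metabolite,
        trend_fit=tf,
        pointwise=table,
        pointwise_significant_days=table.loc[table["significant"], "day"].tolist(),
        band_excludes_zero_days=days[excludes].tolist(),
    )
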