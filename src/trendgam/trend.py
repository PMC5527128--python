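"""Common + treatment-differential trend models for one response series.

The model for a metabolite concentration over time is

    response ~ treatment_shift + s_common(day) + 1[treated] * s_diff(day)

where both smooths are sum-to-zero centered (the common smooth over all
observations, the differential smooth over treated observations only, so that
a constant treatment effect is absorbed by the shift factor and the
differential smoother captures a genuine trend difference).  Ratios of two
metabolites are modeled with the same structure on the per-observation ratio
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trendgam import gam
from trendgam.splines import apply_centering, build_cr_basis

MIN_DISTINCT_DAYS = 10
SUITABILITY_MESSAGE = (
    "trend models need a dense time course: at least "
    f"{MIN_DISTINCT_DAYS} distinct sampling days are required"
)

FAMILIES = ("gamma-log", "gaussian-log-transformed")


@dataclass
class SmootherSummary:
    """Summary of one smooth term: complexity, significance and band."""

    edf: float
    p_value: float
    statistic: float
    rank: int
    band: pd.DataFrame = field(repr=False)


@dataclass
class TrendFit:
    """Result of the three-term trend model for one response."""

    response: str
    family: str
    treatment_coef: float
    treatment_se: float
    intercept: float
    common: SmootherSummary
    differential: SmootherSummary
    diagnostics: dict = field(repr=False)
    elicitation_day: float | None
    fit: gam.FittedGAM = field(repr=False)
    n_obs: int = 0

    def summary_row(self) -> dict:
        return {
            "response": self.response,
            "family": self.family,
            "n_obs": self.n_obs,
            "intercept": self.intercept,
            "treatment_coef": self.treatment_coef,
            "treatment_se": self.treatment_se,
            "common_edf": self.common.edf,
            "common_p": self.common.p_value,
            "diff_edf": self.differential.edf,
            "diff_p": self.differential.p_value,
            "dispersion": self.fit.dispersion,
            "converged": self.fit.converged,
        }


def _band_frame(band: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": band["grid"],
            "estimate": band["estimate"],
            "se": band["se"],
            "lower": band["lower"],
            "upper": band["upper"],
            "extrapolated": band["extrapolated"],
        }
    )


def _validate_subset(sub: pd.DataFrame, label: str, family: str) -> None:
    if sub.empty:
        raise ValueError(f"no observations for response '{label}'")
    groups = set(sub["group"].unique())
    missing = {"control", "treated"} - groups
    if missing:
        raise ValueError(f"response '{label}': group(s) {sorted(missing)} absent")
    if sub["day"].nunique() < MIN_DISTINCT_DAYS:
        raise ValueError(f"response '{label}': {SUITABILITY_MESSAGE}")
    if family == "gamma-log":
        bad = sub.index[sub["concentration"] <= 0].tolist()
        if bad:
            raise ValueError(
                f"response '{label}': gamma family needs positive concentrations; "
                f"offending rows {bad[:20]}"
            )


def fit_trend_model(
    data: pd.DataFrame,
    metabolite: str,
    k: int = 10,
    family: str = "gamma-log",
    elicitation_day: float | None = None,
    grid_size: int = 100,
) -> TrendFit:
    """Fit the three-term trend model for one metabolite.

    Parameters
    ----------
    data
        Long-format table with columns metabolite, day, replicate, group,
        concentration; ``group`` must take values 'control' and 'treated'.
    k
        Basis dimension shared by the common and differential smoothers.
    family
        'gamma-log' fits the concentrations with a Gamma/log GAM;
        'gaussian-log-transformed' fits a Gaussian/identity GAM to the
        log-concentrations.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got '{family}'")
    sub = data.loc[data["metabolite"] == metabolite].copy()
    _validate_subset(sub, metabolite, family)
    sub = sub.sort_values(["group", "replicate", "day"], kind="mergesort").reset_index(drop=True)
    days = sub["day"].to_numpy(dtype=float)
    treated = (sub["group"] == "treated").to_numpy().astype(float)
    y = sub["concentration"].to_numpy(dtype=float)
    if family == "gaussian-log-transformed":
        if np.any(y <= 0):
            raise ValueError(
                f"response '{metabolite}': log transform needs positive concentrations"
            )
        y = np.log(y)
        fam, link = "gaussian", "identity"
    else:
        fam, link = "gamma", "log"

    common_basis = apply_centering(build_cr_basis(days, k), days)
    treated_days = days[treated == 1]
    diff_basis = apply_centering(build_cr_basis(treated_days, k), treated_days)

    spec = gam.ModelSpec(
        parametric_terms=(
            gam.ParametricTerm("intercept", np.ones_like(days)),
            gam.ParametricTerm("treatment", treated),
        ),
        smooth_terms=(
            gam.SmoothTerm("s_common", common_basis, days),
            gam.SmoothTerm("s_diff", diff_basis, days, by=treated),
        ),
        family=fam,
        link=link,
    )
    fit = gam.optimize_reml(spec, y)

    grid_all = np.linspace(days.min(), days.max(), grid_size)
    grid_trt = np.linspace(treated_days.min(), treated_days.max(), grid_size)
    common = SmootherSummary(
        edf=fit.edf["s_common"],
        band=_band_frame(gam.confidence_band(fit, "s_common", grid_all)),
        **_test_fields(gam.approx_pvalue(fit, "s_common")),
    )
    differential = SmootherSummary(
        edf=fit.edf["s_diff"],
        band=_band_frame(gam.confidence_band(fit, "s_diff", grid_trt)),
        **_test_fields(gam.approx_pvalue(fit, "s_diff")),
    )
    i_trt = fit.term_slice("treatment").start
    return TrendFit(
        response=metabolite,
        family=family,
        treatment_coef=float(fit.coefficients[i_trt]),
        treatment_se=float(np.sqrt(fit.covariance[i_trt, i_trt])),
        intercept=float(fit.coefficients[fit.term_slice("intercept").start]),
        common=common,
        differential=differential,
        diagnostics=_diag_summary(fit),
        elicitation_day=elicitation_day,
        fit=fit,
        n_obs=int(y.size),
    )


def _test_fields(test: dict) -> dict:
    return {"p_value": test["p_value"], "statistic": test["statistic"], "rank": test["rank"]}


def _diag_summary(fit: gam.FittedGAM) -> dict:
    d = gam.residual_diagnostics(fit)
    return {
        "qq_correlation": d["qq_correlation"],
        "hetero_slope": d["hetero_slope"],
        "hetero_slope_p": d["hetero_slope_p"],
        "deviance": fit.deviance,
        "dispersion": fit.dispersion,
        "lambda_at_bound": fit.lambda_at_bound,
    }


def fit_ratio_model(
    data: pd.DataFrame,
    numerator: str,
    denominator: str,
    k: int = 10,
    family: str = "gamma-log",
    elicitation_day: float | None = None,
    grid_size: int = 100,
) -> TrendFit:
    """Fit the trend model to the per-observation ratio of two metabolites.

    Observations are matched on (day, replicate, group); unmatched rows or
    zero denominators are rejected.
    """
    keys = ["day", "replicate", "group"]
    num = data.loc[data["metabolite"] == numerator, keys + ["concentration"]]
    den = data.loc[data["metabolite"] == denominator, keys + ["concentration"]]
    if num.empty or den.empty:
        raise ValueError(f"missing observations for '{numerator}' or '{denominator}'")
    merged = num.merge(den, on=keys, how="outer", suffixes=("_num", "_den"), indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", keys]
    if len(unmatched):
        raise ValueError(
            f"unmatched observations between '{numerator}' and '{denominator}': "
            f"{unmatched.head(20).to_dict('records')}"
        )
    if np.any(merged["concentration_den"].to_numpy() == 0):
        raise ValueError(f"zero denominator concentrations for '{denominator}'")
    label = f"{numerator}/{denominator}"
    ratio = merged.assign(
        metabolite=label,
        concentration=merged["concentration_num"] / merged["concentration_den"],
    )[["metabolite"] + keys + ["concentration"]]
    return fit_trend_model(
        ratio, label, k=k, family=family, elicitation_day=elicitation_day, grid_size=grid_size
    )


def fit_all(
    data: pd.DataFrame,
    responses: list[str] | None = None,
    ratios: list[tuple[str, str]] | None = None,
    k: int = 10,
    family: str = "gamma-log",
    elicitation_day: float | None = None,
) -> tuple[pd.DataFrame, dict[str, TrendFit]]:
    """Fit the trend model for every response and ratio pair.

    Returns a summary table (one row per response/ratio; failures recorded in
    the ``message`` column rather than raised) and the per-response fits.
    No multiplicity adjustment is applied across responses.
    """
    if responses is None:
        responses = sorted(data["metabolite"].unique())
    ratios = ratios or []
    rows, fits = [], {}
    jobs: list[tuple[str, tuple]] = [("metabolite", (r,)) for r in responses]
    jobs += [("ratio", pair) for pair in ratios]
    for kind, args in jobs:
        label = args[0] if kind == "metabolite" else f"{args[0]}/{args[1]}"
        try:
            if kind == "metabolite":
                tf = fit_trend_model(
                    data, args[0], k=k, family=family, elicitation_day=elicitation_day
                )
            else:
                tf = fit_ratio_model(
                    data, args[0], args[1], k=k, family=family, elicitation_day=elicitation_day
                )
            fits[label] = tf
            rows.append({**tf.summary_row(), "kind": kind, "message": ""})
        except Exception as e:  # per-row failure is recorded, not fatal
            rows.append(
                {
                    "response": label,
                    "kind": kind,
                    "family": family,
                    "converged": False,
                    "message": str(e),
                }
            )
    columns = [
        "response",
        "kind",
        "family",
        "n_obs",
        "intercept",
        "treatment_coef",
        "treatment_se",
        "common_edf",
        "common_p",
        "diff_edf",
        "diff_p",
        "dispersion",
        "converged",
        "message",
    ]
    table = pd.DataFrame(rows).reindex(columns=columns)
    return table, fits
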