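"""Synthetic time-course generator emulating a two-group elicitation design.

Generates positive concentrations for a roster of metabolites (default: five
aglycones x three glycoside modifications, two correlated pathway branches)
over a daily sampling grid, with smooth baseline trends, a multiplicative
treatment fold-change curve that is exactly 1 before the onset day, Gamma
noise at constant coefficient of variation, and an optional shared
replicate-level branch factor inducing within-branch correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

AGLYCONES = ("Dp", "Cy", "Pt", "Pn", "Mv")
MODIFICATIONS = ("glu", "ac-glu", "pc-glu")
BRANCH_OF = {"Dp": "delphinidin", "Pt": "delphinidin", "Mv": "delphinidin",
             "Cy": "cyanidin", "Pn": "cyanidin"}
DEFAULT_FOLD = {"delphinidin": 3.0, "cyanidin": 1.63}

TREND_SHAPES = ("logistic-growth", "flat", "linear")


@dataclass(frozen=True)
class TrendShape:
    """Baseline mean trend of one metabolite.

    ``logistic-growth``: baseline + asymptote / (1 + exp(-rate (t - midpoint)))
    ``linear``: baseline + rate * t; ``flat``: baseline.
    All parameter choices must keep the mean strictly positive over the
    sampling days.
    """

    kind: str = "logistic-growth"
    baseline: float = 5.0
    asymptote: float = 50.0
    rate: float = 0.6
    midpoint: float = 7.0

    def __post_init__(self):
        if self.kind not in TREND_SHAPES:
            raise ValueError(f"unknown trend shape '{self.kind}'")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "flat":
            return np.full_like(t, self.baseline)
        if self.kind == "linear":
            return self.baseline + self.rate * t
        return self.baseline + self.asymptote / (1.0 + np.exp(-self.rate * (t - self.midpoint)))


def fold_curve(t: np.ndarray, fold: float, onset_day: float, plateau_day: float) -> np.ndarray:
    """Smooth multiplicative treatment effect: exactly 1 for t <= onset_day,
    rising along a smoothstep to ``fold`` at ``plateau_day`` and beyond."""
    t = np.asarray(t, dtype=float)
    if plateau_day <= onset_day:
        raise ValueError("plateau_day must exceed onset_day")
    u = np.clip((t - onset_day) / (plateau_day - onset_day), 0.0, 1.0)
    s = u * u * (3.0 - 2.0 * u)
    return fold**s


@dataclass(frozen=True)
class MetaboliteSpec:
    name: str
    branch: str
    trend: TrendShape
    fold: float = 1.0  # plateau treatment fold-change (1 = no effect)


def _default_roster() -> tuple[MetaboliteSpec, ...]:
    """Fifteen metabolites; branch glucosides and p-coumaroyl derivatives get
    the branch fold (3.0 delphinidin, 1.63 cyanidin), acetyl derivatives none."""
    # staggered baselines/asymptotes so the roster is not degenerate
    scale = {"Dp": 30.0, "Cy": 60.0, "Pt": 10.0, "Pn": 80.0, "Mv": 8.0}
    mod_scale = {"glu": 1.0, "ac-glu": 0.3, "pc-glu": 1.6}
    mod_rate = {"glu": 0.6, "ac-glu": 0.5, "pc-glu": 0.7}
    roster = []
    for ag in AGLYCONES:
        for mod in MODIFICATIONS:
            name = f"{ag}-{mod}"
            branch = BRANCH_OF[ag]
            fold = 1.0 if mod == "ac-glu" else DEFAULT_FOLD[branch]
            trend = TrendShape(
                kind="logistic-growth",
                baseline=2.0 * mod_scale[mod],
                asymptote=scale[ag] * mod_scale[mod],
                rate=mod_rate[mod],
                midpoint=7.0 if branch == "delphinidin" else 5.0,
            )
            roster.append(MetaboliteSpec(name=name, branch=branch, trend=trend, fold=fold))
    return tuple(roster)


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and noise parameters of the simulated study."""

    days: tuple[float, ...] = tuple(float(d) for d in range(1, 21))
    elicitation_day: float = 5.0
    replicates: int = 3
    metabolites: tuple[MetaboliteSpec, ...] = field(default_factory=_default_roster)
    onset_day: float = 9.0
    plateau_day: float = 13.0
    noise_cv: float = 0.10
    noise: str = "gamma"  # or "lognormal"
    branch_sd: float = 0.0  # s.d. of the shared log-normal replicate-level branch factor
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        if self.noise not in ("gamma", "lognormal"):
            raise ValueError("noise must be 'gamma' or 'lognormal'")
        if self.branch_sd < 0:
            raise ValueError("branch_sd must be >= 0")
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")


def default_config(**overrides) -> SyntheticConfig:
    """The study-design default: 20 daily samples, 3 replicates per group,
    15 metabolites in two branches, elicitation at day 5, CV 10% Gamma noise,
    within-branch replicate correlation."""
    params = {"branch_sd": 0.15, "seed": 0}
    params.update(overrides)
    return SyntheticConfig(**params)


def _draw_noisy(rng: np.random.Generator, mean: np.ndarray, cv: float, kind: str) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("trend produced non-positive means; check shape parameters")
    if kind == "gamma":
        shape = 1.0 / cv**2
        return rng.gamma(shape=shape, scale=mean * cv**2)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return mean * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=mean.shape)


def simulate_timecourse(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the long-format dataset implied by ``config``.

    The mean of each cell is ``baseline(day) * fold_curve(day)^{1[treated]} *
    branch_factor(group, replicate, branch)``; noise is Gamma (or lognormal)
    at the configured CV.  Deterministic given (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    groups = ("control", "treated")
    branches = sorted({m.branch for m in config.metabolites})
    # one shared multiplicative factor per (group, replicate, branch)
    factors = {}
    for g in groups:
        for rep in range(1, config.replicates + 1):
            for br in branches:
                factors[(g, rep, br)] = (
                    float(rng.lognormal(mean=-0.5 * config.branch_sd**2, sigma=config.branch_sd))
                    if config.branch_sd > 0
                    else 1.0
                )
    records = []
    for m in config.metabolites:
        base = m.trend(days)
        fc = fold_curve(days, m.fold, config.onset_day, config.plateau_day)
        for g in groups:
            treated = g == "treated"
            for rep in range(1, config.replicates + 1):
                mean = base * (fc if treated else 1.0) * factors[(g, rep, m.branch)]
                conc = _draw_noisy(rng, mean, config.noise_cv, config.noise)
                for d, c in zip(days, conc):
                    records.append(
                        {
                            "metabolite": m.name,
                            "day": float(d),
                            "replicate": f"R{rep}",
                            "group": g,
                            "concentration": float(c),
                        }
                    )
    return pd.DataFrame.from_records(records)


def simulate_for_recovery(
    g: Callable[[np.ndarray], np.ndarray],
    d: Callable[[np.ndarray], np.ndarray] | None = None,
    days: np.ndarray | None = None,
    replicates: int = 3,
    intercept: float = 2.0,
    treatment_shift: float = 0.0,
    noise_cv: float = 0.10,
    noise: str = "gamma",
    seed: int = 0,
    metabolite: str = "synthetic",
) -> tuple[pd.DataFrame, dict]:
    """Generate data whose log-mean is exactly the trend-model structure.

    log mean = intercept + treatment_shift * 1[treated] + g(day)
               + d(day) * 1[treated]

    Returns the long-format dataset and a truth record holding the evaluated
    g / d on the design days (useful for parameter-recovery checks).
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(days if days is not None else np.arange(1.0, 21.0), dtype=float)
    g_vals = np.asarray(g(days), dtype=float)
    d_vals = np.asarray(d(days), dtype=float) if d is not None else np.zeros_like(days)
    if not (np.all(np.isfinite(g_vals)) and np.all(np.isfinite(d_vals))):
        raise ValueError("trend functions must be finite on the design days")
    records = []
    for grp, treated in (("control", 0.0), ("treated", 1.0)):
        log_mean = intercept + treatment_shift * treated + g_vals + d_vals * treated
        mean = np.exp(log_mean)
        for rep in range(1, replicates + 1):
            conc = _draw_noisy(rng, mean, noise_cv, noise)
            for day, c in zip(days, conc):
                records.append(
                    {
                        "metabolite": metabolite,
                        "day": float(day),
                        "replicate": f"R{rep}",
                        "group": grp,
                        "concentration": float(c),
                    }
                )
    truth = {
        "days": days,
        "g": g_vals,
        "d": d_vals,
        "intercept": intercept,
        "treatment_shift": treatment_shift,
        "noise_cv": noise_cv,
    }
    return pd.DataFrame.from_records(records), truth


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON/YAML-serializable form of a config (inverse of config_from_dict)."""
    out = asdict(config)
    out["days"] = list(config.days)
    out["metabolites"] = [
        {**asdict(m), "trend": asdict(m.trend)} for m in config.metabolites
    ]
    return out


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "metabolites" in d:
        mets = []
        for m in d["metabolites"]:
            m = dict(m)
            trend = m.pop("trend", {})
            mets.append(MetaboliteSpec(trend=TrendShape(**trend), **m))
        d["metabolites"] = tuple(mets)
    if "days" in d:
        d["days"] = tuple(float(x) for x in d["days"])
    return SyntheticConfig(**d)
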