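import numpy as np
import pandas as pd
import pytest

from trendgam import gam, splines, synthetic


@pytest.fixture(scope="session")
def daily_design():
    """Paper-style design days: 1..20 daily, 3 replicates per group."""
    return np.repeat(np.arange(1.0, 21.0), 3)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated default-design dataset (15 metabolites, 1800 rows)."""
    return synthetic.simulate_timecourse(synthetic.default_config(seed=11))


@pytest.fixture
def gaussian_smooth_model():
    """Factory: (spec, y, X, S, basis) for a 1-smooth Gaussian model."""

    def make(seed=0, n=60, k=8, noise=0.4, tmax=10.0):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0.0, tmax, n))
        t[: k + 2] = np.linspace(0.0, tmax, k + 2)  # guarantee k distinct values
        t = np.sort(t)
        basis = splines.apply_centering(splines.build_cr_basis(t, k), t)
        y = np.sin(t * rng.uniform(0.4, 1.2)) * rng.uniform(0.5, 2.0) + 0.2 * t
        y = rng.normal(y, noise)
        spec = gam.ModelSpec(
            parametric_terms=(gam.ParametricTerm("intercept", np.ones_like(t)),),
            smooth_terms=(gam.SmoothTerm("s", basis, t),),
            family="gaussian",
            link="identity",
        )
        X = np.column_stack([np.ones_like(t), basis.evaluate(t)])
        return spec, y, X, basis.penalty, basis

    return make


def recovery(g, d=None, seed=0, **kw):
    """Shorthand for the log-scale truth simulator."""
    return synthetic.simulate_for_recovery(g, d, seed=seed, **kw)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small handmade long table for io tests."""
    rows = []
    for m in ("A", "B"):
        for day in (1.0, 2.0, 3.0):
            for rep in ("R1", "R2"):
                for grp in ("control", "treated"):
                    rows.append(
                        {
                            "metabolite": m,
                            "day": day,
                            "replicate": rep,
                            "group": grp,
                            "concentration": 1.0 + day + (0.5 if m == "B" else 0.0),
                        }
                    )
    return pd.DataFrame(rows)
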