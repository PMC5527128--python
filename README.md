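# trendgam

Trend-level statistical analysis of time-course metabolomics data.

Instead of testing treatment effects day by day, `trendgam` models the whole
concentration *trend* of a metabolite with a penalized-spline generalized
additive model (GAM) containing three terms:

```
concentration(t) ~ treatment_shift + s_common(t) + 1[treated] * s_diff(t)
```

* `s_common(t)` — the time trend shared by control and treated cultures;
* `s_diff(t)` — the *additional* trend present only in treated samples (its
  significance measures a treatment-induced trend change);
* `treatment_shift` — a constant multiplicative offset (log link).

Models use cubic regression splines with exact second-derivative penalties,
Gamma/log or Gaussian/identity (on log data) families, and smoothing
parameters selected by REML. Each smooth is reported with its effective
degrees of freedom (e.d.f.; ≈1 means near-linear), an approximate Wald
p-value and a pointwise 95% credible band. The same machinery fits ratios of
two metabolites, which tests whether a treatment affects both in the same
way.

Also included:

* **Screening**: autoscaled PCA, Pearson correlation matrices with p-values,
  and the per-timepoint Welch t-test + Benjamini–Hochberg FDR comparator.
* **Synthetic data**: a generator emulating a two-group elicitation design
  (daily sampling, replicated, two correlated pathway branches, smooth
  positive trends, Gamma noise at constant CV) so the entire pipeline is
  testable without any external data.
* **Utilities**: tidy-CSV readers/writers with validation, and the
  absorbance-to-concentration conversion `A535 × dilution / ε`.

## CLI

```bash
# simulate the default design (15 metabolites, 20 days, 3 replicates/group)
trendgam simulate --seed 1 --out data.csv

# fit the trend model to every metabolite
trendgam fit --data data.csv --elicitation-day 5 --out-prefix results/fit
#   -> results/fit_summary.tsv  (one row per metabolite: e.d.f., p-values, shift)
#   -> results/fit_bands.tsv    (per-day band for both smoothers)
#   -> results/fit_fits.json    (machine-readable per-fit records)

# ratio of two metabolites
trendgam ratio --data data.csv --numerator Dp-pc-glu --denominator Dp-glu \
    --out-prefix results/ratio

# PCA + correlation screening
trendgam screen --data data.csv --out-prefix results/scr

# per-day t-tests (BH-FDR at 0.01) vs the GAM differential band
trendgam compare --data data.csv --metabolite Cy-glu --out-prefix results/cmp

# everything at once
trendgam report --data data.csv --out-prefix results/all
```

Input CSV columns: `metabolite, day, replicate, group, concentration`
(`group` ∈ {control, treated}; concentrations strictly positive). Other
column names can be remapped with `--column-map mapping.yaml`, e.g.
`{metabolite: compound, day: t}`. Exit codes: 0 success, 2 bad
input/config, 3 model failure.

Outputs are deterministic: fixed column order, floats at 6 significant
digits, JSON with sorted keys — reruns with the same seed are
byte-identical.

### JSON fit record schema

`*_fits.json` maps each response label to an object with keys:
`response, family, n_obs, intercept, treatment_coef, treatment_se,
elicitation_day, common {edf, p_value, statistic, rank},
differential {edf, p_value, statistic, rank}, diagnostics {qq_correlation,
hetero_slope, hetero_slope_p, deviance, dispersion, lambda_at_bound},
smoothing_parameters, total_edf, deviance`.

## Python API sketch

```python
from trendgam import synthetic, trend, screening

data = synthetic.simulate_timecourse(synthetic.default_config(seed=1))
tf = trend.fit_trend_model(data, "Dp-glu", k=10, family="gamma-log")
print(tf.common.edf, tf.differential.p_value)
tf.differential.band          # day / estimate / se / lower / upper

report = screening.compare_gam_vs_pointwise(data, "Cy-glu", alpha=0.01)
report.n_pointwise_significant, report.n_band_excludes_zero
```

Band plots (common + differential panels with the elicitation-day marker)
are available via `trendgam.plotting.plot_trend_fit(tf, "fit.png")`.

## Notes on statistical conventions

* Smoothing selection: Laplace-approximate REML (exact for Gaussian;
  performance-iteration on the converged working model for Gamma).
* Posterior covariance: `V_beta = phi * (X'WX + S_lambda)^-1`; bands are
  `estimate ± 1.96 SE` on the link scale.
* Smooth-term p-values use a rank-`max(1, round(edf))` pseudo-inverse Wald
  statistic (chi-square for Gaussian, F for Gamma). These are approximate —
  treat borderline values with caution.
* Dispersion: Pearson estimator with `n − total e.d.f.` residual dof.
* No multiplicity adjustment is applied across metabolites in `fit_all`
  (BH-FDR applies across *days* within the pointwise comparator only).
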