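# naspatial

Disease mapping and neighbourhood-adjustment causal analysis for areal
count data.

`naspatial` is for epidemiologists and biostatisticians who work with
registry counts aggregated to administrative areas (municipalities,
counties) and want to estimate the effect of an area-level exposure —
here, physician density — on a disease outcome such as late-stage cancer
incidence, while defending against *unmeasured spatially structured
confounding*.

The package implements the full areal pipeline:

* **Indirect age-sex standardization** — pooled stratum rates
  `r_s = Σ C_is / Σ P_is` applied to each area's population structure
  give expected counts `E_i = Σ_s r_s P_is` and standardized incidence
  ratios `RR_i = Y_i / E_i`, plus quartile aggregation and stage-share
  descriptives.
* **BYM disease mapping** — the Besag–York–Mollié Poisson model
  `log μ_i = log E_i + β₀ + β_x X_i + γ'Z_i + φ_i + θ_i` with an
  intrinsic-CAR structured effect φ on the contiguity graph and an iid
  effect θ, fitted by Metropolis-within-Gibbs MCMC.
* **Neighbourhood-adjustment (NA) model** — a causal-inference method for
  spatial data: the unmeasured confounder U is modelled jointly with the
  exposure, `U | X ~ N(δ·S X, Q_U⁻¹)` with `S` the row-stochastic
  neighbourhood smoother and `Q_U` a proper-CAR precision, and imputed as
  missing data inside the Gibbs sampler.  The confounding bias
  `B(X) = δ·S X` is thereby attributed to δ instead of to β_x, de-biasing
  the exposure effect.
* **Posterior summaries** — mean coefficients, 95% equal-tailed credible
  intervals, percent change `(1−exp β)·100`, geometric-mean relative risk
  `exp(mean β)`, and the population-average exposure–response density.
* **A synthetic municipality generator** — contiguity graphs, stratified
  populations, a smooth exposure field, a coupled spatial confounder and
  Poisson counts, with the generating truth reported separately — so the
  whole pipeline is testable without access-restricted registry data.

See `docs/methods.md` for the models, their assumptions and the design
choices.

## Worked example

Simulate a confounded 150-area study (true exposure effect −0.03 on the
log scale, confounder coupling δ = 0.3) and compare the BYM and NA
estimates:

```python
import naspatial as ns

study = ns.generate_study(ns.GeneratorConfig(n_areas=150), seed=1)
print(ns.truth_report(study).beta_x)            # -0.03

bym = ns.fit_bym(study.areas, study.graph,
                 ns.BymSpec(iterations=3000, burn_in=600, seed=2))
na = ns.fit_na(study.areas, study.graph,
               ns.NaSpec(iterations=3000, burn_in=600, seed=3))
print(ns.summarize_effect(bym, "beta_x").rounded())
print(ns.summarize_effect(na, "beta_x").rounded())
print(ns.bias_gap(bym, na))
```

Output:

```
BYM {'mean': 0.051, 'ci_lower': -0.091, 'ci_upper': 0.192, 'percent_change': -5.3, 'rr': 1.05, ...}
NA  {'mean': -0.031, 'ci_lower': -0.141, 'ci_upper': 0.077, 'percent_change': 3.1, 'rr': 0.97, ...}
bias gap (BYM - NA): 0.083 +/- 0.008
```

Read: the confounder pushes the naive spatial estimate up to +0.051 (an
apparently *harmful* exposure, RR 1.05); the NA model attributes that
shared smooth variation to the confounder and recovers −0.031, within a
rounding step of the generating truth, i.e. a ~3% decrease in late-stage
risk per additional physician per 10,000 (RR 0.97).  The positive bias
gap is the signature of upward spatial confounding.  Descriptive quartile
aggregates on the same study illustrate why raw maps mislead here: the
aggregated RR *rises* with exposure quartile (1.36 → 1.67) even though
the true effect is protective.

The same pipeline is available from the shell:

```sh
naspatial simulate --seed 7 --out-dir study/
naspatial standardize --strata study/strata.csv --out standardized.csv
naspatial fit-bym --areas study/areas.csv --edges study/edges.txt --seed 2 --out bym.csv
naspatial fit-na  --areas study/areas.csv --edges study/edges.txt --seed 3 --out na.csv
naspatial summarize --draws na.csv --param beta_x --out summary.json
```

All commands are byte-reproducible given their seeds.

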