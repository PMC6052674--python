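# terrapath

Activity and movement analysis for biologging studies of free-ranging
ectotherms — built around the data streams a box-turtle field study
produces: tri-axial accelerometer bursts, hourly daytime GPS fixes,
fine-scale thread-trailing paths, internal body temperature, and
weather-station records.

The package is aimed at movement ecologists who need the full chain
from raw logger output to publishable summaries, with every stage
testable against synthetic data of known ground truth.

## What it computes

**ODBA.** Each 30-s burst of tri-axial acceleration is reduced to
overall dynamic body acceleration: per axis the static (gravitational)
component is removed by a running mean (full-burst mean by default),
and ODBA is the burst mean of |d_x| + |d_y| + |d_z|, in g.

**Active/inactive classification.** Per individual, the transformed
values x = ODBA^(−1/3) are modelled as a two-Gaussian mixture

    f(x) = π·N(x; μ_a, σ_a²) + (1−π)·N(x; μ_b, σ_b²),   μ_a < μ_b,

fitted by non-linear least squares against the empirical density.
Because the transform is decreasing, component *a* (low transformed
mean) is the *active*, high-ODBA state.  Each burst gets the posterior
probability of activity; hourly activity is the exact active fraction.

**Movement modes.** Steps (length, absolute turning angle in
[0°, 180°]) are clustered by k-means (k = 2) on standardised
(log length, angle).  The cluster with the larger mean turning angle is
labelled *extensive* (exploratory) and the other *intensive*
(foraging) — the operational convention of the field study this
package accompanies, which inverts much of the area-restricted-search
literature.  A subsampling utility reproduces the resolution bias:
the same path looks more "intensive" at hourly GPS resolution than at
thread-trailing resolution.

**Thermal performance curves.** Mean ODBA per 1 °C of body temperature
is fitted with candidate curves (constant, quadratic, Gaussian, skewed
Gaussian, cubic regression splines), ranked by small-sample-corrected
least-squares AIC; performance breadth is the temperature interval
where the winning curve stays above 80% of its maximum.

**Environmental models.** Random-intercept mixed models (individual as
the grouping factor) relate log hourly displacement and hourly ODBA to
ambient temperature, absolute humidity, cloud cover (ordinal 0–5),
precipitation, and time of day, with backward-stepwise deletion,
likelihood-ratio tests against the null, Wald CIs, and
marginal/conditional r² (variance of the fixed-effect predictor over
total variance, without and with the individual variance).  Hourly
activity proportions are fitted as a binomial random-intercept GLMM by
Gauss–Hermite quadrature maximum likelihood.

**Synthetic studies.** `terrapath.synth` generates complete studies
with known truth — mixture parameters, two-mode correlated-random-walk
paths, thermoconforming body temperature, weather with configurable
effect sizes — so every stage above can be validated end to end.

## Worked example

`examples/02_activity_classification.py` simulates 1000 bursts for one
individual, fits the mixture and classifies every burst:

```
fitted mixture (transformed scale), n=1000:
  active   component: mu_a=3.00  sigma_a=0.54
  inactive component: mu_b=7.10  sigma_b=0.82
  mixing weight (active) = 0.32, converged=True
label accuracy vs hidden truth: 99.8%
active ODBA range:   0.0106-0.3349 g
inactive ODBA range: 0.0010-0.0096 g
```

The fitted means/SDs sit on top of the generating values (3.0/0.5 and
7.0/0.8), 99.8% of bursts are labelled correctly, and the active and
inactive ODBA ranges are disjoint: the posterior rule induces a single
per-individual activity threshold near 0.01 g.

The other examples cover ODBA conversion (`01`), the
resolution-bias experiment (`03`, intensive share rising from 48% to
56% under hourly subsampling), thermal performance curves (`04`),
the environmental mixed models (`05`, backward deletion retaining
exactly the injected precipitation and time-of-day effects with
marginal r² ≈ 0.014 and conditional r² ≈ 0.102), and the full pipeline
on a written study bundle (`06`).

A thin CLI mirrors the pipeline for shell use:

```
terrapath simulate --out bundle/ --seed 1
terrapath validate bundle/
terrapath run-all bundle/ --out results/ --seed 1
```

## Layout

- `src/terrapath/` — `accel`, `activity`, `paths`, `geo`, `thermal`,
  `envstats`, `synth`, `studyio`, `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limits
- `tests/` — unit, property and end-to-end suites
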