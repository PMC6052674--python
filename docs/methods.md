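# Methods

This note documents the models implemented in `terrapath`, the
assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the
numerical choices that matter for reproducibility.

## ODBA (`terrapath.accel`)

A burst is an (n × 3) array of acceleration samples in g.  The static
(gravitational) component per axis is estimated by a centred running
mean; the default window is the **full burst**, the common choice for
short fixed-duration bursts, where the estimate is simply the per-axis
mean.  ODBA is the burst mean of the summed absolute dynamic residuals.
Consequences tested as invariants: ODBA ≥ 0; with the full-burst
window, ODBA is exactly invariant to any constant per-axis offset
(pure-offset miscalibration is harmless); scaling the dynamic
component by c scales ODBA by |c|.

Device calibration is a per-axis affine map, corrected = (raw −
offset) × gain.  Body temperature is joined to bursts by the nearest
logger reading within ±150 s (the loggers run at 5-min resolution, so
this accepts at most half an interval of mismatch).  Temperature
binning for thermal analysis uses the nearest whole degree,
floor(t + 0.5); the SE of a single-record bin is 0 by convention.

## Activity classification (`terrapath.activity`)

Assumption: pooled per-burst ODBA of one individual reflects two
latent states, and the power transform x = ODBA^(−1/3) makes each
state approximately Gaussian, so pooled transformed values follow a
two-component Gaussian mixture.  The exponent −1/3 is part of the
method definition.  Since the transform is strictly decreasing, the
component with the lower transformed mean is the *active* state.

The default density is the proper weighted mixture π·N_a + (1−π)·N_b.
An `as-printed` compatibility mode fits the equal-unit-weight sum
N_a + N_b instead; that object integrates to 2 and is not a density,
so it is kept only for comparison with legacy analyses that used the
unnormalised form.

Fitting is non-linear least squares of the mixture density against an
empirical density — a Freedman–Diaconis histogram by default, a
Gaussian KDE as an alternative — evaluated at bin centres.
Parameters are optimised as (μ₁, μ₂, log σ₁, log σ₂, logit π) to keep
scales positive and the weight in (0, 1).  Initialisation: means from
a median split, pooled half-SD for the scales, π = 0.5; up to 20
seeded random restarts on failure.  Components are re-ordered to
μ_a < μ_b after convergence.  Degenerate inputs (n below 50,
near-constant values) raise instead of returning a silent fit.

A fit is flagged `boundary` when the weight leaves [0.05, 0.95] or
the means are separated by less than 2 pooled SDs — below that
separation a two-Gaussian mixture is effectively unimodal and the
two-state interpretation is not identifiable.

Classification is the per-burst posterior probability of the active
component; a burst is active iff p > 0.5, with an exact tie resolved
to *inactive* (deterministic and conservative about activity).
Classification uses only the individual's own fit, never pooled data.
Zero ODBA values (possible after calibration) are floored at half the
smallest positive value before the transform, which is undefined at 0.
Hourly activity is the exact ratio of active bursts to bursts.

## Path analysis (`terrapath.paths`, `terrapath.geo`)

Thread-trailing records (segment distance, compass bearing) are
dead-reckoned with the compass convention 0° = north, clockwise:
each segment advances (d sin b, d cos b).  Projection between WGS84
and UTM is a 6th-order Krüger series in the third flattening
(sub-millimetre accuracy inside a zone; validated by round-trip and a
local-ellipsoid geodesic oracle).  Only the northern hemisphere is
handled.  Step distances are Euclidean in projected metres — at step
scales of metres to hundreds of metres the difference from geodesic
distance is far below GPS error.

Turning angles are reported as absolute values in [0°, 180°]; signed
angles centred at zero cannot produce mean angles above 90°, which
field reports of reversal-heavy paths require.  A path of n points
yields n−1 steps and n−2 angles; zero-length steps leave the adjacent
angles undefined rather than fabricating a heading.  Steps spanning
the overnight gap (last evening fix to first morning fix) are excluded
from statistics, because animals can move before devices resume.

Mode clustering is k-means, k = 2, 10 seeded restarts, on standardised
(log(step length + ε), turning angle) with ε = 0.01 m so that
zero-length GPS-jitter steps remain admissible; Ward hierarchical
clustering is available behind a flag.  Label semantics follow the
accompanying field study's convention: the higher-turning cluster is
**extensive** (exploratory), the straighter one **intensive**
(foraging).  Readers should note this inverts the usual
area-restricted-search usage, where intensive search is the
high-turning mode; the package follows the study convention verbatim
and keeps an explicit `unassigned` category for steps without angles,
which is why mode counts need not sum to the fix count.

## Thermal performance curves (`terrapath.thermal`)

Candidates: constant; quadratic; Gaussian and skewed Gaussian, each
with a baseline offset so that every candidate family is closed under
affine rescaling of the response (this makes the ranking invariant to
the units of the activity measure); cubic B-spline regressions with 4,
6 and 8 degrees of freedom, interior knots at quantiles.  Fits are
least squares on the per-degree bin means, inverse-variance weighted
by bin count — edge bins hold far fewer records and would otherwise
dominate flexible fits.

Model ranking uses the least-squares AIC with the Hurvich–Tsai
small-sample correction, n ln(SSE/n) + 2k + 2k(k+1)/(n−k−1).  The
correction is not optional here: with ~26 one-degree bins and
candidates up to k = 8, the uncorrected criterion selects a spurious
peaked or spline model on genuinely flat data in roughly a fifth of
replicates, a scale-free property of nested least-squares comparisons
that no sample size removes.  Even with the correction a small
fraction of flat replicates is won by a flexible model, which is why
the package's own flat-curve validation is a majority-over-replicates
check.  Selection also applies the Burnham–Anderson parsimony
convention: among models within 2 AIC units of the minimum, the one
with fewest parameters wins.

Breadth: the curve is evaluated on a 0.1 °C grid over the observed
range; t_opt is the argmax and the breadth at level L (default 0.8)
is the maximal contiguous interval containing t_opt where the curve
stays ≥ L × maximum.  Breadth is monotone non-increasing in L.

## Environmental models (`terrapath.envstats`)

Linear responses (log hourly displacement; mean hourly ODBA) use a
random-intercept linear mixed model fitted by maximum likelihood
(statsmodels MixedLM is the fitting engine; the surrounding
statistics are computed in-package).  Distance is natural-log
transformed before modelling, and group means in reports stay on the
original scale.  The likelihood-ratio test compares the full model
against the intercept-plus-random-effect null, so the χ² degrees of
freedom equal the number of fixed terms — the random effect is present
in both models by construction.  Variance-partition coefficients:

    r2_marginal    = var(Xβ) / (var(Xβ) + σ²_id + σ²_res)
    r2_conditional = (var(Xβ) + σ²_id) / (var(Xβ) + σ²_id + σ²_res)

Backward-stepwise deletion removes the least-significant term while
the AIC (−2ℓ + 2(p+2)) does not increase; a p-threshold mode
(α = 0.05) is available.  Interactions are excluded from the candidate
set.  CIs are 95% Wald intervals.  Time of day enters as the numeric
hour.  Gradient optimisers can stall at the zero-variance boundary,
so fitting falls back through bfgs → powell → Nelder–Mead and accepts
the first converged finite-likelihood solution; a group variance
estimated at (near) zero is reported as a `singular` flag, never
hidden.

Hourly activity proportions (active bursts out of bursts) use a
binomial random-intercept GLMM written in-package: the random
intercept is integrated out with 25-node Gauss–Hermite quadrature and
the likelihood maximised numerically, with Wald CIs from the numerical
Hessian.  The installed Python stack offers no ML binomial GLMM
(statsmodels' mixed GLM is Bayesian-approximate), and in the
zero-variance limit the implementation reproduces the ordinary
binomial GLM, which is tested.  r² values for this model are on the
latent scale, with logistic residual variance π²/3.  Fully
active/inactive datasets and apparent separation are flagged.

## Synthetic studies (`terrapath.synth`)

The generator emulates the five input streams with every parameter
recorded, and all randomness derived from one integer seed (identical
seed and config ⇒ bitwise-identical tables).

*Bursts.*  Hidden active/inactive state per burst; per state the
transformed ODBA is Gaussian.  Defaults (μ_a = 3.0, σ_a = 0.5,
μ_b = 7.0, σ_b = 0.8, π = 0.3) put the active component near 0.037 g
and the inactive one near 0.003 g — inside the ranges field ODBA
studies of box turtles report — with the components 5σ apart and
roughly a third of daytime bursts active.  Configurations whose
transformed support reaches non-positive values (μ − 5σ ≤ 0) are
rejected; the residual ~3×10⁻⁷ tail is redrawn at sampling time.  The
tri-axial signal inverts the ODBA operator exactly (gravity vector
plus a zero-mean alternating dynamic component whose per-axis
amplitudes sum to the target), rather than simulating biomechanics:
the pipeline consumes nothing but ODBA, so realism beyond the exact
target value would add noise without adding test power.

*Fine paths.*  Two-mode correlated random walk at 5-min resolution
during the 07:00–19:00 recording window.  Per mode, step lengths are
log-normal (strictly positive, right-skewed like real displacement
data) and turning angles are wrapped-normal about a per-mode centre
with a random sign.  A symmetric zero-centred family cannot yield mean
absolute angles above 90°, while reversal-heavy exploratory movement
shows means near 150°; the per-mode centre (default 150° extensive,
15° intensive) is the minimal extension that covers both regimes.
Mode switching is a two-state Markov chain (default stay-switch
probability 0.1 per 5-min step).

*Hourly GPS.*  Per-hour displacement follows the log-linear model
ln L = α + Xβ + b_i + ε with b_i ~ N(0, 0.3²), ε ~ N(0, 0.7²) and
α = ln 17 − (0.7² + 0.3²)/2 + 0.02·12.5 — the log-normal variance
terms and the mean of the default time-of-day effect are recentred so
the day-averaged arithmetic dry-hour mean is ~17 m, the magnitude
reported for free-ranging box turtles.  Default β:
precipitation −0.27 (rain reduces hourly distance to ~13/17 of dry),
hour −0.02 (movement declines through the day), zero for temperature,
humidity and cloud.  The hourly track is generated directly from this
model rather than by rescaling the fine CRW, so the covariate
structure the mixed models are meant to recover is exact by
construction; the fine paths remain the pure CRW used for the
resolution comparison.  The two tracks are therefore not the same
trajectory — a deliberate simplification; the field comparison they
emulate also came from different animals and years.

*Activity effects.*  Weather acts on the log-odds of the active burst
state (defaults: temperature +0.02, humidity +0.04, cloud +0.08, hour
−0.08 per unit on the logit scale, precipitation 0).  This leaves the
mixture components untouched while inducing the corresponding effects
on mean hourly ODBA and on the classified activity proportion —
matching the field account that mode-level ODBA differences arise
mainly from a changed likelihood of activity rather than a changed
intensity of it.  Effects are mean-centred over the study so the
overall activity level stays at the configured π.

*Body temperature.*  Thermoconformer: ambient interpolated to 5-min
resolution plus AR(1) noise (φ = 0.9, σ = 0.3 °C).  No basking or
microhabitat selection is modelled.

*Weather.*  Day-level AR(1) baseline temperature around 20 °C with a
diurnal sinusoid peaking mid-afternoon; absolute humidity coupled to
temperature; ordinal cloud cover 0–5 from a thresholded latent AR(1);
precipitation concentrated in the cloudiest hours at ~8% of hours
overall, matching the sparse-rain regime of a midwestern summer.

What passing tests on these data do **not** show: robustness to GPS
positional error (fixes are exact), to missing bursts or logger
drop-outs, to behavioural rhythms beyond a linear hour term, or to
activity–temperature confounding beyond what the diurnal cycle
induces.  On that last point: because activity declines through the
day while temperature rises, a study simulated with the default
activity effects shows a mild *apparent* thermal performance peak even
though no direct temperature dependence of the mixture is configured —
a realistic confounding that analyses of real field TPCs face too.

## Problem sizes

Validation uses synthetic studies of 3–12 individuals over 4–14 days
(up to ~12,000 bursts and ~2,200 fixes, the scale of the motivating
field dataset), 100 replicate individuals of 500 bursts for mixture
recovery, 500 null replicates for LRT calibration and 200 for CI
coverage, and 8,000-record generators for thermal curves — sizes at
which every Monte-Carlo tolerance used in the tests is several
standard errors wide.

## Known limitations

- The UTM transform covers the northern hemisphere only.
- The NLS mixture fit assumes a usable empirical density; with fewer
  than ~50 bursts per individual it refuses rather than guessing.
- The binomial GLMM uses non-adaptive quadrature; with very large
  random-effect variances (σ ≳ 3 on the logit scale) more nodes would
  be needed than the default 25.
- `as-printed` mixture mode reports weight 0.5 by definition; its
  posterior classification coincides with the weighted mode only when
  the true mixing weight is 1/2.
- Information-criterion curve selection retains an irreducible
  false-structure rate on flat truth (see the thermal section); breadth
  estimates are robust to this, model identity is not.
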