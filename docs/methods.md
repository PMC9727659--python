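# Methods

## The model

`biphasefit` analyses univariate population time series that grow in two
phases. The state `C(t)` (coral cover in %, normalized cell density, spheroid
equivalent radius in μm, …) follows a piecewise autonomous ODE with a change
point `T`:

    dC/dt = f1(C)   for t ≤ T,
    dC/dt = f2(C)   for t > T,        C(0) = C0.

Four rate-law pairs ship as built-ins:

| kind | f1 | f2 | process parameters |
|---|---|---|---|
| `delayed_logistic` | 0 | r C (1 − C/K) | T, C0, r, K |
| `delayed_normalized_logistic` | 0 | r C (1 − C) | T, C0, r |
| `biphasic_logistic` | r1 C (1 − C/K1) | r2 C (1 − C/K2) | T, C0, r1, r2, K1, K2 |
| `single_phase_logistic` | r C (1 − C/K) | same | C0, r, K (no change point) |

Custom models are registered by supplying two rate callables and parameter
metadata. The state is deliberately *not* clipped to [0, K]: the spheroid
first phase runs above its phase-1 capacity (a shrinking spheroid), which is
exactly the regime `biphasic_logistic` is meant for. `single_phase_logistic`
simply has no `T`; profiling code skips it — single-phase analyses are a
configuration of the same machinery, not a separate code path.

## Observation model and estimation

Observations `y_i` at times `t_i` (i = 1..I) are the model trajectory plus
i.i.d. additive Gaussian noise with constant standard deviation σ (same units
as the measurement). The full parameter θ stacks the process parameters and
σ. We optimize and profile σ itself rather than σ²; likelihood-based
intervals are invariant to that monotone reparametrization, and measurement
units are the natural reporting scale.

The MLE maximizes the Gaussian log-likelihood subject to box bounds using
Nelder–Mead. Bounds are enforced by a logit-type coordinate transform: each
bounded coordinate is mapped to the real line, the simplex runs
unconstrained, and every iterate stays strictly inside the box. Two numerical
details matter:

* **Stopping criteria.** Absolute tolerances 1e-8 on the transformed simplex
  and on the function value, at most 1e5 evaluations. On the transformed
  scale an absolute 1e-8 corresponds to a relative ~1e-8 on each parameter's
  position inside its box.
* **Starts at a bound.** A starting value pinned to a bound maps to |z| ≈ 28,
  where the transform is flat and the simplex cannot move that coordinate.
  Starting z values are clipped to ±7 (a fraction ~1e-3 inside the box); the
  search itself can still approach the bound arbitrarily closely. Without
  this, profiles whose nuisance optimum leaves a bound (e.g. an initial
  condition estimated at its floor) stall there.

The starting estimate is user-supplied. An optional multistart (N uniform
draws within bounds, seeded) adds robustness for multimodal surfaces.

**σ concentration.** For fixed process parameters the maximizing σ is the RMS
residual, in closed form. `fit_mle` and `profile_parameter` accept
`concentrate_sigma=True` to search only the process parameters and recover σ
analytically — exact, one dimension cheaper, and tested to agree with the
all-numeric route. The default is `False`, matching the plain "optimize
everything numerically" procedure; the Monte-Carlo coverage machinery turns
it on for speed.

## Numerical solution of the ODE

All built-ins have exact piecewise-logistic solutions (`solver="closed_form"`),
used by the fast paths and as the oracle for the integrator. The generic path
(`solver="rk2"`, the default) is Heun's second-order explicit Runge–Kutta
with a fixed step, by default 1/1000 of the output horizon. The step sequence
is split so that the change point and every output time are landed on
exactly: the right-hand side is discontinuous at `T`, and a step straddling
the discontinuity would destroy second-order accuracy. Within a segment the
number of sub-steps is `ceil(span/step)`, so the effective step never exceeds
the nominal one; convergence studies should use nominal steps that divide the
segment lengths. Non-finite states abort with the blow-up time and the
offending parameters.

## Profile likelihoods and confidence intervals

The normalized log-likelihood is `l(θ) − l(θ̂)` (zero at the MLE). For an
interest parameter ψ the profile is the normalized log-likelihood maximized
over the remaining (nuisance) parameters at each fixed ψ, evaluated on two
uniform meshes from the MLE out to the lower and upper bound — 40 points per
side by default (80 mesh points plus the MLE; each side excludes the MLE and
includes the bound). Nuisance optimizations are warm-started: first point
from the MLE nuisance values, second from the previous optimum, later points
from linear extrapolation of the previous two optima, falling back to the
previous optimum and then the MLE if the extrapolation leaves the bounds.
After each mesh-point search the objective is also evaluated at the MLE
nuisance values and the better of the two is kept — this costs one evaluation
and makes exactly-separable cases (e.g. the σ profile, whose nuisance optimum
*is* the MLE process vector) exact.

Confidence intervals use the asymptotic chi-squared calibration of the
likelihood-ratio statistic with one degree of freedom: the interval at level
α collects ψ values whose profile exceeds `−0.5·χ²₁(α)` (−1.92, −3.32, −5.41
at 95/99/99.9%). Endpoints are read off by linear interpolation between the
two mesh points straddling the threshold. If the profile at a bound is still
above the threshold, the endpoint is the bound and a flag marks practical
non-identifiability at that level. Failed mesh points (recorded as NaN; an
error if more than 20% fail) are interpolation gaps, not zeros. If the
profile re-crosses the threshold, the outermost crossings are reported and
the interval is flagged multimodal. If a mesh-point optimization beats the
recorded MLE, the profile is renormalized to its maximum and the improvement
is exposed on the result rather than silently ignored.

## Parameter-wise profile predictions

Each profile stores the nuisance optimum λ*(ψ) per mesh point. The
parameter-wise prediction envelope for ψ at level α is the pointwise min/max
of the mean trajectories at every (ψ_j, λ*(ψ_j)) whose profile value clears
the α threshold, together with the MLE trajectory. No refinement between mesh
points is attempted: the envelope inherits the 80-point profile resolution
and stays linear in cost. Envelopes are of the *mean* trajectory only;
noise-inclusive data intervals are out of scope. σ's envelope is zero-width
by construction (the mean does not depend on it) up to optimizer tolerance
(~1e-8 relative drift of the nuisance optima). Unions of envelopes take the
pointwise min of lowers and max of uppers; they contain every constituent,
and their exact coverage is not claimed — they are a diagnostic showing which
parameter drives predictive uncertainty where (change point and initial
condition early, carrying capacity late). The default prediction level is
95%, configurable; the default grid is 200 uniform points over the
observation window, extendable for forecasting.

## Model comparison

Approaches (model + rule for which parameters are fixed) are ranked by
AIC = −2·max log-likelihood + 2k, with k the number of estimated parameters
including σ. "Fix the initial condition to the first measurement" means the
observation at the earliest time point, removed from θ and from k. Reports
carry ΔAIC relative to the best row; non-converged fits are flagged, and the
standalone `aic()` refuses them.

## Synthetic data: what the fixtures emulate, and what they do not

`generate_synthetic` draws observations as exact trajectory + seeded
N(0, σ²) noise — precisely the observation model the inference assumes. The
three named fixtures reproduce the *scale and cadence* of the case studies;
their generating parameters sit inside the 99.9% intervals estimated from
the real datasets:

* **coral** — delayed logistic; T = 600 d, C0 = 3%, r = 0.002 d⁻¹, K = 80%,
  σ = 2%; 12 irregular survey times over 3600 days.
* **proliferation** — normalized delayed logistic; T = 40 h, C0 = 0.03,
  r = 0.105 h⁻¹, σ = 0.03; 2-hourly over 120 h.
* **spheroid** — logistic–logistic; T = 40 h, R(0) = 540 μm, r1 = 0.2 h⁻¹,
  r2 = 0.02 h⁻¹, K1 = 200 μm, K2 = 320 μm, σ = 4 μm; 2-hourly to 48 h then
  6-hourly to 120 h.

The real observation times and values are not published as printed tables, so
the fixtures emulate sampling design, not the actual data; passing tests
demonstrate correct behaviour *under the assumed observation model* (exact
error distribution, constant variance, no model misspecification), which real
data need not satisfy. Each fixture records its seed; coverage replicates
derive per-replicate generators from `(seed, replicate)` pairs.

## Small-sample behaviour of the interval calibration

The χ²₁ threshold is asymptotic. The coral design is deliberately sparse —
I = 12 observations against 5 parameters — and there the 95% profile
intervals undercover. The effect is quantitatively predicted by exact
small-sample theory for the linear-Gaussian analogue: with p = 4 mean
parameters and n = 12, the likelihood-ratio interval for a mean parameter
has true coverage P(F₁,₈ ≤ 8(e^{3.84/12} − 1)) ≈ 0.88, and for σ (residual
sum of squares ~ σ²χ²₈ scaled by 1/n) ≈ 0.78. The package's Monte-Carlo
coverage experiment on the coral fixture reproduces these numbers
(≈ 0.84–0.89 for the process parameters, ≈ 0.78 for σ over 200 replicates),
which is evidence the profiling machinery is correct — the asymptotic
calibration itself is what falls short at this sample size. On the dense
proliferation/spheroid designs (I = 61 and 37) the approximation is far
better. Users who need calibrated intervals from very sparse designs should
treat the 95% label as approximate or raise the threshold level.

## Problem sizes used by the test suite

Chosen once as package defaults for routine continuous testing: the coverage
experiment runs 200 replicates of the coral fixture at 20 mesh points per
side with σ concentration (the mesh halving relative to the 40-point default
changes interval endpoints only through linear interpolation between mesh
points and slightly *narrows* them, so it does not flatter coverage); the
AIC model-recovery simulation uses 50 replicates (the delayed truth wins in
~80% — in the losing draws the fitted delayed model gains fewer than 2
log-likelihood units, so the two-parameter penalty prevails, an expected
consequence of the coral design's weak delay signal); the shrinking-noise
identifiability check uses 9 replicates per noise level at 12 mesh points
per side.

## Known limitations

* Gaussian, homoscedastic errors only; no lognormal/exponential error models.
* Univariate profiles only — no bivariate profile surfaces or full-vector
  confidence regions, and no bootstrap recalibration of thresholds.
* The constrained predictive profile over trajectory space is not
  implemented; predictions are parameter-wise (and unions thereof).
* Fixed-step explicit integration: stiff rate laws need an externally chosen
  smaller step.
* Exactly two phases; the registry is extensible but no three-phase built-ins
  ship.
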