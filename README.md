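# biphasefit

Profile-likelihood analysis of **biphasic population growth**: fitting
piecewise ODE growth models with a change point to noisy time series,
assessing which parameters the data actually pin down, and propagating
parameter uncertainty into prediction bands.

Populations across the life sciences grow in two phases — coral cover
recovering after a storm (flat, then sigmoidal, over years), cell
proliferation assays (lag, then logistic growth, over hours), tumour
spheroids (shrinking during formation, then growing) — and the time `T` at
which the dynamics switch is often the scientifically interesting quantity.
`biphasefit` is for modellers and quantitative biologists who want more than
a point estimate of `T` read off by eye: it delivers likelihood-based
confidence intervals for the change point and every other parameter,
diagnoses practical non-identifiability, and shows how each parameter's
uncertainty shapes the predicted growth curve.

## The model and the statistics

The state `C(t)` follows a piecewise autonomous ODE,

```
dC/dt = f1(C)  (t ≤ T),    dC/dt = f2(C)  (t > T),    C(0) = C0,
```

with built-in rate-law pairs: delayed logistic (`f1 = 0`,
`f2 = r C (1 − C/K)`), its normalized variant (K = 1), a logistic–logistic
model with separate rates and capacities per phase, and a single-phase
logistic. Observations are `y_i ~ N(C(t_i; θ), σ²)`, i.i.d., with σ
estimated alongside the process parameters. The toolkit provides:

* **MLE** — bounded Nelder–Mead on a logit-transformed parameter space;
  trajectories via Heun's RK2 (split exactly at `T`) or closed forms.
* **Profile likelihoods** — each parameter ψ profiled over two uniform
  40-point meshes from the MLE to its bounds, nuisance parameters
  re-optimized with warm starts; `ℓ̂p(ψ) = sup_λ [ℓ(ψ, λ) − ℓ(θ̂)] ≤ 0`.
* **Confidence intervals** — likelihood-ratio thresholds `−½ χ²₁(α)`
  (−1.92, −3.32, −5.41 at 95/99/99.9%), endpoints interpolated on the mesh,
  with flags for bound-limited (practically non-identifiable) and multimodal
  profiles.
* **Parameter-wise profile predictions** — the mean trajectory evaluated
  along each profile curve `(ψ, λ*(ψ))` above the threshold, giving a
  per-parameter envelope, plus pointwise unions across parameters.
* **AIC model comparison** — e.g. full biphasic fit vs. the common
  single-phase shortcuts (fix `T = 0`, pin `C0` to the first measurement).
* **Synthetic data** — seeded generators matching the scale and sampling
  cadence of the three case studies, and a Monte-Carlo coverage experiment
  for the intervals.

## Worked example

Fit the coral-scale synthetic dataset (12 irregular surveys over ~10 years,
generated with the recorded seed) with the delayed logistic model:

```python
import biphasefit as bf
from biphasefit import BiphasicGrowthMLE

spec = bf.case_study_fixture("coral")
data = bf.dataset_from_fixture(spec)

est = BiphasicGrowthMLE(
    model="delayed_logistic",
    start={"T": 600, "C0": 3, "r": 0.002, "K": 80, "sigma": 2},
    bounds=spec.bounds,
    solver="closed_form",
)
est.fit(data.times, data.observations)
print({k: round(v, 4) for k, v in est.mle_.items()})
print(est.confidence_intervals(level=0.999).round(4))
```

```
{'T': 144.0454, 'C0': 1.4197, 'r': 0.002, 'K': 79.7385, 'sigma': 1.3971}
                mle    lower     upper  lower_at_bound  upper_at_bound  multimodal
parameter
T          144.0454   0.0000  852.9945            True           False       False
C0           1.4197   0.4379    4.7121           False           False       False
r            0.0020   0.0016    0.0025           False           False       False
K           79.7385  73.2040   89.1798           False           False       False
sigma        1.3971   0.8069    3.3100           False           False       False
```

Read: growth rate, carrying capacity, initial cover and noise scale are
practically identifiable (narrow, well-formed 99.9% intervals containing the
generating values 0.002, 80, 3 and 2). The change point is not: its profile
is still above the threshold at the lower bound (`lower_at_bound=True`), so
this noisy draw cannot rule out `T = 0` — only an upper limit (~850 days) is
learned. Prediction envelopes localize each parameter's influence:

```python
env = est.prediction_envelope(["T", "K"], level=0.95)
print(round(env.width[0], 2), round(env.width[-1], 2))   # 1.52  3.44
```

The change point widens the band early (width 1.52% at t = 0 comes from `T`
and vanishes late), the carrying capacity widens it late (3.44% at
t = 3600 d). An AIC comparison of the standard modelling approaches on the
same draw ranks the single-phase readings marginally ahead of the full
biphasic fit (ΔAIC ≈ 1.9) — consistent with the weakly identified delay:

```python
report = bf.compare_approaches(
    data, bf.standard_approaches(est.start, bounds=spec.bounds),
    solver="closed_form",
)
print(report)
```

```
                                   approach  k  max_loglik   AIC   dAIC  converged
                 single-phase, C0 estimated  4      -21.07 50.14      0       True
single-phase, C0 fixed to first measurement  3      -22.18 50.35 0.2113       True
        biphasic (all parameters estimated)  5      -21.04 52.08  1.939       True
```

The same pipeline is available from the shell:

```bash
biphasefit simulate --fixture coral --out coral.csv
biphasefit profile --data coral.csv \
    --start "T=600,C0=3,r=0.002,K=80,sigma=2" \
    --bounds "T=0:2500,C0=0.01:40,r=1e-4:0.01,K=40:150,sigma=0.2:20" \
    --out results/
```

which writes per-parameter profile CSVs and a JSON interval table with
identifiability flags (`fit`, `predict` and `compare` subcommands likewise;
a TOML config file can replace the flags).

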