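# scrofit

Parameter estimation for dynamic biological models from noisy, incomplete
time-series data, built around the **Swarm-based Chemical Reaction
Optimization (S-CRO)** hybrid metaheuristic, with differential evolution
(DE), the firefly algorithm (FA) and chemical reaction optimization (CRO)
as baselines, a chi-square **practical-identifiability test**, and **AIC
model selection**.

## The problem

Kinetic parameters of ODE models of cellular processes are rarely measured
directly; they are estimated by fitting model output `y(t; θ)` to
observations `ỹ` via nonlinear least squares,

    J(θ) = Σ_{observed (n,s)} ( ỹ_ns − y_ns(θ) )² ,

a multi-modal problem when the data carry substantial measurement noise
and missing entries.  S-CRO attacks it by sorting the population each
iteration, refining the stronger half with firefly attraction moves
(`β(r) = β₀ e^{−μ r²}`) followed by chemical-reaction operators (on-wall
collision, decomposition, inter-molecular collision, synthesis — each
governed by a potential/kinetic-energy account that never creates energy),
and re-seeding the weaker half with a best-guided random update.

After fitting, two statistical checks are provided:

- **Identifiability** — per observed state, the residual variance point
  estimate `ŝ²` and its chi-square confidence interval
  `[(N−1)ŝ²/χ²_{(1+γ)/2}, (N−1)ŝ²/χ²_{(1−γ)/2}]`; the fit passes when the
  truly injected noise variance lies inside the interval for every state.
- **Model selection** — `AIC = N ln(MSE) + 2D` over candidate structures
  refit on the same data; the smaller AIC wins.

Three benchmark systems ship with true parameters, bounds and sampling
grids: a two-parameter nonlinear discrete map, a four-state synthetic
transcriptional oscillator (two RNA-producing bistable switches), and a
six-state, 17-parameter DegS–DegU extracellular-protease network of
*B. subtilis*.  See `docs/methods.md` for the model equations and all
algorithmic conventions.

## Worked example

Fit the oscillator from 15%-noise synthetic data at the study settings
(20 solutions, 100 iterations) and test identifiability:

```python
import scrofit as sf
from scrofit.objective import Objective
from scrofit.validation import identifiability_test

result, truth, data, real_var = sf.estimate_benchmark(
    "oscillator", algorithm="scro", noise_percent=15.0, seed=1)
pred = Objective(sf.get_model("oscillator"), data).predict(
    result.best_params.values)
print(identifiability_test(pred, data, real_var, gamma=0.95).table())
```

Running `python examples/estimate_oscillator.py` prints:

```
best fitness 48.64 after 3392 model evaluations
 parameter     true  estimate  rel.err
       K_A     0.57    0.5384    -5.5%
       n_A      1.5     1.542    +2.8%
       K_B      2.5     2.485    -0.6%
       n_B      6.5     6.206    -4.5%
         k      6.5     6.608    +1.7%

error-variance identifiability test (gamma = 0.95):
                   A                       B                       ...
Real variance      4.042e-02               4.412e-01               ...
Variance point     4.239e-02               4.378e-01               ...
Variance interval  [3.268e-02, 5.720e-02]  [3.375e-01, 5.908e-01]  ...
Test               Pass
```

All five parameters are recovered within a few percent despite 15%
signal-proportional noise, and the residual variance of the refit is
statistically indistinguishable from the injected noise on every state —
the estimates are practically identifiable.  The other scripts in
`examples/` demonstrate simulation (`simulate_models.py`), AIC selection
between the true and an ablated structure (`model_selection.py`) and the
four-method comparison grid (`compare_optimizers.py`).

A thin CLI mirrors the library:

```sh
scrofit simulate --model oscillator --out traj.csv
scrofit estimate --model protease --algorithm scro --noise 15 --seed 1 --out fit.json
scrofit select --model oscillator --seed 1 --out report.json
scrofit benchmark --models oscillator,protease --replicates 20 --out grid.csv
```

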