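# Methods

## Problem

A dynamic biological model predicts state trajectories `y(t; θ)` from a
parameter vector `θ` with box bounds.  Experiments yield noisy, possibly
incomplete observations `ỹ` on a sampling grid.  Estimation minimizes the
nonlinear least-squares fitness

    J(θ) = Σ_{(n,s) observed} ( ỹ_ns − y_ns(θ) )²

over the box.  Residuals are unweighted; per-state weights exist as an
option but default to 1.  `J` is multi-modal for the models considered, so
the package estimates `θ` with population metaheuristics and then asks two
statistical questions: are the estimates *practically identifiable* given
the noise, and which of several candidate model structures should be
preferred.

## Optimizers

All four methods share one substrate: a population of `NP` candidate
vectors ("molecules"), each carrying a potential energy `PE = J(position)`
and — for the chemical-reaction family — a kinetic energy `KE ≥ 0`, a
tolerance budget that lets a molecule accept a worse position.  All
randomness in a run flows from one seeded generator, so identical
configurations reproduce bit-for-bit.  Simulation failures (stiff
blow-ups, divergent orbits) score `+inf` instead of raising, because
population methods routinely propose unstable parameter vectors; the
evaluation is still counted.

**Firefly algorithm (FA).**  Attractiveness `β(r) = β₀·exp(−μ r²)` with
Euclidean distance `r`; move `x ← x + β(x_j − x) + α·w·(u − ½)` with
per-coordinate uniform `u`, bound width `w`, clamped to the box.  The
classic pairwise sweep (every firefly moves toward every brighter one) is
the default; brightness comparisons use the values from the start of the
sweep and each firefly is re-evaluated once per iteration, keeping the
budget at one evaluation per firefly per iteration.  The standalone FA
baseline keeps a constant random step `α` (the canonical form); an
optional geometric decay (`fa_alpha_decay`) turns it into a convergent
variant.

**Chemical reaction optimization (CRO).**  Four reactions, each drawn per
molecule from one uniform `r`: on-wall collision (`r ≤ 0.33`),
decomposition (`0.33 < r < 0.5`), synthesis (`0.5 ≤ r ≤ 0.7`),
inter-molecular collision (`r > 0.7`).  Energy rules:

- *On-wall*: small Gaussian bounce; accept iff `PE' ≤ PE + KE`; then
  `KE' = (PE + KE − PE')·q`, `q ~ U(LR, 1)` — `LR` bounds the fraction of
  the residual retained, the rest is dissipated.
- *Decomposition*: two far offspring (Gaussian at 50% of the bound
  width); accept iff `PE₁' + PE₂' ≤ PE + KE`; the residual splits `k` /
  `1 − k`, `k ~ U(0,1)`.
- *Inter-molecular*: both partners bounce; accept iff the pair's total
  energy covers both new `PE`s; the residual is redistributed by a uniform
  share.
- *Synthesis*: one product on the line through the parents,
  `x = x₁ + λ(x₂ − x₁)`, a single `λ ~ U(−0.5, 1.5)` shared by all
  coordinates (clamped); accept iff `PE' ≤` the pair's total energy; the
  product keeps the whole residual as `KE`.

No reaction ever increases the total `PE + KE` of the molecules involved
(verified by a 10⁴-application audit in the test suite).  Decomposition
grows and synthesis shrinks the population; at the end of each iteration
the population is restored to `NP` by dropping the worst or refilling with
best-guided random clones.

*Bounce kernel.*  The small-perturbation reactions need a step scale.  Two
choices are implemented: `"width"` — a fixed fraction (`on_wall_scale`,
default 1%) of the bound width, geometrically decayed per iteration; and
`"spread"` (default) — per molecule, half its elementwise distance to the
incumbent best, floored by half the per-coordinate spread of the better
half of the population and by a decayed sliver of the width.  The spread
kernel lets far molecules take exploratory bounces while molecules near
the incumbent refine on the scale that still separates them, and it keeps
coordinated steps alive along sloppy (weakly identified) parameter
directions, which a fixed isotropic kernel explores poorly.  A known
limitation follows from the same construction: once a plain-CRO population
collapses onto the incumbent, the kernel loses its scale and refinement
stalls near the plateau — visible in the quadratic sanity test, where CRO
stops around 10⁻² while DE, FA and the hybrid reach 10⁻⁶ or better.

**Differential evolution (DE).**  DE/rand/1/bin with greedy selection.
The replication presets keep the stated mutation factors (2.5; 3.0 for the
large model); the stated crossover coefficients (1.5; 2.5) exceed the
valid probability range and are clamped to 1.0.  These settings make the
baseline essentially a clamped random search — consistent with its weak
published performance — so the convergence sanity test supplies standard
coefficients (F = 0.7, CR = 0.9) instead.

**S-CRO hybrid.**  Each iteration has three phases:

1. *Initial selection*: sort by fitness, split into a potential group
   (best `⌈split_fraction·NP⌉`, default half) and a weak group.
2. *Neighbouring improvement + reactions* on the potential group: a
   firefly sweep followed by one CRO reaction per molecule (partners drawn
   uniformly from the group).  Inside the hybrid the sweep attracts each
   solution only to the *best* neighbour (`scro_sweep="best"`): the
   pairwise rule applies up to `|P1|−1` contractions per molecule per
   iteration and collapses the group before the reactions can exploit it,
   which measurably biases sloppy-direction estimates.  The random-step
   scale decays geometrically (`step_decay`, default 0.97).
3. *Random update* of the weak group:
   `x ← x + r₁·(best − x) + r₂·(z − x)` per coordinate, with fresh uniform
   `r₁, r₂` and `z` uniform in the box; kinetic energy is re-endowed at
   `initial_ke`.  This is the escape mechanism; it is exempt from the
   energy audit by construction.

The population is then merged, restored to `NP`, and an elitist snapshot
of the best-ever solution is refreshed; the reported trace is therefore
non-increasing.

Defaults: `β₀ = 0.5`, `μ = 0.01`, `α = 0.2`, `LR = 0.1`,
`initial_ke = 1000` (large relative to converged fitness values, so early
exploration is tolerant and late refinement is effectively greedy once the
budgets dissipate), `split_fraction = 0.5`.

## Benchmark models

The three benchmark systems are this package's concrete renderings,
written to honour the documented constraints (state names and counts,
parameter counts, orders, units, true values and bounds, qualitative
behaviour) with each right-hand side isolated in one unit-tested compiled
kernel.

**Simulated nonlinear map** (2 states, 2 parameters):

    x₁(k+1) = a·x₁ + x₂/(1 + x₂²) + w₁
    x₂(k+1) = b·x₂·(1 − x₂)       + w₂

with truth `(a, b) = (0.8, 1.5)`, bounds `a ∈ [0, 2]`, `b ∈ [0, 3]`,
initial state `(0.1, 0.1)`, 800 steps, and independent zero-mean Gaussian
process noise (s.d. 0.01 per state).  The stable fixed point depends on
both parameters, so the pair is identifiable even from the stationary part
of the series.  Candidate `a > 1` makes the orbit explode; the simulator
reports the diverging step and the objective maps it to `+inf`.

**Transcriptional oscillator** (4 states, 5 parameters).  Two
RNA-producing switches coupled through an activator/inhibitor pair:

    dA/dt = k·C − A                      (activator RNA)
    dB/dt = k·D − B                      (inhibitor RNA)
    dC/dt = 1/(1 + (B/K_B)^{n_B}) − C    (switch Sw21, inhibited by B)
    dD/dt = (A/K_A)^{n_A}/(1 + (A/K_A)^{n_A}) − D   (switch Sw12,
                                                     activated by A)

Truth `(K_A, n_A, K_B, n_B, k) = (0.57 µM, 1.5, 2.5 µM, 6.5, 6.5)`; the
fifth parameter is read as the shared RNA production rate.  Time is in
units of the RNA decay rate.  At the true parameters the system is a
relaxation oscillator with period ≈ 6.6; the default grid is 100 uniform
points on `[0, 13]` (≈ two periods) from `(1, 1, 0.5, 0.5)`.  Bounds were
chosen to contain both the truth and the competitor estimates that the
replication targets reference: `K_A ∈ [0.1, 3]`, `n_A ∈ [0.5, 3]`,
`K_B ∈ [0.5, 5]`, `n_B ∈ [3, 10]`, `k ∈ [3, 10]`.  Hill terms degenerate
gracefully (`n = 0 → ½`, `K = 0 →` full activation) so ablated variants
remain integrable.

**Extracellular protease production** (6 states, 17 parameters).  A
DegS–DegU two-component network for *B. subtilis*: states AprE (A), DegU
(B), DegU~P (C), DegU~P dimer (D), mAprE (E), mDegU (F).

    dA/dt = p10·E − p8·A
    dB/dt = p13 + deph − phos − p2·B
    dC/dt = phos − deph − 2·p5·C² + 2·p6·D − p7·C
    dD/dt = p5·C² − p6·D
    dE/dt = p9 + p14·p16·D/(p16 + D) − p1·E
    dF/dt = p15 − p12·F
    phos  = p3·B·p11/(p11 + B),   deph = p4·C·p17/(p17 + C)

Parameter values and bounds follow the tabulated list (rates in s⁻¹,
syntheses in #/s, p14 dimensionless; 602 # ≈ 1 µM/l — units are carried as
metadata only).  Roles were assigned so that every tabulated value lands
in a biologically sensible slot *and* the six states settle at comparable
magnitudes (≈ 0.7–6 over the default window): with signal-proportional
noise, an unweighted least-squares objective is otherwise dominated by the
largest state and the parameters of the small states become invisible to
the optimizer, which would defeat both the recovery and the
identifiability analyses.  The three externally spot-checked parameters
are strongly identified: p3 (phosphorylation) sets the DegU/DegU~P
balance, p10 (translation) the mAprE→AprE gain, p12 (mDegU decay) the
level and saturation timescale of mDegU.  The default grid is 100 uniform
points on `[0, 600] s` from `(0, 0.1, 0, 0, 0, 0)` — the transient window
up to the slowest saturation (`1/p12 ≈ 100 s`, steady by `≈ 5/p12`).

## Synthetic data

The generator emulates the study's *in silico* protocol: the deterministic
model prediction plus x% white Gaussian noise,
`ỹ = y·(1 + (x/100)·z)`, `z ~ N(0,1)` iid (an "absolute" scheme scaled by
each state's signal s.d. is available).  Study noise levels are 5/10/15%.
Incompleteness is an exact uniformly random mask over observed entries
(default fraction 0; the replication harness labels 0.2 as its
"incomplete" convention), always retaining at least one entry per state.
`make_benchmark` returns, alongside the dataset, the *sample* variance of
the noise actually injected per state — the "real variance" that the
identifiability test uses as its reference, computed with the same
estimator as the test's point estimate so the two are exactly comparable.
The full chain (process noise, measurement noise, masking) is driven by
sub-seeds of one seed.

What the generator does *not* emulate: correlated or heteroscedastic
error structures beyond signal-proportionality, systematic (bias) errors,
non-Gaussian outliers, and irregular sampling.  Passing tests therefore
show correct recovery under the stated noise model, not robustness to
arbitrary real-data pathologies.

## Identifiability test

For a fitted model, per observed state: residuals `e = ỹ − y(θ̂)` over the
masked-in entries; point estimate `ŝ²` = unbiased sample variance
(divisor `N−1`, mean-centered — the zero-mean alternative differs at
O(ē²) and is switchable); interval

    [ (N−1)·ŝ²/χ²_{(1+γ)/2, N−1} ,  (N−1)·ŝ²/χ²_{(1−γ)/2, N−1} ]

at confidence `100γ%` (equal tails, `δ = 1 − γ = 0.05` by default).  A
state passes when the real (injected) noise variance lies inside the
interval; the model verdict is the AND over states.  Interpretation: if
the fit is good, its residuals are statistically pure measurement noise;
a wrong or non-identifiable fit inflates the residual variance and the
interval excludes the real value.  Coverage of the interval construction
is verified by simulation (95% ± 1.5% over 2000 Gaussian datasets).

## Model selection

`AIC = N·ln(MSE) + 2D`, `MSE = J(θ̂)/N`, with `N` the number of observed
entries and `D` the number of *free* parameters; perfect fits are floored
at machine epsilon.  Candidates are refit on the same dataset and the
minimal AIC wins (ties broken by declaration order).  Constant-offset AIC
variants would not change the ordering.  Ablated candidates are expressed
by collapsing selected bounds to zero-width intervals at 0, which keeps
the full simulation path intact while freezing the coordinates and
reducing `D`; the ablations used in the replication zero both Hill
exponents and the production rate (oscillator) and p3, p10, p15
(protease) — each breaks the dynamics qualitatively.

## Numerical choices

- Integration: LSODA (`scipy.integrate.odeint`) at `rtol 1e-7`,
  `atol 1e-9`, `mxstep 5000`; solutions sampled exactly on the requested
  grid; halving the tolerances moves sampled states by < 1e-5 relative.
  Hill terms clip negative state excursions at 0 before exponentiation.
- Out-of-bounds repair everywhere: clamp to the violated bound.
- Non-finite energy residuals (from `+inf` fitness) re-endow `initial_ke`
  rather than propagating.
- Discrete-map orbits abort (and score `+inf`) once a state magnitude
  exceeds 1e12.
- Model kernels are numba-compiled; results are independent of the
  compilation (pure elementwise arithmetic).

## Problem sizes used by the tests and the acceptance script

Replication runs use the study settings: map — 20 solutions,
50 iterations, 20 seeds; oscillator — 20 solutions, 100 iterations,
`β₀ = 0.5`, `μ = 0.01`, 20 seeds; protease — 50 solutions,
200 iterations, `β₀ = 0.7`, `μ = 0.05`, 10 seeds.  The four-method
comparison and the model-selection repetitions run all methods at one
shared budget (NP = 20, T = 100, 20 paired seeds per model), and the
replication grid defaults to 20 replicates per cell with a flag restoring
100.  Reported quantities are medians over seeds.

## Known limitations

- Plain CRO's refinement plateau (above) — inherent to the operator set,
  and consistent with its weak published standing.
- The biological-model renderings are faithful to the documented
  constraints but are not transcriptions of the original SBML models;
  absolute state magnitudes (hence per-state variances) are this
  package's own.
- Sloppy parameter pairs (e.g. mDegU synthesis/decay) converge last; at
  the study budgets their medians sit within ~8% of the reference values,
  not at the least-squares optimum (~2%).
- No structural identifiability analysis, profile likelihoods, AICc/BIC,
  gradient-based polishing, or parallel evaluation.
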