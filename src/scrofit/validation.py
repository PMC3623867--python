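"""Post-estimation statistics: practical identifiability via the residual
error-variance test, and AIC model selection.

The identifiability test asks whether the measurement-noise variance implied
by a fitted model is statistically consistent with the noise that is
actually present: per observed state, the sample variance of the fit
residuals yields a point estimate and a chi-square confidence interval; if
the real noise variance falls outside the interval, the fitted parameter
set could not plausibly have generated the data.  Model selection combines
this verdict with the Akaike Information Criterion computed from the
best-fit mean squared error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .models import DynamicalModel, ParameterSet, Trajectory
from .objective import Dataset, Objective, _aligned_columns

__all__ = [
    "VarianceTestResult",
    "ModelSelectionReport",
    "residuals",
    "variance_point",
    "variance_interval",
    "identifiability_test",
    "aic",
    "compare_models",
    "fix_parameters",
]


@dataclass
class StateVariance:
    """Per-state outcome of the error-variance test."""

    state: str
    real_variance: float
    point: float
    lo: float
    hi: float
    n: int

    @property
    def passed(self) -> bool:
        return self.lo <= self.real_variance <= self.hi


@dataclass
class VarianceTestResult:
    """Identifiability verdict: every observed state must pass."""

    states: list[StateVariance]
    gamma: float

    @property
    def passed(self) -> bool:
        return all(s.passed for s in self.states)

    @property
    def significance(self) -> float:
        return 1.0 - self.gamma

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "passed": bool(self.passed),
            "states": [asdict(s) | {"passed": bool(s.passed)}
                       for s in self.states],
        }

    def table(self) -> str:
        """Plain-text table: one column per state, verdict row at the end."""
        names = [s.state for s in self.states]
        rows = [
            ("", *names),
            ("Real variance", *(f"{s.real_variance:.3e}" for s in self.states)),
            ("Variance point", *(f"{s.point:.3e}" for s in self.states)),
            ("Variance interval",
             *(f"[{s.lo:.3e}, {s.hi:.3e}]" for s in self.states)),
            ("Test", "Pass" if self.passed else "Fail"),
        ]
        widths = [max(len(str(r[i])) if i < len(r) else 0 for r in rows)
                  for i in range(len(names) + 1)]
        return "\n".join(
            "  ".join(str(c).ljust(w) for c, w in zip(r, widths)) for r in rows
        )


def residuals(prediction: Trajectory, data: Dataset) -> dict[str, np.ndarray]:
    """Per-state residual vectors ``e = y~ - y`` over observed entries only.

    The sum of squared residuals across states equals the least-squares
    fitness of the same prediction/data pair.
    """
    pred = _aligned_columns(prediction, data)
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(data.state_names):
        sel = data.mask[:, j]
        out[name] = data.observations[sel, j] - pred[sel, j]
    return out


def variance_point(residual: Sequence[float], n: int | None = None) -> float:
    """Unbiased sample variance of a residual vector (divisor ``N - 1``),
    mean-centered by default (measurement noise is assumed zero-mean but the
    fit may leave a small offset)."""
    e = np.asarray(residual, dtype=float)
    n = e.size if n is None else n
    if n < 2:
        raise ValueError("at least two residuals are required")
    return float(np.sum((e - e.mean()) ** 2) / (n - 1))


def variance_interval(s2: float, n: int, gamma: float = 0.95) -> tuple[float, float]:
    """Chi-square confidence interval for a variance at confidence level
    ``100*gamma`` percent (equal tail split):

    ``[(N-1) s2 / chi2_{(1+g)/2, N-1},  (N-1) s2 / chi2_{(1-g)/2, N-1}]``
    """
    if n < 2:
        raise ValueError("at least two samples are required")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    if s2 == 0.0:
        return 0.0, 0.0
    df = n - 1
    lo = df * s2 / stats.chi2.ppf((1.0 + gamma) / 2.0, df)
    hi = df * s2 / stats.chi2.ppf((1.0 - gamma) / 2.0, df)
    return float(lo), float(hi)


def identifiability_test(
    prediction: Trajectory,
    data: Dataset,
    real_variance: dict[str, float],
    gamma: float = 0.95,
) -> VarianceTestResult:
    """Error-variance identifiability test of a fitted model.

    ``prediction`` is the model output at the estimated parameters;
    ``real_variance`` maps each state to the variance of the noise actually
    injected (known for synthetic data).  A state passes when its real
    variance lies in the chi-square interval around the residual variance
    point estimate; the overall verdict is the AND over states.
    """
    res = residuals(prediction, data)
    states = []
    for name, e in res.items():
        if e.size < 2:
            continue
        s2 = variance_point(e)
        lo, hi = variance_interval(s2, e.size, gamma)
        states.append(StateVariance(
            state=name, real_variance=float(real_variance[name]),
            point=s2, lo=lo, hi=hi, n=e.size,
        ))
    return VarianceTestResult(states=states, gamma=gamma)


def aic(best_fitness: float, n: int, d: int) -> float:
    """Akaike Information Criterion for a least-squares fit:
    ``AIC = N * ln(MSE) + 2 * D`` with ``MSE = best_fitness / N``.

    ``n`` is the number of observed data entries and ``d`` the number of
    estimated (free) parameters.  Perfect fits are floored at machine
    epsilon so the logarithm stays defined.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if best_fitness < 0:
        raise ValueError("best_fitness must be nonnegative")
    mse = max(best_fitness / n, np.finfo(float).eps)
    return float(n * math.log(mse) + 2 * d)


@dataclass
class CandidateReport:
    model_id: str
    aic: float
    best_fitness: float
    n_free_parameters: int
    variance_test: VarianceTestResult
    best_params: dict = field(default_factory=dict)


@dataclass
class ModelSelectionReport:
    """AIC comparison of candidate models refit on one shared dataset."""

    candidates: list[CandidateReport]
    winner: str

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "candidates": [
                {
                    "model_id": c.model_id,
                    "aic": c.aic,
                    "best_fitness": c.best_fitness,
                    "n_free_parameters": c.n_free_parameters,
                    "variance_test": c.variance_test.to_dict(),
                    "best_params": c.best_params,
                }
                for c in self.candidates
            ],
        }

    def table(self) -> str:
        lines = []
        for c in self.candidates:
            mark = " (winner)" if c.model_id == self.winner else ""
            lines.append(f"Model {c.model_id}{mark}  AIC = {c.aic:.4g}  "
                         f"D = {c.n_free_parameters}")
            lines.append(c.variance_test.table())
            lines.append("")
        return "\n".join(lines)


def fix_parameters(
    space: ParameterSet, fixed: dict[str, float]
) -> ParameterSet:
    """Pin selected parameters to constants by collapsing their bounds.

    The returned space has zero-width intervals at the fixed values, so any
    optimizer confined to the box keeps them constant; the remaining
    parameters stay free.  Used to build ablated model variants.
    """
    values = space.values.copy()
    lower = space.lower.copy()
    upper = space.upper.copy()
    for name, val in fixed.items():
        i = space.names.index(name)
        values[i] = lower[i] = upper[i] = val
    return ParameterSet(list(space.names), values, lower, upper)


def n_free(space: ParameterSet) -> int:
    """Number of estimable parameters (non-degenerate bounds)."""
    return int(np.count_nonzero(space.width > 0))


def compare_models(
    candidates: Sequence[tuple[str, DynamicalModel, ParameterSet]],
    data: Dataset,
    real_variance: dict[str, float],
    config,
    gamma: float = 0.95,
    initial_state: np.ndarray | None = None,
) -> ModelSelectionReport:
    """Refit every candidate on the same dataset and pick the AIC winner.

    Each candidate is ``(label, model, search_space)``; ablated variants are
    expressed through spaces with fixed (zero-width) coordinates.  Ties on
    AIC are broken by declaration order.  Alongside AIC, each candidate
    carries its error-variance test verdict against ``real_variance``.
    """
    from .optimizers import run  # deferred: optimizers imports objective

    reports = []
    for label, model, space in candidates:
        result = run(model, data, config, initial_state=initial_state,
                     space=space)
        obj = Objective(model, data, initial_state)
        pred = obj.predict(result.best_params.values)
        vt = identifiability_test(pred, data, real_variance, gamma)
        reports.append(CandidateReport(
            model_id=label,
            aic=aic(result.best_fitness, data.n_observed, n_free(space)),
            best_fitness=result.best_fitness,
            n_free_parameters=n_free(space),
            variance_test=vt,
            best_params=dict(zip(space.names,
                                 result.best_params.values.tolist())),
        ))
    winner = min(reports, key=lambda c: c.aic).model_id
    return ModelSelectionReport(candidates=reports, winner=winner)
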