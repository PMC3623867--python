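"""Nonlinear least-squares objective between model output and observations.

The fitness of a candidate parameter vector is the unweighted sum of squared
residuals over every observed (time, state) entry; masked-out entries (the
"incomplete" part of noisy-and-incomplete data) contribute nothing.  This is
the quantity every optimizer in :mod:`scrofit.optimizers` minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    DynamicalModel,
    DivergenceError,
    IntegrationError,
    ParameterSet,
    Trajectory,
    integrate,
    simulate_discrete_map,
)

__all__ = ["Dataset", "AlignmentError", "EmptyDataError", "fitness",
           "evaluate_params", "Objective"]


class AlignmentError(ValueError):
    """Prediction and data are on different grids or state sets."""


class EmptyDataError(ValueError):
    """The dataset holds no observed entries."""


@dataclass
class Dataset:
    """Noisy, possibly incomplete observations of a trajectory.

    ``mask[i, s]`` is True where state ``s`` was observed at time ``i``.
    ``noise_meta`` records how synthetic noise was generated (percent level,
    scheme, seed) so downstream identifiability tests can recover the truly
    injected noise variance.
    """

    times: np.ndarray
    observations: np.ndarray
    state_names: list[str]
    mask: np.ndarray | None = None
    noise_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.atleast_2d(np.asarray(self.observations, float))
        if self.mask is None:
            self.mask = np.isfinite(self.observations)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.observations.shape != (len(self.times), len(self.state_names)):
            raise ValueError("observations shape must be (n_times, n_states)")
        if self.mask.shape != self.observations.shape:
            raise ValueError("mask shape must match observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def _aligned_columns(prediction: Trajectory, data: Dataset) -> np.ndarray:
    if prediction.times.shape != data.times.shape or not np.allclose(
        prediction.times, data.times
    ):
        raise AlignmentError("prediction and data are on different time grids")
    try:
        cols = [prediction.state_names.index(s) for s in data.state_names]
    except ValueError as exc:
        raise AlignmentError(f"state missing from prediction: {exc}") from None
    return prediction.states[:, cols]


def fitness(prediction: Trajectory, data: Dataset) -> float:
    """Sum of squared residuals over observed entries (columns matched by
    state name, so column order is immaterial)."""
    if data.n_observed == 0:
        raise EmptyDataError("dataset holds no observed entries")
    pred = _aligned_columns(prediction, data)
    resid = np.where(data.mask, pred - data.observations, 0.0)
    return float(np.sum(resid * resid))


@dataclass
class Objective:
    """Callable objective: parameter vector -> fitness, with an evaluation
    ledger.

    Simulation failures (stiffness blow-ups, divergent orbits) map to an
    ``inf`` fitness instead of raising, because population methods routinely
    propose unstable parameter vectors and must carry on; the evaluation is
    still counted.
    """

    model: DynamicalModel
    data: Dataset
    initial_state: np.ndarray | None = None
    rtol: float = 1e-7
    atol: float = 1e-9
    n_evaluations: int = 0

    def __call__(self, theta: np.ndarray) -> float:
        self.n_evaluations += 1
        try:
            pred = self.predict(theta)
        except (IntegrationError, DivergenceError):
            return float("inf")
        return fitness(pred, self.data)

    def predict(self, theta: np.ndarray) -> Trajectory:
        """Deterministic model output at ``theta`` on the data grid."""
        if self.model.kind == "ode":
            return integrate(
                self.model, theta, self.data.times, self.initial_state,
                rtol=self.rtol, atol=self.atol,
            )
        return simulate_discrete_map(
            self.model, theta, n_steps=len(self.data.times) - 1,
            noise=False, initial_state=self.initial_state,
        )


def evaluate_params(
    model: DynamicalModel,
    params: ParameterSet | np.ndarray,
    data: Dataset,
    initial_state: np.ndarray | None = None,
) -> float:
    """One-shot fitness of ``params`` for ``model`` against ``data``."""
    theta = params.values if isinstance(params, ParameterSet) else np.asarray(
        params, float)
    return Objective(model, data, initial_state)(theta)
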