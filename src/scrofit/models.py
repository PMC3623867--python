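"""Benchmark dynamical models and the trajectory/parameter containers.

The module defines the three built-in benchmark systems used throughout the
package — a two-parameter nonlinear discrete map, a four-state synthetic
transcriptional oscillator, and a six-state / seventeen-parameter
extracellular protease production network — plus a small registry so models
are addressable by id and loadable from a declarative specification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint

from . import _kernels

__all__ = [
    "ParameterSet",
    "Trajectory",
    "DynamicalModel",
    "DivergenceError",
    "IntegrationError",
    "get_model",
    "register_model",
    "list_models",
    "model_from_spec",
    "simulate_discrete_map",
    "ode_rhs",
    "integrate",
    "simulate",
]


class DivergenceError(RuntimeError):
    """A discrete-map orbit left the finite range."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a finite trajectory."""


@dataclass
class ParameterSet:
    """Named parameter vector with box bounds.

    ``values`` must lie inside ``[lower, upper]`` componentwise; bounds are
    the search space handed to the optimizers.
    """

    names: list[str]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        d = len(self.names)
        if not (self.values.shape == self.lower.shape == self.upper.shape == (d,)):
            raise ValueError("names, values, lower and upper must share one length")
        if d < 1:
            raise ValueError("at least one parameter is required")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        if np.any(self.values < self.lower - 1e-12) or np.any(
            self.values > self.upper + 1e-12
        ):
            raise ValueError("values must lie within the bounds")

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def with_values(self, values: Sequence[float]) -> "ParameterSet":
        return replace(self, values=np.asarray(values, dtype=float))

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(values, self.lower, self.upper)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "values": self.values.tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
        }


@dataclass
class Trajectory:
    """Model output sampled on a time grid: ``states[i, s]`` at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray
    state_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must have one row per time point")
        if self.states.shape[1] != len(self.state_names):
            raise ValueError("states must have one column per state name")

    @property
    def n_states(self) -> int:
        return len(self.state_names)


@dataclass
class DynamicalModel:
    """A benchmark system: either an ODE right-hand side or a discrete map.

    ``dynamics`` is ``f(y, t, p) -> dy/dt`` for ODE models and an orbit
    kernel ``f(x0, p, n_steps, w) -> (orbit, bad_index)`` for discrete maps.
    ``process_noise`` (per-state standard deviations) only applies to
    discrete-map models, where noise enters the state update itself.
    """

    id: str
    kind: str  # "ode" | "discrete-map"
    state_names: list[str]
    dynamics: Callable
    parameter_space: ParameterSet
    default_initial_state: np.ndarray
    default_times: np.ndarray
    process_noise: np.ndarray | None = None
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.default_initial_state = np.asarray(self.default_initial_state, float)
        self.default_times = np.asarray(self.default_times, float)
        if self.kind not in ("ode", "discrete-map"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if np.any(np.diff(self.default_times) <= 0):
            raise ValueError("default_times must be strictly increasing")

    @property
    def n_states(self) -> int:
        return len(self.state_names)


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

def _nonlinear_map() -> DynamicalModel:
    space = ParameterSet(
        names=["a", "b"],
        values=np.array([0.8, 1.5]),
        lower=np.array([0.0, 0.0]),
        upper=np.array([2.0, 3.0]),
    )
    return DynamicalModel(
        id="simulated_nonlinear",
        kind="discrete-map",
        state_names=["x1", "x2"],
        dynamics=_kernels.nonlinear_map_orbit,
        parameter_space=space,
        default_initial_state=np.array([0.1, 0.1]),
        default_times=np.arange(801, dtype=float),
        process_noise=np.array([0.01, 0.01]),
    )


def _oscillator() -> DynamicalModel:
    # Two bistable-switch transcriptional oscillator; thresholds in uM,
    # Hill coefficients and the shared production rate dimensionless in
    # units of the RNA decay rate.  The default grid spans roughly two
    # oscillation periods (period ~6.6 time units at the true parameters).
    space = ParameterSet(
        names=["K_A", "n_A", "K_B", "n_B", "k"],
        values=np.array([0.57, 1.5, 2.5, 6.5, 6.5]),
        lower=np.array([0.1, 0.5, 0.5, 3.0, 3.0]),
        upper=np.array([3.0, 3.0, 5.0, 10.0, 10.0]),
    )
    return DynamicalModel(
        id="oscillator",
        kind="ode",
        state_names=["A", "B", "C", "D"],
        dynamics=_kernels.oscillator_rhs,
        parameter_space=space,
        default_initial_state=np.array([1.0, 1.0, 0.5, 0.5]),
        default_times=np.linspace(0.0, 13.0, 100),
        units={"K_A": "uM", "K_B": "uM"},
    )


def _protease() -> DynamicalModel:
    # 17-parameter DegS-DegU network; values and bounds as tabulated for the
    # extracellular protease production model (rates s^-1, syntheses #/s,
    # p14 dimensionless).  The default grid spans the transient up to the
    # slow mDegU saturation (~1/p12 seconds).
    values = np.array(
        [0.04, 0.0004, 0.15, 0.04, 0.004, 0.025, 0.1, 7.0, 0.02, 12.0,
         7.0, 0.0099, 0.4, 0.004, 0.048, 7.0, 7.0]
    )
    lower = np.array(
        [0.02, 0.0002, 0.05, 0.02, 0.002, 0.010, 0.05, 5.0, 0.005, 10.0,
         5.0, 0.0001, 0.2, 0.002, 0.02, 5.0, 5.0]
    )
    upper = np.array(
        [0.06, 0.0006, 0.30, 0.06, 0.006, 0.035, 0.20, 9.0, 0.04, 14.0,
         9.0, 0.0100, 0.6, 0.006, 0.06, 9.0, 9.0]
    )
    names = [f"p{i}" for i in range(1, 18)]
    units = {n: "s^-1" for n in names}
    units.update({"p9": "#/s", "p13": "#/s", "p15": "#/s", "p14": ""})
    return DynamicalModel(
        id="protease",
        kind="ode",
        state_names=["AprE", "DegU", "DegUP", "Dim", "mAprE", "mDegU"],
        dynamics=_kernels.protease_rhs,
        parameter_space=ParameterSet(names, values, lower, upper),
        default_initial_state=np.zeros(6) + np.array([0, 0.1, 0, 0, 0, 0]),
        default_times=np.linspace(0.0, 600.0, 100),
        units=units,
    )


_REGISTRY: dict[str, Callable[[], DynamicalModel]] = {
    "simulated_nonlinear": _nonlinear_map,
    "oscillator": _oscillator,
    "protease": _protease,
}


def get_model(model_id: str) -> DynamicalModel:
    """Return a fresh instance of a registered model."""
    try:
        return _REGISTRY[model_id]()
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_model(model_id: str, factory: Callable[[], DynamicalModel]) -> None:
    _REGISTRY[model_id] = factory


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def model_from_spec(spec: dict) -> DynamicalModel:
    """Build a user-defined ODE model from a declarative specification.

    ``spec`` needs: ``id``, ``states`` (names), ``parameters`` (list of
    ``{name, value, lower, upper}``), ``equations`` (one expression per
    state in terms of state and parameter names; numpy functions are exposed
    as ``exp``, ``log``, ``sqrt`` ...), and optionally ``initial_state``
    and ``times`` (``[t0, t1, n]``).
    """
    states = list(spec["states"])
    pnames = [p["name"] for p in spec["parameters"]]
    space = ParameterSet(
        names=pnames,
        values=np.array([p["value"] for p in spec["parameters"]], float),
        lower=np.array([p["lower"] for p in spec["parameters"]], float),
        upper=np.array([p["upper"] for p in spec["parameters"]], float),
    )
    exprs = [compile(e, f"<{spec.get('id', 'model')}:{s}>", "eval")
             for s, e in zip(states, spec["equations"])]
    allowed = {k: getattr(np, k) for k in
               ("exp", "log", "log10", "sqrt", "sin", "cos", "tanh", "abs")}
    allowed["pi"] = np.pi

    def rhs(y, t, p):
        env = dict(allowed)
        env["t"] = t
        env.update(zip(states, y))
        env.update(zip(pnames, p))
        return np.array([eval(e, {"__builtins__": {}}, env) for e in exprs])

    t0, t1, n = spec.get("times", [0.0, 10.0, 100])
    return DynamicalModel(
        id=spec.get("id", "user"),
        kind="ode",
        state_names=states,
        dynamics=rhs,
        parameter_space=space,
        default_initial_state=np.asarray(
            spec.get("initial_state", np.zeros(len(states))), float
        ),
        default_times=np.linspace(float(t0), float(t1), int(n)),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_discrete_map(
    model: DynamicalModel,
    params: ParameterSet | np.ndarray | None = None,
    n_steps: int = 800,
    seed: int | None = None,
    noise: bool = True,
    initial_state: np.ndarray | None = None,
) -> Trajectory:
    """Iterate a discrete-map model for ``n_steps`` steps.

    With ``noise=True`` and a ``process_noise`` spec on the model, iid
    zero-mean Gaussian process noise is injected into every state update
    (reproducible per ``seed``); otherwise the orbit is deterministic.
    Raises :class:`DivergenceError` if the orbit leaves the finite range.
    """
    if model.kind != "discrete-map":
        raise ValueError("simulate_discrete_map requires a discrete-map model")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    theta = _theta(model, params)
    x0 = model.default_initial_state if initial_state is None else np.asarray(
        initial_state, float)
    if noise and model.process_noise is not None:
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((n_steps, model.n_states)) * model.process_noise
    else:
        w = np.zeros((n_steps, model.n_states))
    orbit, bad = model.dynamics(x0, theta, n_steps, w)
    if bad >= 0:
        raise DivergenceError(f"orbit diverged at step {bad}")
    times = np.arange(n_steps + 1, dtype=float)
    return Trajectory(times, orbit, list(model.state_names))


def ode_rhs(
    model: DynamicalModel, state: np.ndarray, params: ParameterSet | np.ndarray,
    t: float = 0.0,
) -> np.ndarray:
    """Evaluate the model's derivative vector at one state point."""
    if model.kind != "ode":
        raise ValueError("ode_rhs requires an ODE model")
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_states,):
        raise ValueError(
            f"state must have length {model.n_states}, got {state.shape}"
        )
    return np.asarray(model.dynamics(state, t, _theta(model, params)), float)


def integrate(
    model: DynamicalModel,
    params: ParameterSet | np.ndarray | None = None,
    times: np.ndarray | None = None,
    initial_state: np.ndarray | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate an ODE model over a strictly increasing time grid.

    Uses LSODA (adaptive stiff/non-stiff switching) and samples the solution
    exactly at ``times``.  Raises :class:`IntegrationError` on solver
    failure or non-finite output.
    """
    if model.kind != "ode":
        raise ValueError("integrate requires an ODE model")
    t = model.default_times if times is None else np.asarray(times, float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    x0 = model.default_initial_state if initial_state is None else np.asarray(
        initial_state, float)
    theta = _theta(model, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = odeint(
            model.dynamics, x0, t, args=(theta,), rtol=rtol, atol=atol,
            mxstep=5000, full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(out)):
        t_fail = float(info.get("tcur", [t[-1]])[-1])
        raise IntegrationError(f"ODE integration failed near t={t_fail:g}")
    return Trajectory(t, out, list(model.state_names))


def simulate(
    model: DynamicalModel,
    params: ParameterSet | np.ndarray | None = None,
    times: np.ndarray | None = None,
    initial_state: np.ndarray | None = None,
    seed: int | None = None,
    noise: bool = False,
) -> Trajectory:
    """Kind-dispatching front end: integrate ODE models, iterate maps."""
    if model.kind == "ode":
        return integrate(model, params, times, initial_state)
    t = model.default_times if times is None else np.asarray(times, float)
    return simulate_discrete_map(
        model, params, n_steps=len(t) - 1, seed=seed, noise=noise,
        initial_state=initial_state,
    )


def _theta(model: DynamicalModel, params) -> np.ndarray:
    if params is None:
        return model.parameter_space.values.copy()
    if isinstance(params, ParameterSet):
        return params.values.copy()
    theta = np.asarray(params, dtype=float)
    if theta.shape != (model.parameter_space.dim,):
        raise ValueError(
            f"expected {model.parameter_space.dim} parameters, got {theta.shape}"
        )
    return theta
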