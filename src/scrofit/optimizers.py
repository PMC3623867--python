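"""Population-based estimators: DE, firefly (FA), chemical reaction
optimization (CRO) and the swarm/CRO hybrid (S-CRO).

All four share one substrate: a population of candidate parameter vectors
("molecules") carrying a potential energy (the least-squares fitness) and,
for the CRO family, a kinetic energy — a per-molecule tolerance budget that
lets a molecule accept a worse position, is partially dissipated on every
accepted reaction, and is never created by a reaction.  The hybrid sorts the
population each iteration, applies firefly attraction moves followed by CRO
reaction operators to the strong half, and re-seeds the weak half with a
best-guided random update.

Every closed-form rule (attractiveness, move, energy bookkeeping, operator
selection) lives in one small function here so each can be amended in a
single place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .models import DynamicalModel, ParameterSet
from .objective import Dataset, Objective

__all__ = [
    "Molecule",
    "Population",
    "OptimizerConfig",
    "OptimizationResult",
    "ALGORITHMS",
    "fa_distance",
    "fa_attractiveness",
    "fa_move",
    "cro_on_wall",
    "cro_decompose",
    "cro_inter_collision",
    "cro_synthesis",
    "select_cro_operator",
    "split_population",
    "random_update_weak",
    "init_population",
    "scro_iterate",
    "minimize",
    "run",
]

ALGORITHMS = ("de", "fa", "cro", "scro")


@dataclass
class Molecule:
    """One candidate solution: position in parameter space, potential energy
    (its fitness) and kinetic energy (its CRO tolerance budget)."""

    position: np.ndarray
    pe: float
    ke: float = 0.0

    def copy(self) -> "Molecule":
        return Molecule(self.position.copy(), self.pe, self.ke)


@dataclass
class Population:
    molecules: list[Molecule]
    best: Molecule  # elitist snapshot, never worse than any current member

    def refresh_best(self) -> None:
        cur = min(self.molecules, key=lambda m: m.pe)
        if cur.pe < self.best.pe:
            self.best = cur.copy()

    @property
    def size(self) -> int:
        return len(self.molecules)


@dataclass
class OptimizerConfig:
    """Run settings shared by all four algorithms.

    FA coefficients: ``beta0`` initial attractiveness, ``mu`` light
    absorption, ``alpha`` random-step scale (as a fraction of the bound
    width, decayed by ``step_decay`` each iteration).  CRO coefficients:
    ``loss_rate`` bounds the kinetic-energy fraction retained on a bounce,
    ``initial_ke`` endows fresh molecules, ``on_wall_scale`` /
    ``decompose_scale`` are perturbation kernels as fractions of the bound
    width.  ``split_fraction`` is the share of the sorted population treated
    as "potential" solutions by the hybrid.
    """

    algorithm: str = "scro"
    np_size: int = 20
    iterations: int = 100
    beta0: float = 0.5
    mu: float = 0.01
    alpha: float = 0.2
    step_decay: float = 0.97
    loss_rate: float = 0.1
    initial_ke: float = 1000.0
    de_f: float = 2.5
    de_cr: float = 1.0
    split_fraction: float = 0.5
    on_wall_scale: float = 0.01
    decompose_scale: float = 0.5
    fa_sweep: str = "pairwise"  # or "best": attract only to the best neighbour
    fa_alpha_decay: float = 1.0  # standalone FA keeps a constant step (canonical)
    scro_sweep: str = "best"  # attraction rule inside the hybrid
    scro_kernel: str = "spread"  # hybrid bounce kernel: "spread" or "width"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"expected one of {ALGORITHMS}")
        if self.np_size < 2:
            raise ValueError("population size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.loss_rate <= 1.0:
            raise ValueError("loss_rate must be in [0, 1]")
        if not 0.0 < self.split_fraction <= 1.0:
            raise ValueError("split_fraction must be in (0, 1]")
        if self.fa_sweep not in ("pairwise", "best"):
            raise ValueError("fa_sweep must be 'pairwise' or 'best'")
        if self.scro_sweep not in ("pairwise", "best"):
            raise ValueError("scro_sweep must be 'pairwise' or 'best'")
        if self.scro_kernel not in ("spread", "width"):
            raise ValueError("scro_kernel must be 'spread' or 'width'")


@dataclass
class OptimizationResult:
    best_params: ParameterSet
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration (non-increasing)
    n_evaluations: int
    seed: int | None
    algorithm: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_params": self.best_params.to_dict(),
            "best_fitness": self.best_fitness,
            "trace": self.trace.tolist(),
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# Firefly primitives
# ---------------------------------------------------------------------------

def fa_distance(xi: np.ndarray, xj: np.ndarray) -> float:
    """Euclidean distance between two solution vectors."""
    return float(np.linalg.norm(np.asarray(xi, float) - np.asarray(xj, float)))


def fa_attractiveness(r: float, beta0: float, mu: float) -> float:
    """Attractiveness decaying with distance: ``beta0 * exp(-mu * r**2)``."""
    return beta0 * math.exp(-mu * r * r)


def fa_move(
    xi: np.ndarray,
    xj: np.ndarray,
    beta: float,
    alpha: float,
    space: ParameterSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move ``xi`` toward the brighter ``xj``:
    ``x + beta*(xj - x) + alpha*width*(u - 1/2)`` with per-coordinate
    uniform ``u``, clamped to the bounds."""
    u = rng.random(len(xi))
    new = xi + beta * (xj - xi) + alpha * space.width * (u - 0.5)
    return space.clip(new)


# ---------------------------------------------------------------------------
# CRO reaction operators
#
# Every operator obeys the same energy account: a candidate is accepted only
# if the incoming potential + kinetic energy can pay for the candidate's
# potential energy, and the residual is (partially) retained as new kinetic
# energy.  Reactions therefore never increase the total energy of the
# molecules involved.
# ---------------------------------------------------------------------------

def _fresh_ke(residual: float, initial_ke: float) -> float:
    # Non-finite energies (failed simulations) cannot support a meaningful
    # budget; re-endow the default instead of propagating inf.
    return residual if np.isfinite(residual) else initial_ke


def cro_on_wall(
    m: Molecule,
    space: ParameterSet,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    loss_rate: float,
    step: float | np.ndarray = 0.01,
    initial_ke: float = 1000.0,
) -> bool:
    """On-wall collision: a small Gaussian bounce of one molecule.

    ``step`` is the absolute per-coordinate standard deviation of the
    bounce.  Accepted iff ``PE_new <= PE + KE``; on acceptance
    ``KE_new = (PE + KE - PE_new) * q`` with ``q ~ U(loss_rate, 1)`` (the
    remainder is dissipated).  Returns True if the move was accepted.
    """
    cand = space.clip(m.position + rng.standard_normal(space.dim) * step)
    pe_new = objective(cand)
    if pe_new > m.pe + m.ke:
        return False
    q = rng.uniform(loss_rate, 1.0)
    residual = m.pe + m.ke - pe_new
    m.position = cand
    m.pe = pe_new
    m.ke = _fresh_ke(residual, initial_ke) * q
    return True


def cro_decompose(
    m: Molecule,
    space: ParameterSet,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    scale: float = 0.5,
    initial_ke: float = 1000.0,
) -> tuple[Molecule, Molecule] | None:
    """Decomposition: one molecule diffuses into two far-apart offspring.

    Executed only if the parent's total energy covers both offspring
    potential energies; the residual is split between them by a uniform
    ``k`` and ``1 - k``.  Returns the offspring pair, or None on rejection.
    """
    x1 = space.clip(m.position + rng.standard_normal(space.dim) * scale * space.width)
    x2 = space.clip(m.position + rng.standard_normal(space.dim) * scale * space.width)
    pe1 = objective(x1)
    pe2 = objective(x2)
    if pe1 + pe2 > m.pe + m.ke:
        return None
    k = rng.random()
    residual = _fresh_ke(m.pe + m.ke - pe1 - pe2, initial_ke)
    return Molecule(x1, pe1, residual * k), Molecule(x2, pe2, residual * (1.0 - k))


def cro_inter_collision(
    m1: Molecule,
    m2: Molecule,
    space: ParameterSet,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    step: float | np.ndarray = 0.01,
    initial_ke: float = 1000.0,
) -> bool:
    """Inter-molecular collision: both molecules bounce with small
    perturbations (``step`` = absolute per-coordinate s.d.); accepted iff
    the pair's total energy covers both new potential energies, with the
    residual redistributed by a uniform share.
    """
    c1 = space.clip(m1.position + rng.standard_normal(space.dim) * step)
    c2 = space.clip(m2.position + rng.standard_normal(space.dim) * step)
    pe1 = objective(c1)
    pe2 = objective(c2)
    total = m1.pe + m1.ke + m2.pe + m2.ke
    if pe1 + pe2 > total:
        return False
    p = rng.random()
    residual = _fresh_ke(total - pe1 - pe2, initial_ke)
    m1.position, m1.pe, m1.ke = c1, pe1, residual * p
    m2.position, m2.pe, m2.ke = c2, pe2, residual * (1.0 - p)
    return True


def cro_synthesis(
    m1: Molecule,
    m2: Molecule,
    space: ParameterSet,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    initial_ke: float = 1000.0,
) -> Molecule | None:
    """Synthesis: combine two molecules into one by a random blend along
    the line through both parents (``x1 + lam*(x2 - x1)`` with one
    ``lam ~ U(-0.5, 1.5)`` shared by all coordinates, clamped to bounds),
    so the product explores the direction the parents span.  Accepted iff
    the combined energy covers the product's potential energy; the product
    inherits the whole residual as kinetic energy, so it starts with a
    substantially larger budget than either parent had."""
    lam = rng.uniform(-0.5, 1.5)
    x = space.clip(m1.position + lam * (m2.position - m1.position))
    pe = objective(x)
    total = m1.pe + m1.ke + m2.pe + m2.ke
    if pe > total:
        return None
    return Molecule(x, pe, _fresh_ke(total - pe, initial_ke))


def select_cro_operator(r: float) -> str:
    """Map one uniform draw to a reaction operator.

    ``r <= 0.33`` on-wall; ``0.33 < r < 0.5`` decomposition;
    ``0.5 <= r <= 0.7`` synthesis; ``r > 0.7`` inter-molecular collision.
    """
    if r <= 0.33:
        return "on_wall"
    if r < 0.5:
        return "decompose"
    if r <= 0.7:
        return "synthesis"
    return "inter"


# ---------------------------------------------------------------------------
# Population plumbing
# ---------------------------------------------------------------------------

def init_population(
    space: ParameterSet,
    np_size: int,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    initial_ke: float = 1000.0,
) -> Population:
    """Uniform random initialization within the box bounds."""
    mols = []
    for _ in range(np_size):
        x = space.lower + rng.random(space.dim) * space.width
        mols.append(Molecule(x, objective(x), initial_ke))
    best = min(mols, key=lambda m: m.pe).copy()
    return Population(mols, best)


def split_population(
    pop: Population, split_fraction: float
) -> tuple[list[Molecule], list[Molecule]]:
    """Sort ascending by fitness (stable, so ties keep insertion order) and
    split: the best ``ceil(split_fraction * NP)`` form the potential group."""
    order = sorted(range(pop.size), key=lambda i: pop.molecules[i].pe)
    k = math.ceil(split_fraction * pop.size)
    p1 = [pop.molecules[i] for i in order[:k]]
    p2 = [pop.molecules[i] for i in order[k:]]
    return p1, p2


def random_update_weak(
    m: Molecule,
    best: Molecule,
    space: ParameterSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best-guided random restart for a weak solution:
    ``x + r1*(best - x) + r2*(z - x)`` per coordinate, with fresh uniform
    ``r1, r2`` and ``z`` uniform in the bounds.  With the perturbation
    coefficient at zero the update contracts toward the current best."""
    r1 = rng.random(space.dim)
    r2 = rng.random(space.dim)
    z = space.lower + rng.random(space.dim) * space.width
    new = m.position + r1 * (best.position - m.position) + r2 * (z - m.position)
    return space.clip(new)


def _restore_np(
    pop: Population,
    np_size: int,
    space: ParameterSet,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    initial_ke: float,
) -> None:
    """Truncate (drop worst) or refill (best-guided clones) to NP."""
    if pop.size > np_size:
        pop.molecules.sort(key=lambda m: m.pe)
        del pop.molecules[np_size:]
    while pop.size < np_size:
        x = random_update_weak(pop.best, pop.best, space, rng)
        pop.molecules.append(Molecule(x, objective(x), initial_ke))


def _fa_sweep(
    mols: list[Molecule],
    space: ParameterSet,
    cfg: OptimizerConfig,
    alpha_t: float,
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
    mode: str = "pairwise",
) -> None:
    """Firefly attraction pass over ``mols``.

    ``mode="pairwise"`` is the classic rule (move toward every brighter
    neighbour); ``"best"`` attracts each firefly only to the brightest one,
    which applies a single contraction per firefly per iteration and slows
    population collapse.  Brightness comparisons use the fitness values
    from the start of the sweep; each firefly is re-evaluated once after
    its full set of moves, which keeps the evaluation budget at one per
    firefly per iteration.
    """
    pe0 = [m.pe for m in mols]
    x0 = [m.position.copy() for m in mols]
    for i, m in enumerate(mols):
        moved = False
        if mode == "best":
            js = [int(np.argmin(pe0))]
        else:
            js = range(len(mols))
        for j in js:
            if pe0[j] < pe0[i]:
                beta = fa_attractiveness(
                    fa_distance(m.position, x0[j]), cfg.beta0, cfg.mu
                )
                m.position = fa_move(m.position, x0[j], beta, alpha_t, space, rng)
                moved = True
        if moved:
            m.pe = objective(m.position)


def _cro_step(
    mols: list[Molecule],
    space: ParameterSet,
    cfg: OptimizerConfig,
    step: Callable[[Molecule], np.ndarray],
    rng: np.random.Generator,
    objective: Callable[[np.ndarray], float],
) -> list[Molecule]:
    """One CRO reaction pass over ``mols`` (mutated in place; appended
    offspring are returned as part of the new molecule list).

    ``step`` maps a molecule to the absolute bounce kernel handed to the
    small-perturbation operators.  Operators are drawn per molecule by
    :func:`select_cro_operator`; partners for two-molecule reactions are
    drawn uniformly among the other live molecules.  Decomposition grows
    and synthesis shrinks the list.
    """
    alive = [True] * len(mols)
    extra: list[Molecule] = []
    for i in range(len(mols)):
        if not alive[i]:
            continue
        op = select_cro_operator(rng.random())
        partners = [j for j in range(len(mols)) if alive[j] and j != i]
        if op in ("inter", "synthesis") and not partners:
            op = "on_wall"
        if op == "on_wall":
            cro_on_wall(mols[i], space, rng, objective, cfg.loss_rate,
                        step=step(mols[i]), initial_ke=cfg.initial_ke)
        elif op == "decompose":
            off = cro_decompose(mols[i], space, rng, objective,
                                scale=cfg.decompose_scale,
                                initial_ke=cfg.initial_ke)
            if off is not None:
                mols[i] = off[0]
                extra.append(off[1])
        elif op == "inter":
            j = partners[rng.integers(len(partners))]
            cro_inter_collision(mols[i], mols[j], space, rng, objective,
                                step=step(mols[i]), initial_ke=cfg.initial_ke)
        else:  # synthesis
            j = partners[rng.integers(len(partners))]
            prod = cro_synthesis(mols[i], mols[j], space, rng, objective,
                                 initial_ke=cfg.initial_ke)
            if prod is not None:
                mols[i] = prod
                alive[j] = False
    return [m for m, a in zip(mols, alive) if a] + extra


def scro_iterate(
    pop: Population,
    cfg: OptimizerConfig,
    objective: Callable[[np.ndarray], float],
    space: ParameterSet,
    rng: np.random.Generator,
    iteration: int = 0,
    cro_enabled: bool = True,
) -> Population:
    """One hybrid iteration: sort/split, firefly moves then CRO reactions on
    the potential group, best-guided random update of the weak group, merge,
    restore NP and refresh the elitist best."""
    decay = cfg.step_decay ** iteration
    p1, p2 = split_population(pop, cfg.split_fraction)
    _fa_sweep(p1, space, cfg, cfg.alpha * decay, rng, objective,
              mode=cfg.scro_sweep)
    if cro_enabled:
        p1 = _cro_step(p1, space, cfg,
                       _kernel_step(p1, space, cfg, decay, pop.best),
                       rng, objective)
    for m in p2:
        m.position = random_update_weak(m, pop.best, space, rng)
        m.pe = objective(m.position)
        m.ke = cfg.initial_ke
    pop.molecules = p1 + p2
    pop.refresh_best()
    _restore_np(pop, cfg.np_size, space, rng, objective, cfg.initial_ke)
    pop.refresh_best()
    return pop


# ---------------------------------------------------------------------------
# Full algorithms
# ---------------------------------------------------------------------------

def _kernel_step(mols, space: ParameterSet, cfg: OptimizerConfig,
                 decay: float, best: Molecule | None = None):
    """Bounce-kernel factory for the small-perturbation reactions: returns
    a function mapping a molecule to its absolute per-coordinate step.

    ``"width"``: one fixed fraction of the bound width for every molecule,
    geometrically decayed per iteration (the canonical choice).
    ``"spread"``: half the molecule's elementwise distance to the current
    best solution, floored by a decayed sliver of the width — molecules far
    from the incumbent take exploratory bounces while molecules near it
    refine on the scale that still separates them, so the kernel adapts
    per molecule and shrinks automatically as the population converges.
    """
    if cfg.scro_kernel == "spread" and best is not None:
        ref = best.position
        # floor: the spread of the better half keeps bounces exploring the
        # directions the population still disagrees about; the decayed
        # width sliver keeps the kernel alive once fully converged
        half = sorted(mols, key=lambda m: m.pe)[:max(2, len(mols) // 2)]
        spread = np.std([m.position for m in half], axis=0)
        floor = np.maximum(np.maximum(0.5 * spread,
                                      1e-4 * decay * space.width), 1e-12)

        def step(m: Molecule) -> np.ndarray:
            return np.maximum(0.5 * np.abs(m.position - ref), floor)

        return step
    fixed = cfg.on_wall_scale * decay * space.width
    return lambda m: fixed


def _iterate_fa(pop, cfg, objective, space, rng, t):
    _fa_sweep(pop.molecules, space, cfg, cfg.alpha * cfg.fa_alpha_decay ** t,
              rng, objective, mode=cfg.fa_sweep)
    pop.refresh_best()


def _iterate_cro(pop, cfg, objective, space, rng, t):
    step = _kernel_step(pop.molecules, space, cfg, cfg.step_decay ** t,
                        pop.best)
    pop.molecules = _cro_step(pop.molecules, space, cfg, step, rng, objective)
    pop.refresh_best()
    _restore_np(pop, cfg.np_size, space, rng, objective, cfg.initial_ke)
    pop.refresh_best()


def _iterate_de(pop, cfg, objective, space, rng, t):
    """DE/rand/1/bin with greedy selection (crossover rate clamped to 1)."""
    cr = min(cfg.de_cr, 1.0)
    n = pop.size
    for i in range(n):
        if n >= 4:
            idx = rng.permutation(n - 1)[:3]
            idx[idx >= i] += 1
        else:  # tiny populations: sample donors with replacement
            idx = rng.integers(n, size=3)
        a, b, c = (pop.molecules[j].position for j in idx)
        mutant = space.clip(a + cfg.de_f * (b - c))
        cross = rng.random(space.dim) < cr
        cross[rng.integers(space.dim)] = True
        trial = np.where(cross, mutant, pop.molecules[i].position)
        pe = objective(trial)
        if pe <= pop.molecules[i].pe:
            pop.molecules[i] = Molecule(trial, pe, pop.molecules[i].ke)
    pop.refresh_best()


_ITERATES = {
    "scro": lambda pop, cfg, f, s, rng, t: scro_iterate(pop, cfg, f, s, rng, t),
    "fa": _iterate_fa,
    "cro": _iterate_cro,
    "de": _iterate_de,
}


def minimize(
    objective: Callable[[np.ndarray], float],
    space: ParameterSet,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Minimize an arbitrary objective over a box with the configured
    algorithm.  All randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counter = _Counting(objective)
    pop = init_population(space, config.np_size, rng, counter, config.initial_ke)
    step = _ITERATES[config.algorithm]
    trace = np.empty(config.iterations)
    for t in range(config.iterations):
        step(pop, config, counter, space, rng, t)
        trace[t] = pop.best.pe
    return OptimizationResult(
        best_params=space.with_values(pop.best.position),
        best_fitness=float(pop.best.pe),
        trace=trace,
        n_evaluations=counter.n,
        seed=config.seed,
        algorithm=config.algorithm,
        config=asdict(config),
    )


class _Counting:
    def __init__(self, fn):
        self.fn = fn
        self.n = getattr(fn, "n_evaluations", 0)

    def __call__(self, x):
        v = self.fn(x)
        self.n = getattr(self.fn, "n_evaluations", self.n + 1)
        return v


def run(
    model: DynamicalModel,
    data: Dataset,
    config: OptimizerConfig,
    algorithm: str | None = None,
    initial_state: np.ndarray | None = None,
    space: ParameterSet | None = None,
) -> OptimizationResult:
    """Estimate model parameters from a dataset.

    Builds the least-squares objective for ``model`` against ``data`` and
    minimizes it with the selected algorithm (``config.algorithm`` unless
    overridden).  ``space`` replaces the model's parameter space when some
    parameters are fixed (e.g. ablated model variants).
    """
    if algorithm is not None:
        config = OptimizerConfig(**{**asdict(config), "algorithm": algorithm})
    obj = Objective(model, data, initial_state)
    return minimize(obj, space if space is not None else model.parameter_space,
                    config)
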