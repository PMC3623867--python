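import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scrofit as sf
from scrofit import optimizers as op
from scrofit.optimizers import (Molecule, OptimizerConfig, cro_decompose,
                                cro_inter_collision, cro_on_wall,
                                cro_synthesis, fa_attractiveness, fa_distance,
                                fa_move, init_population, minimize,
                                random_update_weak, scro_iterate,
                                select_cro_operator, split_population)

vec3 = st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=3)


# ---------------------------------------------------------------------------
# firefly primitives
# ---------------------------------------------------------------------------

def test_distance_basics():
    assert fa_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert fa_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)


@settings(derandomize=True, max_examples=50)
@given(vec3, vec3, vec3)
def test_distance_triangle_inequality(a, b, c):
    a, b, c = map(np.array, (a, b, c))
    assert fa_distance(a, c) <= fa_distance(a, b) + fa_distance(b, c) + 1e-9


def test_attractiveness_closed_form():
    assert fa_attractiveness(0.0, 0.5, 0.01) == 0.5
    # beta0=0.5, mu=0.01, r=10 -> 0.5/e
    assert fa_attractiveness(10.0, 0.5, 0.01) == pytest.approx(
        0.5 * math.exp(-1.0))
    betas = [fa_attractiveness(r, 0.5, 0.01) for r in range(21)]
    assert all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))


def test_move_degenerate_coefficients(box3, rng):
    xi, xj = np.array([1.0, -2.0, 0.5]), np.array([-3.0, 4.0, 1.0])
    np.testing.assert_allclose(fa_move(xi, xj, 1.0, 0.0, box3, rng), xj)
    np.testing.assert_allclose(fa_move(xi, xj, 0.0, 0.0, box3, rng), xi)


def test_move_respects_bounds_under_extreme_coefficients(box3, rng):
    for _ in range(10_000):
        beta = rng.uniform(-3, 4)
        alpha = rng.uniform(0, 5)
        xi = box3.lower + rng.random(3) * box3.width
        xj = box3.lower + rng.random(3) * box3.width
        out = fa_move(xi, xj, beta, alpha, box3, rng)
        assert np.all(out >= box3.lower) and np.all(out <= box3.upper)


# ---------------------------------------------------------------------------
# CRO reaction operators
# ---------------------------------------------------------------------------

def _sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def test_on_wall_rejection_leaves_molecule_unchanged(box3, rng):
    m = Molecule(np.array([1.0, 1.0, 1.0]), pe=3.0, ke=0.0)
    before = m.copy()
    accepted = cro_on_wall(m, box3, rng, lambda x: 1e9, loss_rate=0.1)
    assert not accepted
    np.testing.assert_array_equal(m.position, before.position)
    assert (m.pe, m.ke) == (before.pe, before.ke)


def test_on_wall_with_unit_loss_rate_conserves_energy(box3, rng):
    # loss_rate = 1 forces q = 1: a lossless bounce
    m = Molecule(np.array([1.0, 1.0, 1.0]), pe=_sphere([1, 1, 1]), ke=5.0)
    total = m.pe + m.ke
    assert cro_on_wall(m, box3, rng, _sphere, loss_rate=1.0, step=0.05)
    assert m.pe + m.ke == pytest.approx(total)


def test_synthesis_boundary_gives_zero_kinetic_energy(box3, rng):
    m1 = Molecule(np.array([1.0, 0.0, 0.0]), pe=2.0, ke=1.0)
    m2 = Molecule(np.array([0.0, 1.0, 0.0]), pe=3.0, ke=4.0)
    prod = cro_synthesis(m1, m2, box3, rng, lambda x: 10.0)
    assert prod is not None
    assert prod.ke == pytest.approx(0.0)


def test_synthesis_budget_dominates_parents_when_fit_improves(box3, rng):
    # PE_new <= min(PE1, PE2)  =>  KE_new >= max(KE1, KE2)
    m1 = Molecule(np.array([1.0, 0.0, 0.0]), pe=2.0, ke=1.5)
    m2 = Molecule(np.array([0.0, 1.0, 0.0]), pe=3.0, ke=0.5)
    prod = cro_synthesis(m1, m2, box3, rng, lambda x: 1.9)
    assert prod is not None
    assert prod.ke >= max(m1.ke, m2.ke)


def test_decompose_rejected_without_energy(box3, rng):
    m = Molecule(np.zeros(3), pe=0.0, ke=0.0)
    assert cro_decompose(m, box3, rng, lambda x: 1.0) is None


def test_inter_collision_gate_failure_leaves_pair_unchanged(box3, rng):
    m1 = Molecule(np.ones(3), pe=3.0, ke=0.0)
    m2 = Molecule(-np.ones(3), pe=3.0, ke=0.0)
    b1, b2 = m1.copy(), m2.copy()
    assert not cro_inter_collision(m1, m2, box3, rng, lambda x: 1e6)
    np.testing.assert_array_equal(m1.position, b1.position)
    np.testing.assert_array_equal(m2.position, b2.position)


def test_reaction_operators_never_create_energy(box3, rng):
    """Audit over 10^4 random operator applications: the total potential +
    kinetic energy of the molecules involved never increases."""
    for _ in range(10_000):
        kind = rng.integers(4)
        m1 = Molecule(box3.clip(rng.normal(0, 2, 3)), pe=0.0,
                      ke=float(rng.uniform(0, 4)))
        m1.pe = _sphere(m1.position)
        m2 = Molecule(box3.clip(rng.normal(0, 2, 3)), pe=0.0,
                      ke=float(rng.uniform(0, 4)))
        m2.pe = _sphere(m2.position)
        before = m1.pe + m1.ke + m2.pe + m2.ke
        if kind == 0:
            cro_on_wall(m1, box3, rng, _sphere, loss_rate=0.1, step=0.5)
            after = m1.pe + m1.ke + m2.pe + m2.ke
        elif kind == 1:
            off = cro_decompose(m1, box3, rng, _sphere)
            after = (m2.pe + m2.ke) + (
                sum(o.pe + o.ke for o in off) if off else m1.pe + m1.ke)
        elif kind == 2:
            cro_inter_collision(m1, m2, box3, rng, _sphere, step=0.5)
            after = m1.pe + m1.ke + m2.pe + m2.ke
        else:
            prod = cro_synthesis(m1, m2, box3, rng, _sphere)
            after = (prod.pe + prod.ke) if prod else before
        assert after <= before + 1e-9


def test_operator_selection_rule():
    assert select_cro_operator(0.2) == "on_wall"
    assert select_cro_operator(0.33) == "on_wall"
    assert select_cro_operator(0.4) == "decompose"
    assert select_cro_operator(0.65) == "synthesis"
    assert select_cro_operator(0.7) == "synthesis"
    assert select_cro_operator(0.71) == "inter"


def test_operator_selection_frequencies_match_interval_lengths(rng):
    draws = rng.random(1_000_000)
    tags = np.array([select_cro_operator(r) for r in draws[:100_000]])
    freqs = {t: np.mean(tags == t)
             for t in ("on_wall", "decompose", "synthesis", "inter")}
    assert freqs["on_wall"] == pytest.approx(0.33, abs=0.01)
    assert freqs["decompose"] == pytest.approx(0.17, abs=0.01)
    assert freqs["synthesis"] == pytest.approx(0.20, abs=0.01)
    assert freqs["inter"] == pytest.approx(0.30, abs=0.01)


# ---------------------------------------------------------------------------
# population plumbing
# ---------------------------------------------------------------------------

def test_init_population_within_bounds_and_seeded(box3):
    pop1 = init_population(box3, 16, np.random.default_rng(3), _sphere)
    pop2 = init_population(box3, 16, np.random.default_rng(3), _sphere)
    for m1, m2 in zip(pop1.molecules, pop2.molecules):
        np.testing.assert_array_equal(m1.position, m2.position)
        assert np.all(m1.position >= box3.lower)
        assert np.all(m1.position <= box3.upper)


def test_init_population_degenerate_bound_is_constant():
    space = sf.ParameterSet(["a", "b"], [1.0, 0.5], [1.0, 0.0], [1.0, 1.0])
    pop = init_population(space, 10, np.random.default_rng(0), _sphere)
    assert all(m.position[0] == 1.0 for m in pop.molecules)


def test_split_population_partitions_by_fitness(box3):
    mols = [Molecule(np.zeros(3), pe=v) for v in (3.0, 1.0, 2.0, 4.0)]
    pop = op.Population(mols, mols[1].copy())
    p1, p2 = split_population(pop, 0.5)
    assert sorted(m.pe for m in p1) == [1.0, 2.0]
    assert sorted(m.pe for m in p2) == [3.0, 4.0]
    assert len(p1) + len(p2) == 4
    p1, p2 = split_population(pop, 1.0)
    assert p2 == []


class _ScriptedRNG:
    """Plays back pre-arranged uniform draws for operator unit tests."""

    def __init__(self, arrays):
        self.arrays = list(arrays)

    def random(self, n=None):
        return np.asarray(self.arrays.pop(0))


def test_random_update_with_zero_perturbation_contracts_toward_best(box3):
    m = Molecule(np.array([4.0, -4.0, 2.0]), pe=10.0)
    best = Molecule(np.array([1.0, 1.0, 1.0]), pe=0.0)
    rng = _ScriptedRNG([
        np.full(3, 0.6),   # r1: pull toward best
        np.zeros(3),       # r2: perturbation coefficient zero
        np.full(3, 0.5),   # z draw (unused once r2 = 0)
    ])
    out = random_update_weak(m, best, box3, rng)
    d_before = np.linalg.norm(m.position - best.position)
    d_after = np.linalg.norm(out - best.position)
    assert d_after <= d_before
    np.testing.assert_allclose(out, m.position + 0.6 * (best.position
                                                        - m.position))


def test_random_update_stays_in_bounds(box3, rng):
    best = Molecule(np.array([4.9, -4.9, 0.0]), pe=0.0)
    for _ in range(10_000):
        m = Molecule(box3.lower + rng.random(3) * box3.width, pe=1.0)
        out = random_update_weak(m, best, box3, rng)
        assert np.all(out >= box3.lower) and np.all(out <= box3.upper)


# ---------------------------------------------------------------------------
# hybrid iteration
# ---------------------------------------------------------------------------

def _fresh_pop(space, cfg, seed=11):
    rng = np.random.default_rng(seed)
    return init_population(space, cfg.np_size, rng, _sphere,
                           cfg.initial_ke), rng


def test_scro_iterate_keeps_population_size_and_improves_best(box3):
    cfg = OptimizerConfig(np_size=12, iterations=5, seed=0)
    pop, rng = _fresh_pop(box3, cfg)
    for t in range(5):
        before = pop.best.pe
        scro_iterate(pop, cfg, _sphere, box3, rng, iteration=t)
        assert pop.size == cfg.np_size
        assert pop.best.pe <= before
    assert pop.best.pe <= min(m.pe for m in pop.molecules)


def test_scro_without_reactions_equals_attraction_plus_weak_update(box3):
    """Disabling the reaction step reduces one hybrid iteration to the
    firefly sweep on the strong half plus the weak-half random update."""
    cfg = OptimizerConfig(np_size=10, iterations=1, seed=4)
    pop_a, rng_a = _fresh_pop(box3, cfg, seed=21)
    scro_iterate(pop_a, cfg, _sphere, box3, rng_a, iteration=0,
                 cro_enabled=False)

    pop_b, rng_b = _fresh_pop(box3, cfg, seed=21)
    p1, p2 = split_population(pop_b, cfg.split_fraction)
    op._fa_sweep(p1, box3, cfg, cfg.alpha, rng_b, _sphere,
                 mode=cfg.scro_sweep)
    for m in p2:
        m.position = random_update_weak(m, pop_b.best, box3, rng_b)
        m.pe = _sphere(m.position)
        m.ke = cfg.initial_ke
    pop_b.molecules = p1 + p2
    pop_b.refresh_best()
    op._restore_np(pop_b, cfg.np_size, box3, rng_b, _sphere, cfg.initial_ke)
    pop_b.refresh_best()

    for ma, mb in zip(pop_a.molecules, pop_b.molecules):
        np.testing.assert_array_equal(ma.position, mb.position)
    assert pop_a.best.pe == pop_b.best.pe


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alg", ["de", "fa", "cro", "scro"])
def test_smoke_run_tiny_population(alg, box3):
    cfg = OptimizerConfig(algorithm=alg, np_size=2, iterations=1, seed=0)
    res = minimize(_sphere, box3, cfg)
    assert len(res.trace) == 1
    assert res.best_fitness == res.trace[-1]


def test_unknown_algorithm_rejected():
    with pytest.raises(ValueError, match="unknown algorithm"):
        OptimizerConfig(algorithm="annealing")


@pytest.mark.parametrize("alg", ["de", "fa", "cro", "scro"])
def test_trace_is_nonincreasing(alg, box3):
    cfg = OptimizerConfig(algorithm=alg, np_size=8, iterations=30, seed=2)
    res = minimize(_sphere, box3, cfg)
    assert np.all(np.diff(res.trace) <= 0)


def test_identical_seed_gives_identical_result(box3):
    cfg = OptimizerConfig(np_size=8, iterations=10, seed=99)
    r1 = minimize(_sphere, box3, cfg)
    r2 = minimize(_sphere, box3, cfg)
    np.testing.assert_array_equal(r1.best_params.values,
                                  r2.best_params.values)
    np.testing.assert_array_equal(r1.trace, r2.trace)
    assert r1.n_evaluations == r2.n_evaluations


# Convergence floors calibrated to each algorithm's refinement mechanics on
# a noiseless quadratic: DE and FA contract geometrically; the hybrid ends
# at its jitter floor; plain CRO plateaus once the population collapses onto
# the incumbent (its bounce kernel then has no scale left to exploit).
@pytest.mark.parametrize("alg, threshold, kw", [
    ("de", 1e-6, dict(de_f=0.7, de_cr=0.9)),
    ("fa", 1e-6, dict(fa_alpha_decay=0.93)),
    ("scro", 1e-4, dict(step_decay=0.95, initial_ke=0.0)),
    ("cro", 1e-1, dict(initial_ke=0.0)),
])
@pytest.mark.parametrize("seed", [7, 23])
def test_quadratic_oracle_convergence(alg, threshold, kw, seed, box3):
    target = np.array([1.2, -2.3, 0.7])

    def quad(x):
        return float(np.sum((x - target) ** 2))

    cfg = OptimizerConfig(algorithm=alg, np_size=20, iterations=200,
                          seed=seed, **kw)
    res = minimize(quad, box3, cfg)
    assert res.best_fitness < threshold
    np.testing.assert_allclose(res.best_params.values, target,
                               atol=10 * math.sqrt(threshold))
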