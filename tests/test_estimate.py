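"""Density estimation: pseudo-inverse, kernel, NNLS, l1 linear programming,
redundancy maps and physiological upper bounds."""

import numpy as np
import pytest

from ionrep.clamp import LinearSystem
from ionrep.estimate import (DensityBounds, DensityVector, KernelBasis,
                             density_upper_bounds, kernel_basis,
                             l1_minimal_solution, nonneg_particular_solution,
                             pseudo_inverse_solution, redundancy_map)
from ionrep.synthetic import toy_linear_system


def make_system(w, y):
    w = np.atleast_2d(np.asarray(w, float))
    y = np.asarray(y, float)
    return LinearSystem(W=w, Y=y, species=[f"s{i}" for i in range(w.shape[1])],
                        times=np.arange(w.shape[0], dtype=float),
                        v0=np.zeros(w.shape[0]))


# ------------------------------------------------------------ pseudo-inverse


def test_pinv_identity_returns_y():
    sys = make_system(np.eye(3), [1.0, -2.0, 3.0])
    np.testing.assert_allclose(pseudo_inverse_solution(sys).values,
                               [1.0, -2.0, 3.0], atol=1e-12)


def test_pinv_minimum_norm_split():
    sys = make_system([[1.0, 1.0]], [2.0])
    np.testing.assert_allclose(pseudo_inverse_solution(sys).values,
                               [1.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_pinv_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((6, 9))
    y = rng.standard_normal(6)
    sys = make_system(w, y)
    oracle = np.linalg.pinv(w) @ y
    np.testing.assert_allclose(pseudo_inverse_solution(sys).values, oracle,
                               atol=1e-8)


# ------------------------------------------------------------------- kernel


def test_kernel_empty_for_full_rank_square():
    sys = make_system(np.eye(4) + 0.1, np.ones(4))
    assert kernel_basis(sys).dimension == 0


def test_kernel_of_duplicated_column():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((8, 3))
    w = np.column_stack([a[:, 0], a[:, 0], a[:, 1], a[:, 2]])
    kb = kernel_basis(make_system(w, np.zeros(8)))
    assert kb.dimension == 1
    v = kb.basis[:, 0]
    expected = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2.0)
    assert abs(abs(v @ expected) - 1.0) < 1e-10


def test_kernel_vectors_annihilate_w(linear_system):
    kb = kernel_basis(linear_system)
    assert kb.dimension > 0
    wn = np.linalg.norm(linear_system.W)
    for j in range(kb.dimension):
        assert np.linalg.norm(linear_system.W @ kb.basis[:, j]) < 1e-7 * wn
    # columns orthonormal
    gram = kb.basis.T @ kb.basis
    np.testing.assert_allclose(gram, np.eye(kb.dimension), atol=1e-10)


# --------------------------------------------------------------------- NNLS


def test_nnls_boundary_optimum():
    sys = make_system([[1.0]], [-3.0])
    assert nonneg_particular_solution(sys).values[0] == 0.0


def test_nnls_equals_unconstrained_when_interior():
    rng = np.random.default_rng(2)
    w = rng.standard_normal((12, 4))
    kappa = np.array([0.5, 1.0, 2.0, 0.3])
    sys = make_system(w, w @ kappa)
    np.testing.assert_allclose(nonneg_particular_solution(sys).values, kappa,
                               atol=1e-8)


def test_nnls_matches_active_set_hand_solution():
    """3-variable toy with one forced-negative coordinate: the solution
    clamps it to zero and the free coordinates satisfy the KKT equations."""
    w = np.eye(3)
    y = np.array([1.0, -2.0, 3.0])
    sys = make_system(w, y)
    sol = nonneg_particular_solution(sys).values
    np.testing.assert_allclose(sol, [1.0, 0.0, 3.0], atol=1e-12)
    grad = w.T @ (w @ sol - y)
    assert np.all(grad[sol > 0] < 1e-10)       # stationarity on the support
    assert np.all(grad >= -1e-10)              # dual feasibility


# ----------------------------------------------------------------------- l1


def test_l1_with_empty_kernel_returns_particular():
    sys = make_system(np.eye(2), [1.0, 2.0])
    kb = kernel_basis(sys)
    kp = nonneg_particular_solution(sys)
    np.testing.assert_allclose(l1_minimal_solution(sys, kb, kp).values,
                               kp.values)


def test_l1_hand_solvable():
    """W=[1 2], Y=[2]: the cheapest non-negative solution is (0, 1)."""
    sys = make_system([[1.0, 2.0]], [2.0])
    kb = kernel_basis(sys)
    kp = DensityVector(sys.species, np.array([2.0, 0.0]))
    sol = l1_minimal_solution(sys, kb, kp)
    np.testing.assert_allclose(sol.values, [0.0, 1.0], atol=1e-9)
    assert sol.total == pytest.approx(1.0, abs=1e-9)


def test_l1_matches_grid_search_on_1d_kernel():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((6, 2))
    w = np.column_stack([a, a @ [0.6, -0.2]])  # third column in span
    kappa = np.array([1.0, 0.8, 0.5])
    sys = make_system(w, w @ kappa)
    kb = kernel_basis(sys)
    assert kb.dimension == 1
    kp = nonneg_particular_solution(sys)
    sol = l1_minimal_solution(sys, kb, kp)
    b = kb.basis[:, 0]
    # dense grid over the feasible gamma interval
    with np.errstate(divide="ignore"):
        lims = -kp.values / b
    lo = max(lims[b > 0].min(initial=np.inf) * 0 + lims[b < 0].max(initial=-1e6), -1e6)
    hi = min(lims[b > 0].min(initial=1e6), 1e6)
    grid = np.linspace(lo, hi, 200001)
    totals = kp.values.sum() + grid * b.sum()
    feas = np.all(kp.values[None, :] + grid[:, None] * b[None, :] >= -1e-12, axis=1)
    best = totals[feas].min()
    assert sol.total == pytest.approx(best, abs=1e-4)


def test_l1_beats_random_feasible_perturbations(linear_system):
    """l1 optimality: no random feasible kernel move lowers the total."""
    kb = kernel_basis(linear_system)
    kp = nonneg_particular_solution(linear_system)
    sol = l1_minimal_solution(linear_system, kb, kp)
    rng = np.random.default_rng(0)
    k = kb.dimension
    wins = 0
    for _ in range(1000):
        gamma = rng.standard_normal(k) * rng.choice([0.01, 0.1, 1.0])
        cand = kp.values + kb.basis @ gamma
        if np.all(cand >= 0) and cand.sum() < sol.total - 1e-6:
            wins += 1
    assert wins == 0


def test_planted_sparse_solution_bounds_l1(seed=7):
    sys, kappa, _ = toy_linear_system(n=9, m=20, rank=5, seed=seed)
    kb = kernel_basis(sys)
    kp = nonneg_particular_solution(sys)
    sol = l1_minimal_solution(sys, kb, kp)
    assert sol.total <= kappa.total + 1e-6
    assert sys.residual_rms(sol.values) < 1e-6


# ------------------------------------------------------------ redundancy map


def test_redundancy_row_reads_off_kernel_vector():
    """Kernel spanned by (1, -0.49, -0.45): the SK-family compensation
    signature appears directly as the echelon row."""
    vec = np.array([1.0, -0.49, -0.45])
    basis = (vec / np.linalg.norm(vec))[:, None]
    kb = KernelBasis(basis=basis, rank=2, singular_values=np.array([1.0, 0.5]),
                     species=["SK2", "SK3", "SK4"])
    rmap = redundancy_map(kb, "SK2")
    row = rmap.row_for("SK2")
    np.testing.assert_allclose(row, [1.0, -0.49, -0.45], atol=1e-12)


def test_pinned_species_flagged():
    basis = np.array([[0.0], [1.0]])
    kb = KernelBasis(basis=basis, rank=1, singular_values=np.array([1.0]),
                     species=["hERG", "other"])
    rmap = redundancy_map(kb, "hERG")
    assert rmap.pinned == ["hERG"]


def test_map_rows_stay_in_kernel(linear_system):
    kb = kernel_basis(linear_system)
    rmap = redundancy_map(kb, ["SK2", "BK"])
    wn = np.linalg.norm(linear_system.W)
    for row in rmap.rows:
        # rows may be huge (implausible compensations are the finding);
        # kernel membership is relative to the row magnitude
        rel = np.linalg.norm(linear_system.W @ row) / np.linalg.norm(row)
        assert rel < 1e-6 * wn
    for lead, row in zip(rmap.leading, rmap.rows):
        assert row[rmap.species.index(lead)] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- bounds


def test_bounds_closed_form_for_ohmic_species():
    """Constant observed current c and an ohmic species: the bound is
    c / (g * min |V - E|) over the sampled voltages."""
    from ionrep.species import species_list
    from ionrep.environment import DEFAULT_ENVIRONMENT as env
    spec = species_list(["bgK"])[0]
    ek = env.nernst("K")
    volts = np.array([-120.0, -60.0, 0.0, 40.0])
    c = 5.0
    iv = np.column_stack([volts, np.full(4, c)])
    bounds = density_upper_bounds(iv, [spec], env)
    g = spec.conductance
    expected = max(abs(c) / (g * abs(v - ek) * 1e-3) for v in volts)
    assert bounds["bgK"] == pytest.approx(expected, rel=1e-9)


def test_bounds_undefined_for_silent_species():
    """A species with zero conducting fraction everywhere gets no bound."""
    from ionrep.species import species_list
    spec = species_list(["P2RX4"])[0]  # closed without ATP
    iv = np.column_stack([[-40.0, 0.0], [1.0, 1.0]])
    bounds = density_upper_bounds(iv, [spec])
    assert not np.isfinite(bounds["P2RX4"])


def test_bounds_cover_generating_density():
    """An I-V generated by a single species at density d yields a bound >= d
    with equality at the argmax voltage."""
    from ionrep.species import species_list
    from ionrep.environment import DEFAULT_ENVIRONMENT as env
    from ionrep.gating import with_defaults
    spec = species_list(["Kv9.3"])[0]
    d = 4.0
    volts = np.arange(-60.0, 61.0, 20.0)
    u = with_defaults({"ca": 100.0})
    cur = []
    for v in volts:
        ss = spec.gating.steady_state(v, u)
        cur.append(d * spec.unit_current(ss, v, env, u))
    iv = np.column_stack([volts, cur])
    bounds = density_upper_bounds(iv, [spec], env)
    assert bounds["Kv9.3"] == pytest.approx(d, rel=1e-9)
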