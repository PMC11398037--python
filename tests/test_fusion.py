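"""BGD template fusion: step arithmetic, planted recovery, simplex invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pathgait.fusion import (FusionProblem, bgd_step, default_fusion_target,
                             fuse, optimize_fusion_weights)
from pathgait.synthetic import WalkerParams, generate_walker_sequence
from pathgait.templates import EnergyImage, compute_all_templates


@pytest.fixture(scope="module")
def walker_templates():
    walk = generate_walker_sequence(WalkerParams(cycle_frames=20, n_cycles=1,
                                                 noise_rate=0.0, seed=3))
    from pathgait.cycles import segment_sequence
    cyc = segment_sequence(walk.sequence)[0]
    return compute_all_templates(cyc)


def simplex_ls_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Constrained least squares on the probability simplex (SLSQP)."""
    res = minimize(lambda w: ((X @ w - y) ** 2).sum(),
                   x0=np.full(X.shape[1], 1.0 / X.shape[1]),
                   jac=lambda w: 2.0 * X.T @ (X @ w - y),
                   bounds=[(0, 1)] * X.shape[1],
                   constraints={"type": "eq", "fun": lambda w: w.sum() - 1.0},
                   method="SLSQP", options={"ftol": 1e-14, "maxiter": 500})
    return res.x


def test_bgd_step_matches_hand_computation():
    """4-pixel, 2-template toy system checked against explicit arithmetic."""
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.0]])
    y = np.array([1.0, 0.0, 1.0, 0.5])
    w = np.array([0.5, 0.5])
    problem = FusionProblem(X, y, learning_rate=0.1, n_restarts=1)
    # by hand: e = y - Xw = (0.5, -0.5, 0, 0.25)
    # X^T e = (1*0.5 + 0*(-0.5) + 1*0 + 0.5*0.25, 0*0.5 + 1*(-0.5) + 1*0 + 0*0.25)
    #       = (0.625, -0.5);  grad = -2 X^T e = (-1.25, 1.0)
    e = y - X @ w
    assert np.allclose(e, [0.5, -0.5, 0.0, 0.25])
    grad = -2.0 * X.T @ e
    assert np.allclose(grad, [-1.25, 1.0])
    step = w - 0.1 * grad / 4.0            # gradient normalized by n_pixels
    assert np.allclose(step, [0.53125, 0.475])
    # Euclidean simplex projection of an all-positive point subtracts
    # (sum - 1)/k from every component: theta = 0.00625/2 = 0.003125
    expected = step - (step.sum() - 1.0) / 2.0
    assert np.allclose(expected, [0.528125, 0.471875])
    w2, cost2 = bgd_step(w, problem, learning_rate=0.1)
    assert np.allclose(w2, expected)
    assert cost2 == pytest.approx(((y - X @ w2) ** 2).sum())


def test_bgd_step_at_optimum_is_fixed_point():
    X = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
    w_star = np.array([0.25, 0.75])
    y = X @ w_star
    problem = FusionProblem(X, y)
    w2, cost = bgd_step(w_star, problem)
    assert np.allclose(w2, w_star)
    assert cost == pytest.approx(0.0, abs=1e-24)


def test_single_template_self_target():
    X = np.array([[0.3], [0.8], [0.1]])
    problem = FusionProblem(X, X[:, 0])
    w, cost = bgd_step(np.array([1.0]), problem)
    assert w[0] == pytest.approx(1.0)
    assert cost == pytest.approx(0.0, abs=1e-24)


@pytest.mark.parametrize("plant", [(1.0, 0.0, 0.0), (0.2, 0.3, 0.5), (0.6, 0.1, 0.3)])
def test_planted_weights_recovered(walker_templates, plant):
    gei, geni, aei = walker_templates
    target = EnergyImage("FEI", np.clip(
        plant[0] * gei.pixels + plant[1] * geni.pixels + plant[2] * aei.pixels, 0, 255))
    fw = optimize_fusion_weights(gei, geni, aei, target, seed=0)
    assert np.abs(fw.weights - np.array(plant)).max() < 1e-3
    X = np.stack([t.pixels.ravel() / 255.0 for t in walker_templates], axis=1)
    oracle = simplex_ls_oracle(X, target.pixels.ravel() / 255.0)
    assert np.abs(fw.weights - oracle).max() < 1e-3


def test_zero_target_matches_simplex_grid_oracle(walker_templates):
    gei, geni, aei = walker_templates
    fw = optimize_fusion_weights(gei, geni, aei, np.zeros((256, 256)), seed=0)
    X = np.stack([t.pixels.ravel() / 255.0 for t in walker_templates], axis=1)
    best_cost, best_w = np.inf, None
    for a in np.arange(0.0, 1.0001, 0.01):
        for b in np.arange(0.0, 1.0001 - a, 0.01):
            w = np.array([a, b, 1.0 - a - b])
            cost = float(((X @ w) ** 2).sum())
            if cost < best_cost:
                best_cost, best_w = cost, w
    assert np.abs(fw.weights - best_w).max() <= 0.01 + 1e-9
    assert fw.cost <= best_cost + 1e-6


def test_cost_non_increasing_along_descent(walker_templates):
    gei, geni, aei = walker_templates
    X = np.stack([t.pixels.ravel() / 255.0 for t in (gei, geni, aei)], axis=1)
    y = default_fusion_target(gei, geni, aei).pixels.ravel() / 255.0
    problem = FusionProblem(X, y)
    w = np.full(3, 1.0 / 3.0)
    cost = problem.cost(w)
    for _ in range(200):
        w, new_cost = bgd_step(w, problem)
        # monotone up to float roundoff on a cost of magnitude ~1e3
        assert new_cost <= cost * (1 + 1e-12) + 1e-12
        cost = new_cost


def test_weights_always_on_simplex(walker_templates, rng):
    gei, geni, aei = walker_templates
    for seed in range(3):
        target = EnergyImage("FEI", rng.random((256, 256)) * 255)
        fw = optimize_fusion_weights(gei, geni, aei, target, seed=seed)
        assert fw.weights.min() >= 0.0
        assert fw.weights.sum() == pytest.approx(1.0)


def test_fuse_identity_and_mean(walker_templates):
    gei, geni, aei = walker_templates
    fei = fuse(gei, geni, aei, np.array([1.0, 0.0, 0.0]))
    assert np.array_equal(fei.pixels, gei.pixels)
    mean = fuse(gei, geni, aei, np.full(3, 1.0 / 3.0))
    stack = np.stack([t.pixels for t in walker_templates])
    assert np.allclose(mean.pixels, stack.mean(axis=0))
    assert fei.kind == "FEI"


def test_fuse_is_convex_combination(walker_templates, rng):
    gei, geni, aei = walker_templates
    w = rng.dirichlet(np.ones(3))
    fei = fuse(gei, geni, aei, w)
    stack = np.stack([t.pixels for t in walker_templates])
    assert (fei.pixels >= stack.min(axis=0) - 1e-9).all()
    assert (fei.pixels <= stack.max(axis=0) + 1e-9).all()


def test_fuse_rejects_wrong_weight_count(walker_templates):
    gei, geni, aei = walker_templates
    with pytest.raises(ValueError, match="3 fusion weights"):
        fuse(gei, geni, aei, np.array([0.5, 0.5]))


def test_degenerate_all_zero_templates_rejected():
    z = EnergyImage("GEI", np.zeros((16, 16)))
    with pytest.raises(ValueError, match="degenerate"):
        optimize_fusion_weights(z, z, z, z)


def test_restarts_are_seeded_and_deterministic(walker_templates):
    gei, geni, aei = walker_templates
    t = default_fusion_target(gei, geni, aei)
    a = optimize_fusion_weights(gei, geni, aei, t, seed=5)
    b = optimize_fusion_weights(gei, geni, aei, t, seed=5)
    assert np.array_equal(a.weights, b.weights)
    assert a.cost == b.cost and a.n_iter == b.n_iter
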