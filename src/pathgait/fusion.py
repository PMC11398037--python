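"""Fused energy image (FEI): weighting GEI/GEnI/AEI by batch gradient descent.

The three templates of one cycle are stacked as the columns of an
``n_pixels x 3`` matrix ``X`` (pixels rescaled to [0, 1]); a target image
``y`` is approximated by the convex combination ``X w``. Full-batch gradient
descent minimizes the summed squared error ``cost(w) = ||y - X w||^2``,
starting from the uniform weights ``1/n_images`` and, on restarts, from
seeded random points of the probability simplex; every step is followed by
the Euclidean projection onto the simplex (negative components end at zero,
the vector sums to one), so the returned weights always form a convex
combination. The restart with the
smallest final cost wins. Each gait cycle is fitted independently — its
templates have their own optimal weights.

Because the cost is quadratic in the three weights, the per-iteration
gradient ``-2 X^T (y - X w)`` is evaluated from the precomputed 3x3 Gram
matrix ``X^T X`` and the vector ``X^T y``; this is algebraically identical
to the full-batch computation and makes each descent step O(1) in the image
size.

The method never defines a canonical target image; callers choose. The
pipeline default is the per-pixel maximum of the three templates, which
emphasizes every template's high-energy regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .templates import EnergyImage


@dataclass
class FusionProblem:
    """Least-squares fusion problem over the probability simplex."""

    image_matrix: np.ndarray       # (n_pixels, n_images), values in [0, 1]
    target_pixels: np.ndarray      # (n_pixels,), values in [0, 1]
    learning_rate: float | None = None   # None -> 1/trace(2*G/n), always stable
    max_iter: int = 5000
    cost_tol: float = 1e-8
    n_restarts: int = 5
    seed: int = 0

    _gram: np.ndarray = field(init=False, repr=False, default=None)
    _xty: np.ndarray = field(init=False, repr=False, default=None)
    _yty: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        X = np.asarray(self.image_matrix, dtype=np.float64)
        y = np.asarray(self.target_pixels, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("image_matrix must be (n_pixels, n_images) matching target")
        if not np.all(np.abs(X) < 1e12) or not np.isfinite(X).all():
            raise ValueError("non-finite template values")
        self.image_matrix = X
        self.target_pixels = y
        self._gram = X.T @ X
        self._xty = X.T @ y
        self._yty = float(y @ y)

    @property
    def n_pixels(self) -> int:
        return self.image_matrix.shape[0]

    @property
    def n_images(self) -> int:
        return self.image_matrix.shape[1]

    def cost(self, weights: np.ndarray) -> float:
        """Summed squared reconstruction error ||y - X w||^2."""
        w = np.asarray(weights, dtype=np.float64)
        return float(self._yty - 2.0 * w @ self._xty + w @ self._gram @ w)

    def gradient(self, weights: np.ndarray) -> np.ndarray:
        """True cost gradient -2 X^T (y - X w)."""
        w = np.asarray(weights, dtype=np.float64)
        return 2.0 * (self._gram @ w - self._xty)

    def default_learning_rate(self) -> float:
        tr = float(np.trace(self._gram)) * 2.0 / self.n_pixels
        return 1.0 / max(tr, 1e-12)


@dataclass
class FusionWeights:
    """Optimized simplex weights with bookkeeping."""

    weights: np.ndarray
    cost: float
    n_iter: int
    restart_index: int


def _project_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based).

    Negative components end at zero and the result sums to one. Unlike the
    naive clip-then-divide-by-sum rescaling, the Euclidean projection makes
    the descent a textbook projected gradient method whose fixed points are
    exactly the constrained minima; radial rescaling admits spurious fixed
    points on ill-conditioned template sets.
    """
    u = np.sort(w)[::-1]
    css = np.cumsum(u) - 1.0
    k = np.arange(1, w.size + 1)
    rho = np.max(k[u - css / k > 0])
    theta = css[rho - 1] / rho
    return np.clip(w - theta, 0.0, None)


def bgd_step(weights: np.ndarray, problem: FusionProblem,
             learning_rate: float | None = None) -> tuple[np.ndarray, float]:
    """One batch-gradient-descent step followed by the simplex projection.

    The gradient is normalized by n_pixels (equivalently: the step descends
    the mean squared error), so learning rates are image-size independent.
    The step is projected onto the probability simplex, keeping the weights
    a convex combination. Returns the projected weights and their cost.
    Raises on divergence.
    """
    lr = learning_rate if learning_rate is not None else (
        problem.learning_rate if problem.learning_rate is not None
        else problem.default_learning_rate())
    grad = problem.gradient(weights) / problem.n_pixels
    w = _project_simplex(np.asarray(weights, dtype=np.float64) - lr * grad)
    cost = problem.cost(w)
    if not np.isfinite(cost):
        raise FloatingPointError("diverged; reduce learning_rate")
    return w, cost


def _descend(problem: FusionProblem, w0: np.ndarray,
             lr: float) -> tuple[np.ndarray, float, int]:
    w = _project_simplex(np.asarray(w0, dtype=np.float64))
    cost = problem.cost(w)
    for it in range(1, problem.max_iter + 1):
        w_new, cost_new = bgd_step(w, problem, lr)
        delta = cost - cost_new
        w, cost = w_new, cost_new
        if abs(delta) < problem.cost_tol:
            return w, cost, it
    return w, cost, problem.max_iter


def solve_fusion_weights(problem: FusionProblem) -> FusionWeights:
    """Multi-restart BGD: uniform init first, then seeded random simplex points."""
    lr = (problem.learning_rate if problem.learning_rate is not None
          else problem.default_learning_rate())
    rng = np.random.default_rng(problem.seed)
    best: FusionWeights | None = None
    for r in range(max(1, problem.n_restarts)):
        if r == 0:
            w0 = np.full(problem.n_images, 1.0 / problem.n_images)
        else:
            w0 = rng.dirichlet(np.ones(problem.n_images))
        w, cost, n_iter = _descend(problem, w0, lr)
        if best is None or cost < best.cost:
            best = FusionWeights(weights=w, cost=cost, n_iter=n_iter, restart_index=r)
    return best


def optimize_fusion_weights(gei: EnergyImage, geni: EnergyImage, aei: EnergyImage,
                            target: EnergyImage | np.ndarray, *,
                            learning_rate: float | None = None, max_iter: int = 5000,
                            cost_tol: float = 1e-8, n_restarts: int = 5,
                            seed: int = 0) -> FusionWeights:
    """Fit simplex fusion weights for the three templates against a target.

    Template and target pixels (in [0, 255]) are rescaled to [0, 1]
    internally. Raises on degenerate all-zero templates.
    """
    mats = [t.pixels for t in (gei, geni, aei)]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("templates must share one grid")
    X = np.stack([m.ravel() / 255.0 for m in mats], axis=1)
    if not X.any():
        raise ValueError("degenerate all-zero templates")
    t = target.pixels if isinstance(target, EnergyImage) else np.asarray(target)
    if t.shape != mats[0].shape:
        raise ValueError("target must share the template grid")
    problem = FusionProblem(X, t.ravel() / 255.0, learning_rate=learning_rate,
                            max_iter=max_iter, cost_tol=cost_tol,
                            n_restarts=n_restarts, seed=seed)
    return solve_fusion_weights(problem)


def default_fusion_target(gei: EnergyImage, geni: EnergyImage, aei: EnergyImage,
                          mode: str = "max") -> EnergyImage:
    """Pipeline default target: per-pixel max (or mean) of the three templates."""
    stack = np.stack([t.pixels for t in (gei, geni, aei)])
    if mode == "max":
        return EnergyImage("FEI", stack.max(axis=0))
    if mode == "mean":
        return EnergyImage("FEI", stack.mean(axis=0))
    raise ValueError("target mode must be 'max' or 'mean'")


def fuse(gei: EnergyImage, geni: EnergyImage, aei: EnergyImage,
         weights: FusionWeights | np.ndarray) -> EnergyImage:
    """FEI(x, y) = sum_k w_k * template_k(x, y), clipped to [0, 255]."""
    w = weights.weights if isinstance(weights, FusionWeights) else np.asarray(weights)
    if w.shape != (3,):
        raise ValueError("need exactly 3 fusion weights")
    out = (w[0] * gei.pixels + w[1] * geni.pixels + w[2] * aei.pixels)
    return EnergyImage("FEI", np.clip(out, 0.0, 255.0))
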