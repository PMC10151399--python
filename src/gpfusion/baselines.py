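"""Gradient-boosting and support-vector-regression baselines.

Both learners are written out from first principles:

* :func:`fit_gbm` — stochastic gradient boosting under Gaussian loss with
  depth-1 regression trees (stumps). The model starts from the optimal
  constant (the response mean); each iteration draws a without-replacement
  subsample, fits a stump to the negative gradient (the residual), and adds
  it shrunken by the learning rate. For squared loss the per-leaf means
  solve the line search exactly.
* :func:`fit_svr_linear` — ε-insensitive linear support-vector regression
  solved in the dual by SMO-style maximal-violating-pair updates with an
  unregularized intercept; cost ``C`` bounds the dual variables, the tube
  width ``ε`` enters through an L1 term on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# gradient boosting machine
# ---------------------------------------------------------------------------

@dataclass
class GBMSpec:
    M: int = 5000               # boosting iterations (trees)
    depth: int = 1              # interaction depth; stumps only
    shrinkage: float = 0.001    # ν
    min_node: int = 10          # minimum terminal-node size
    bag_fraction: float = 0.5   # subsample share per iteration
    seed: int = 0

    def __post_init__(self):
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if not (0 < self.shrinkage <= 1):
            raise ValueError("shrinkage must lie in (0, 1]")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.depth != 1:
            raise NotImplementedError("only depth-1 trees (stumps) are supported")


@dataclass
class Stump:
    feature: int | None         # None -> root-only tree (no valid split)
    threshold: float
    left: float                 # mean residual, x[feature] <= threshold
    right: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.feature is None:
            return np.full(X.shape[0], self.left)
        return np.where(X[:, self.feature] <= self.threshold, self.left, self.right)


@dataclass
class GBMEnsemble:
    f0: float
    shrinkage: float
    stumps: list = field(default_factory=list)
    loss_path: np.ndarray | None = None
    n_features: int = 0


def _fit_stump(X: np.ndarray, r: np.ndarray, min_node: int) -> Stump:
    """Exhaustive variance-reduction split over all (feature, midpoint)
    thresholds, vectorized across features. Ties break toward the lowest
    feature index, then the lowest threshold."""
    n, p = X.shape
    if n < 2 * min_node:
        return Stump(None, 0.0, float(r.mean()), float(r.mean()))
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    rs = r[order]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1]
    n_left = np.arange(1, n, dtype=float)[:, None]
    n_right = n - n_left
    sl = csum[:-1]
    # maximizing sum_L^2/n_L + sum_R^2/n_R  ==  minimizing split SSE
    gain = sl**2 / n_left + (total - sl) ** 2 / n_right
    valid = (Xs[:-1] < Xs[1:]) & (n_left >= min_node) & (n_right >= min_node)
    if not valid.any():
        return Stump(None, 0.0, float(r.mean()), float(r.mean()))
    scores = np.where(valid, gain, -np.inf).T      # feature-major for tie-break
    j, i = np.unravel_index(int(np.argmax(scores)), scores.shape)
    thr = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    left = float(sl[i, j] / (i + 1))
    right = float((total[j] - sl[i, j]) / (n - i - 1))
    return Stump(int(j), float(thr), left, right)


def fit_gbm(X: np.ndarray, y: np.ndarray, spec: GBMSpec | None = None) -> GBMEnsemble:
    """Stochastic gradient boosting with stumps under squared-error loss."""
    spec = spec or GBMSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y must be row-aligned")
    rng = np.random.default_rng(spec.seed)
    n = len(y)
    f0 = float(y.mean())
    pred = np.full(n, f0)
    ens = GBMEnsemble(f0=f0, shrinkage=spec.shrinkage, n_features=X.shape[1])
    losses = np.empty(spec.M)
    n_bag = max(1, int(round(spec.bag_fraction * n)))
    for t in range(spec.M):
        sub = rng.choice(n, size=n_bag, replace=False) if n_bag < n else np.arange(n)
        resid = y[sub] - pred[sub]           # negative gradient of squared loss
        stump = _fit_stump(X[sub], resid, spec.min_node)
        ens.stumps.append(stump)
        pred += spec.shrinkage * stump.predict(X)
        losses[t] = float(np.mean((y - pred) ** 2))
    ens.loss_path = losses
    return ens


def predict_gbm(ensemble: GBMEnsemble, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ensemble.n_features:
        raise ValueError(
            f"expected {ensemble.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    pred = np.full(X.shape[0], ensemble.f0)
    for stump in ensemble.stumps:
        pred += ensemble.shrinkage * stump.predict(X)
    return pred


# ---------------------------------------------------------------------------
# linear epsilon-insensitive support vector regression
# ---------------------------------------------------------------------------

@dataclass
class SVRSpec:
    epsilon: float = 0.1
    C: float = 1.0
    tol: float = 0.01
    max_iter: int = 200_000

    def __post_init__(self):
        if self.epsilon < 0 or self.C <= 0:
            raise ValueError("need epsilon >= 0 and C > 0")


class SVRConvergenceError(RuntimeError):
    pass


def _pair_step(theta_i, theta_j, g, a, eps, C):
    """Minimize the 1-D restriction phi(t) of the dual along
    (theta_i + t, theta_j - t); returns the optimal step t."""
    t_lo = max(-C - theta_i, theta_j - C)
    t_hi = min(C - theta_i, theta_j + C)
    if t_lo >= t_hi:
        return 0.0

    def phi(t):
        return (
            g * t
            + 0.5 * a * t * t
            + eps * (abs(theta_i + t) - abs(theta_i) + abs(theta_j - t) - abs(theta_j))
        )

    cands = [t_lo, t_hi]
    kinks = [-theta_i, theta_j]
    cands += [k for k in kinks if t_lo < k < t_hi]
    if a > 0:
        # stationary point on each smooth segment
        pts = sorted(set(cands))
        for lo, hi in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (lo + hi)
            s1 = np.sign(theta_i + mid) or 1.0
            s2 = np.sign(theta_j - mid) or 1.0
            t_star = -(g + eps * (s1 - s2)) / a
            if lo <= t_star <= hi:
                cands.append(t_star)
    vals = [phi(t) for t in cands]
    return cands[int(np.argmin(vals))]


def fit_svr_linear(
    X: np.ndarray, y: np.ndarray, spec: SVRSpec | None = None, return_details: bool = False
):
    """Solve linear ε-SVR by SMO over the combined dual variables.

    The dual in θ_i = α_i − α_i* is
    ``min ½ θᵀKθ − yᵀθ + ε‖θ‖₁ s.t. Σθ = 0, |θ_i| ≤ C`` with ``K = XXᵀ``;
    the equality constraint carries the unregularized intercept. At each
    step the maximal violating pair (over the feasible interval of the bias)
    is optimized exactly along its 1-D restriction. Terminates when the KKT
    violation drops below ``tol``.

    Returns ``(beta0, beta)``; with ``return_details`` also a dict holding
    the dual variables, bias interval and iteration count.
    """
    spec = spec or SVRSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n != len(y):
        raise ValueError("X and y must be row-aligned")
    K = X @ X.T
    diagK = np.diag(K).copy()
    theta = np.zeros(n)
    f = np.zeros(n)                       # K @ theta
    eps, C = spec.epsilon, spec.C

    it = 0
    while True:
        d = f - y
        # per-point feasible interval [lo_i, hi_i] for the bias multiplier
        lo = np.where(theta > 0, d + eps, d - eps)
        lo[theta <= -C] = -np.inf
        hi = np.where(theta < 0, d - eps, d + eps)
        hi[theta >= C] = np.inf
        i = int(np.argmax(lo))
        j = int(np.argmin(hi))
        violation = lo[i] - hi[j]
        if violation <= spec.tol:
            break
        if it >= spec.max_iter:
            gap = _duality_gap(X, y, theta, eps, C)
            raise SVRConvergenceError(
                f"no convergence in {spec.max_iter} iterations; duality gap {gap:.3e}"
            )
        g = d[i] - d[j]
        a = diagK[i] + diagK[j] - 2.0 * K[i, j]
        t = _pair_step(theta[i], theta[j], g, a, eps, C)
        if t == 0.0:
            break
        theta[i] += t
        theta[j] -= t
        f += t * (K[:, i] - K[:, j])
        it += 1

    beta = X.T @ theta
    d = f - y
    lo_f = lo[np.isfinite(lo)]
    hi_f = hi[np.isfinite(hi)]
    b_mult = 0.5 * (lo_f.max() + hi_f.min()) if len(lo_f) and len(hi_f) else 0.0
    beta0 = -float(b_mult)
    if return_details:
        return beta0, beta, {"theta": theta, "iterations": it, "violation": float(violation)}
    return beta0, beta


def _duality_gap(X, y, theta, eps, C):
    beta = X.T @ theta
    resid = y - X @ beta
    primal = 0.5 * beta @ beta + C * np.sum(np.maximum(np.abs(resid) - eps, 0.0))
    dual = theta @ y - 0.5 * theta @ (X @ beta) - eps * np.sum(np.abs(theta))
    return primal - dual


def svr_objective(X, y, beta0, beta, spec: SVRSpec | None = None) -> float:
    """Primal ε-insensitive objective; used for oracle comparisons."""
    spec = spec or SVRSpec()
    resid = np.abs(y - beta0 - X @ beta) - spec.epsilon
    return 0.5 * float(beta @ beta) + spec.C * float(np.sum(np.maximum(resid, 0.0)))
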