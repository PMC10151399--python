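"""Bayesian hyperparameter optimization for the multimodal network.

A Gaussian-process surrogate (Matérn-5/2 kernel) with the
expected-improvement acquisition searches the hyperparameter domain:
hidden-layer counts and first-layer widths per tower, L2 coefficient,
dropout rate, log learning-decay, early-stopping patience and log learning
rate. Integer-valued dimensions are proposed continuously and rounded at
evaluation time. A seeded quasi-random (Sobol) design provides the initial
evaluations; a pure random-search optimizer over the same space is included
as the reference baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    integer: bool = False

    def round(self, x: float):
        x = float(np.clip(x, self.low, self.high))
        return int(round(x)) if self.integer else x


@dataclass
class HyperSpace:
    """Box-bounded search domain; integer dims rounded after proposal."""

    dims: list

    @classmethod
    def mmdl_default(cls, modalities=("year", "genomic", "ndvi")) -> "HyperSpace":
        """The network's tuning domain: per-tower depth/width plus shared
        regularization and optimizer settings (log scales for learning rate
        and decay)."""
        depth_hi = {"year": 4, "genomic": 6, "ndvi": 6}
        width_hi = {"year": 16, "genomic": 1024, "ndvi": 64}
        dims = []
        for q in modalities:
            dims.append(Dimension(f"nHL_{q}", 1, depth_hi[q], integer=True))
        for q in modalities:
            dims.append(Dimension(f"N1_{q}", 1, width_hi[q], integer=True))
        dims += [
            Dimension("l2", 1e-8, 1e-2),
            Dimension("dropout", 1e-4, 0.5),
            Dimension("lwd", np.log(4e-5), np.log(4e-1)),
            Dimension("patience", 0, 64, integer=True),
            Dimension("llr", np.log(1e-5), np.log(1e-2)),
        ]
        return cls(dims)

    @property
    def names(self):
        return [d.name for d in self.dims]

    def to_params(self, x: np.ndarray) -> dict:
        return {d.name: d.round(v) for d, v in zip(self.dims, x)}

    def _bounds(self):
        lo = np.array([d.low for d in self.dims], dtype=float)
        hi = np.array([d.high for d in self.dims], dtype=float)
        return lo, hi

    def sample(self, rng, n: int) -> np.ndarray:
        lo, hi = self._bounds()
        return lo + rng.random((n, len(self.dims))) * (hi - lo)

    def sobol(self, seed: int, n: int) -> np.ndarray:
        lo, hi = self._bounds()
        eng = qmc.Sobol(d=len(self.dims), scramble=True, seed=seed)
        m = int(np.ceil(np.log2(max(n, 1))))
        pts = eng.random_base2(m) if n > 1 else eng.random(1)
        return lo + pts[:n] * (hi - lo)

    def unit(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self._bounds()
        return (np.atleast_2d(X) - lo) / (hi - lo)


@dataclass
class TuneResult:
    best_params: dict
    best_objective: float
    trace: list = field(default_factory=list)   # (params, objective) per evaluation
    seed: int = 0

    def best_so_far(self) -> np.ndarray:
        vals = np.array([v for _, v in self.trace])
        return np.minimum.accumulate(vals)


def _expected_improvement(mu, sigma, best):
    """EI for minimization; zero where the posterior is degenerate."""
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def bayesian_optimize(
    objective,
    space: HyperSpace,
    n_iter: int = 150,
    n_init: int = 10,
    seed: int = 0,
    n_candidates: int = 1024,
) -> TuneResult:
    """Minimize ``objective(params_dict)`` over ``space``.

    ``n_init`` Sobol points are evaluated first, then ``n_iter``
    GP-guided evaluations: at each step the surrogate is refitted and the
    expected improvement is maximized over a seeded random candidate set.
    A non-finite objective value is recorded with a large penalty so the
    search continues around it. Fully reproducible from ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    X, yv, trace = [], [], []

    def evaluate(x):
        params = space.to_params(x)
        try:
            val = float(objective(params))
        except FloatingPointError:
            val = np.nan
        if not np.isfinite(val):
            finite = [v for v in yv if np.isfinite(v)]
            val = (max(finite) + 10 * (np.std(finite) + 1.0)) if finite else 1e6
        X.append(np.asarray(x, dtype=float))
        yv.append(val)
        trace.append((params, val))
        return val

    for x in space.sobol(seed, n_init):
        evaluate(x)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(len(space.dims), 0.3),
        length_scale_bounds=(1e-2, 1e2),
        nu=2.5,
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    for _ in range(n_iter):
        Xu = space.unit(np.vstack(X))
        ys = np.asarray(yv)
        mu_y, sd_y = ys.mean(), ys.std() + 1e-12
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-10, normalize_y=False, n_restarts_optimizer=0,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xu, (ys - mu_y) / sd_y)
        cand = space.sample(rng, n_candidates)
        mu, sigma = gp.predict(space.unit(cand), return_std=True)
        ei = _expected_improvement(mu, sigma, (min(yv) - mu_y) / sd_y)
        evaluate(cand[int(np.argmax(ei))])

    best_i = int(np.argmin(yv))
    return TuneResult(
        best_params=trace[best_i][0],
        best_objective=float(yv[best_i]),
        trace=trace,
        seed=seed,
    )


def random_search(objective, space: HyperSpace, n_iter: int, seed: int = 0) -> TuneResult:
    """Uniform random search over the same space — the reference baseline."""
    rng = np.random.default_rng(seed)
    trace = []
    for x in space.sample(rng, n_iter):
        params = space.to_params(x)
        val = float(objective(params))
        if not np.isfinite(val):
            val = 1e6
        trace.append((params, val))
    best_i = int(np.argmin([v for _, v in trace]))
    return TuneResult(
        best_params=trace[best_i][0],
        best_objective=trace[best_i][1],
        trace=trace,
        seed=seed,
    )


def params_to_config(params: dict, modalities=("year", "genomic", "ndvi"), **overrides):
    """Translate a search point into an :class:`~gpfusion.mmdl.MMDLConfig`."""
    from gpfusion.mmdl import MMDLConfig

    kw = dict(
        nHL={q: int(params[f"nHL_{q}"]) for q in modalities},
        N1={q: max(1, int(params[f"N1_{q}"])) for q in modalities},
        l2=params["l2"],
        dropout=params["dropout"],
        wd=float(np.exp(params["lwd"])),
        patience=int(params["patience"]),
        lr=float(np.exp(params["llr"])),
    )
    kw.update(overrides)
    return MMDLConfig(**kw)


def tune_mmdl(blocks: dict, y, n_iter: int = 20, n_init: int = 8, seed: int = 0,
              modalities=None, **config_overrides) -> TuneResult:
    """Tune the multimodal network on one training set.

    The objective trains one network per proposed configuration and returns
    the held-out validation-split MSE. ``n_iter`` defaults to a desk-scale
    budget; raise it for full runs.
    """
    from gpfusion.mmdl import build_mmdl, train_mmdl

    modalities = tuple(modalities or sorted(blocks, key=["year", "genomic", "ndvi"].index))
    space = HyperSpace.mmdl_default(modalities)
    dims = {q: blocks[q].shape[1] for q in modalities}

    def objective(params):
        cfg = params_to_config(params, modalities, seed=seed, **config_overrides)
        model = build_mmdl(dims, cfg)
        _, history = train_mmdl(model, blocks, y, cfg)
        return history[-1]["val_loss"]

    return bayesian_optimize(objective, space, n_iter=n_iter, n_init=n_init, seed=seed)
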