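"""Bayesian GBLUP reaction-norm model fitted by Gibbs sampling.

The phenotype of line *j* in year *i* is modeled as

    y_ij = μ + year_i + g_j + (year×g)_ij + Σ_l β_vg,l x_vg,jl
                                          + Σ_l β_gf,l x_gf,jl + ε_ij

with flat priors on the fixed effects (intercept, year contrasts, NDVI
coefficients), line effects ``g ~ N(0, σ_g² G)`` where ``G`` is the genomic
relationship matrix, year-by-line interaction ``u ~ N(0, σ_Yg² (I ⊗ G))``
and i.i.d. Gaussian residuals. Variance components carry scaled-inverse-χ²
priors with ``df0`` degrees of freedom and scales chosen so the prior mode
matches an ``R2``-partition of the sample variance of the response — the
convention of standard Bayesian whole-genome regression software.

Sampling uses the eigendecomposition ``G = Γ Λ Γᵀ``: line effects are
reparameterized as ``g = Γ a`` with independent prior ``a_k ~ N(0, σ_g²
λ_k)``, and the interaction reuses the same eigenbasis within each year, so
each Gibbs update is a blocked multivariate-normal draw with a cheap
banded-free Cholesky solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from gpfusion.trial_data import DesignBlocks, PredictorSpec


@dataclass
class ChainSettings:
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GBLUPSpec:
    """Model + chain configuration.

    ``df0`` and ``R2`` follow the default-prior convention: each variance
    component gets a scaled-inverse-χ² prior with ``df0`` degrees of freedom
    whose mode equals its share of ``R2 · var(y)`` (the genetic terms split
    ``R2`` equally; the residual gets ``1 − R2``).
    """

    predictor: PredictorSpec = field(default_factory=PredictorSpec)
    chain: ChainSettings = field(default_factory=ChainSettings)
    df0: float = 5.0
    R2: float = 0.5
    fixed_variances: dict | None = None   # e.g. {"g": 1e6, "u": 1e6, "e": 1.0}
    keep_samples: bool = True

    def __post_init__(self):
        if self.df0 <= 0:
            raise ValueError("df0 must be positive")
        if not (0 < self.R2 < 1):
            raise ValueError("R2 must lie in (0, 1)")


@dataclass
class PosteriorSummary:
    beta_hat: np.ndarray
    beta_names: list
    g_hat: np.ndarray
    u_hat: np.ndarray | None
    var_hat: dict
    spec: GBLUPSpec
    line_ids: list
    year_labels: list
    samples: dict = field(default_factory=dict)

    @property
    def heritability(self) -> float:
        """Posterior-mean ratio σ_g² / (σ_g² + σ²)."""
        return self.var_hat["g"] / (self.var_hat["g"] + self.var_hat["e"])


class ChainDivergence(RuntimeError):
    pass


def _scaled_inv_chi2(rng, df: float, ssq: float) -> float:
    """Draw σ² ~ ssq / χ²_df."""
    return ssq / rng.chisquare(df)


def _draw_coef_block(rng, WtW, Wte, sigma2_e, prior_prec_diag):
    """One blocked Gaussian draw for coefficients with Gaussian prior.

    Full conditional precision P = WᵀW/σ² + diag(prior_prec); returns a
    sample of N(P⁻¹ Wᵀe*/σ², P⁻¹).
    """
    P = WtW / sigma2_e
    P[np.diag_indices_from(P)] += prior_prec_diag
    c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), Wte / sigma2_e)
    z = rng.standard_normal(P.shape[0])
    # sample = mean + P^{-1/2} z  via solve with the upper factor
    from scipy.linalg import solve_triangular

    dev = solve_triangular(c.T if low else c, z, lower=False)
    return mean + dev


def fit_gblup(blocks: DesignBlocks, spec: GBLUPSpec) -> PosteriorSummary:
    """Run the Gibbs sampler and return posterior means.

    ``blocks`` must come from :func:`gpfusion.trial_data.assemble_predictors`
    with the same :class:`PredictorSpec` (year / NDVI blocks define the
    fixed effects; the genomic relationship matrix rides on
    ``blocks.features``). Reproducible given ``spec.chain.seed``.
    """
    ps = spec.predictor
    ch = spec.chain
    rng = np.random.default_rng(ch.seed)
    y = np.asarray(blocks.y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response")
    n = len(y)
    G = blocks.features.G
    J = G.shape[0]

    # fixed-effect design: intercept + year contrasts (reference = first
    # year alphabetically, absorbed by the intercept) + NDVI columns
    cols = [np.ones((n, 1))]
    names = ["mu"]
    if ps.include_year and blocks.X_year.shape[1] > 1:
        cols.append(blocks.X_year[:, 1:])
        names += [f"year:{yl}" for yl in blocks.year_labels[1:]]
    if blocks.X_ndvi.shape[1]:
        cols.append(blocks.X_ndvi)
        names += [f"ndvi:{c}" for c in blocks.ndvi_names]
    X = np.column_stack(cols)
    p_fix = X.shape[1]

    # eigenbasis of G (+ floor for numerically zero eigenvalues)
    lam, Gamma = np.linalg.eigh(0.5 * (G + G.T))
    lam = np.maximum(lam, 1e-10)
    W_g = Gamma[blocks.line_index, :]              # n x J, record -> line eigenrow
    use_u = ps.include_year_by_G and len(blocks.year_labels) > 1

    vy = float(np.var(y, ddof=1)) if n > 1 else 1.0
    n_gen = 1 + int(use_u)
    S_g = vy * spec.R2 / n_gen * (spec.df0 + 2) / spec.df0 / float(np.mean(np.diag(G)))
    S_e = vy * (1 - spec.R2) * (spec.df0 + 2) / spec.df0
    fixed = spec.fixed_variances or {}

    XtX = X.T @ X + 1e-8 * np.eye(p_fix)          # ridge for rank safety
    XtX_chol = cho_factor(XtX, lower=True)
    WgtWg = W_g.T @ W_g

    years_idx = [np.flatnonzero(blocks.year_index == i) for i in range(len(blocks.year_labels))]
    if use_u:
        WutWu = [W_g[ix].T @ W_g[ix] for ix in years_idx]

    beta = np.zeros(p_fix)
    a = np.zeros(J)                                # g = Gamma a
    a_u = np.zeros((len(blocks.year_labels), J)) if use_u else None
    sigma2_g = fixed.get("g", vy * spec.R2 / n_gen)
    sigma2_u = fixed.get("u", vy * spec.R2 / n_gen) if use_u else 0.0
    sigma2_e = fixed.get("e", vy * (1 - spec.R2))

    n_keep = (ch.n_iter - ch.burn_in) // ch.thin
    keep_beta = np.zeros((n_keep, p_fix))
    keep_g = np.zeros((n_keep, J))
    keep_u = np.zeros((n_keep, len(blocks.year_labels) * J)) if use_u else None
    keep_var = np.zeros((n_keep, 3))
    kept = 0

    g_rec = W_g @ a
    u_rec = np.zeros(n)
    from scipy.linalg import solve_triangular

    for it in range(ch.n_iter):
        # --- fixed effects: flat prior, joint Gaussian draw
        resid_f = y - g_rec - u_rec
        mean_b = cho_solve(XtX_chol, X.T @ resid_f)
        z = rng.standard_normal(p_fix)
        dev = solve_triangular(XtX_chol[0].T, z, lower=False) * np.sqrt(sigma2_e)
        beta = mean_b + dev
        fitted_f = X @ beta

        # --- line effects in the eigenbasis
        e_star = y - fitted_f - u_rec
        a = _draw_coef_block(
            rng, WgtWg.copy(), W_g.T @ e_star, sigma2_e, 1.0 / (sigma2_g * lam)
        )
        g_rec = W_g @ a

        # --- year x line interaction, one eigenbasis block per year
        if use_u:
            e_star = y - fitted_f - g_rec
            for i, ix in enumerate(years_idx):
                a_u[i] = _draw_coef_block(
                    rng,
                    WutWu[i].copy(),
                    W_g[ix].T @ e_star[ix],
                    sigma2_e,
                    1.0 / (sigma2_u * lam),
                )
            u_rec = np.einsum("nj,nj->n", W_g, a_u[blocks.year_index])

        # --- variance components
        if "g" not in fixed:
            ssq = float(np.sum(a**2 / lam)) + spec.df0 * S_g
            sigma2_g = _scaled_inv_chi2(rng, spec.df0 + J, ssq)
        if use_u and "u" not in fixed:
            ssq = float(np.sum(a_u**2 / lam)) + spec.df0 * S_g
            sigma2_u = _scaled_inv_chi2(rng, spec.df0 + a_u.size, ssq)
        if "e" not in fixed:
            e = y - fitted_f - g_rec - u_rec
            ssq = float(e @ e) + spec.df0 * S_e
            sigma2_e = _scaled_inv_chi2(rng, spec.df0 + n, ssq)

        if not np.isfinite(sigma2_e) or not np.isfinite(beta).all():
            raise ChainDivergence(f"non-finite draw at iteration {it}")

        if it >= ch.burn_in and (it - ch.burn_in) % ch.thin == 0 and kept < n_keep:
            keep_beta[kept] = beta
            keep_g[kept] = g_rec_lines = Gamma @ a
            if use_u:
                keep_u[kept] = (a_u @ Gamma.T).ravel()
            keep_var[kept] = (sigma2_g, sigma2_u, sigma2_e)
            kept += 1

    u_hat = keep_u[:kept].mean(axis=0).reshape(len(blocks.year_labels), J) if use_u else None
    samples = {}
    if spec.keep_samples:
        samples = {
            "beta": keep_beta[:kept],
            "g": keep_g[:kept],
            "var": keep_var[:kept],
        }
    return PosteriorSummary(
        beta_hat=keep_beta[:kept].mean(axis=0),
        beta_names=names,
        g_hat=keep_g[:kept].mean(axis=0),
        u_hat=u_hat,
        var_hat={
            "g": float(keep_var[:kept, 0].mean()),
            "u": float(keep_var[:kept, 1].mean()),
            "e": float(keep_var[:kept, 2].mean()),
        },
        spec=spec,
        line_ids=list(blocks.features.line_ids),
        year_labels=list(blocks.year_labels),
        samples=samples,
    )


def predict_gblup(summary: PosteriorSummary, new_blocks: DesignBlocks) -> np.ndarray:
    """Predict records from posterior means.

    Unobserved lines must be present in the GRM used at fit time (their
    effects were sampled jointly through ``G``). When the fitted model had
    no year block (the leave-one-year-out protocol) predictions are the
    intercept + NDVI part + genomic effect only.
    """
    ps = summary.spec.predictor
    n = new_blocks.n
    pred = np.full(n, summary.beta_hat[summary.beta_names.index("mu")])
    if ps.include_year and len(summary.year_labels) > 1:
        for i, yl in enumerate(summary.year_labels[1:], start=1):
            name = f"year:{yl}"
            j = summary.beta_names.index(name)
            mask = np.array([summary.year_labels[0]] * n, dtype=object)
            # map new records' year labels onto training labels
            new_lab = np.array(new_blocks.year_labels, dtype=object)[new_blocks.year_index]
            pred += np.where(new_lab == yl, summary.beta_hat[j], 0.0)
    if new_blocks.X_ndvi.shape[1]:
        for c, colname in enumerate(new_blocks.ndvi_names):
            name = f"ndvi:{colname}"
            if name in summary.beta_names:
                pred += new_blocks.X_ndvi[:, c] * summary.beta_hat[summary.beta_names.index(name)]
    line_pos = {l: i for i, l in enumerate(summary.line_ids)}
    unknown = sorted(set(new_blocks.records["line"]) - set(line_pos))
    if unknown:
        raise KeyError(f"lines absent from the fitted GRM: {unknown[:10]}")
    idx = new_blocks.records["line"].map(line_pos).to_numpy(int)
    pred += summary.g_hat[idx]
    if summary.u_hat is not None and ps.include_year_by_G:
        new_lab = np.array(new_blocks.year_labels, dtype=object)[new_blocks.year_index]
        for i, yl in enumerate(summary.year_labels):
            mask = new_lab == yl
            if mask.any():
                pred[mask] += summary.u_hat[i, idx[mask]]
    return pred
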