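"""Synthetic wheat-trial generator.

Produces genotypes, phenotypes and NDVI covariates with the statistical
structure the prediction models assume, so the whole stack can be exercised
and validated without any external download:

* biallelic SNPs with allele frequencies drawn from a configurable range,
  independent across markers (no linkage disequilibrium);
* line genetic values ``g ~ N(0, σ_g² G)`` drawn through the Cholesky
  factor of the realized genomic relationship matrix;
* fixed year effects and random year-by-line interaction effects at
  configurable variance shares;
* NDVI timepoint covariates built from the genetic value plus year-specific
  offsets and noise, with a target genetic correlation;
* Gaussian residuals scaled so that ``var(g) / (var(g) + var(ε))`` hits the
  requested narrow-sense heritability.

Every latent component is returned in a truth record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gpfusion.genotype_qc import (
    CodedGenotypes,
    GenotypeCalls,
    GenomicFeatures,
    build_genomic_features,
)
from gpfusion.trial_data import N_TIMEPOINTS


@dataclass
class SimulationConfig:
    """Knobs of the generator.

    ``h2`` is the within-year narrow-sense heritability
    ``σ_g²/(σ_g²+σ_ε²)``; ``var_year`` and ``var_gxe`` are the absolute
    variance shares of the year main effect and the year-by-line
    interaction on a total phenotypic variance of 1, so the genetic and
    residual variances split the remainder according to ``h2``.
    """

    J: int = 300                       # lines
    p: int = 1000                      # markers
    years: tuple = ("2015-2016", "2016-2017")
    environments: tuple = ("none",)
    trait: str = "YLD"
    mu: float = 500.0                  # grand mean, g/m^2 scale
    pheno_scale: float = 50.0          # sd multiplier applied to the unit-variance model
    maf_range: tuple = (0.05, 0.5)
    h2: float = 0.5
    var_year: float = 0.2
    var_gxe: float = 0.1
    ndvi_gen_cor: float = 0.5
    ndvi_year_sd: float = 0.1          # sd of per-(year, timepoint) NDVI offsets
    het_rate: float = 0.0              # AB injection rate, for QC exercise
    missing_rate: float = 0.0          # NA injection rate
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if self.var_year + self.var_gxe >= 1:
            raise ValueError("variance shares of year and year x line must sum below 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class SimulatedTrial:
    """Phenotypes, NDVI and latent truth from one generator run."""

    records: pd.DataFrame
    ndvi: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeCalls, CodedGenotypes]:
    """Draw binary genotypes; per marker the B-allele frequency is uniform in
    ``maf_range``. Optional AB / NA injection dirties the call matrix for
    QC testing; the coded matrix returned alongside is always clean."""
    rng = np.random.default_rng(config.seed)
    q = rng.uniform(*config.maf_range, size=config.p)
    X = (rng.random((config.J, config.p)) < q).astype(float)
    line_ids = [f"L{j:04d}" for j in range(config.J)]
    marker_ids = [f"M{k:05d}" for k in range(config.p)]

    calls = np.where(X == 1.0, "BB", "AA").astype(object)
    if config.het_rate > 0:
        calls[rng.random(X.shape) < config.het_rate] = "AB"
    if config.missing_rate > 0:
        calls[rng.random(X.shape) < config.missing_rate] = "NA"

    coded = CodedGenotypes(
        line_ids=line_ids,
        marker_ids=marker_ids,
        X=X,
        maf=np.minimum(X.mean(axis=0), 1 - X.mean(axis=0)),
    )
    return GenotypeCalls(line_ids, marker_ids, calls), coded


def simulate_trial(
    config: SimulationConfig,
    coded: CodedGenotypes,
    features: GenomicFeatures | None = None,
) -> SimulatedTrial:
    """Generate phenotype records and NDVI covariates over a GRM.

    The phenotype follows the reaction-norm decomposition
    ``y = μ + year_i + g_j + (year×g)_ij + ε_ij`` on a unit total variance,
    then is shifted/scaled to an agronomic range. Each NDVI timepoint value
    is ``ρ·g̃ + √(1−ρ²)·z`` plus a (year, timepoint) offset, where ``g̃`` is
    the standardized genetic value and ``ρ = ndvi_gen_cor``.
    """
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    if features is None:
        features = build_genomic_features(coded)
    J = len(features.line_ids)
    C = features.L.T  # lower factor: C @ C.T = G + jitter I

    rem = 1.0 - config.var_year - config.var_gxe
    sig_g = np.sqrt(config.h2 * rem)
    sig_e = np.sqrt((1.0 - config.h2) * rem)
    sig_year = np.sqrt(config.var_year)
    sig_gxe = np.sqrt(config.var_gxe)

    g = sig_g * (C @ rng.standard_normal(J))
    years = list(config.years)
    envs = list(config.environments)
    year_eff = {y: sig_year * rng.standard_normal() for y in years}
    gxe = {y: sig_gxe * (C @ rng.standard_normal(J)) for y in years}

    rows = []
    eps_store = {}
    for y in years:
        for env in envs:
            eps = sig_e * rng.standard_normal(J)
            eps_store[(y, env)] = eps
            vals = config.mu + config.pheno_scale * (
                year_eff[y] + g + gxe[y] + eps
            )
            for j, line in enumerate(features.line_ids):
                rows.append((line, y, env, config.trait, vals[j]))
    records = pd.DataFrame(rows, columns=["line", "year", "environment", "trait", "value"])

    # NDVI: shared genetic signal + (year, timepoint) offset + line noise
    rho = config.ndvi_gen_cor
    g_std = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
    ndvi_rows = []
    for y in years:
        for period, n_tp in N_TIMEPOINTS.items():
            for t in range(1, n_tp + 1):
                offset = config.ndvi_year_sd * rng.standard_normal()
                noise = rng.standard_normal(J)
                x = rho * g_std + np.sqrt(max(0.0, 1 - rho**2)) * noise + offset
                # map to a plausible NDVI reflectance range
                x = 0.6 + 0.08 * x
                for j, line in enumerate(features.line_ids):
                    ndvi_rows.append((line, y, period, t, x[j]))
    ndvi = pd.DataFrame(ndvi_rows, columns=["line", "year", "period", "timepoint", "value"])

    truth = {
        "g": g,
        "g_std": g_std,
        "year_effects": year_eff,
        "gxe": gxe,
        "residuals": eps_store,
        "sigma2_g": sig_g**2,
        "sigma2_e": sig_e**2,
        "sigma2_year": sig_year**2,
        "sigma2_gxe": sig_gxe**2,
        "h2": config.h2,
        "mu": config.mu,
        "pheno_scale": config.pheno_scale,
        "seed": config.seed,
        "line_ids": list(features.line_ids),
    }
    return SimulatedTrial(records=records, ndvi=ndvi, truth=truth)


def simulate_dataset(config: SimulationConfig):
    """One-call convenience: genotypes, GRM features, trial, truth."""
    calls, coded = simulate_genotypes(config)
    features = build_genomic_features(coded)
    trial = simulate_trial(config, coded, features)
    return calls, coded, features, trial
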