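"""Synthetic GBS-like genotype panels and multi-environment phenotypes.

The generator emulates the structure of a genotyping-by-sequencing panel of
a few hundred outbred genotypes evaluated as plot means over several years:
unlinked biallelic SNPs with minor-allele frequencies drawn from a stated
range, optional random missingness, additive marker effects that are either
polygenic (every marker contributes) or sparse (a fraction pi_true of
markers has exactly zero effect), a shared random year effect, and
within-environment residual noise scaled to hit a target narrow-sense
heritability h2 at the plot-mean level.

There is deliberately no linkage disequilibrium and no population
structure: unlinked loci keep closed-form expectations testable, so
recovery tests measure the estimators rather than the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    PhenotypeRecords,
    ValidationError,
    impute_missing_mode,
)

ARCHITECTURES = ("polygenic", "sparse")


@dataclass
class SimulationConfig:
    """Study-scale defaults: 322 genotypes, 3 environments, scaled-down panel.

    ``pi_true`` (probability a marker has zero effect) defaults from the
    architecture: 0.0 for ``polygenic``, 0.9 for ``sparse``.  ``h2`` is the
    narrow-sense heritability at the plot-mean, within-environment level.
    """

    n_genotypes: int = 322
    n_markers: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    architecture: str = "polygenic"
    pi_true: float | None = None
    sigma2_alpha_true: float = 1.0
    h2: float = 0.5
    n_env: int = 3
    env_sd: float = 1.0
    grand_mean: float = 10.0
    trait_name: str = "sim_trait"
    seed: int | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(f"architecture must be one of {ARCHITECTURES}")
        if self.pi_true is None:
            self.pi_true = 0.0 if self.architecture == "polygenic" else 0.9
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValidationError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.pi_true <= 1.0:
            raise ValidationError("pi_true must lie in [0, 1]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValidationError("h2 must lie in [0, 1]")
        if self.n_genotypes < 1 or self.n_markers < 1:
            raise ValidationError("need >= 1 genotype and >= 1 marker")
        if self.n_env < 1:
            raise ValidationError("need >= 1 environment")


@dataclass
class GroundTruth:
    """The latent quantities real data never reveal, kept for recovery tests."""

    effects: np.ndarray
    qtl_indices: np.ndarray
    true_bv: np.ndarray
    realized_h2: float
    sigma2_eps: float = np.nan


def _rng(cfg: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def simulate_genotype_panel(cfg: SimulationConfig,
                            rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Unlinked biallelic panel: p_j ~ U(maf_low, maf_high), dosage ~ Bin(2, p_j)."""
    rng = _rng(cfg, rng)
    n, m = cfg.n_genotypes, cfg.n_markers
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int16)
    missing = (
        rng.random((n, m)) < cfg.missing_rate
        if cfg.missing_rate > 0
        else np.zeros((n, m), dtype=bool)
    )
    sample_ids = [f"G{i + 1:04d}" for i in range(n)]
    marker_ids = [f"M{j + 1:05d}" for j in range(m)]
    return GenotypeMatrix(sample_ids, marker_ids, dosages, missing)


def simulate_marker_effects(cfg: SimulationConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Spike-and-slab effects: zero w.p. pi_true, else N(0, sigma2_alpha_true)."""
    rng = _rng(cfg, rng)
    m = cfg.n_markers
    nonzero = rng.random(m) >= cfg.pi_true
    effects = np.zeros(m)
    effects[nonzero] = rng.normal(0.0, np.sqrt(cfg.sigma2_alpha_true), nonzero.sum())
    return effects


def simulate_multi_env_phenotypes(
    g: GenotypeMatrix,
    effects: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeRecords, GroundTruth]:
    """Plot-mean records y_it = mu + e_t + bv_i + eps_it at target h2.

    True breeding values are centered dosages times effects (mode-imputed
    first if the panel has missing calls, so the truth is well defined).
    The residual variance solves var(bv) / (var(bv) + s2_eps) = h2; h2 = 1
    means no residual noise.  Year effects are N(0, env_sd^2), shared by all
    genotypes within an environment.
    """
    rng = _rng(cfg, rng)
    effects = np.asarray(effects, dtype=float)
    if effects.size != g.n_markers:
        raise ValidationError("effects length must equal marker count")
    complete = impute_missing_mode(g)
    Z = complete.dosages.astype(float)
    Zc = Z - Z.mean(axis=0)
    true_bv = Zc @ effects
    var_bv = float(true_bv.var())
    if var_bv == 0.0:
        if cfg.h2 > 0:
            raise ValidationError("all marker effects are zero: h2 > 0 is undefined")
        sigma2_eps = 1.0  # pure-noise trait on a unit scale
    elif cfg.h2 == 0.0:
        raise ValidationError("h2 = 0 with nonzero genetic variance is inconsistent")
    else:
        sigma2_eps = var_bv * (1.0 - cfg.h2) / cfg.h2

    env_ids = [f"{2013 + t}" for t in range(cfg.n_env)]
    env_effects = rng.normal(0.0, cfg.env_sd, size=cfg.n_env)
    eps = (
        rng.normal(0.0, np.sqrt(sigma2_eps), size=(g.n_samples, cfg.n_env))
        if sigma2_eps > 0
        else np.zeros((g.n_samples, cfg.n_env))
    )
    rows = {
        "genotype_id": np.repeat(g.sample_ids, cfg.n_env),
        "environment_id": np.tile(env_ids, g.n_samples),
        "trait_name": cfg.trait_name,
        "value": (cfg.grand_mean + true_bv[:, None] + env_effects[None, :] + eps).ravel(),
    }
    records = PhenotypeRecords(pd.DataFrame(rows))
    var_eps_real = float(eps.var())
    realized_h2 = var_bv / (var_bv + var_eps_real) if (var_bv + var_eps_real) > 0 else 0.0
    truth = GroundTruth(
        effects=effects,
        qtl_indices=np.flatnonzero(effects != 0.0),
        true_bv=true_bv,
        realized_h2=realized_h2,
        sigma2_eps=sigma2_eps,
    )
    return records, truth


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, PhenotypeRecords, GroundTruth]:
    """Panel + effects + phenotypes from one generator stream."""
    rng = _rng(cfg, rng)
    g = simulate_genotype_panel(cfg, rng)
    effects = simulate_marker_effects(cfg, rng)
    ph, truth = simulate_multi_env_phenotypes(g, effects, cfg, rng)
    return g, ph, truth
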