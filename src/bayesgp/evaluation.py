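"""Canned validation studies: closed-form oracles and simulation benchmarks.

Each function sets up a self-contained experiment -- an analytic cross-check
of a Gibbs kernel, or a synthetic study-scale dataset pushed through the
full EBV -> whole-genome-regression -> cross-validation pipeline -- and
returns plain numbers.  They are the package's own evidence that the
samplers target the right posteriors and that prediction accuracy behaves
the way quantitative genetics says it must (increasing in heritability,
near zero for a null trait, near one for a noiseless trait, and nearly
method-independent on a polygenic architecture).

Simulation studies run at a few hundred genotypes and a few hundred to a
thousand markers with shortened chains (still hundreds of retained draws);
these problem sizes give Monte Carlo error well inside the decision bands
while keeping each study in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blup import compute_ebv, fit_mixed_model
from .crossval import cross_validate, run_full_pipeline
from .io import PhenotypeRecords
from .regression import (
    ChainConfig,
    HyperParams,
    run_chain,
    update_effect_given_variance,
    update_inclusion_and_effect,
    update_locus_variance_bayesA,
    update_pi,
    update_residual_variance,
)
from .simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotype_panel,
    simulate_marker_effects,
    simulate_multi_env_phenotypes,
)

METHODS = ("bayesA", "bayesB", "bayesCpi")


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def kernel_moment_summary(seed: int = 0, n_draws: int = 20_000) -> dict:
    """Empirical means of each Gibbs kernel beside its closed-form target.

    The effect update is checked against its conjugate normal posterior
    (single observation, z = 1, restored residual 2, unit variances ->
    N(1, 0.5)); the variance updates against scaled-inverse-chi-square
    means; pi against the Beta(m-k+1, k+1) mean; and the inclusion
    indicator against the two-component marginal-likelihood ratio.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    y1, z1 = np.array([2.0]), np.array([1.0])
    hp = HyperParams(nu_alpha=5.0, s2_alpha=1.0, nu_e=5.0, s2_e=1.0)

    effect = np.mean([
        update_effect_given_variance(y1, z1, 1.0, 1.0, rng) for _ in range(n_draws)
    ])
    locus_var = np.mean([
        update_locus_variance_bayesA(0.0, hp, rng) for _ in range(n_draws)
    ])
    resid_var = np.mean([
        update_residual_variance(np.empty(0), hp, rng) for _ in range(n_draws)
    ])
    pi_draws = np.mean([update_pi(10, 3, rng) for _ in range(n_draws)])
    incl = np.mean([
        update_inclusion_and_effect(y1, z1, 0.5, 1.0, 1.0, rng)[0]
        for _ in range(n_draws)
    ])
    f_slab = stats.norm.pdf(2.0, 0.0, np.sqrt(2.0))
    f_spike = stats.norm.pdf(2.0, 0.0, 1.0)
    return {
        "effect_mean": float(effect), "effect_expected": 1.0,
        "locus_variance_mean": float(locus_var), "locus_variance_expected": 1.25,
        "residual_variance_mean": float(resid_var), "residual_variance_expected": 5 / 3,
        "pi_mean": float(pi_draws), "pi_expected": 8 / 12,
        "inclusion_rate": float(incl),
        "inclusion_expected": float(f_slab / (f_slab + f_spike)),
        "n_draws": n_draws,
    }


def ridge_equivalence(seed: int = 0, n: int = 100, m: int = 50) -> dict:
    """BayesCpi with pi = 0 and fixed variances against closed-form ridge.

    With the mixture turned off and both variances held constant the
    posterior mean of the marker effects is exactly the ridge estimator
    (Z'Z + lambda I)^-1 Z'y with lambda = sigma2_e / sigma2_alpha, so the
    chain's posterior means must line up with it to Monte Carlo error.
    """
    s2a, s2e = 0.09, 1.0
    rng = np.random.default_rng(seed)
    Z = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
    beta = rng.normal(0, np.sqrt(s2a), m)
    Zc = Z - Z.mean(0)
    y = Zc @ beta + rng.normal(0, np.sqrt(s2e), n)
    ridge = np.linalg.solve(Zc.T @ Zc + (s2e / s2a) * np.eye(m), Zc.T @ (y - y.mean()))
    hp = HyperParams(s2_alpha=s2a, s2_e=s2e, pi_init=0.0, pi_fixed=True)
    ps = run_chain(y, Z, "bayesCpi", ChainConfig(6000, 1000, 5, seed=seed + 1), hp,
                   fixed_effect_variance=s2a, fixed_residual_variance=s2e)
    return {
        "corr": float(np.corrcoef(ps.alpha_mean, ridge)[0, 1]),
        "slope": float(np.polyfit(ridge, ps.alpha_mean, 1)[0]),
        "n": n, "m": m,
    }


def henderson_discrepancy() -> dict:
    """EBVs against direct inversion of the full mixed-model equations.

    A fixed 4-genotype x 2-environment balanced table is fitted by the
    package, then the coefficient matrix of Henderson's equations is built
    explicitly at the same variance components and inverted; the statistic
    is the largest absolute disagreement between the two BLUP vectors.
    """
    values = np.array([[10.0, 12.0], [8.0, 11.0], [13.0, 15.0], [9.0, 10.0]])
    q, r = values.shape
    rows = {
        "genotype_id": np.repeat([f"g{i}" for i in range(q)], r),
        "environment_id": np.tile([f"E{t}" for t in range(r)], q),
        "trait_name": "trait",
        "value": values.ravel(),
    }
    ph = PhenotypeRecords(pd.DataFrame(rows))
    vc = fit_mixed_model(ph, "trait")
    ebv = compute_ebv(ph, "trait", vc)

    y = values.ravel()
    X = np.ones((q * r, 1))
    Z1 = np.kron(np.eye(q), np.ones((r, 1)))
    Z2 = np.kron(np.ones((q, 1)), np.eye(r))
    W = np.hstack([X, Z1, Z2])
    C = W.T @ W
    C[1:1 + q, 1:1 + q] += np.eye(q) * vc.sigma2_eps / vc.sigma2_g
    C[1 + q:, 1 + q:] += np.eye(r) * vc.sigma2_eps / max(vc.sigma2_env, 1e-10)
    theta = np.linalg.inv(C) @ (W.T @ y)
    direct = theta[1:1 + q]
    got = ebv.values.loc[[f"g{i}" for i in range(q)]].to_numpy()
    return {"max_abs_diff": float(np.abs(got - direct).max()), "n": q * r}


# ---------------------------------------------------------------------------
# simulation benchmarks
# ---------------------------------------------------------------------------


def _pipeline_ebv(g, ph, trait="sim_trait"):
    vc = fit_mixed_model(ph, trait)
    return compute_ebv(ph, trait, vc)


def sparse_recovery(
    seed: int = 0,
    n_seeds: int = 5,
    n: int = 300,
    m: int = 1000,
    pi_true: float = 0.9,
    h2: float = 0.5,
    cfg: ChainConfig = ChainConfig(3000, 1000, 2),
) -> dict:
    """BayesCpi on a sparse architecture: does it find pi and the QTL?

    For each replicate, a panel with ~m(1 - pi_true) QTL is simulated at
    heritability h2, EBVs extracted by the mixed model, and one BayesCpi
    chain fitted to the full panel.  Reported are the median (over
    replicates) posterior mean of pi and the median posterior inclusion
    probabilities of true QTL and of null markers.
    """
    pis, qtl_incl, null_incl = [], [], []
    for s in _child_seeds(seed, n_seeds):
        sim = SimulationConfig(n_genotypes=n, n_markers=m, architecture="sparse",
                               pi_true=pi_true, h2=h2, seed=s)
        g, ph, truth = simulate_dataset(sim)
        ebv = _pipeline_ebv(g, ph)
        y = ebv.values.loc[g.sample_ids].to_numpy()
        ps = run_chain(y, g, "bayesCpi", cfg,
                       rng=np.random.default_rng(s + 1))
        pis.append(ps.pi_mean)
        qtl = truth.effects != 0
        qtl_incl.append(ps.inclusion_prob[qtl].mean())
        null_incl.append(ps.inclusion_prob[~qtl].mean())
    return {
        "pi_mean_median": float(np.median(pis)),
        "pi_true": pi_true,
        "qtl_inclusion_median": float(np.median(qtl_incl)),
        "null_inclusion_median": float(np.median(null_incl)),
        "n": n, "m": m, "n_seeds": n_seeds,
    }


def _cv_accuracy_for_trait(g, ph, method, cfg, seed, k=10, repeats=1):
    ebv = _pipeline_ebv(g, ph)
    res = cross_validate(ebv, g, method, cfg, k=k, repeats=repeats, seed=seed)
    return res.accuracy


def heritability_sweep(
    seed: int = 0,
    h2_levels: tuple = (0.1, 0.5, 0.9),
    replicates: int = 5,
    n: int = 300,
    m: int = 150,
    cfg: ChainConfig = ChainConfig(800, 200, 2),
) -> dict:
    """Mean cross-validated accuracy at several heritabilities, same panel.

    One genotype panel is shared across all levels; at each h2, `replicates`
    independent polygenic traits are simulated and pushed through the full
    pipeline (mixed-model EBVs, then 10-fold cross-validated BayesCpi).
    """
    panel_seed, *rep_seeds = _child_seeds(seed, 1 + replicates * len(h2_levels))
    base = SimulationConfig(n_genotypes=n, n_markers=m, seed=panel_seed)
    g = simulate_genotype_panel(base)
    out = {}
    idx = 0
    for h2 in h2_levels:
        accs = []
        for _ in range(replicates):
            s = rep_seeds[idx]
            idx += 1
            sim = SimulationConfig(n_genotypes=n, n_markers=m, h2=h2, seed=s)
            rng = np.random.default_rng(s)
            effects = simulate_marker_effects(sim, rng)
            ph, _ = simulate_multi_env_phenotypes(g, effects, sim, rng)
            accs.append(_cv_accuracy_for_trait(g, ph, "bayesCpi", cfg, seed=s))
        out[h2] = float(np.mean(accs))
    return out


def noiseless_accuracy(seed: int = 0, n: int = 300, m: int = 100,
                       n_qtl: int = 10,
                       cfg: ChainConfig = ChainConfig(800, 200, 2)) -> float:
    """Accuracy at h2 = 1 with fewer markers than genotypes (should be ~1)."""
    s1, s2 = _child_seeds(seed, 2)
    sim = SimulationConfig(n_genotypes=n, n_markers=m, architecture="sparse",
                           pi_true=1 - n_qtl / m, h2=1.0, seed=s1)
    g, ph, _ = simulate_dataset(sim)
    return _cv_accuracy_for_trait(g, ph, "bayesCpi", cfg, seed=s2)


def null_accuracy(seed: int = 0, n: int = 300, m: int = 150,
                  cfg: ChainConfig = ChainConfig(800, 200, 2)) -> float:
    """Accuracy for a pure-noise trait (all marker effects zero; ~0)."""
    s1, s2 = _child_seeds(seed, 2)
    sim = SimulationConfig(n_genotypes=n, n_markers=m, pi_true=1.0, h2=0.0, seed=s1)
    g, ph, _ = simulate_dataset(sim)
    return _cv_accuracy_for_trait(g, ph, "bayesCpi", cfg, seed=s2)


def method_agreement(seed: int = 0, n: int = 300, m: int = 200, h2: float = 0.5,
                     cfg: ChainConfig = ChainConfig(1000, 300, 2)) -> dict:
    """Accuracy of all three methods on one polygenic trait, shared folds.

    On a trait to which every marker contributes, the three priors shrink
    differently but predict almost identically; the figure of merit is the
    largest pairwise difference in mean accuracy.
    """
    s1, s2 = _child_seeds(seed, 2)
    sim = SimulationConfig(n_genotypes=n, n_markers=m, h2=h2, seed=s1)
    g, ph, _ = simulate_dataset(sim)
    ebv = _pipeline_ebv(g, ph)
    accs = {
        method: cross_validate(ebv, g, method, cfg, k=10, repeats=1, seed=s2).accuracy
        for method in METHODS
    }
    accs["max_gap"] = float(max(accs.values()) - min(accs.values()))
    return accs


def pipeline_reproducibility(seed: int = 0,
                             cfg: ChainConfig = ChainConfig(400, 100, 2)) -> bool:
    """Whether two identically seeded end-to-end runs agree bit for bit."""
    sim = SimulationConfig(n_genotypes=60, n_markers=40, h2=0.8,
                           seed=_child_seeds(seed, 1)[0])
    g, ph, _ = simulate_dataset(sim)
    runs = [
        run_full_pipeline(ph, g, traits=["sim_trait"], methods=["bayesB"],
                          cfg=cfg, k=4, repeats=1, seed=seed)
        for _ in range(2)
    ]
    return runs[0][0].fold_correlations == runs[1][0].fold_correlations
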