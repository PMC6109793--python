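"""Full Gibbs chains: ridge equivalence, recovery, equivariance, prediction."""

import numpy as np
import pytest

from bayesgp import (
    BayesAlphabetModel,
    ChainConfig,
    EBVTable,
    GenotypeMatrix,
    HyperParams,
    SimulationConfig,
    ValidationError,
    predict_gebv,
    run_chain,
    simulate_genotype_panel,
    simulate_marker_effects,
)
from bayesgp.regression import METHODS, PosteriorSummary

SHORT = ChainConfig(n_iter=1500, burn_in=500, thin=2, seed=0)


def ridge_problem(seed=7, n=100, m=50, s2a=0.09, s2e=1.0):
    rng = np.random.default_rng(seed)
    Z = rng.binomial(2, rng.uniform(0.1, 0.5, m), (n, m)).astype(float)
    beta = rng.normal(0, np.sqrt(s2a), m)
    Zc = Z - Z.mean(0)
    y = Zc @ beta + rng.normal(0, np.sqrt(s2e), n)
    ridge = np.linalg.solve(Zc.T @ Zc + (s2e / s2a) * np.eye(m), Zc.T @ (y - y.mean()))
    return y, Z, ridge, s2a, s2e


def simulated_response(n=200, m=100, n_qtl=10, h2=0.8, seed=5):
    """Single-stage phenotype: centered dosages x effects + noise at h2."""
    cfg = SimulationConfig(n_genotypes=n, n_markers=m, architecture="sparse",
                           pi_true=1 - n_qtl / m, h2=h2, seed=seed)
    rng = np.random.default_rng(seed)
    g = simulate_genotype_panel(cfg, rng)
    effects = simulate_marker_effects(cfg, rng)
    Zc = g.dosages.astype(float)
    Zc = Zc - Zc.mean(0)
    bv = Zc @ effects
    noise_var = bv.var() * (1 - h2) / h2 if h2 < 1 else 0.0
    y = bv + rng.normal(0, np.sqrt(noise_var), n)
    return y, g, effects, bv


class TestRidgeEquivalence:
    def test_bayescpi_with_fixed_prior_is_ridge_regression(self):
        y, Z, ridge, s2a, s2e = ridge_problem()
        hp = HyperParams(s2_alpha=s2a, s2_e=s2e, pi_init=0.0, pi_fixed=True)
        ps = run_chain(y, Z, "bayesCpi", ChainConfig(6000, 1000, 5, seed=1), hp,
                       fixed_effect_variance=s2a, fixed_residual_variance=s2e)
        corr = np.corrcoef(ps.alpha_mean, ridge)[0, 1]
        slope = np.polyfit(ridge, ps.alpha_mean, 1)[0]
        assert corr > 0.99
        assert 0.95 < slope < 1.05
        assert (ps.inclusion_prob == 1.0).all()


class TestNullSignal:
    def test_zero_response_gives_null_effects(self):
        rng = np.random.default_rng(3)
        Z = rng.binomial(2, 0.3, (60, 30)).astype(float)
        y = np.zeros(60)
        hp = HyperParams(s2_alpha=0.01, s2_e=1.0, pi_init=0.0)
        ps = run_chain(y, Z, "bayesA", SHORT, hp)
        mcse = ps.alpha_sd / np.sqrt(ps.n_retained)
        assert (np.abs(ps.alpha_mean) < 5 * (mcse + 1e-3)).all()
        assert abs(ps.mu_mean) < 0.1


class TestEffectRecovery:
    @pytest.mark.parametrize("method", METHODS)
    def test_recovers_sparse_effects(self, method):
        y, g, effects, _ = simulated_response()
        ps = run_chain(y, g, method, SHORT)
        corr = np.corrcoef(ps.alpha_mean, effects)[0, 1]
        assert corr > 0.5

    def test_sparsity_recovered_by_bayescpi(self):
        y, g, effects, _ = simulated_response(n=200, m=400, n_qtl=20, h2=0.8, seed=9)
        ps = run_chain(y, g, "bayesCpi", SHORT)
        assert ps.pi_mean > 0.5
        qtl = effects != 0
        assert ps.inclusion_prob[qtl].mean() > ps.inclusion_prob[~qtl].mean()


class TestReproducibilityAndEquivariance:
    def test_identical_seed_gives_bit_identical_summaries(self):
        y, g, _, _ = simulated_response(n=60, m=40)
        cfg = ChainConfig(600, 100, 2, seed=42)
        a = run_chain(y, g, "bayesB", cfg)
        b = run_chain(y, g, "bayesB", cfg)
        assert (a.alpha_mean == b.alpha_mean).all()
        assert (a.inclusion_prob == b.inclusion_prob).all()
        assert a.mu_mean == b.mu_mean and a.pi_mean == b.pi_mean

    def test_location_equivariance(self):
        y, g, _, _ = simulated_response(n=80, m=40)
        hp = HyperParams(s2_alpha=0.05, s2_e=1.0, pi_init=0.0)
        cfg = ChainConfig(3000, 500, 2, seed=11)
        a = run_chain(y, g, "bayesA", cfg, hp)
        b = run_chain(y + 50.0, g, "bayesA", cfg, hp)
        assert b.mu_mean - a.mu_mean == pytest.approx(50.0, abs=0.05)
        mcse = (a.alpha_sd + b.alpha_sd) / np.sqrt(a.n_retained)
        assert (np.abs(a.alpha_mean - b.alpha_mean) < 4 * (mcse + 1e-3)).all()

    def test_scale_equivariance_with_rederived_priors(self):
        a_scale = 4.0
        y, g, _, _ = simulated_response(n=80, m=40)
        cfg = ChainConfig(3000, 500, 2, seed=13)
        ps1 = run_chain(y, g, "bayesCpi", cfg)
        ps2 = run_chain(a_scale * y, g, "bayesCpi", cfg)
        big = np.abs(ps1.alpha_mean) > np.quantile(np.abs(ps1.alpha_mean), 0.8)
        ratio = ps2.alpha_mean[big] / ps1.alpha_mean[big]
        assert np.median(ratio) == pytest.approx(a_scale, rel=0.2)


class TestStrandInvariance:
    def test_swapping_ref_alt_leaves_accuracy_unchanged(self):
        # ridge-mode chain so Monte Carlo error is the only slack needed
        y, Z, _, s2a, s2e = ridge_problem(seed=21, n=100, m=30)
        hp = HyperParams(s2_alpha=s2a, s2_e=s2e, pi_init=0.0, pi_fixed=True)
        cfg = ChainConfig(4000, 500, 2, seed=2)
        train, test = np.arange(70), np.arange(70, 100)

        def accuracy(Zm):
            ps = run_chain(y[train], Zm[train], "bayesCpi", cfg, hp,
                           fixed_effect_variance=s2a, fixed_residual_variance=s2e)
            gebv = predict_gebv(ps, Zm[test])
            return np.corrcoef(y[test], gebv)[0, 1]

        assert accuracy(Z) == pytest.approx(accuracy(2.0 - Z), abs=0.02)


class TestPrediction:
    def make_summary(self, alpha, centers, marker_ids=None):
        m = len(alpha)
        return PosteriorSummary(
            method="bayesA", alpha_mean=np.array(alpha, float),
            alpha_sd=np.zeros(m), mu_mean=0.0, pi_mean=0.0, sigma2_e_mean=1.0,
            inclusion_prob=np.ones(m), column_centers=np.array(centers, float),
            n_retained=100, marker_ids=marker_ids,
        )

    def test_zero_effects_give_zero_gebv(self):
        ps = self.make_summary([0.0, 0.0], [1.0, 0.5])
        Z = np.array([[0, 1], [2, 2]], float)
        assert (predict_gebv(ps, Z) == 0).all()

    def test_hand_arithmetic_single_marker(self):
        ps = self.make_summary([2.0], [1.0])
        Z = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(predict_gebv(ps, Z), [-2.0, 0.0, 2.0])

    def test_consistent_column_permutation_is_invariant(self, rng):
        m = 8
        alpha = rng.normal(size=m)
        centers = rng.uniform(0, 2, m)
        Z = rng.integers(0, 3, (12, m)).astype(float)
        perm = rng.permutation(m)
        base = predict_gebv(self.make_summary(alpha, centers), Z)
        permuted = predict_gebv(self.make_summary(alpha[perm], centers[perm]), Z[:, perm])
        np.testing.assert_allclose(base, permuted)

    def test_marker_mismatch_raises_with_names(self):
        ps = self.make_summary([1.0, 2.0], [1.0, 1.0], marker_ids=["m1", "m2"])
        g = GenotypeMatrix(["s1"], ["m1", "m3"], np.array([[0, 1]]))
        with pytest.raises(ValidationError, match="m2"):
            predict_gebv(ps, g)


class TestModelSurface:
    def test_from_ebv_aligns_and_fits(self):
        y, g, _, _ = simulated_response(n=60, m=30)
        import pandas as pd

        order = np.random.default_rng(0).permutation(60)
        table = EBVTable("sim", pd.Series(y[order], index=np.array(g.sample_ids)[order]))
        model = BayesAlphabetModel.from_ebv(table, g, "bayesCpi")
        res = model.fit(config=ChainConfig(600, 100, 2), seed=1)
        assert res.effects.shape == (30, 3)
        assert "bayesCpi" in res.summary()
        preds = res.predict(g)
        assert np.corrcoef(preds.to_numpy(), y)[0, 1] > 0.5

    def test_missing_calls_rejected(self):
        g = GenotypeMatrix(["a", "b"], ["m"], np.array([[0], [1]]),
                           np.array([[True], [False]]))
        with pytest.raises(ValidationError, match="impute"):
            BayesAlphabetModel(np.zeros(2), g)

    def test_tiny_panels_warn(self):
        rng = np.random.default_rng(1)
        Z = rng.binomial(2, 0.4, (5, 6)).astype(float)
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="fewer than 10"):
            run_chain(y, Z, "bayesA", ChainConfig(200, 50, 1, seed=0),
                      HyperParams(s2_alpha=0.1, s2_e=1.0, pi_init=0.0))
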