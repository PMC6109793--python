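"""Mixed-model EBV extraction: REML estimates, BLUP shrinkage, oracles."""

import numpy as np
import pandas as pd
import pytest

from bayesgp import (
    PhenotypeMixedModel,
    PhenotypeRecords,
    ValidationError,
    compute_ebv,
    fit_mixed_model,
)
from bayesgp.blup import VarianceComponents


def records_from_matrix(values: np.ndarray, trait="trait") -> PhenotypeRecords:
    """Build a balanced table from a (genotypes x environments) value matrix."""
    q, r = values.shape
    rows = {
        "genotype_id": np.repeat([f"g{i}" for i in range(q)], r),
        "environment_id": np.tile([f"E{t}" for t in range(r)], q),
        "trait_name": trait,
        "value": values.ravel(),
    }
    return PhenotypeRecords(pd.DataFrame(rows))


def simulate_balanced(q, r, s2g, s2env, s2eps, rng):
    g = rng.normal(0, np.sqrt(s2g), q)
    e = rng.normal(0, np.sqrt(s2env), r)
    eps = rng.normal(0, np.sqrt(s2eps), (q, r))
    return 5.0 + g[:, None] + e[None, :] + eps, g


class TestHendersonOracle:
    def brute_force_blups(self, values, s2g, s2env, s2eps):
        """Explicit construction and inversion of the full MME matrix."""
        q, r = values.shape
        y = values.ravel()
        n = q * r
        X = np.ones((n, 1))
        Z1 = np.kron(np.eye(q), np.ones((r, 1)))
        Z2 = np.kron(np.ones((q, 1)), np.eye(r))
        W = np.hstack([X, Z1, Z2])
        C = W.T @ W
        C[1:1 + q, 1:1 + q] += np.eye(q) * s2eps / s2g
        C[1 + q:, 1 + q:] += np.eye(r) * s2eps / s2env
        theta = np.linalg.inv(C) @ (W.T @ y)
        return theta[1:1 + q]

    def test_ebvs_match_direct_mme_inversion(self, balanced_table):
        ph = PhenotypeRecords(balanced_table)
        vc = fit_mixed_model(ph, "BY")
        ebv = compute_ebv(ph, "BY", vc)
        values = balanced_table.pivot_table(
            index="genotype_id", columns="environment_id", values="value"
        ).to_numpy()
        expected = self.brute_force_blups(values, vc.sigma2_g,
                                          max(vc.sigma2_env, 1e-10), vc.sigma2_eps)
        got = ebv.values.loc[[f"g{i+1}" for i in range(4)]].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_blups_match_gls_route(self, balanced_table):
        """Independent check through V-inverse GLS instead of the MME."""
        ph = PhenotypeRecords(balanced_table)
        vc = fit_mixed_model(ph, "BY")
        ebv = compute_ebv(ph, "BY", vc)
        values = balanced_table.pivot_table(
            index="genotype_id", columns="environment_id", values="value"
        ).to_numpy()
        q, r = values.shape
        y = values.ravel()
        Z1 = np.kron(np.eye(q), np.ones((r, 1)))
        Z2 = np.kron(np.ones((q, 1)), np.eye(r))
        V = (vc.sigma2_g * Z1 @ Z1.T + max(vc.sigma2_env, 1e-10) * Z2 @ Z2.T
             + vc.sigma2_eps * np.eye(q * r))
        Vi = np.linalg.inv(V)
        ones = np.ones(q * r)
        beta = (ones @ Vi @ y) / (ones @ Vi @ ones)
        u = vc.sigma2_g * Z1.T @ Vi @ (y - beta * ones)
        got = ebv.values.loc[[f"g{i+1}" for i in range(4)]].to_numpy()
        np.testing.assert_allclose(got, u, atol=1e-6)


class TestRemlAgainstStatsmodels:
    def test_variance_components_match_mixedlm(self, rng):
        values, _ = simulate_balanced(40, 3, 2.0, 1.0, 1.0, rng)
        ph = records_from_matrix(values)
        vc = fit_mixed_model(ph, "trait")

        import statsmodels.api as sm

        df = ph.data.copy()
        df["grp"] = 1
        md = sm.MixedLM.from_formula(
            "value ~ 1", groups="grp", re_formula="0",
            vc_formula={"g": "0 + C(genotype_id)", "e": "0 + C(environment_id)"},
            data=df,
        )
        with np.errstate(all="ignore"):
            ref = md.fit(reml=True)
        # vcomp keys sort alphabetically: e (environment) then g (genotype)
        np.testing.assert_allclose(vc.sigma2_env, ref.vcomp[0], rtol=0.02, atol=1e-4)
        np.testing.assert_allclose(vc.sigma2_g, ref.vcomp[1], rtol=0.02, atol=1e-4)
        np.testing.assert_allclose(vc.sigma2_eps, ref.scale, rtol=0.02, atol=1e-4)
        np.testing.assert_allclose(vc.mu_hat, ref.params.iloc[0], atol=1e-4)


class TestDegenerateAndLimits:
    def test_identical_observations(self):
        values = np.full((5, 3), 7.5)
        vc = fit_mixed_model(records_from_matrix(values), "trait")
        assert vc.mu_hat == pytest.approx(7.5)
        assert vc.sigma2_g <= 1e-9 and vc.sigma2_eps <= 1e-9
        assert vc.converged

    def test_no_shrinkage_limit_recovers_genotype_means(self, rng):
        values, _ = simulate_balanced(6, 3, 4.0, 0.0, 1.0, rng)
        ph = records_from_matrix(values)
        vc = VarianceComponents(1.0, 1e-10, 1e-9, values.mean(), True, 0)
        ebv = compute_ebv(ph, "trait", vc)
        expected = values.mean(axis=1) - values.mean()
        np.testing.assert_allclose(
            ebv.values.loc[[f"g{i}" for i in range(6)]].to_numpy(), expected, atol=1e-5
        )

    def test_total_shrinkage_limit_zeroes_ebvs(self, rng):
        values, _ = simulate_balanced(6, 3, 4.0, 1.0, 1.0, rng)
        ph = records_from_matrix(values)
        vc = VarianceComponents(1e-12, 1.0, 1.0, values.mean(), True, 0)
        ebv = compute_ebv(ph, "trait", vc)
        assert np.abs(ebv.values.to_numpy()).max() < 1e-6

    def test_single_environment_warns_and_fits(self, rng):
        values, _ = simulate_balanced(10, 1, 2.0, 0.0, 1.0, rng)
        ph = records_from_matrix(values)
        with pytest.warns(UserWarning, match="one environment"):
            vc = fit_mixed_model(ph, "trait")
        assert vc.sigma2_env == 0.0

    def test_absent_trait_errors(self, balanced_table):
        ph = PhenotypeRecords(balanced_table)
        with pytest.raises(ValidationError, match="absent"):
            fit_mixed_model(ph, "no_such_trait")


class TestInvariants:
    def test_shrinkage_never_exceeds_mean_deviation(self, rng):
        values, _ = simulate_balanced(25, 3, 2.0, 1.0, 1.5, rng)
        ph = records_from_matrix(values)
        vc = fit_mixed_model(ph, "trait")
        ebv = compute_ebv(ph, "trait", vc)
        deviations = values.mean(axis=1) - values.mean()
        got = ebv.values.loc[[f"g{i}" for i in range(25)]].to_numpy()
        assert (np.abs(got) <= np.abs(deviations) + 1e-8).all()

    def test_replication_weighted_ebvs_center_near_zero(self, rng):
        values, _ = simulate_balanced(30, 3, 2.0, 1.0, 1.0, rng)
        vc_scale = values.std()
        ph = records_from_matrix(values)
        vc = fit_mixed_model(ph, "trait")
        ebv = compute_ebv(ph, "trait", vc)
        assert abs(ebv.values.sum()) < 1e-6 * vc_scale * len(ebv)

    def test_location_shift_moves_mean_only(self, rng):
        values, _ = simulate_balanced(15, 3, 2.0, 1.0, 1.0, rng)
        ph1 = records_from_matrix(values)
        ph2 = records_from_matrix(values + 100.0)
        vc1 = fit_mixed_model(ph1, "trait")
        vc2 = fit_mixed_model(ph2, "trait")
        assert vc2.mu_hat - vc1.mu_hat == pytest.approx(100.0, abs=1e-6)
        e1 = compute_ebv(ph1, "trait", vc1).values.to_numpy()
        e2 = compute_ebv(ph2, "trait", vc2).values.to_numpy()
        np.testing.assert_allclose(e1, e2, atol=1e-8)

    def test_scaling_scales_ebvs_and_variances(self, rng):
        a = 3.0
        values, _ = simulate_balanced(15, 3, 2.0, 1.0, 1.0, rng)
        ph1 = records_from_matrix(values)
        ph2 = records_from_matrix(values * a)
        vc1 = fit_mixed_model(ph1, "trait")
        vc2 = fit_mixed_model(ph2, "trait")
        assert vc2.sigma2_g == pytest.approx(a**2 * vc1.sigma2_g, rel=1e-4)
        assert vc2.sigma2_eps == pytest.approx(a**2 * vc1.sigma2_eps, rel=1e-4)
        e1 = compute_ebv(ph1, "trait", vc1).values.to_numpy()
        e2 = compute_ebv(ph2, "trait", vc2).values.to_numpy()
        np.testing.assert_allclose(e2, a * e1, atol=1e-6)


class TestParameterRecovery:
    def test_single_dataset_recovery_within_30pct(self, rng):
        values, _ = simulate_balanced(50, 3, 2.0, 1.0, 1.0, rng)
        vc = fit_mixed_model(records_from_matrix(values), "trait")
        assert vc.converged
        assert vc.sigma2_g == pytest.approx(2.0, rel=0.3)
        assert vc.sigma2_eps == pytest.approx(1.0, rel=0.3)
        # with only 3 environment levels sigma2_env has ~2 df of information,
        # so only an order-of-magnitude statement is meaningful
        assert 0.05 < vc.sigma2_env < 10.0

    def test_median_relative_error_over_replicates(self):
        errs_g, errs_eps = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            values, _ = simulate_balanced(100, 3, 2.0, 1.0, 1.0, rng)
            vc = fit_mixed_model(records_from_matrix(values), "trait")
            errs_g.append(abs(vc.sigma2_g - 2.0) / 2.0)
            errs_eps.append(abs(vc.sigma2_eps - 1.0) / 1.0)
        assert np.median(errs_g) < 0.25
        assert np.median(errs_eps) < 0.25


class TestModelSurface:
    def test_results_summary_reports_components(self, balanced_table):
        ph = PhenotypeRecords(balanced_table)
        res = PhenotypeMixedModel.from_records(ph, "BY").fit()
        text = res.summary()
        assert "sigma2_genotype" in text and "genotypes:        4" in text
        assert res.ebv_table().trait_name == "BY"

    def test_genotype_without_trait_observations_excluded(self, balanced_table):
        extra = pd.DataFrame([{"genotype_id": "g9", "environment_id": "E1",
                               "trait_name": "other", "value": 1.0}])
        ph = PhenotypeRecords(pd.concat([balanced_table, extra], ignore_index=True))
        with pytest.warns(UserWarning, match="excluded"):
            vc = fit_mixed_model(ph, "BY")
        with pytest.warns(UserWarning, match="excluded"):
            ebv = compute_ebv(ph, "BY", vc)
        assert "g9" not in ebv.values.index
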