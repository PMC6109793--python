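"""Two-way random-effects mixed model for multi-environment trial means.

The model for the plot mean of genotype i in environment t is

    y_it = mu + g_i + e_t + eps_it,

with genotype effects g_i ~ N(0, sigma2_g), environment (year) effects
e_t ~ N(0, sigma2_env) and residuals eps_it ~ N(0, sigma2_eps), all
mutually independent.  Variance components are estimated by EM-REML on
Henderson's mixed-model equations; the genotype BLUPs at the REML estimates
are the estimated breeding values (EBVs) passed on to genomic prediction.

Environments are treated as random alongside genotypes: with only a handful
of years the environmental variance is weakly identified either way, and
the symmetric treatment keeps breeding values estimable.  Unbalanced data
are supported throughout -- nothing assumes equal replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .io import EBVTable, PhenotypeRecords, ValidationError

VAR_FLOOR = 1e-10


@dataclass
class VarianceComponents:
    """REML variance-component estimates for the two-way random model."""

    sigma2_g: float
    sigma2_env: float
    sigma2_eps: float
    mu_hat: float
    converged: bool
    n_iter: int
    loglik: float = np.nan

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_env", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


class PhenotypeMixedModel:
    """EM-REML fit of ``y = mu + genotype + environment + residual``.

    Construct from a long-format DataFrame with columns genotype_id,
    environment_id and value (one trait), or via :meth:`from_records` for a
    :class:`~bayesgp.io.PhenotypeRecords` plus trait name.
    """

    def __init__(self, data: pd.DataFrame, trait_name: str = "trait"):
        df = data.copy()
        for col in ("genotype_id", "environment_id", "value"):
            if col not in df.columns:
                raise ValidationError(f"mixed-model data lacks column {col!r}")
        self.trait_name = trait_name
        self.y = df["value"].to_numpy(dtype=float)
        if len(self.y) == 0:
            raise ValidationError("no observations")
        g_codes, g_ids = pd.factorize(df["genotype_id"].astype(str))
        e_codes, e_ids = pd.factorize(df["environment_id"].astype(str))
        self.genotype_ids = [str(s) for s in g_ids]
        self.environment_ids = [str(s) for s in e_ids]
        self._g_codes = g_codes
        self._e_codes = e_codes
        self.n_obs = len(self.y)
        self.n_genotypes = len(self.genotype_ids)
        self.n_environments = len(self.environment_ids)
        if self.n_genotypes < 2:
            raise ValidationError("mixed model needs >= 2 genotypes")
        self.single_environment = self.n_environments < 2
        if self.single_environment:
            warnings.warn(
                "only one environment: environmental variance is confounded "
                "with the grand mean and is fixed at 0",
                stacklevel=2,
            )

    @classmethod
    def from_records(cls, ph: PhenotypeRecords, trait_name: str) -> "PhenotypeMixedModel":
        sub = ph.for_trait(trait_name)
        other = set(ph.genotypes()) - set(sub["genotype_id"])
        if other:
            warnings.warn(
                f"{len(other)} genotypes have no observations for trait "
                f"{trait_name!r} and are excluded",
                stacklevel=2,
            )
        return cls(sub, trait_name)

    # -- design matrices -------------------------------------------------

    def _incidence(self) -> tuple[np.ndarray, np.ndarray | None]:
        n, q, r = self.n_obs, self.n_genotypes, self.n_environments
        Z1 = np.zeros((n, q))
        Z1[np.arange(n), self._g_codes] = 1.0
        if self.single_environment:
            return Z1, None
        Z2 = np.zeros((n, r))
        Z2[np.arange(n), self._e_codes] = 1.0
        return Z1, Z2

    # -- REML log-likelihood (Woodbury form, cheap in q + r) -------------

    def _reml_loglik(self, s2g, s2env, s2eps) -> float:
        y = self.y
        n = self.n_obs
        Z1, Z2 = self._incidence()
        W = Z1 if Z2 is None else np.hstack([Z1, Z2])
        gdiag = np.full(self.n_genotypes, s2g)
        if Z2 is not None:
            gdiag = np.concatenate([gdiag, np.full(self.n_environments, s2env)])
        A = W.T @ W / s2eps + np.diag(1.0 / gdiag)
        cho = cho_factor(A, lower=True)
        logdet_A = 2.0 * np.log(np.diag(cho[0])).sum()
        logdet_V = n * np.log(s2eps) + logdet_A + np.log(gdiag).sum()

        def vinv(x):
            return (x - W @ cho_solve(cho, W.T @ x) / s2eps) / s2eps

        ones = np.ones(n)
        vy = vinv(y)
        vx = vinv(ones)
        xvx = ones @ vx
        xvy = ones @ vy
        ypy = y @ vy - xvy**2 / xvx
        return -0.5 * (logdet_V + np.log(xvx) + ypy)

    # -- Henderson mixed-model equations ---------------------------------

    def _solve_mme(self, s2g, s2env, s2eps):
        """Solve the MME at given variances; returns (mu, u, v, Cinv, theta, Wty)."""
        Z1, Z2 = self._incidence()
        ones = np.ones((self.n_obs, 1))
        blocks = [ones, Z1] if Z2 is None else [ones, Z1, Z2]
        W = np.hstack(blocks)
        WtW = W.T @ W
        Wty = W.T @ self.y
        C = WtW.copy()
        q = self.n_genotypes
        idx = np.arange(1, 1 + q)
        C[idx, idx] += s2eps / max(s2g, VAR_FLOOR)
        if Z2 is not None:
            idx2 = np.arange(1 + q, C.shape[0])
            C[idx2, idx2] += s2eps / max(s2env, VAR_FLOOR)
        cho = cho_factor(C, lower=True)
        theta = cho_solve(cho, Wty)
        Cinv = cho_solve(cho, np.eye(C.shape[0]))
        mu = theta[0]
        u = theta[1:1 + q]
        v = None if Z2 is None else theta[1 + q:]
        return mu, u, v, Cinv, theta, Wty

    # -- fitting ----------------------------------------------------------

    def fit(self, tol: float = 1e-8, max_iter: int = 1000) -> "MixedModelResults":
        """EM-REML iteration until the REML log-likelihood change < ``tol``."""
        y = self.y
        n, q, r = self.n_obs, self.n_genotypes, self.n_environments
        ybar = y.mean()
        vary = y.var(ddof=1) if n > 1 else 0.0
        if vary <= VAR_FLOOR:
            # degenerate: all observations (numerically) identical
            vc = VarianceComponents(VAR_FLOOR, 0.0 if self.single_environment else VAR_FLOOR,
                                    VAR_FLOOR, ybar, True, 0)
            return MixedModelResults(self, vc)

        k = 2 if self.single_environment else 3
        s2g = s2env = s2eps = max(vary / k, VAR_FLOOR)
        if self.single_environment:
            s2env = 0.0
        ll_prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            mu, u, v, Cinv, theta, Wty = self._solve_mme(s2g, s2env, s2eps)
            tr_g = np.trace(Cinv[1:1 + q, 1:1 + q])
            s2g_new = (u @ u + s2eps * tr_g) / q
            if not self.single_environment:
                tr_e = np.trace(Cinv[1 + q:, 1 + q:])
                s2env_new = (v @ v + s2eps * tr_e) / r
            else:
                s2env_new = 0.0
            s2eps_new = (y @ y - theta @ Wty) / (n - 1)
            s2g = max(s2g_new, VAR_FLOOR)
            s2env = max(s2env_new, VAR_FLOOR) if not self.single_environment else 0.0
            s2eps = max(s2eps_new, VAR_FLOOR)
            ll = self._reml_loglik(s2g, max(s2env, VAR_FLOOR), s2eps)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        vc = VarianceComponents(s2g, s2env, s2eps, float(mu), converged, n_iter, float(ll))
        return MixedModelResults(self, vc)


class MixedModelResults:
    """Results wrapper: variance components plus genotype/environment BLUPs."""

    def __init__(self, model: PhenotypeMixedModel, vc: VarianceComponents):
        self.model = model
        self.vc = vc
        mu, u, v, _, _, _ = model._solve_mme(
            max(vc.sigma2_g, VAR_FLOOR),
            max(vc.sigma2_env, VAR_FLOOR),
            max(vc.sigma2_eps, VAR_FLOOR),
        )
        self.mu_hat = float(mu)
        self.genotype_blups = pd.Series(u, index=model.genotype_ids, name="ebv")
        self.environment_blups = (
            None if v is None else pd.Series(v, index=model.environment_ids)
        )

    @property
    def converged(self) -> bool:
        return self.vc.converged

    def ebv_table(self) -> EBVTable:
        return EBVTable(self.model.trait_name, self.genotype_blups)

    def summary(self) -> str:
        vc = self.vc
        h2_line = vc.sigma2_g / max(vc.sigma2_g + vc.sigma2_eps, VAR_FLOOR)
        lines = [
            "Two-way random-effects mixed model (EM-REML)",
            "=" * 52,
            f"trait:            {self.model.trait_name}",
            f"observations:     {self.model.n_obs}",
            f"genotypes:        {self.model.n_genotypes}",
            f"environments:     {self.model.n_environments}",
            f"converged:        {vc.converged} ({vc.n_iter} iterations)",
            f"REML loglik:      {vc.loglik:.6f}",
            "-" * 52,
            f"grand mean (mu):  {vc.mu_hat:.6g}",
            f"sigma2_genotype:  {vc.sigma2_g:.6g}",
            f"sigma2_env:       {vc.sigma2_env:.6g}",
            f"sigma2_residual:  {vc.sigma2_eps:.6g}",
            f"plot-level h2:    {h2_line:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_mixed_model(
    ph: PhenotypeRecords, trait_name: str, tol: float = 1e-8, max_iter: int = 1000
) -> VarianceComponents:
    """REML variance components for one trait of a phenotype table."""
    return PhenotypeMixedModel.from_records(ph, trait_name).fit(tol, max_iter).vc


def compute_ebv(ph: PhenotypeRecords, trait_name: str, vc: VarianceComponents) -> EBVTable:
    """Genotype BLUPs (EBVs) at given variance components.

    Solves the mixed-model equations once at ``vc``; genotypes without
    observations for the trait are excluded (with a warning from the model
    constructor).
    """
    model = PhenotypeMixedModel.from_records(ph, trait_name)
    return MixedModelResults(model, vc).ebv_table()
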