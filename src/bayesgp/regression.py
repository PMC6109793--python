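"""Bayesian whole-genome regression: BayesA, BayesB and BayesC-pi samplers.

The model regresses a vector of breeding values y (length N) on a centered
SNP dosage matrix Z (N x M):

    y_i = mu + sum_j Z_ij * alpha_j + e_i,     e_i ~ N(0, sigma2_e),

with the three classical priors on the marker effects alpha_j:

* BayesA   -- every marker has an effect; alpha_j | sigma2_j ~ N(0, sigma2_j)
  with locus-specific variances under scaled-inverse-chi-square priors.
* BayesB   -- a mixture: with probability pi the effect is exactly zero,
  otherwise normal with a locus-specific scaled-inverse-chi-square variance.
  Inclusion indicators are sampled with the effect integrated out
  (stochastic-search variable selection); pi is sampled by default.
* BayesCpi -- the mixture with a single common slab variance, and pi treated
  as unknown with a uniform prior (Beta-Bernoulli update).

Inference is a systematic-scan Gibbs sampler; the fixed update order
(intercept, markers in index order, variances, pi, residual variance) makes
runs bit-reproducible given a seed.  Posterior means of the marker effects
over the retained draws give genomic estimated breeding values (GEBVs) by
summing effects over loci on centered dosages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import EBVTable, GenotypeMatrix, ValidationError

METHODS = ("bayesA", "bayesB", "bayesCpi")

_METHOD_ALIASES = {m.lower(): m for m in METHODS}
_METHOD_ALIASES.update({"bayesc": "bayesCpi", "bayescpi": "bayesCpi"})


def _canonical_method(method: str) -> str:
    try:
        return _METHOD_ALIASES[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None


class ChainError(RuntimeError):
    """The sampler reached a non-finite state."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings.

    Defaults are 30,000 iterations with a 10,000-iteration burn-in and
    thinning interval 20, i.e. 1,000 retained draws.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int | None = None

    def __post_init__(self):
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValidationError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_retained < 50:
            raise ValidationError(
                f"only {self.n_retained} retained draws; need >= 50 "
                "(reduce thin or burn_in, or raise n_iter)"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def default_chain_config() -> ChainConfig:
    """The chain settings used throughout: 30,000 / 10,000 / 20."""
    return ChainConfig()


@dataclass(frozen=True)
class HyperParams:
    """Prior hyperparameters for the marker-effect and residual variances.

    ``nu_alpha``/``s2_alpha`` are the degrees of freedom and scale of the
    scaled-inverse-chi-square prior on marker-effect variances (slab
    variance for BayesCpi); ``nu_e``/``s2_e`` the same for the residual.
    ``pi_init`` is the starting probability that a marker has zero effect
    (identically 0 for BayesA); ``pi_fixed`` holds pi at that value instead
    of sampling it.  ``r2_partition`` records the assumed fraction of the
    response variance attributed to markers when the scales were derived.
    """

    nu_alpha: float = 5.0
    s2_alpha: float = 1.0
    nu_e: float = 5.0
    s2_e: float = 1.0
    pi_init: float = 0.5
    pi_fixed: bool = False
    r2_partition: float = 0.5

    def __post_init__(self):
        if self.nu_alpha <= 2 or self.nu_e <= 2:
            raise ValidationError("prior df must exceed 2 for a finite prior mean")
        if not 0.0 <= self.pi_init <= 1.0:
            raise ValidationError("pi_init must lie in [0, 1]")
        if not 0.0 < self.r2_partition < 1.0:
            raise ValidationError("r2_partition must lie in (0, 1)")
        if self.s2_alpha <= 0 or self.s2_e <= 0:
            raise ValidationError("prior scales must be positive")


def derive_hyperparameters(
    y: np.ndarray,
    z: np.ndarray,
    r2_partition: float = 0.5,
    pi_init: float = 0.0,
    nu_alpha: float = 5.0,
    nu_e: float = 5.0,
) -> HyperParams:
    """Derive prior scales from an assumed variance partition.

    A fraction ``r2_partition`` of var(y) is attributed to the markers and
    the rest to the residual.  With M_Sx the summed column variance of the
    centered dosage matrix ``z`` and an expected fraction ``1 - pi_init`` of
    markers in the model, the scales solve the prior-mean identities

        s2_e     = var(y) (1 - R2) (nu_e + 2) / nu_e
        s2_alpha = var(y) R2 (nu_alpha + 2) / (nu_alpha MSx (1 - pi_init))

    so that the implied prior means of the residual and per-marker genetic
    variances reproduce the partition.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValidationError("need >= 2 response values to derive hyperparameters")
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValidationError("response has zero variance; cannot derive prior scales")
    z = np.asarray(z, dtype=float)
    msx = float(np.sum(np.var(z, axis=0)))
    if msx <= 0:
        raise ValidationError("all markers are monomorphic; cannot derive prior scales")
    if pi_init >= 1.0:
        raise ValidationError("pi_init must be < 1 to derive a slab scale")
    s2_e = vy * (1.0 - r2_partition) * (nu_e + 2.0) / nu_e
    s2_alpha = (
        vy * r2_partition * (nu_alpha + 2.0)
        / (nu_alpha * msx * (1.0 - pi_init))
    )
    return HyperParams(
        nu_alpha=nu_alpha, s2_alpha=s2_alpha, nu_e=nu_e, s2_e=s2_e,
        pi_init=pi_init, r2_partition=r2_partition,
    )


# ---------------------------------------------------------------------------
# single Gibbs updates (closed-form full conditionals)
# ---------------------------------------------------------------------------


def _sample_scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator) -> float:
    # X ~ ScaledInvChi2(df, scale)  <=>  X = df * scale / chi2(df)
    return df * scale / rng.chisquare(df)


def _sample_effect(r: float, c: float, sigma2_j: float, sigma2_e: float,
                   rng: np.random.Generator) -> float:
    # conjugate normal full conditional; r = z_j' y_resid (with j restored),
    # c = z_j'z_j
    v = sigma2_e / (c + sigma2_e / sigma2_j)
    mean = v * r / sigma2_e
    return mean + math.sqrt(v) * rng.standard_normal()


def _inclusion_probability(r: float, c: float, pi: float, sigma2_slab: float,
                           sigma2_e: float) -> float:
    """P(delta_j = 1 | ...) with the effect integrated out, in log space."""
    if pi >= 1.0:
        return 0.0
    if pi <= 0.0:
        return 1.0
    v = 1.0 / (c / sigma2_e + 1.0 / sigma2_slab)
    log_bf = 0.5 * math.log(v / sigma2_slab) + 0.5 * v * (r / sigma2_e) ** 2
    if not math.isfinite(log_bf):
        raise ChainError("non-finite marginal-likelihood ratio in inclusion update")
    log_odds = math.log1p(-pi) - math.log(pi) + log_bf
    if log_odds > 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    return math.exp(log_odds) / (1.0 + math.exp(log_odds))


def update_effect_given_variance(y_resid: np.ndarray, z_j: np.ndarray,
                                 sigma2_j: float, sigma2_e: float,
                                 rng: np.random.Generator) -> float:
    """Draw alpha_j from its conjugate normal full conditional.

    ``y_resid`` must have marker j's contribution restored (i.e. exclude
    alpha_j from the current fit).
    """
    if sigma2_j <= 0 or sigma2_e <= 0:
        raise ValidationError("variances must be positive")
    y_resid = np.asarray(y_resid, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if not (np.isfinite(y_resid).all() and np.isfinite(z_j).all()):
        raise ValidationError("non-finite inputs to effect update")
    return _sample_effect(float(z_j @ y_resid), float(z_j @ z_j),
                          sigma2_j, sigma2_e, rng)


def update_locus_variance_bayesA(alpha_j: float, hp: HyperParams,
                                 rng: np.random.Generator) -> float:
    """Draw sigma2_j ~ ScaledInvChi2(nu+1, (nu s2 + alpha_j^2)/(nu+1))."""
    if not math.isfinite(alpha_j):
        raise ValidationError("non-finite effect")
    df = hp.nu_alpha + 1.0
    scale = (hp.nu_alpha * hp.s2_alpha + alpha_j**2) / df
    return _sample_scaled_inv_chi2(df, scale, rng)


def update_inclusion_and_effect(y_resid: np.ndarray, z_j: np.ndarray, pi: float,
                                sigma2_slab: float, sigma2_e: float,
                                rng: np.random.Generator) -> tuple[int, float]:
    """Draw (delta_j, alpha_j) for the spike-and-slab mixture.

    delta_j comes from its Bernoulli full conditional with alpha_j
    integrated out (slab-vs-spike marginal-likelihood ratio); the effect is
    then drawn from the conjugate normal if included, else set to zero.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValidationError("pi must lie in [0, 1]")
    y_resid = np.asarray(y_resid, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    r = float(z_j @ y_resid)
    c = float(z_j @ z_j)
    p1 = _inclusion_probability(r, c, pi, sigma2_slab, sigma2_e)
    if rng.random() < p1:
        return 1, _sample_effect(r, c, sigma2_slab, sigma2_e, rng)
    return 0, 0.0


def update_pi(m: int, k: int, rng: np.random.Generator) -> float:
    """Draw pi ~ Beta(m - k + 1, k + 1): uniform prior, k of m markers in."""
    if not 0 <= k <= m:
        raise ValidationError("need 0 <= k <= m")
    return rng.beta(m - k + 1.0, k + 1.0)


def update_residual_variance(residuals: np.ndarray, hp: HyperParams,
                             rng: np.random.Generator) -> float:
    """Draw sigma2_e ~ ScaledInvChi2(nu_e + n, (nu_e s2_e + e'e)/(nu_e + n))."""
    residuals = np.asarray(residuals, dtype=float)
    if not np.isfinite(residuals).all():
        raise ValidationError("non-finite residuals")
    n = residuals.size
    df = hp.nu_e + n
    scale = (hp.nu_e * hp.s2_e + float(residuals @ residuals)) / df
    return _sample_scaled_inv_chi2(df, scale, rng)


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Posterior-mean summaries of one chain, sufficient for prediction."""

    method: str
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    mu_mean: float
    pi_mean: float
    sigma2_e_mean: float
    inclusion_prob: np.ndarray
    column_centers: np.ndarray
    n_retained: int
    marker_ids: list | None = None
    trace: dict | None = None


def _as_dosage_array(g) -> tuple[np.ndarray, list | None]:
    if isinstance(g, GenotypeMatrix):
        if g.has_missing:
            raise ValidationError("genotype matrix has missing calls; impute first")
        return np.asarray(g.dosages, dtype=float), list(g.marker_ids)
    z = np.asarray(g, dtype=float)
    if z.ndim != 2:
        raise ValidationError("dosage array must be 2-D")
    return z, None


def run_chain(
    y: np.ndarray,
    g,
    method: str,
    cfg: ChainConfig | None = None,
    hp: HyperParams | None = None,
    rng: np.random.Generator | None = None,
    fixed_effect_variance: float | None = None,
    fixed_residual_variance: float | None = None,
) -> PosteriorSummary:
    """Run one Gibbs chain and return posterior-mean summaries.

    Parameters
    ----------
    y
        Response vector (EBVs), length N.
    g
        :class:`GenotypeMatrix` (no missing calls) or a plain N x M dosage
        array.  Columns are centered internally; the centers are stored in
        the summary and re-used at prediction time.
    method
        One of ``bayesA``, ``bayesB``, ``bayesCpi``.
    cfg, hp
        Chain settings and prior hyperparameters.  When ``hp`` is None it is
        derived from the data (``pi_init`` 0 for BayesA, 0.5 otherwise).
    rng
        Optional generator; by default one is created from ``cfg.seed``.
    fixed_effect_variance, fixed_residual_variance
        Hold the corresponding variance(s) at a constant instead of sampling
        them -- with ``pi_fixed`` and pi = 0 this turns BayesCpi into exact
        Bayesian ridge regression, used as an analytic cross-check.
    """
    method = _canonical_method(method)
    cfg = cfg or default_chain_config()
    y = np.asarray(y, dtype=float).ravel()
    Z, marker_ids = _as_dosage_array(g)
    n, m = Z.shape
    if y.size != n:
        raise ValidationError(f"response length {y.size} != {n} samples")
    if not np.isfinite(y).all():
        raise ValidationError("response contains non-finite values")
    if n < 10:
        warnings.warn("fewer than 10 samples: predictions are essentially noise",
                      stacklevel=2)

    if hp is None:
        hp = derive_hyperparameters(
            y, Z - Z.mean(axis=0), pi_init=0.0 if method == "bayesA" else 0.5
        )
    centers = Z.mean(axis=0)
    Zc = np.asfortranarray(Z - centers)
    zz = np.einsum("ij,ij->j", Zc, Zc)

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    # state
    mu = float(y.mean())
    alpha = np.zeros(m)
    delta = np.ones(m, dtype=np.int8)
    pi = 0.0 if method == "bayesA" else float(hp.pi_init)
    sigma2_e = fixed_residual_variance if fixed_residual_variance is not None else hp.s2_e
    per_locus = method in ("bayesA", "bayesB")
    if fixed_effect_variance is not None:
        sigma2_j = np.full(m, float(fixed_effect_variance))
        sigma2_common = float(fixed_effect_variance)
    else:
        sigma2_j = np.full(m, hp.s2_alpha)
        sigma2_common = hp.s2_alpha
    e = y - mu  # alpha starts at zero

    # accumulators
    a_sum = np.zeros(m)
    a_sqsum = np.zeros(m)
    d_sum = np.zeros(m)
    mu_sum = 0.0
    pi_trace = np.empty(cfg.n_retained)
    s2e_trace = np.empty(cfg.n_retained)
    mu_trace = np.empty(cfg.n_retained)
    kept = 0

    nu_a, s2_a = hp.nu_alpha, hp.s2_alpha
    sample_pi = (method == "bayesCpi" and not hp.pi_fixed) or (
        method == "bayesB" and not hp.pi_fixed
    )

    for it in range(cfg.n_iter):
        # intercept (flat prior)
        mu_new = mu + e.mean() + math.sqrt(sigma2_e / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new

        # marker effects, fixed index order
        for j in range(m):
            zj = Zc[:, j]
            aj = alpha[j]
            r = float(zj @ e) + aj * zz[j]
            slab = sigma2_j[j] if per_locus else sigma2_common
            if method == "bayesA":
                dj, new = 1, _sample_effect(r, zz[j], slab, sigma2_e, rng)
            else:
                p1 = _inclusion_probability(r, zz[j], pi, slab, sigma2_e)
                if rng.random() < p1:
                    dj, new = 1, _sample_effect(r, zz[j], slab, sigma2_e, rng)
                else:
                    dj, new = 0, 0.0
            delta[j] = dj
            diff = new - aj
            if diff != 0.0:
                e -= zj * diff
            alpha[j] = new

        k = int(delta.sum())

        # effect variances
        if fixed_effect_variance is None:
            if method == "bayesA":
                sigma2_j = (nu_a * s2_a + alpha**2) / rng.chisquare(nu_a + 1.0, m)
            elif method == "bayesB":
                chi_in = rng.chisquare(nu_a + 1.0, m)
                chi_out = rng.chisquare(nu_a, m)
                sigma2_j = np.where(
                    delta == 1,
                    (nu_a * s2_a + alpha**2) / chi_in,
                    nu_a * s2_a / chi_out,
                )
            else:  # bayesCpi: common slab variance from the included effects
                ss = float(alpha @ alpha)
                sigma2_common = (nu_a * s2_a + ss) / rng.chisquare(nu_a + k)

        # pi
        if method != "bayesA" and sample_pi:
            pi = update_pi(m, k, rng)

        # residual variance
        if fixed_residual_variance is None:
            sigma2_e = (hp.nu_e * hp.s2_e + float(e @ e)) / rng.chisquare(hp.nu_e + n)

        if not (math.isfinite(mu) and math.isfinite(sigma2_e) and sigma2_e > 0):
            raise ChainError(f"chain diverged at iteration {it}")

        if it >= cfg.burn_in and (it + 1 - cfg.burn_in) % cfg.thin == 0:
            a_sum += alpha
            a_sqsum += alpha**2
            d_sum += delta
            mu_sum += mu
            pi_trace[kept] = pi
            s2e_trace[kept] = sigma2_e
            mu_trace[kept] = mu
            kept += 1

    nr = kept
    a_mean = a_sum / nr
    a_var = np.maximum(a_sqsum / nr - a_mean**2, 0.0)
    return PosteriorSummary(
        method=method,
        alpha_mean=a_mean,
        alpha_sd=np.sqrt(a_var),
        mu_mean=mu_sum / nr,
        pi_mean=float(pi_trace[:nr].mean()),
        sigma2_e_mean=float(s2e_trace[:nr].mean()),
        inclusion_prob=d_sum / nr,
        column_centers=centers,
        n_retained=nr,
        marker_ids=marker_ids,
        trace={"pi": pi_trace[:nr], "sigma2_e": s2e_trace[:nr], "mu": mu_trace[:nr]},
    )


def predict_gebv(ps: PosteriorSummary, g) -> np.ndarray:
    """GEBVs: sum of posterior-mean effects over loci, on centered dosages.

    Dosage columns are centered with the *training* column means stored in
    the summary; the intercept is excluded because prediction accuracy is a
    correlation and translation-invariant.
    """
    Z, marker_ids = _as_dosage_array(g)
    if ps.marker_ids is not None and marker_ids is not None:
        if marker_ids != ps.marker_ids:
            missing = sorted(set(ps.marker_ids) - set(marker_ids))
            if missing:
                raise ValidationError(f"markers absent from prediction set: {missing[:10]}")
            raise ValidationError("marker order differs from the training set")
    if Z.shape[1] != ps.alpha_mean.size:
        raise ValidationError(
            f"{Z.shape[1]} markers supplied but {ps.alpha_mean.size} trained"
        )
    return (Z - ps.column_centers) @ ps.alpha_mean


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class BayesAlphabetModel:
    """Whole-genome regression of breeding values on SNP dosages.

    Examples
    --------
    >>> model = BayesAlphabetModel.from_ebv(ebv_table, genotypes, "bayesCpi")
    >>> res = model.fit(seed=1)
    >>> gebv = res.predict(genotypes)
    """

    def __init__(self, y: np.ndarray, genotypes: GenotypeMatrix, method: str = "bayesCpi"):
        self.method = _canonical_method(method)
        if genotypes.has_missing:
            raise ValidationError("genotype matrix has missing calls; impute first")
        y = np.asarray(y, dtype=float).ravel()
        if y.size != genotypes.n_samples:
            raise ValidationError("response length does not match genotype samples")
        self.y = y
        self.genotypes = genotypes

    @classmethod
    def from_ebv(cls, ebv: EBVTable, genotypes: GenotypeMatrix,
                 method: str = "bayesCpi") -> "BayesAlphabetModel":
        """Align an EBV table with a genotype matrix (subset and reorder rows)."""
        missing = set(ebv.values.index) - set(genotypes.sample_ids)
        if missing:
            raise ValidationError(
                f"EBV genotypes absent from genotype matrix: {sorted(missing)[:10]}"
            )
        keep = [i for i, s in enumerate(genotypes.sample_ids) if s in set(ebv.values.index)]
        sub = genotypes.subset_samples(keep)
        y = ebv.values.loc[sub.sample_ids].to_numpy()
        model = cls(y, sub, method)
        model.trait_name = ebv.trait_name
        return model

    def fit(self, config: ChainConfig | None = None, hyper: HyperParams | None = None,
            seed: int | None = None) -> "BayesAlphabetResults":
        cfg = config or default_chain_config()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        ps = run_chain(self.y, self.genotypes, self.method, cfg, hyper)
        return BayesAlphabetResults(self, ps, cfg)


class BayesAlphabetResults:
    """Posterior summaries of a fitted whole-genome regression."""

    def __init__(self, model: BayesAlphabetModel, posterior: PosteriorSummary,
                 config: ChainConfig):
        self.model = model
        self.posterior = posterior
        self.config = config
        idx = pd.Index(model.genotypes.marker_ids, name="marker_id")
        self.effects = pd.DataFrame(
            {
                "alpha_mean": posterior.alpha_mean,
                "alpha_sd": posterior.alpha_sd,
                "inclusion_prob": posterior.inclusion_prob,
            },
            index=idx,
        )

    def predict(self, genotypes: GenotypeMatrix) -> pd.Series:
        gebv = predict_gebv(self.posterior, genotypes)
        return pd.Series(gebv, index=genotypes.sample_ids, name="gebv")

    def summary(self, top: int = 10) -> str:
        ps = self.posterior
        lines = [
            f"Bayesian whole-genome regression ({ps.method})",
            "=" * 52,
            f"samples:          {self.model.genotypes.n_samples}",
            f"markers:          {self.model.genotypes.n_markers}",
            f"retained draws:   {ps.n_retained}",
            f"posterior mu:     {ps.mu_mean:.6g}",
            f"posterior pi:     {ps.pi_mean:.4f}",
            f"posterior s2_e:   {ps.sigma2_e_mean:.6g}",
            "-" * 52,
            f"top {top} markers by |posterior mean effect|:",
        ]
        ranked = self.effects.reindex(
            self.effects["alpha_mean"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(ranked.to_string(float_format=lambda v: f"{v: .5f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# marker-effect files (CLI plumbing)
# ---------------------------------------------------------------------------


def write_marker_effects(ps: PosteriorSummary, path) -> None:
    """Write posterior summaries to TSV, including what prediction needs."""
    with open(path, "w") as fh:
        fh.write(f"#method={ps.method}\tmu_mean={ps.mu_mean:.10g}\t"
                 f"pi_mean={ps.pi_mean:.10g}\tsigma2_e_mean={ps.sigma2_e_mean:.10g}\t"
                 f"n_retained={ps.n_retained}\n")
        fh.write("marker_id\talpha_mean\talpha_sd\tinclusion_prob\tcolumn_center\n")
        ids = ps.marker_ids or [f"M{j}" for j in range(ps.alpha_mean.size)]
        for j, mid in enumerate(ids):
            fh.write(f"{mid}\t{ps.alpha_mean[j]:.10g}\t{ps.alpha_sd[j]:.10g}\t"
                     f"{ps.inclusion_prob[j]:.10g}\t{ps.column_centers[j]:.10g}\n")


def read_marker_effects(path) -> PosteriorSummary:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"marker_id": str})
    return PosteriorSummary(
        method=meta["method"],
        alpha_mean=df["alpha_mean"].to_numpy(),
        alpha_sd=df["alpha_sd"].to_numpy(),
        mu_mean=float(meta["mu_mean"]),
        pi_mean=float(meta["pi_mean"]),
        sigma2_e_mean=float(meta["sigma2_e_mean"]),
        inclusion_prob=df["inclusion_prob"].to_numpy(),
        column_centers=df["column_center"].to_numpy(),
        n_retained=int(meta["n_retained"]),
        marker_ids=list(df["marker_id"]),
    )
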