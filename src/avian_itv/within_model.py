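"""Measurement-error regression of group CVs on geographic covariates.

Stage-1 output gives, per station j x species k, a posterior mean CV
estimate (cv_hat) and its posterior SD (tau_hat), both on the CV x 1000
scale.  The model treats cv_hat as a noisy observation of a latent true CV
theta_jk with *known* observation SD tau_hat:

    cv_hat_jk ~ Normal(theta_jk, tau_hat_jk)          (observation layer)
    theta_jk  ~ Normal(mu_theta_jk, sigma_theta)      (process layer)
    mu_theta_jk = alpha_k + beta1_k Lat + beta2_k DistEdge
                 + beta3_k SpatVar + beta4_k TempVar
    (alpha_k, beta1_k .. beta4_k) ~ MVN(mu, Sigma)    (species layer)

where the covariates are centered within species.  The cross-species
effects are the components mu_beta1..mu_beta4 of ``mu``; they measure the
change in CV x 1000 per unit change of a covariate (per degree of latitude,
per log-km of edge distance, per log unit of spatial or temporal
environmental CV).

Gibbs scheme: theta, the species coefficient vectors, and mu all have
conjugate (multivariate) normal full conditionals; the 5x5 covariance Sigma
has an inverse-Wishart full conditional; sigma_theta is slice-sampled with a
half-normal prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .covariates import WITHIN_COVARIATES
from .diagnostics import McmcConfig, PosteriorDraws, PosteriorSummary, summarize_draws
from .sampling import mvn_precision_draw, slice_sample_scalar

__all__ = [
    "WithinPriors",
    "WithinPosterior",
    "fit_within_model",
    "summarize_effect",
    "effects_table",
    "posterior_predictive_check",
]

EFFECT_NAMES = ["mu_alpha", "mu_beta1", "mu_beta2", "mu_beta3", "mu_beta4"]


@dataclass(frozen=True)
class WithinPriors:
    """Weakly informative priors on the CV x 1000 scale.

    The intercept mean gets a much wider prior than the slopes because group
    CVs x 1000 sit far from zero (a CV of 0.025 is 25 on this scale).
    Sigma carries a conjugate inverse-Wishart prior with identity scale and
    p + 2 degrees of freedom — close to the weakest proper choice.
    """

    intercept_sd: float = 100.0
    slope_sd: float = 5.0
    sigma_theta_scale: float = 5.0  # HalfNormal(0, ·)
    iw_df: float = 7.0
    iw_scale: float = 1.0  # multiplies the identity


class WithinPosterior:
    """Draws from :func:`fit_within_model` plus design bookkeeping."""

    def __init__(self, draws: PosteriorDraws, design: pd.DataFrame, species: list[str]):
        self.draws = draws
        self.design = design
        self.species_names = species

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def effect(self, name: str) -> np.ndarray:
        """(chain, draw) array for one of mu_alpha, mu_beta1..mu_beta4."""
        return self.draws.scalar("mu", EFFECT_NAMES.index(name))


def _design_arrays(design: pd.DataFrame):
    species = design["species"].unique().tolist()
    sp = design["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    X = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(dtype=float) for c in WITHIN_COVARIATES]
    )
    y = design["cv_hat"].to_numpy(dtype=float)
    tau = design["tau_hat"].to_numpy(dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_hat must be > 0 for every row")
    return species, sp, X, y, tau


def fit_within_model(
    design: pd.DataFrame,
    mcmc: McmcConfig = McmcConfig(iterations=5000, warmup=2500),
    priors: WithinPriors = WithinPriors(),
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    record_theta: bool = True,
) -> WithinPosterior:
    """Fit the within-species measurement-error regression by Gibbs sampling.

    ``design`` is the table from
    :func:`avian_itv.covariates.assemble_within_design`: columns cv_hat and
    tau_hat on the x1000 scale plus the four centered covariates.  Requires
    at least 2 species with at least 2 rows each.  The convergence gate
    (R-hat <= 1.01, ESS > 400, zero divergences) is evaluated on the
    cross-species effects, the species coefficients and the scale
    parameters; failing it flags the posterior, it does not raise.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    species, sp, X, y, tau = _design_arrays(design)
    K, N, P = len(species), len(design), X.shape[1]
    counts = np.bincount(sp, minlength=K)
    if K < 2 or counts.min() < 2:
        raise ValueError("need >= 2 species with >= 2 rows each")
    for k in range(K):
        if np.linalg.matrix_rank(X[sp == k]) < P:
            raise ValueError(f"rank-deficient design for species {species[k]!r}")

    tau2 = tau**2
    # per-row outer products, for weighted per-species Gram matrices
    outer = np.einsum("np,nq->npq", X, X)
    prior_mu_prec = np.diag(
        1.0 / np.array([priors.intercept_sd**2] + [priors.slope_sd**2] * (P - 1))
    )
    iw_df0 = priors.iw_df
    iw_scale0 = priors.iw_scale * np.eye(P)
    scale2 = priors.sigma_theta_scale**2

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chain_out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        # initialise from per-species least squares with jitter
        b = np.empty((K, P))
        for k in range(K):
            Xk, yk = X[sp == k], y[sp == k]
            b[k], *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        b += rng.normal(0, 0.1, b.shape)
        mu = b.mean(axis=0)
        Sigma = np.cov(b.T) + 0.1 * np.eye(P)
        sigma_theta = max(float(np.std(y - (X * b[sp]).sum(axis=1))), 0.1)

        kept = {
            "mu": np.empty((mcmc.kept, P)),
            "b": np.empty((mcmc.kept, K, P)),
            "Sigma": np.empty((mcmc.kept, P, P)),
            "sigma_theta": np.empty(mcmc.kept),
        }
        if record_theta:
            kept["theta"] = np.empty((mcmc.kept, N))
        j = 0
        for it in range(mcmc.iterations):
            # theta is integrated out analytically: marginally
            # cv_hat ~ Normal(X b, sqrt(tau^2 + sigma_theta^2)), which removes
            # the latent-state funnel that cripples a centered Gibbs sweep.
            w = 1.0 / (tau2 + sigma_theta**2)

            Sinv = np.linalg.inv(Sigma)
            gram = np.zeros((K, P, P))
            np.add.at(gram, sp, outer * w[:, None, None])
            Xty = np.stack(
                [np.bincount(sp, X[:, p_] * y * w, minlength=K) for p_ in range(P)],
                axis=1,
            )

            # mu with the species coefficients also integrated out (Woodbury
            # per species block): marginally y_k ~ N(X_k mu, X_k Sigma X_k' + D_k)
            A = gram + Sinv
            Ainv_gram = np.linalg.solve(A, gram)
            marg_prec = gram - np.einsum("kpq,kqr->kpr", gram, Ainv_gram)
            marg_rhs = Xty - np.einsum(
                "kpq,kq->kp", gram, np.linalg.solve(A, Xty[..., None])[..., 0]
            )
            prec_mu = marg_prec.sum(axis=0) + prior_mu_prec
            rhs_mu = marg_rhs.sum(axis=0)
            mu = mvn_precision_draw(prec_mu, rhs_mu, rng)

            rhs_b = Xty + Sinv @ mu
            b = mvn_precision_draw(A, rhs_b, rng)

            dev = b - mu
            Sigma = invwishart.rvs(
                df=iw_df0 + K, scale=iw_scale0 + dev.T @ dev, random_state=rng
            )

            resid = y - (X * b[sp]).sum(axis=1)
            resid2 = resid * resid

            def logp_st(t):
                v = tau2 + np.exp(2 * t)
                return (
                    -0.5 * float(np.sum(np.log(v) + resid2 / v))
                    - np.exp(2 * t) / (2 * scale2)
                    + t
                )

            sigma_theta = float(
                np.exp(
                    slice_sample_scalar(np.log(sigma_theta), logp_st, rng, width=0.3)
                )
            )

            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                kept["mu"][j] = mu
                kept["b"][j] = b
                kept["Sigma"][j] = Sigma
                kept["sigma_theta"][j] = sigma_theta
                if record_theta:
                    # conditional draw of the latent states given the rest
                    prec_t = 1.0 / tau2 + 1.0 / sigma_theta**2
                    mean_t = (y / tau2 + (X * b[sp]).sum(axis=1) / sigma_theta**2) / prec_t
                    kept["theta"][j] = rng.normal(mean_t, 1.0 / np.sqrt(prec_t))
                j += 1
        chain_out.append(kept)

    draws = PosteriorDraws(
        {k: np.stack([c[k] for c in chain_out]) for k in chain_out[0]}
    )
    draws.check_gate(["mu", "b", "sigma_theta"], rhat_max=rhat_max, ess_min=ess_min)
    return WithinPosterior(draws, design, species)


def summarize_effect(draws: np.ndarray, name: str = "effect") -> PosteriorSummary:
    """Mean, equal-tailed 89% CI, p(>0), R-hat and ESS for scalar draws."""
    return summarize_draws(draws, name)


def effects_table(posterior: WithinPosterior) -> pd.DataFrame:
    """Cross-species effect summaries with the gate verdict attached."""
    rows = []
    for name in EFFECT_NAMES:
        s = summarize_effect(posterior.effect(name), name)
        rows.append(
            {
                "parameter": name,
                "mean": s.mean,
                "ci_low89": s.ci89[0],
                "ci_high89": s.ci89[1],
                "p_gt0": s.p_gt0,
                "rhat": s.rhat,
                "ess": s.ess,
                "converged_gate": posterior.converged,
            }
        )
    return pd.DataFrame(rows)


def posterior_predictive_check(
    posterior: WithinPosterior,
    design: pd.DataFrame | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Replicate cv_hat data through both model layers.

    For each of ``n_replicates`` posterior draws, simulate theta_rep from
    the process layer and cv_hat_rep from the observation layer.  Returns
    the observed values, the replicate matrix, and per-replicate means/SDs
    for graphical checks (data are emitted, not plotted).
    """
    if design is None:
        design = posterior.design
    if len(design) == 0:
        raise ValueError("empty design")
    species, sp, X, y, tau = _design_arrays(design)
    rng = np.random.default_rng(seed)
    b = posterior.draws.flat("b")
    st = posterior.draws.flat("sigma_theta")
    idx = rng.choice(len(st), size=n_replicates, replace=len(st) < n_replicates)
    reps = np.empty((n_replicates, len(design)))
    for r, i in enumerate(idx):
        m_proc = (X * b[i][sp]).sum(axis=1)
        theta_rep = rng.normal(m_proc, st[i])
        reps[r] = rng.normal(theta_rep, tau)
    return {
        "observed": y,
        "replicates": reps,
        "replicate_means": reps.mean(axis=1),
        "replicate_sds": reps.std(axis=1, ddof=1),
        "observed_mean": float(y.mean()),
        "observed_sd": float(y.std(ddof=1)),
    }
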