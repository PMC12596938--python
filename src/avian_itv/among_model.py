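"""Among-species regression of species-average CVs with phylogenetic structure.

Species-average CV estimates (cvsp_hat, x1000 scale) with posterior SDs
(tausp_hat) from stage 1 enter a second measurement-error regression:

    cvsp_hat_k ~ Normal(xi_k, tausp_hat_k)            (observation layer)
    xi_k       ~ Normal(mu_xi_k, sigma_xi)            (process layer)
    mu_xi_k = kappa + eta_k + zeta1 GenTime + zeta2 HWI
             + zeta3 RangeSize + zeta4 MigStatus
    eta ~ MVN(0, sigma_phylo^2 P)                     (phylogenetic layer)

with covariates centered and scaled across species.  P is the
Brownian-motion correlation matrix implied by the phylogeny: for an
ultrametric tree of depth T, P_ab is the shared root-to-ancestor path
length of tips a and b divided by T (equivalently 1 - d_ab / 2T with d_ab
the patristic distance).  sigma_phylo scales the *variance* of the
phylogenetic intercepts; P itself is a correlation matrix.

Gibbs scheme mirrors the within-species model: xi, eta and the coefficient
vector are conjugate (multivariate) normal, sigma_xi and sigma_phylo are
slice-sampled under half-normal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular

from .covariates import AMONG_COVARIATES
from .diagnostics import McmcConfig, PosteriorDraws
from .sampling import mvn_precision_draw, slice_sample_scalar
from .within_model import summarize_effect

__all__ = [
    "PhyloCorrelation",
    "AmongPriors",
    "AmongPosterior",
    "phylo_correlation",
    "fit_among_model",
    "among_effects_table",
]

ZETA_NAMES = ["kappa", "zeta1", "zeta2", "zeta3", "zeta4"]


@dataclass(frozen=True)
class PhyloCorrelation:
    """Brownian correlation matrix for an ordered species list."""

    species: tuple[str, ...]
    P: np.ndarray
    tree_depth: float

    def __post_init__(self) -> None:
        P = self.P
        if P.shape != (len(self.species),) * 2:
            raise ValueError("P shape does not match species list")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("P must be symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-10):
            raise ValueError("P must have unit diagonal")
        if np.linalg.eigvalsh(P).min() < -1e-8:
            raise ValueError("P is not positive semidefinite")

    @classmethod
    def identity(cls, species: list[str]) -> "PhyloCorrelation":
        """Star-phylogeny correlation: independent species intercepts."""
        return cls(tuple(species), np.eye(len(species)), 1.0)


def phylo_correlation(tree, species: list[str]) -> PhyloCorrelation:
    """Correlation matrix from pairwise patristic distances on a phylogeny.

    ``tree`` is a dendropy Tree, a newick string, or a path to a newick
    file.  All requested species must be tips.  For a non-ultrametric tree
    a warning is emitted and the maximum root-to-tip depth is used as T.
    """
    if isinstance(tree, str):
        if "(" in tree:
            tree = dendropy.Tree.get(data=tree, schema="newick")
        else:
            tree = dendropy.Tree.get(path=tree, schema="newick")
    labels = {t.label for t in tree.taxon_namespace}
    missing = [s for s in species if s not in labels]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    tree.calc_node_root_distances()
    depths = np.array([leaf.root_distance for leaf in tree.leaf_node_iter()])
    T = float(depths.max())
    if T <= 0:
        raise ValueError("tree has zero depth")
    if np.ptp(depths) > 1e-6 * T:
        warnings.warn(
            "tree is not ultrametric; using max root-to-tip depth as T",
            stacklevel=2,
        )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(species)
    P = np.eye(n)
    for a in range(n):
        for b_ in range(a + 1, n):
            d = pdm.patristic_distance(taxa[species[a]], taxa[species[b_]])
            P[a, b_] = P[b_, a] = 1.0 - d / (2.0 * T)
    evals = np.linalg.eigvalsh(P)
    if evals.min() < -1e-8:
        raise ValueError("phylogenetic correlation matrix is not PSD")
    if evals.min() < 1e-10:  # jitter exact singularity from zero-length splits
        P = P + 1e-8 * np.eye(n)
        P = P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
    return PhyloCorrelation(tuple(species), P, T)


@dataclass(frozen=True)
class AmongPriors:
    intercept_sd: float = 100.0
    slope_sd: float = 5.0
    sigma_xi_scale: float = 5.0  # HalfNormal(0, ·)
    sigma_phylo_scale: float = 5.0  # HalfNormal(0, ·)


class AmongPosterior:
    def __init__(self, draws: PosteriorDraws, profiles: pd.DataFrame, species: list[str]):
        self.draws = draws
        self.profiles = profiles
        self.species_names = species

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def effect(self, name: str) -> np.ndarray:
        return self.draws.scalar("coef", ZETA_NAMES.index(name))


def fit_among_model(
    profiles: pd.DataFrame,
    P: PhyloCorrelation | None,
    mcmc: McmcConfig = McmcConfig(iterations=5000, warmup=2500),
    priors: AmongPriors = AmongPriors(),
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    include_phylo: bool = True,
) -> AmongPosterior:
    """Fit the among-species regression by Gibbs sampling.

    ``profiles`` is the table from
    :func:`avian_itv.covariates.build_species_profiles` (cvsp_hat/tausp_hat
    on the x1000 scale, centered-scaled covariates).  ``P`` must cover every
    species, in any order.  With ``include_phylo=False`` the phylogenetic
    intercepts are dropped, leaving an ordinary measurement-error
    regression — the nested model used as an equivalence oracle.
    """
    species = profiles["species"].tolist()
    K = len(species)
    if K < 5:
        raise ValueError("need at least 5 species")
    y = profiles["cvsp_hat"].to_numpy(dtype=float)
    tau = profiles["tausp_hat"].to_numpy(dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tausp_hat must be > 0")
    W = np.column_stack(
        [np.ones(K)] + [profiles[c].to_numpy(dtype=float) for c in AMONG_COVARIATES]
    )
    P_ = W.shape[1]
    if include_phylo:
        if P is None:
            raise ValueError("a PhyloCorrelation is required when include_phylo=True")
        order = [P.species.index(s) for s in species]
        Pm = P.P[np.ix_(order, order)]
        Pinv = np.linalg.inv(Pm + 1e-10 * np.eye(K))

    tau2 = tau**2
    prior_coef_prec = np.diag(
        1.0 / np.array([priors.intercept_sd**2] + [priors.slope_sd**2] * (P_ - 1))
    )
    sxs = priors.sigma_xi_scale**2
    sps = priors.sigma_phylo_scale**2
    eyeK = np.eye(K)

    # Both latent layers (xi and eta) are integrated out analytically:
    # marginally y ~ MVN(W c, sigma_phylo^2 P + diag(tau^2 + sigma_xi^2)),
    # leaving a Gibbs state of just (c, sigma_xi, sigma_phylo) that mixes
    # nearly independently.  xi and eta are drawn conditionally when a
    # sweep is recorded.

    def _chol_marginal(sigma_xi: float, sigma_phylo: float) -> np.ndarray:
        V = np.diag(tau2 + sigma_xi**2)
        if include_phylo:
            V = V + sigma_phylo**2 * Pm
        return np.linalg.cholesky(V)

    def _mvn_loglik(chol: np.ndarray, r: np.ndarray) -> float:
        z = solve_triangular(chol, r, lower=True)
        return -float(np.log(np.diag(chol)).sum()) - 0.5 * float(z @ z)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chain_out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        coef, *_ = np.linalg.lstsq(W, y, rcond=None)
        coef = coef + rng.normal(0, 0.1, P_)
        sigma_xi = max(float(np.std(y - W @ coef)), 0.2)
        sigma_phylo = 0.5 * sigma_xi + 0.1

        kept = {
            "coef": np.empty((mcmc.kept, P_)),
            "xi": np.empty((mcmc.kept, K)),
            "eta": np.empty((mcmc.kept, K)),
            "sigma_xi": np.empty(mcmc.kept),
            "sigma_phylo": np.empty(mcmc.kept),
        }
        j = 0
        for it in range(mcmc.iterations):
            chol = _chol_marginal(sigma_xi, sigma_phylo)
            Vinv_W = cho_solve((chol, True), W)
            prec_c = W.T @ Vinv_W + prior_coef_prec
            rhs_c = Vinv_W.T @ y
            coef = mvn_precision_draw(prec_c, rhs_c, rng)

            r = y - W @ coef

            def logp_sx(t):
                return (
                    _mvn_loglik(_chol_marginal(np.exp(t), sigma_phylo), r)
                    - np.exp(2 * t) / (2 * sxs)
                    + t
                )

            sigma_xi = float(
                np.exp(slice_sample_scalar(np.log(sigma_xi), logp_sx, rng, width=0.4))
            )

            if include_phylo:

                def logp_sp(t):
                    return (
                        _mvn_loglik(_chol_marginal(sigma_xi, np.exp(t)), r)
                        - np.exp(2 * t) / (2 * sps)
                        + t
                    )

                sigma_phylo = float(
                    np.exp(
                        slice_sample_scalar(np.log(sigma_phylo), logp_sp, rng, width=0.4)
                    )
                )

            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                # conditional draws of the latent layers
                if include_phylo:
                    prec_e = Pinv / sigma_phylo**2 + eyeK / (tau2 + sigma_xi**2)
                    rhs_e = r / (tau2 + sigma_xi**2)
                    eta = mvn_precision_draw(prec_e, rhs_e, rng)
                else:
                    eta = np.zeros(K)
                prec_x = 1.0 / tau2 + 1.0 / sigma_xi**2
                mean_x = (y / tau2 + (W @ coef + eta) / sigma_xi**2) / prec_x
                xi = rng.normal(mean_x, 1.0 / np.sqrt(prec_x))
                kept["coef"][j] = coef
                kept["xi"][j] = xi
                kept["eta"][j] = eta
                kept["sigma_xi"][j] = sigma_xi
                kept["sigma_phylo"][j] = sigma_phylo
                j += 1
        chain_out.append(kept)

    draws = PosteriorDraws({k: np.stack([c[k] for c in chain_out]) for k in chain_out[0]})
    gate_params = ["coef", "sigma_xi"]
    if include_phylo:
        gate_params.append("sigma_phylo")
    draws.check_gate(gate_params, rhat_max=rhat_max, ess_min=ess_min)
    return AmongPosterior(draws, profiles, species)


def among_effects_table(posterior: AmongPosterior) -> pd.DataFrame:
    rows = []
    for name in ZETA_NAMES:
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
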