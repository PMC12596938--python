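"""Hierarchical model of log traits and uncertainty-propagated CVs.

For individual i at station j of species k the log trait is modelled as

    y_ijk ~ Normal(mu_jk, sigma_jk)

with a species-level layer on the group parameters,

    mu_jk    ~ Normal(mu_mean_k, sigma_mean_k)
    sigma_jk ~ HalfNormal(mu_SD_k, sigma_SD_k)

(HalfNormal(m, s) denotes a Normal(m, s) truncated to positive values), and
a global layer tying species together,

    mu_mean_k    ~ Normal(gamma_mu_mean, phi_mu_mean)
    sigma_mean_k ~ HalfNormal(gamma_sigma_mean, phi_sigma_mean)
    mu_SD_k      ~ HalfNormal(gamma_mu_SD, phi_mu_SD)
    sigma_SD_k   ~ HalfNormal(gamma_sigma_SD, phi_sigma_SD).

The coefficient of variation of each group is the derived quantity

    CV_jk = sigma_jk / mu_jk,

computed per posterior draw so that the posterior mean (cv_hat) and SD
(tau_hat) propagate the full uncertainty of both parameters — including the
dependence of that uncertainty on the group's sample size.  Species-level
CVs average the group CV draws of a species, again per draw.

The sampler is a blocked Gibbs sweep: conjugate normal updates for the
location-type parameters, vectorised slice updates for the scale-type ones.
Note that CV_jk here is the ratio of the SD to the mean of the *log* trait,
not the raw-scale CV; on typical log-gram or log-millimetre scales the two
differ, and all downstream stages use this log-scale definition throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .diagnostics import McmcConfig, PosteriorDraws
from .sampling import slice_sample, slice_sample_scalar

__all__ = [
    "TraitObservationSet",
    "CVPriors",
    "CVPosterior",
    "GroupCV",
    "SpeciesCV",
    "fit_cv_model",
    "derive_group_cv",
    "derive_all_group_cvs",
    "derive_species_cv",
    "derive_all_species_cvs",
]


@dataclass(frozen=True)
class CVPriors:
    """Weakly informative hyperpriors on the log-trait scale."""

    gamma_location_sd: float = 10.0  # Normal(0, ·) on the four gamma parameters
    phi_scale: float = 5.0  # HalfNormal(0, ·) on the four phi parameters


class TraitObservationSet:
    """Log-trait observations grouped by (species, station).

    Holds per-observation log values plus the contiguous group index and the
    per-group sufficient statistics the sampler needs (n, mean, centred sum
    of squares).  Every group must have at least 2 observations.
    """

    def __init__(self, y: np.ndarray, species: np.ndarray, location: np.ndarray):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("log-trait values must be finite")
        keys = pd.DataFrame({"species": species, "location_id": location, "y": y})
        grouped = keys.groupby(["species", "location_id"], sort=True)
        self.groups = grouped.agg(
            n=("y", "size"), ybar=("y", "mean"), sd=("y", lambda s: s.std(ddof=1))
        ).reset_index()
        if (self.groups["n"] < 2).any():
            bad = self.groups.loc[self.groups["n"] < 2, ["species", "location_id"]]
            raise ValueError(f"groups with < 2 observations: {bad.values.tolist()}")
        ss = grouped["y"].apply(lambda s: float(((s - s.mean()) ** 2).sum()))
        self.groups["ss"] = ss.to_numpy()
        self.species_names = self.groups["species"].unique().tolist()
        self.groups["species_index"] = (
            self.groups["species"].map({s: i for i, s in enumerate(self.species_names)})
        )
        self.y = y

    @classmethod
    def from_captures(cls, captures: pd.DataFrame, trait: str = "mass") -> "TraitObservationSet":
        """Build from a filtered capture table; trait values are logged here."""
        df = captures[captures[trait].notna()]
        vals = df[trait].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"{trait} must be positive to take logs")
        return cls(np.log(vals), df["species"].to_numpy(), df["location_id"].to_numpy())

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_species(self) -> int:
        return len(self.species_names)


@dataclass(frozen=True)
class GroupCV:
    """Posterior summary of CV for one station x species group."""

    species: str
    location_id: str
    trait: str
    cv_hat: float
    tau_hat: float
    n_individuals: int
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cv_hat <= 0 or self.tau_hat < 0:
            raise ValueError("cv_hat must be > 0 and tau_hat >= 0")


@dataclass(frozen=True)
class SpeciesCV:
    """Posterior summary of the species-average CV."""

    species: str
    trait: str
    cvsp_hat: float
    tausp_hat: float

    def __post_init__(self) -> None:
        if self.cvsp_hat <= 0:
            raise ValueError("cvsp_hat must be > 0")


class CVPosterior:
    """Posterior draws from :func:`fit_cv_model` plus group bookkeeping."""

    def __init__(self, draws: PosteriorDraws, data: TraitObservationSet, trait: str):
        self.draws = draws
        self.groups = data.groups
        self.species_names = data.species_names
        self.trait = trait

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def cv_draws(self) -> np.ndarray:
        """CV_jk = sigma_jk / mu_jk per draw, shaped (chain, draw, group)."""
        mu = self.draws["mu"]
        if np.any(mu <= 0):
            raise ValueError(
                "mu_jk posterior draws <= 0: log-scale group means of positive "
                "traits should be positive; check data units"
            )
        return self.draws["sigma"] / mu


def _chain_init(stats: dict, rng: np.random.Generator) -> dict:
    g = stats
    sd = np.maximum(g["sd"], 1e-3)
    mu = g["ybar"] + rng.normal(0, 0.1, g["G"]) * sd / np.sqrt(g["n"])
    sigma = sd * np.exp(rng.normal(0, 0.1, g["G"]))
    sp = g["sp"]
    K, J = g["K"], g["J"]
    mu_mean = np.bincount(sp, mu, minlength=K) / J
    sigma_mean = np.maximum(
        np.sqrt(np.maximum(np.bincount(sp, (mu - mu_mean[sp]) ** 2, minlength=K) / J, 0)),
        0.01,
    )
    mu_SD = np.maximum(np.bincount(sp, sigma, minlength=K) / J, 1e-3)
    sigma_SD = np.maximum(
        np.sqrt(np.maximum(np.bincount(sp, (sigma - mu_SD[sp]) ** 2, minlength=K) / J, 0)),
        0.2 * mu_SD,
    )
    return {
        "mu": mu,
        "sigma": sigma,
        "mu_mean": mu_mean,
        "sigma_mean": sigma_mean,
        "mu_SD": mu_SD,
        "sigma_SD": sigma_SD,
        "gamma_mu_mean": float(mu_mean.mean()),
        "phi_mu_mean": max(float(mu_mean.std()), 0.1),
        "gamma_sigma_mean": max(float(sigma_mean.mean()), 0.01),
        "phi_sigma_mean": max(float(sigma_mean.std()), 0.05),
        "gamma_mu_SD": max(float(mu_SD.mean()), 1e-3),
        "phi_mu_SD": max(float(mu_SD.std()), 0.02),
        "gamma_sigma_SD": max(float(sigma_SD.mean()), 1e-3),
        "phi_sigma_SD": max(float(sigma_SD.std()), 0.02),
    }


_GLOBALS = [
    "gamma_mu_mean",
    "phi_mu_mean",
    "gamma_sigma_mean",
    "phi_sigma_mean",
    "gamma_mu_SD",
    "phi_mu_SD",
    "gamma_sigma_SD",
    "phi_sigma_SD",
]


def _run_chain(
    stats: dict, priors: CVPriors, mcmc: McmcConfig, rng: np.random.Generator
) -> dict:
    n, ybar, ss, sp = stats["n"], stats["ybar"], stats["ss"], stats["sp"]
    G, K, J = stats["G"], stats["K"], stats["J"]
    st = _chain_init(stats, rng)
    prior_loc_var = priors.gamma_location_sd**2
    prior_scale_var = priors.phi_scale**2

    kept = {
        k: np.empty((mcmc.kept,) + np.shape(st[k]))
        for k in ("mu", "sigma", "mu_mean", "sigma_mean", "mu_SD", "sigma_SD")
    }
    for k in _GLOBALS:
        kept[k] = np.empty(mcmc.kept)
    idx_keep = 0

    for it in range(mcmc.iterations):
        sig2 = st["sigma"] ** 2
        # group means: conjugate normal
        prec = n / sig2 + 1.0 / st["sigma_mean"][sp] ** 2
        m = (n * ybar / sig2 + st["mu_mean"][sp] / st["sigma_mean"][sp] ** 2) / prec
        st["mu"] = rng.normal(m, 1.0 / np.sqrt(prec))

        # group SDs: slice in log space
        resid2 = ss + n * (ybar - st["mu"]) ** 2
        mu_SD_g = st["mu_SD"][sp]
        sig_SD_g2 = st["sigma_SD"][sp] ** 2

        def logp_sigma(t):
            s = np.exp(t)
            return -n * t - resid2 / (2 * s * s) - (s - mu_SD_g) ** 2 / (2 * sig_SD_g2) + t

        st["sigma"] = np.exp(slice_sample(np.log(st["sigma"]), logp_sigma, rng, width=0.3))

        # species means of group means: conjugate
        sum_mu = np.bincount(sp, st["mu"], minlength=K)
        prec_k = J / st["sigma_mean"] ** 2 + 1.0 / st["phi_mu_mean"] ** 2
        m_k = (sum_mu / st["sigma_mean"] ** 2 + st["gamma_mu_mean"] / st["phi_mu_mean"] ** 2) / prec_k
        st["mu_mean"] = rng.normal(m_k, 1.0 / np.sqrt(prec_k))

        # species SDs of group means: slice
        ssq_mu = np.bincount(sp, (st["mu"] - st["mu_mean"][sp]) ** 2, minlength=K)
        g_sm, p_sm2 = st["gamma_sigma_mean"], st["phi_sigma_mean"] ** 2

        def logp_sigma_mean(t):
            s = np.exp(t)
            return -J * t - ssq_mu / (2 * s * s) - (s - g_sm) ** 2 / (2 * p_sm2) + t

        st["sigma_mean"] = np.exp(
            slice_sample(np.log(st["sigma_mean"]), logp_sigma_mean, rng, width=0.3)
        )

        # species location/scale of group SDs: slice (truncation normaliser
        # of the half-normal depends on both, so neither is conjugate)
        S1 = np.bincount(sp, st["sigma"], minlength=K)
        S2 = np.bincount(sp, st["sigma"] ** 2, minlength=K)
        sSD2 = st["sigma_SD"] ** 2
        g_mSD, p_mSD2 = st["gamma_mu_SD"], st["phi_mu_SD"] ** 2

        def logp_mu_SD(t):
            m_ = np.exp(t)
            quad = S2 - 2 * m_ * S1 + J * m_ * m_
            return (
                -quad / (2 * sSD2)
                - J * log_ndtr(m_ / st["sigma_SD"])
                - (m_ - g_mSD) ** 2 / (2 * p_mSD2)
                + t
            )

        st["mu_SD"] = np.exp(slice_sample(np.log(st["mu_SD"]), logp_mu_SD, rng, width=0.3))

        muSD = st["mu_SD"]
        quad_SD = S2 - 2 * muSD * S1 + J * muSD**2
        g_sSD, p_sSD2 = st["gamma_sigma_SD"], st["phi_sigma_SD"] ** 2

        def logp_sigma_SD(t):
            s = np.exp(t)
            return (
                -J * t
                - quad_SD / (2 * s * s)
                - J * log_ndtr(muSD / s)
                - (s - g_sSD) ** 2 / (2 * p_sSD2)
                + t
            )

        st["sigma_SD"] = np.exp(
            slice_sample(np.log(st["sigma_SD"]), logp_sigma_SD, rng, width=0.3)
        )

        # Interweaving Metropolis moves: the centered parameterisation couples
        # each species' group SDs to (mu_SD_k, sigma_SD_k) in a funnel, which
        # slows the elementwise slice updates.  Two joint moves per species —
        # rescaling the SD deviations together with sigma_SD_k, and
        # translating them together with mu_SD_k — break that coupling.
        g_mSD2, p_mSD2_ = st["gamma_mu_SD"], st["phi_mu_SD"] ** 2
        g_sSD2, p_sSD2_ = st["gamma_sigma_SD"], st["phi_sigma_SD"] ** 2

        def _loglik_sigma(s_arr, ok):
            safe = np.where(ok, s_arr, 1.0)
            return np.where(ok, -n * np.log(safe) - resid2 / (2 * safe * safe), -np.inf)

        ll_cur = -n * np.log(st["sigma"]) - resid2 / (2 * st["sigma"] ** 2)

        # scale move: sigma_SD_k -> c sigma_SD_k, deviations scaled by c
        c = np.exp(rng.normal(0.0, 0.3, K))
        dev = st["sigma"] - st["mu_SD"][sp]
        sig_prop = st["mu_SD"][sp] + c[sp] * dev
        ok = sig_prop > 0
        dll = np.bincount(sp, _loglik_sigma(sig_prop, ok) - ll_cur, minlength=K)
        sSD_prop = c * st["sigma_SD"]
        log_alpha = (
            dll
            - J * (log_ndtr(st["mu_SD"] / sSD_prop) - log_ndtr(st["mu_SD"] / st["sigma_SD"]))
            + (-((sSD_prop - g_sSD2) ** 2) + (st["sigma_SD"] - g_sSD2) ** 2) / (2 * p_sSD2_)
            + np.log(c)
        )
        acc = np.log(rng.uniform(size=K)) < log_alpha
        st["sigma"] = np.where(acc[sp], sig_prop, st["sigma"])
        st["sigma_SD"] = np.where(acc, sSD_prop, st["sigma_SD"])

        # translation move: mu_SD_k and its group SDs shift together
        ll_cur = -n * np.log(st["sigma"]) - resid2 / (2 * st["sigma"] ** 2)
        delta = rng.normal(0.0, 0.5 * st["sigma_SD"])
        muSD_prop = st["mu_SD"] + delta
        sig_prop = st["sigma"] + delta[sp]
        ok = (sig_prop > 0) & (muSD_prop[sp] > 0)
        dll = np.bincount(sp, _loglik_sigma(sig_prop, ok) - ll_cur, minlength=K)
        with np.errstate(invalid="ignore"):
            log_alpha = np.where(
                muSD_prop > 0,
                dll
                - J * (log_ndtr(muSD_prop / st["sigma_SD"]) - log_ndtr(st["mu_SD"] / st["sigma_SD"]))
                + (-((muSD_prop - g_mSD2) ** 2) + (st["mu_SD"] - g_mSD2) ** 2) / (2 * p_mSD2_),
                -np.inf,
            )
        acc = np.log(rng.uniform(size=K)) < log_alpha
        st["sigma"] = np.where(acc[sp], sig_prop, st["sigma"])
        st["mu_SD"] = np.where(acc, muSD_prop, st["mu_SD"])

        # global layer: scalar slice updates on closed-form sufficient sums
        prec0 = K / st["phi_mu_mean"] ** 2 + 1.0 / prior_loc_var
        m0 = (st["mu_mean"].sum() / st["phi_mu_mean"] ** 2) / prec0
        st["gamma_mu_mean"] = rng.normal(m0, 1.0 / np.sqrt(prec0))

        ssq_mm = float(((st["mu_mean"] - st["gamma_mu_mean"]) ** 2).sum())

        def logp_phi_mm(t, ssq=ssq_mm):
            s2 = math.exp(2 * t)
            return -K * t - ssq / (2 * s2) - s2 / (2 * prior_scale_var) + t

        st["phi_mu_mean"] = math.exp(
            slice_sample_scalar(math.log(st["phi_mu_mean"]), logp_phi_mm, rng, 0.3)
        )

        for loc_key, scale_key, vals in (
            ("gamma_sigma_mean", "phi_sigma_mean", st["sigma_mean"]),
            ("gamma_mu_SD", "phi_mu_SD", st["mu_SD"]),
            ("gamma_sigma_SD", "phi_sigma_SD", st["sigma_SD"]),
        ):
            S1 = float(vals.sum())
            S2 = float((vals * vals).sum())
            phi = st[scale_key]

            def logp_loc(g, S1=S1, S2=S2, phi=phi):
                return (
                    -(S2 - 2 * g * S1 + K * g * g) / (2 * phi * phi)
                    - K * float(log_ndtr(g / phi))
                    - g * g / (2 * prior_loc_var)
                )

            st[loc_key] = slice_sample_scalar(
                st[loc_key], logp_loc, rng, width=max(0.1, phi)
            )
            gloc = st[loc_key]

            def logp_scale(t, S1=S1, S2=S2, gloc=gloc):
                s = math.exp(t)
                return (
                    -K * t
                    - (S2 - 2 * gloc * S1 + K * gloc * gloc) / (2 * s * s)
                    - K * float(log_ndtr(gloc / s))
                    - s * s / (2 * prior_scale_var)
                    + t
                )

            st[scale_key] = math.exp(
                slice_sample_scalar(math.log(st[scale_key]), logp_scale, rng, 0.3)
            )

        if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
            for k, buf in kept.items():
                buf[idx_keep] = st[k]
            idx_keep += 1
    return kept


def fit_cv_model(
    data: TraitObservationSet,
    mcmc: McmcConfig = McmcConfig(iterations=50_000, warmup=20_000, thin=20),
    priors: CVPriors = CVPriors(),
    trait: str = "trait",
    rhat_max: float = 1.05,
    ess_min: float = 400.0,
) -> CVPosterior:
    """Fit the hierarchical log-trait model by blocked Gibbs sampling.

    Runs ``mcmc.chains`` independent chains and evaluates the convergence
    gate (R-hat <= ``rhat_max`` and ESS > ``ess_min`` on all group and
    species parameters); a failed gate flags the result as non-converged
    but still returns it.
    """
    g = data.groups
    stats = {
        "n": g["n"].to_numpy(dtype=float),
        "ybar": g["ybar"].to_numpy(dtype=float),
        "ss": g["ss"].to_numpy(dtype=float),
        "sd": g["sd"].to_numpy(dtype=float),
        "sp": g["species_index"].to_numpy(),
        "G": len(g),
        "K": data.n_species,
        "J": np.bincount(g["species_index"].to_numpy(), minlength=data.n_species).astype(float),
    }
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_chain(stats, priors, mcmc, np.random.default_rng(s)) for s in seeds
    ]
    draws = PosteriorDraws(
        {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    )
    draws.check_gate(
        ["mu", "sigma"],
        rhat_max=rhat_max,
        ess_min=ess_min,
    )
    return CVPosterior(draws, data, trait)


def derive_group_cv(posterior: CVPosterior, species: str, location_id: str) -> GroupCV:
    """Posterior of CV_jk = sigma_jk / mu_jk for one group, per draw."""
    g = posterior.groups
    match = g.index[(g["species"] == species) & (g["location_id"] == location_id)]
    if len(match) != 1:
        raise KeyError(f"group ({species!r}, {location_id!r}) not found")
    i = int(g.index.get_indexer(match)[0])
    cv = posterior.cv_draws()[:, :, i].ravel()
    return GroupCV(
        species=species,
        location_id=location_id,
        trait=posterior.trait,
        cv_hat=float(cv.mean()),
        tau_hat=float(cv.std(ddof=0)),
        n_individuals=int(g["n"].iloc[i]),
        draws=cv,
    )


def derive_all_group_cvs(posterior: CVPosterior) -> pd.DataFrame:
    """Table of (species, location_id, trait, cv_hat, tau_hat, n) per group."""
    cv = posterior.cv_draws().reshape(-1, len(posterior.groups))
    out = posterior.groups[["species", "location_id", "n"]].copy()
    out["trait"] = posterior.trait
    out["cv_hat"] = cv.mean(axis=0)
    out["tau_hat"] = cv.std(axis=0, ddof=0)
    return out


def derive_species_cv(posterior: CVPosterior, species: str) -> SpeciesCV:
    """Species-average CV: mean over the species' groups, per draw."""
    mask = (posterior.groups["species"] == species).to_numpy()
    if not mask.any():
        raise KeyError(f"species {species!r} not found")
    cv = posterior.cv_draws()[:, :, mask].mean(axis=2).ravel()
    return SpeciesCV(
        species=species,
        trait=posterior.trait,
        cvsp_hat=float(cv.mean()),
        tausp_hat=float(cv.std(ddof=0)),
    )


def derive_all_species_cvs(posterior: CVPosterior) -> pd.DataFrame:
    rows = [
        derive_species_cv(posterior, s).__dict__ for s in posterior.species_names
    ]
    return pd.DataFrame(rows).rename(columns={"cvsp_hat": "cvsp_hat", "tausp_hat": "tausp_hat"})
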