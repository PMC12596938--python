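"""Convergence diagnostics, posterior summaries and MCMC configuration.

Every model stage reports, for each parameter of interest: posterior mean,
equal-tailed 89% credible interval (5.5% and 94.5% empirical quantiles,
linear interpolation), the posterior probability of being positive, the
rank-normalised split R-hat and the autocorrelation-based effective sample
size (ESS).  Stage-specific convergence gates combine R-hat and ESS
thresholds; a fit that fails its gate is flagged, never silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "McmcConfig",
    "PosteriorSummary",
    "PosteriorDraws",
    "rhat",
    "ess",
    "summarize_draws",
]


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout for a Gibbs fit.

    ``iterations`` counts post-thinning sweeps per chain *including* warmup;
    only post-warmup draws are stored.
    """

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kept(self) -> int:
        return (self.iterations - self.warmup + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of the posterior of one scalar parameter."""

    name: str
    mean: float
    ci89: tuple[float, float]
    p_gt0: float
    rhat: float
    ess: float
    n_draws: int

    def __post_init__(self) -> None:
        if not self.ci89[0] <= self.ci89[1]:
            raise ValueError("ci89 endpoints out of order")
        if not 0.0 <= self.p_gt0 <= 1.0:
            raise ValueError("p_gt0 outside [0, 1]")


def rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat for draws shaped (chain, draw).

    Identical or constant chains return 1.0 by convention (the estimator is
    undefined at zero variance).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat requires draws shaped (chains >= 2, draws)")
    if x.shape[1] < 4:
        raise ValueError("rhat requires at least 4 draws per chain")
    if np.ptp(x) == 0:
        return 1.0
    return float(az.rhat(x))


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size; accepts (draw,) or (chain, draw) arrays.

    Constant draws have no information about mixing and are reported as 0.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("ess expects 1-D or 2-D draws")
    if x.size < 100:
        raise ValueError("ess requires at least 100 draws")
    if np.ptp(x) == 0:
        return 0.0
    return float(az.ess(x))


def rhat_array(chains: np.ndarray) -> np.ndarray:
    """Vectorised R-hat for draws shaped (chain, draw, ...); returns (...)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        return np.asarray(rhat(x))
    ds = az.convert_to_dataset(x)
    out = np.asarray(az.rhat(ds)["x"].values)
    flat = x.reshape(x.shape[0] * x.shape[1], -1)
    constant = np.ptp(flat, axis=0).reshape(out.shape) == 0
    return np.where(constant, 1.0, out)


def ess_array(chains: np.ndarray) -> np.ndarray:
    """Vectorised bulk ESS for draws shaped (chain, draw, ...)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        return np.asarray(ess(x))
    ds = az.convert_to_dataset(x)
    out = np.asarray(az.ess(ds)["x"].values)
    flat = x.reshape(x.shape[0] * x.shape[1], -1)
    constant = np.ptp(flat, axis=0).reshape(out.shape) == 0
    return np.where(constant, 0.0, out)


def summarize_draws(chains: np.ndarray, name: str = "param") -> PosteriorSummary:
    """Posterior summary of one scalar from draws shaped (chain, draw)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    flat = x.ravel()
    if flat.size < 100:
        raise ValueError("need at least 100 draws to summarise")
    lo, hi = np.quantile(flat, [0.055, 0.945])
    return PosteriorSummary(
        name=name,
        mean=float(flat.mean()),
        ci89=(float(lo), float(hi)),
        p_gt0=float(np.mean(flat > 0)),
        rhat=rhat(x) if x.shape[0] >= 2 else float("nan"),
        ess=ess(x),
        n_draws=int(flat.size),
    )


class PosteriorDraws:
    """Container for Gibbs output: name -> array shaped (chain, draw, ...).

    Also records the convergence gate verdict computed at fit time over the
    stage's reported parameters.
    """

    def __init__(self, draws: Mapping[str, np.ndarray]):
        self._draws = {k: np.asarray(v) for k, v in draws.items()}
        shapes = {v.shape[:2] for v in self._draws.values()}
        if len(shapes) != 1:
            raise ValueError("all draw arrays must share (chain, draw) shape")
        self.chains, self.n_kept = shapes.pop()
        self.gate: dict | None = None

    @property
    def names(self) -> list[str]:
        return list(self._draws)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._draws[name]

    def scalar(self, name: str, index: tuple | int = ()) -> np.ndarray:
        """(chain, draw) array for one scalar component of a parameter."""
        if isinstance(index, int):
            index = (index,)
        return self._draws[name][(slice(None), slice(None)) + tuple(index)]

    def flat(self, name: str) -> np.ndarray:
        """Draws with chain and draw axes merged."""
        a = self._draws[name]
        return a.reshape(-1, *a.shape[2:])

    def summarize(self, name: str, index: tuple | int = (), label: str | None = None) -> PosteriorSummary:
        return summarize_draws(self.scalar(name, index), label or name)

    def check_gate(
        self,
        params: Iterable[str],
        rhat_max: float,
        ess_min: float,
    ) -> dict:
        """Evaluate the convergence gate over the named parameters.

        For array-valued parameters the worst R-hat / ESS over components is
        used.  Returns a dict with per-parameter diagnostics, the thresholds,
        a divergence count (0: Gibbs transitions have no divergence concept,
        recorded for report compatibility) and the overall verdict.
        """
        rows = []
        for name in params:
            x = self._draws[name]
            rows.append(
                {
                    "param": name,
                    "rhat": float(np.max(rhat_array(x))),
                    "ess": float(np.min(ess_array(x))),
                }
            )
        converged = all(r["rhat"] <= rhat_max and r["ess"] > ess_min for r in rows)
        self.gate = {
            "rhat_max_allowed": rhat_max,
            "ess_min_required": ess_min,
            "rhat_max_observed": max(r["rhat"] for r in rows),
            "ess_min_observed": min(r["ess"] for r in rows),
            "divergences": 0,
            "params": rows,
            "converged": bool(converged),
        }
        return self.gate

    @property
    def converged(self) -> bool:
        if self.gate is None:
            raise RuntimeError("convergence gate has not been evaluated")
        return self.gate["converged"]
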