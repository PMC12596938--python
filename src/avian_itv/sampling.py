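"""Low-level MCMC building blocks shared by the model modules.

All three model stages are fitted with blocked Gibbs samplers: location-type
parameters have conjugate normal / multivariate-normal full conditionals,
while scale-type parameters (group SDs, process SDs, half-normal
hyperparameters) are updated with a univariate slice sampler.  The slice
sampler is vectorised over arrays of conditionally independent scalars, which
keeps a full sweep over hundreds of groups cheap.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["slice_sample", "slice_sample_scalar", "mvn_draw", "mvn_precision_draw"]


def slice_sample_scalar(
    x0: float,
    logpdf: Callable[[float], float],
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 64,
) -> float:
    """Scalar slice-sampling update; ``logpdf`` is a plain float function.

    Same stepping-out/shrinkage scheme as :func:`slice_sample` but without
    array overhead — used for the global hyperparameters, which are updated
    thousands of times per fit.
    """
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample_scalar: log density not finite at x0")
    logy = f0 + np.log(rng.uniform())
    left = x0 - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logpdf(left) <= logy:
            break
        left -= width
    for _ in range(max_steps):
        if logpdf(right) <= logy:
            break
        right += width
    for _ in range(1000):
        prop = left + rng.uniform() * (right - left)
        if logpdf(prop) >= logy:
            return prop
        if prop < x0:
            left = prop
        else:
            right = prop
    return x0


def slice_sample(
    x0: np.ndarray,
    logpdf: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    width: float | np.ndarray = 1.0,
    max_steps: int = 64,
) -> np.ndarray:
    """One slice-sampling update for an array of independent scalars.

    Parameters
    ----------
    x0
        Current values; each element is an independent scalar parameter.
    logpdf
        Vectorised elementwise log density (up to a constant); must return
        ``-inf`` outside the support.
    rng
        Source of randomness.
    width
        Initial bracket width for the stepping-out procedure.

    Uses stepping-out followed by shrinkage (Neal 2003).  ``logpdf(x0)`` must
    be finite for every element.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    f0 = logpdf(x0)
    if not np.all(np.isfinite(f0)):
        raise ValueError("slice_sample: log density not finite at current state")
    logy = f0 + np.log(rng.uniform(size=x0.shape))
    left = x0 - width * rng.uniform(size=x0.shape)
    right = left + width

    for _ in range(max_steps):
        grow = logpdf(left) > logy
        if not grow.any():
            break
        left = np.where(grow, left - width, left)
    for _ in range(max_steps):
        grow = logpdf(right) > logy
        if not grow.any():
            break
        right = np.where(grow, right + width, right)

    x1 = x0.copy()
    todo = np.ones(x0.shape, dtype=bool)
    for _ in range(1000):
        prop = left + rng.uniform(size=x0.shape) * (right - left)
        ok = logpdf(prop) >= logy
        accept = todo & ok
        x1 = np.where(accept, prop, x1)
        # shrink the bracket for elements still searching
        still = todo & ~ok
        shrink_left = still & (prop < x0)
        left = np.where(shrink_left, prop, left)
        right = np.where(still & ~shrink_left, prop, right)
        todo = still
        if not todo.any():
            break
    return x1


def mvn_draw(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from MVN(mean, cov) via Cholesky; supports batched leading dims."""
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", chol, z)


def mvn_precision_draw(
    precision: np.ndarray, rhs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from MVN with natural parameters (precision matrix, rhs).

    The target is N(precision^-1 rhs, precision^-1); supports batched leading
    dimensions on both arguments.
    """
    chol = np.linalg.cholesky(precision)
    # mean: solve L L' m = rhs
    tmp = np.linalg.solve(chol, rhs[..., None])
    mean = np.linalg.solve(np.swapaxes(chol, -1, -2), tmp)[..., 0]
    z = rng.standard_normal(rhs.shape)
    dev = np.linalg.solve(np.swapaxes(chol, -1, -2), z[..., None])[..., 0]
    return mean + dev
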