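"""Gamma-likelihood primitives shared by the GLM and curve-fitting stages.

Everywhere in this package the gamma distribution is parameterized by
(shape ``k``, mean ``mu``), i.e. scale = mu/k, so that a mean model plugs
into the likelihood directly.  A useful consequence: the score for the mean
parameters factors through ``k``, so the maximum-likelihood mean fit can be
obtained by minimizing the shape-free kernel ``sum(log mu + y/mu)`` and the
shape recovered afterwards from the profile equation
``log(k) - digamma(k) = deviance / (2 n)``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln

#: ceiling for the profiled shape; reached only when the fit is (numerically)
#: saturated and the profile equation has no finite root.
MAX_SHAPE = 1e12
MIN_SHAPE = 1e-8


def loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    """Total gamma log-likelihood of observations ``y`` with means ``mu``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = float(shape)
    n = y.size
    return float(
        n * (k * np.log(k) - gammaln(k))
        + np.sum(-k * np.log(mu) + (k - 1.0) * np.log(y) - k * y / mu)
    )


def deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Shape-free gamma deviance ``2 * sum(-log(y/mu) + (y - mu)/mu)``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def kernel(y: np.ndarray, mu: np.ndarray) -> float:
    """Shape-free negative-likelihood kernel ``sum(log mu + y/mu)``.

    Minimizing this over the mean parameters yields the gamma MLE of the
    mean model for every value of the shape.
    """
    return float(np.sum(np.log(mu) + y / mu))


def profile_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape given fitted means ``mu``.

    Solves ``log(k) - digamma(k) = D/(2n)`` where D is the gamma deviance;
    the left side is strictly decreasing from +inf to 0, so the root is
    unique.  A zero deviance (exact fit) maps to ``MAX_SHAPE``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c = deviance(y, mu) / (2.0 * n)
    if not np.isfinite(c) or c <= 0.0:
        return MAX_SHAPE

    def f(log_k: float) -> float:
        k = np.exp(log_k)
        return np.log(k) - digamma(k) - c

    # log k - digamma(k) ~ 1/(2k) for large k gives a starting guess.
    guess = np.log(max(1.0 / (2.0 * c), MIN_SHAPE))
    lo, hi = guess - 2.0, guess + 2.0
    while f(lo) < 0.0 and lo > np.log(MIN_SHAPE):
        lo -= 4.0
    while f(hi) > 0.0 and hi < np.log(MAX_SHAPE):
        hi += 4.0
    if f(lo) < 0.0:
        return MIN_SHAPE
    if f(hi) > 0.0:
        return MAX_SHAPE
    return float(np.exp(brentq(f, lo, hi, xtol=1e-13, rtol=1e-13)))


def numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``x``."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2.0 * fun(x) + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess


def covariance_from_hessian(hess: np.ndarray) -> np.ndarray | None:
    """Observed-information covariance, or None when the Hessian is singular."""
    if not np.all(np.isfinite(hess)):
        return None
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov
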