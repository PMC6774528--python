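"""Numerical primitives shared across the package.

Stable normal-tail quantities (inverse Mills ratio), finite-difference
Hessians used for observed-information covariance matrices, and moment
calibration/sampling for threshold-truncated lognormal distributions.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root
from scipy.special import log_ndtr, ndtr, ndtri

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def norm_logpdf(x):
    x = np.asarray(x, dtype=float)
    return -0.5 * x * x - _LOG_SQRT_2PI


def inverse_mills(t):
    """Inverse Mills ratio lambda(t) = phi(t) / Phi(t).

    Computed as exp(log phi - log Phi); ``log_ndtr`` keeps the left tail
    accurate, so the ratio is stable for |t| well beyond 40 (where the
    naive quotient underflows to 0/0).
    """
    t = np.asarray(t, dtype=float)
    return np.exp(norm_logpdf(t) - log_ndtr(t))


def inverse_mills_prime(t):
    """d/dt lambda(t) = -lambda(t) (lambda(t) + t)."""
    lam = inverse_mills(t)
    return -lam * (lam + np.asarray(t, dtype=float))


def numerical_hessian(grad, x, rel_step=1e-6):
    """Central-difference Jacobian of an analytic gradient.

    Accurate enough (~1e-8 relative) for observed-information standard
    errors and Newton polishing of low-dimensional likelihoods.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (np.asarray(grad(xp)) - np.asarray(grad(xm))) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Truncated lognormal calibration (biomarker expression levels)
# ---------------------------------------------------------------------------

def truncated_lognormal_moments(mu, s, lower=0.0, upper=np.inf):
    """Mean and SD of exp(N(mu, s^2)) truncated to (lower, upper).

    Uses the closed form E[X^k | a<X<b] = e^{k mu + k^2 s^2 / 2}
    [Phi(b_s - k s) - Phi(a_s - k s)] / [Phi(b_s) - Phi(a_s)] with
    a_s = (ln a - mu)/s.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    a = -np.inf if lower <= 0 else (np.log(lower) - mu) / s
    b = np.inf if np.isinf(upper) else (np.log(upper) - mu) / s
    z = ndtr(b) - ndtr(a)
    if z <= 0:
        raise ValueError("empty truncation interval")

    def raw(k):
        return np.exp(k * mu + 0.5 * k * k * s * s) * (ndtr(b - k * s) - ndtr(a - k * s)) / z

    m1 = raw(1)
    var = raw(2) - m1 * m1
    return m1, np.sqrt(max(var, 0.0))


def solve_truncated_lognormal(mean, sd, lower=0.0, upper=np.inf):
    """Find (mu, s) so the (lower, upper)-truncated lognormal has the
    requested mean and SD. Raises if the targets are infeasible."""
    if mean <= max(lower, 0.0) or (np.isfinite(upper) and mean >= upper):
        raise ValueError(f"target mean {mean} outside truncation interval")
    # untruncated lognormal moment-matching start
    cv2 = (sd / mean) ** 2
    s0 = np.sqrt(np.log1p(cv2))
    mu0 = np.log(mean) - 0.5 * s0 * s0

    def eqs(theta):
        mu, logs = theta
        m, v = truncated_lognormal_moments(mu, np.exp(logs), lower, upper)
        return [m - mean, v - sd]

    sol = root(eqs, [mu0, np.log(s0)], method="hybr", tol=1e-12)
    if not sol.success or max(abs(np.asarray(eqs(sol.x)))) > 1e-8 * max(mean, sd):
        raise ValueError(
            f"could not calibrate truncated lognormal to mean={mean}, sd={sd} "
            f"on ({lower}, {upper})"
        )
    mu, logs = sol.x
    return float(mu), float(np.exp(logs))


def sample_truncated_lognormal(rng, mu, s, lower=0.0, upper=np.inf, size=None):
    """Exact inverse-CDF sampling of a truncated lognormal."""
    a = 0.0 if lower <= 0 else ndtr((np.log(lower) - mu) / s)
    b = 1.0 if np.isinf(upper) else ndtr((np.log(upper) - mu) / s)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + s * ndtri(u))


def truncnorm_loc_for_mean(target_mean, sd, lower):
    """Location parameter of a lower-truncated normal with a given mean.

    The truncated mean loc + sd * lambda((lower - loc)/sd) is strictly
    increasing in loc, so the root is unique; solved by bisection.
    """
    if not np.isfinite(lower):
        return float(target_mean)
    if target_mean <= lower:
        raise ValueError(f"target mean {target_mean} must exceed the lower "
                         f"bound {lower}")
    from scipy.optimize import brentq

    def f(loc):
        lam = np.exp(norm_logpdf((lower - loc) / sd)
                     - log_ndtr(-(lower - loc) / sd))
        return loc + sd * lam - target_mean

    lo = target_mean - 12.0 * sd
    return float(brentq(f, lo, target_mean, xtol=1e-12))


def sample_truncated_normal(rng, mean, sd, lower=0.0, size=None):
    """Inverse-CDF sampling of N(mean, sd^2) truncated to (lower, inf)."""
    mean = np.asarray(mean, dtype=float)
    a = ndtr((lower - mean) / sd)
    if size is None:
        size = mean.shape if mean.shape else None
    u = rng.uniform(0.0, 1.0, size=size)
    # map u uniformly onto (F(lower), 1)
    return mean + sd * ndtri(a + u * (1.0 - a))
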