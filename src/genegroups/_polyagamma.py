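"""Vectorised sampler for the Polya-Gamma distribution PG(1, z).

PG augmentation turns Bernoulli-logit likelihoods into conditionally
Gaussian ones: if omega ~ PG(1, z) then the logistic likelihood contribution
exp(z*y) / (1 + exp(z)) is a Gaussian mixture in omega. The sampler below is
the exact alternating-series rejection method of Devroye (as used for
Bayesian logistic regression by Polson, Scott & Windle), written against
numpy arrays so a whole vector of latent values is augmented per Gibbs
sweep.

A draw from PG(1, z) is J*(1, z/2) / 4 where J* is the tilted Jacobi
distribution; the proposal mixes a truncated exponential (right of t = 0.64)
with a truncated inverse-Gaussian (left of t), and acceptance is decided by
partial sums of the alternating series for the Jacobi density.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

_T = 0.64  # series crossover point; Devroye's recommended value
_HALF_PI2 = np.pi**2 / 8.0


def _log_coef(n: int, x: np.ndarray) -> np.ndarray:
    """log a_n(x), the n-th alternating-series coefficient of the Jacobi density."""
    out = np.empty_like(x)
    small = x <= _T
    xs = x[small]
    out[small] = (
        np.log(np.pi * (n + 0.5))
        + 1.5 * (np.log(2.0) - np.log(np.pi) - np.log(xs))
        - 2.0 * (n + 0.5) ** 2 / xs
    )
    xl = x[~small]
    out[~small] = (
        np.log(np.pi * (n + 0.5)) - (n + 0.5) ** 2 * np.pi**2 * xl / 2.0
    )
    return out


def _mixture_weight(z: np.ndarray) -> np.ndarray:
    """P(proposal comes from the truncated-exponential branch), elementwise.

    p = (pi / (2K)) exp(-K t) with K = pi^2/8 + z^2/2;
    q = 2 exp(-z) F_IG(t; mu=1/z, lambda=1) (z = 0 handled by the CDF formula).
    """
    K = _HALF_PI2 + 0.5 * z * z
    logp = np.log(np.pi / (2.0 * K)) - K * _T
    rt = 1.0 / np.sqrt(_T)
    # inverse-Gaussian CDF at t, lambda = 1, mu = 1/z, written to survive z = 0
    # and large z: F(t) = ndtr(rt*(t z - 1)) + exp(2 z) ndtr(-rt*(t z + 1))
    term1 = np.exp(log_ndtr(rt * (_T * z - 1.0)))
    term2 = np.exp(2.0 * z + log_ndtr(-rt * (_T * z + 1.0)))
    logq = np.log(2.0) - z + np.log(term1 + term2)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(logq - logp))


def _sample_trunc_invgauss(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t], elementwise."""
    out = np.empty_like(z)
    big_mu = z < 1.0 / _T  # mean exceeds the truncation point

    if big_mu.any():
        zb = z[big_mu]
        x = np.empty_like(zb)
        pending = np.ones(zb.shape, dtype=bool)
        while pending.any():
            idx = np.flatnonzero(pending)
            k = idx.size
            e1 = rng.exponential(size=k)
            e2 = rng.exponential(size=k)
            ok = e1 * e1 <= 2.0 * e2 / _T
            cand = _T / (1.0 + _T * e1) ** 2
            # thin by the z-tilt exp(-z^2 x / 2)
            ok &= rng.random(k) <= np.exp(-0.5 * cand * zb[idx] ** 2)
            x[idx[ok]] = cand[ok]
            pending[idx[ok]] = False
        out[big_mu] = x

    if (~big_mu).any():
        zs = z[~big_mu]
        mu = 1.0 / zs
        x = np.empty_like(zs)
        pending = np.ones(zs.shape, dtype=bool)
        while pending.any():
            idx = np.flatnonzero(pending)
            k = idx.size
            m = mu[idx]
            y = rng.standard_normal(k) ** 2
            cand = m + 0.5 * m * m * y - 0.5 * m * np.sqrt(4.0 * m * y + (m * y) ** 2)
            swap = rng.random(k) > m / (m + cand)
            cand[swap] = m[swap] ** 2 / cand[swap]
            ok = cand <= _T
            x[idx[ok]] = cand[ok]
            pending[idx[ok]] = False
        out[~big_mu] = x

    return out


def _series_accept(x: np.ndarray, v: np.ndarray, max_terms: int = 200) -> np.ndarray:
    """Alternating-series accept/reject: True where the proposal is accepted."""
    a0 = np.exp(_log_coef(0, x))
    y = v * a0
    s = a0.copy()
    accepted = np.zeros(x.shape, dtype=bool)
    undecided = np.ones(x.shape, dtype=bool)
    for n in range(1, max_terms + 1):
        if not undecided.any():
            break
        idx = np.flatnonzero(undecided)
        s[idx] += ((-1.0) ** n) * np.exp(_log_coef(n, x[idx]))
        if n % 2 == 1:  # odd partial sums are lower bounds
            acc = y[idx] <= s[idx]
            accepted[idx[acc]] = True
            undecided[idx[acc]] = False
        else:  # even partial sums are upper bounds
            rej = y[idx] > s[idx]
            undecided[idx[rej]] = False
    return accepted


def random_polyagamma(z, rng: np.random.Generator) -> np.ndarray:
    """Draw PG(1, z) variates elementwise for an array of tilts z."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    zz = np.abs(z) / 2.0  # PG(1, z) = J*(1, z/2) / 4; symmetric in z
    K = _HALF_PI2 + 0.5 * zz * zz
    ratio = _mixture_weight(zz)

    out = np.empty_like(zz)
    pending = np.ones(zz.shape, dtype=bool)
    while pending.any():
        idx = np.flatnonzero(pending)
        k = idx.size
        use_exp = rng.random(k) < ratio[idx]
        x = np.empty(k)
        if use_exp.any():
            ke = idx[use_exp]
            x[use_exp] = _T + rng.exponential(size=ke.size) / K[ke]
        if (~use_exp).any():
            ki = idx[~use_exp]
            x[~use_exp] = _sample_trunc_invgauss(zz[ki], rng)
        acc = _series_accept(x, rng.random(k))
        out[idx[acc]] = x[acc] / 4.0
        pending[idx[acc]] = False
    return out


def pg_mean(z) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out
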