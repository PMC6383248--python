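"""Exact Pólya-Gamma PG(1, z) sampling for logistic data augmentation.

Implements Devroye's alternating-series rejection sampler for the
Jacobi-type random variable J*(1, z), with PG(1, c) = J*(1, c/2) / 4
(Polson, Scott & Windle 2013; Devroye 2009). The sampler is exact (no
series truncation) and is compiled with numba; randomness flows through a
``numpy.random.Generator`` so draws are reproducible for a given seed and
numba/numpy version.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "pg_mean", "pg_var"]

# Truncation point separating the inverse-Gaussian and exponential pieces
# of the proposal mixture (Devroye's recommended 0.64).
_TRUNC = 0.64


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss_cdf(t, z):
    """P(X <= t) for X ~ InverseGaussian(mu=1/z, lambda=1); z >= 0.

    At z = 0 the distribution degenerates to the Lévy(0, 1) law and the
    expression reduces to 2*Phi(-1/sqrt(t)).
    """
    rt = math.sqrt(t)
    a = _norm_cdf((t * z - 1.0) / rt)
    # exp(2z) can overflow for huge z, but then the second Phi underflows
    # faster; guard by working in logs.
    b_log = 2.0 * z
    phi = _norm_cdf(-(t * z + 1.0) / rt)
    if phi <= 0.0:
        b = 0.0
    else:
        b = math.exp(b_log + math.log(phi))
    return a + b


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of the alternating series for the J*(1, z) density."""
    if x <= _TRUNC:
        return (
            math.pi
            * (n + 0.5)
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0)


@njit(cache=True)
def _sample_truncated_ig(z, rng):
    """Draw from InverseGaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC]."""
    t = _TRUNC
    if z < 1.0 / t:
        # mu > t: rejection with a truncated Lévy proposal, thinned by
        # exp(-z^2 x / 2) (handles z = 0 exactly: always accepted).
        while True:
            while True:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        # mu <= t: draw IG(mu, 1) until it lands below t.
        mu = 1.0 / z
        while True:
            y = rng.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _sample_jstar(z, rng):
    """One draw of J*(1, z) by Devroye's alternating-series method; z >= 0."""
    t = _TRUNC
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    p = (math.pi / (2.0 * fz)) * math.exp(-fz * t)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(t, z)
    ratio = p / (p + q)
    while True:
        if rng.random() < ratio:
            x = t + rng.standard_exponential() / fz
        else:
            x = _sample_truncated_ig(z, rng)
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg_draw_into(out, c, rng):
    for i in range(c.shape[0]):
        z = abs(c[i]) / 2.0
        out[i] = _sample_jstar(z, rng) / 4.0


def pg_draw(c, rng):
    """Draw PG(1, c_i) for each element of ``c``.

    Parameters
    ----------
    c : array_like
        Tilting parameters (any sign; PG(1, c) depends on |c|).
    rng : numpy.random.Generator
        Source of randomness.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64).ravel())
    out = np.empty_like(c)
    _pg_draw_into(out, c, rng)
    return out


def pg_mean(c):
    """E[PG(1, c)] = tanh(c/2) / (2c), with the c -> 0 limit 1/4."""
    c = np.asarray(c, dtype=np.float64)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-12
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out


def pg_var(c):
    """Var[PG(1, c)]; the c -> 0 limit is 1/24."""
    c = np.asarray(c, dtype=np.float64)
    out = np.full(c.shape, 1.0 / 24.0)
    nz = np.abs(c) > 1e-6
    cn = np.abs(c[nz])
    # (sinh(c) - c) * sech^2(c/2) rewritten with exp(-c) factors so neither
    # piece overflows/underflows for large |c|.
    em = np.exp(-cn)
    num = 2.0 * (1.0 - em * em) - 4.0 * cn * em
    out[nz] = num / ((1.0 + em) ** 2 * 4.0 * cn ** 3)
    return out
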