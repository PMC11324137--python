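"""Numerical kernels for the per-peak likelihood computations.

Peak count vectors are tiny, so Python/array overhead dominates naive
implementations; the kernels below work on the aggregated
(distinct non-zero value, multiplicity) representation and are JIT-compiled
with numba when available (falling back to plain Python otherwise, with
identical results).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f
        return deco

LOG_PHI_MIN = math.log(1e-6)
LOG_PHI_MAX = math.log(1e3)


@njit(cache=True)
def zinb_loglik_kernel(n_zero, values, counts, total, sum_glnv1, n_nonzero,
                       p, mu, phi):
    """ZINB log-likelihood of one peak via the zero/non-zero factorization.

    ``values``/``counts`` aggregate the non-zero cells; ``sum_glnv1`` is
    sum(counts * gammaln(values + 1)), precomputed once per peak.
    """
    a = 1.0 / phi
    l1p = math.log1p(mu * phi)
    ll = 0.0
    if n_zero > 0:
        nb0 = -a * l1p
        if p <= 0.0:
            z = nb0
        elif p >= 1.0:
            z = 0.0
        else:
            x = math.log(p)
            y = math.log1p(-p) + nb0
            hi = x if x > y else y
            z = hi + math.log1p(math.exp(-abs(x - y)))
        ll += n_zero * z
    if n_nonzero > 0:
        if p >= 1.0:
            return -np.inf
        s = 0.0
        for k in range(values.shape[0]):
            s += counts[k] * math.lgamma(values[k] + a)
        ll += (s - sum_glnv1 - n_nonzero * math.lgamma(a)
               + total * (math.log(mu * phi) - l1p)
               - n_nonzero * a * l1p
               + n_nonzero * math.log1p(-p))
    return ll


@njit(cache=True)
def _weighted_nb_obj(eta, w0, mu, values, counts, total, n_nonzero):
    """Responsibility-weighted NB log-likelihood as a function of
    eta = log(phi), up to terms constant in phi."""
    phi = math.exp(eta)
    a = 1.0 / phi
    l1p = math.log1p(mu * phi)
    obj = -w0 * a * l1p
    if n_nonzero > 0:
        s = 0.0
        for k in range(values.shape[0]):
            s += counts[k] * math.lgamma(values[k] + a)
        obj += (s - n_nonzero * math.lgamma(a)
                + total * (math.log(mu * phi) - l1p)
                - n_nonzero * a * l1p)
    return obj


@njit(cache=True)
def _phi_newton_update(phi, w0, mu, values, counts, total, n_nonzero):
    """A few guarded Newton steps on the weighted NB objective in log phi.

    Never returns a point with a lower objective than the input (keeps the
    EM iteration monotone with an inexact M-step)."""
    eta = math.log(phi)
    if eta < LOG_PHI_MIN:
        eta = LOG_PHI_MIN
    if eta > LOG_PHI_MAX:
        eta = LOG_PHI_MAX
    f0 = _weighted_nb_obj(eta, w0, mu, values, counts, total, n_nonzero)
    h = 1e-5
    for _ in range(3):
        fp = _weighted_nb_obj(eta + h, w0, mu, values, counts, total,
                              n_nonzero)
        fm = _weighted_nb_obj(eta - h, w0, mu, values, counts, total,
                              n_nonzero)
        g = (fp - fm) / (2.0 * h)
        c = (fp - 2.0 * f0 + fm) / (h * h)
        if abs(g) < 1e-12:
            break
        if c < 0.0:
            step = -g / c
        else:
            step = 1.0 if g > 0.0 else -1.0
        if step > 2.0:
            step = 2.0
        if step < -2.0:
            step = -2.0
        accepted = False
        for _ in range(25):
            eta_new = eta + step
            if eta_new < LOG_PHI_MIN:
                eta_new = LOG_PHI_MIN
            if eta_new > LOG_PHI_MAX:
                eta_new = LOG_PHI_MAX
            f_new = _weighted_nb_obj(eta_new, w0, mu, values, counts, total,
                                     n_nonzero)
            if f_new >= f0:
                eta, f0 = eta_new, f_new
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return math.exp(eta)


@njit(cache=True)
def em_kernel(n, n_zero, values, counts, total, sum_glnv1, n_nonzero,
              p0, mu0, phi0, tol, max_iter, p_floor, trace):
    """EM iteration for one peak; fills ``trace`` with the log-likelihood
    sequence and returns (p, mu, phi, loglik, n_iter, converged)."""
    p, mu, phi = p0, mu0, phi0
    ll = zinb_loglik_kernel(n_zero, values, counts, total, sum_glnv1,
                            n_nonzero, p, mu, phi)
    trace[0] = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior probability a zero came from the point mass.
        nb0 = math.exp(-(1.0 / phi) * math.log1p(mu * phi))
        denom = p + (1.0 - p) * nb0
        r = p / denom if denom > 0.0 else 1.0
        # M-step.
        p = n_zero * r / n
        if p < p_floor:
            p = p_floor
        if p > 1.0 - 1e-6:
            p = 1.0 - 1e-6
        w0 = n_zero * (1.0 - r)
        mu = total / (w0 + n_nonzero)
        if mu < 1e-10:
            mu = 1e-10
        phi = _phi_newton_update(phi, w0, mu, values, counts, total,
                                 n_nonzero)
        ll_new = zinb_loglik_kernel(n_zero, values, counts, total, sum_glnv1,
                                    n_nonzero, p, mu, phi)
        trace[it] = ll_new
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return p, mu, phi, ll, it, converged


_INVPHI = 0.6180339887498949   # 1/golden ratio
_INVPHI2 = 0.3819660112501051  # 1/golden ratio squared


@njit(cache=True)
def _coord_obj(x, mode, other, phi, n_zero, values, counts, total,
               sum_glnv1, n_nonzero):
    if mode == 0:   # x is mu, other is p
        return zinb_loglik_kernel(n_zero, values, counts, total, sum_glnv1,
                                  n_nonzero, other, x, phi)
    return zinb_loglik_kernel(n_zero, values, counts, total, sum_glnv1,
                              n_nonzero, x, other, phi)


@njit(cache=True)
def golden_max_coord(mode, lo, hi, other, phi, n_zero, values, counts,
                     total, sum_glnv1, n_nonzero, xatol):
    """Golden-section maximization of the peak log-likelihood over one
    coordinate (mode 0: mu at fixed p; mode 1: p at fixed mu)."""
    a, b = lo, hi
    h = b - a
    if h <= xatol:
        x = 0.5 * (a + b)
        return x, _coord_obj(x, mode, other, phi, n_zero, values, counts,
                             total, sum_glnv1, n_nonzero)
    c = a + _INVPHI2 * h
    d = a + _INVPHI * h
    fc = _coord_obj(c, mode, other, phi, n_zero, values, counts, total,
                    sum_glnv1, n_nonzero)
    fd = _coord_obj(d, mode, other, phi, n_zero, values, counts, total,
                    sum_glnv1, n_nonzero)
    while h > xatol:
        if fc > fd:
            b, d, fd = d, c, fc
            h = b - a
            c = a + _INVPHI2 * h
            fc = _coord_obj(c, mode, other, phi, n_zero, values, counts,
                            total, sum_glnv1, n_nonzero)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = _coord_obj(d, mode, other, phi, n_zero, values, counts,
                            total, sum_glnv1, n_nonzero)
    x = 0.5 * (a + b)
    fx = _coord_obj(x, mode, other, phi, n_zero, values, counts, total,
                    sum_glnv1, n_nonzero)
    if fc > fx:
        x, fx = c, fc
    if fd > fx:
        x, fx = d, fd
    return x, fx
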