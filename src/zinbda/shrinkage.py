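"""Empirical-Bayes shrinkage of the per-peak NB dispersion.

Genome-wide, the log of the EM dispersion estimates is approximately
Gaussian, so a log-normal prior log phi ~ N(theta, sigma^2) is placed on the
dispersion. Its hyperparameters are estimated from the EM estimates across
all peaks (theta by the median of log phi-hat; sigma^2 by a robust spread
of log phi-hat minus the median estimation variance, so the prior width
reflects biological spread rather than estimation noise). The shrunken
dispersion for each peak is the mode of the conditional posterior

    log p(phi | y, mu, p, theta, sigma)
      = n1 log(p + (1-p)(1 + mu*phi)^(-1/phi))
        + sum_{i: y_i>0} log Gamma(y_i + 1/phi) - n2 log Gamma(1/phi)
        + n2 (1/phi) log(1/(1 + mu*phi))
        + sum_{i: y_i>0} y_i [log(mu*phi) - log(1 + mu*phi)]
        - (log phi - theta)^2 / (2 sigma^2) - log phi - log sigma
        + const,

maximized by Newton-Raphson in eta = log phi with step-halving and a
bounded golden-section fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .model import PHI_MAX, PHI_MIN, PeakCounts

__all__ = [
    "SIGMA_FLOOR",
    "ShrinkagePrior",
    "ShrunkenDispersion",
    "estimate_prior",
    "log_posterior_phi",
    "posterior_mode_phi",
]

# Floor on the prior scale: prevents a degenerate zero-width prior when the
# estimation-noise adjustment consumes the whole sample variance.
SIGMA_FLOOR = 0.1


@dataclass(frozen=True)
class ShrinkagePrior:
    """Log-normal prior on the dispersion: log phi ~ N(theta, sigma^2)."""

    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ShrunkenDispersion:
    phi_tilde: float
    optim_status: str  # "converged" or "fallback"

    def __post_init__(self) -> None:
        if not (self.phi_tilde > 0.0):
            raise ValueError("phi_tilde must be positive")


def estimate_prior(phi_hats, est_vars=None, min_peaks: int = 50) -> ShrinkagePrior:
    """Hyperparameters of the log-normal dispersion prior.

    theta is the median of log phi-hat across peaks. sigma^2 is a robust
    variance of log phi-hat — the squared scaled median absolute deviation,
    which equals the sample variance for Gaussian spreads — minus the
    median per-peak estimation variance of log phi-hat (delta method from
    the observed information of each EM fit), floored at
    ``SIGMA_FLOOR**2``. Robust moments are used throughout because at small
    cell numbers the dispersion is unidentifiable for a minority of sparse
    peaks, whose wild estimates (and near-infinite delta-method variances)
    would otherwise dominate both terms of the adjustment.

    Parameters
    ----------
    phi_hats : array of valid EM dispersion estimates (one per peak)
    est_vars : matching array of estimation variances of log phi-hat;
        non-finite entries are ignored; ``None`` means no adjustment.
    """
    phi_hats = np.asarray(phi_hats, dtype=float)
    phi_hats = phi_hats[np.isfinite(phi_hats) & (phi_hats > 0)]
    if phi_hats.size < min_peaks:
        raise ValueError(
            f"need at least {min_peaks} valid dispersion estimates to infer "
            f"the prior, got {phi_hats.size}; provide a larger peak set")
    log_phi = np.log(phi_hats)
    theta = float(np.median(log_phi))
    spread = float(stats.median_abs_deviation(log_phi, scale="normal")) ** 2
    noise = 0.0
    if est_vars is not None:
        ev = np.asarray(est_vars, dtype=float)
        ev = ev[np.isfinite(ev) & (ev >= 0)]
        if ev.size:
            noise = float(np.median(ev))
    sigma = float(np.sqrt(max(spread - noise, SIGMA_FLOOR**2)))
    return ShrinkagePrior(theta=theta, sigma=sigma)


def log_posterior_phi(phi: float, y, p: float, mu: float,
                      prior: ShrinkagePrior) -> float:
    """Log conditional posterior density of phi (up to an additive constant
    independent of phi), term by term via log-Gamma functions."""
    if not (phi > 0.0):
        raise ValueError(f"phi must be positive, got {phi}")
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)
    a = 1.0 / phi
    l1p = np.log1p(mu * phi)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    val = 0.0
    if pc.n_zero:
        nb0 = -a * l1p
        val += pc.n_zero * np.logaddexp(logp, log1mp + nb0)
    if pc.n_nonzero:
        val += float(pc.counts @ gammaln(pc.values + a))
        val += -pc.n_nonzero * gammaln(a)
        val += -pc.n_nonzero * a * l1p
        val += pc.total * (np.log(mu * phi) - l1p)
    lphi = np.log(phi)
    val += (-(lphi - prior.theta) ** 2 / (2.0 * prior.sigma**2)
            - lphi - np.log(prior.sigma))
    return float(val)


def posterior_mode_phi(y, p: float, mu: float, prior: ShrinkagePrior,
                       phi_init: float | None = None,
                       max_iter: int = 50, grad_tol: float = 1e-8,
                       max_halvings: int = 30) -> ShrunkenDispersion:
    """Posterior-mode (shrunken) dispersion for one peak.

    Newton-Raphson in eta = log phi with numeric derivatives and
    step-halving; if the iteration fails to reach a stationary point with
    non-positive curvature, falls back to a bounded scalar search on
    eta in [theta - 6 sigma, theta + 6 sigma].
    """
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)

    # Objective in eta = log phi: the full log-likelihood plus the
    # log-normal prior log-density. Differs from ``log_posterior_phi`` only
    # by an additive constant in phi, so the maximizer is identical.
    from .model import _loglik_agg
    inv_2s2 = 1.0 / (2.0 * prior.sigma**2)

    def f(eta: float) -> float:
        return (_loglik_agg(pc, p, mu, float(np.exp(eta)))
                - (eta - prior.theta) ** 2 * inv_2s2 - eta)

    lo = max(prior.theta - 6.0 * prior.sigma, np.log(PHI_MIN))
    hi = min(prior.theta + 6.0 * prior.sigma, np.log(PHI_MAX))

    eta = float(np.clip(np.log(phi_init) if phi_init else prior.theta, lo, hi))
    h = 1e-5
    ok = False
    f_eta = f(eta)
    for _ in range(max_iter):
        fp = f(eta + h)
        fm = f(eta - h)
        g = (fp - fm) / (2.0 * h)
        curv = (fp - 2.0 * f_eta + fm) / h**2
        if abs(g) < grad_tol and curv <= 1e-6:
            ok = True
            break
        if curv < 0:
            step = -g / curv
        else:
            # Uphill gradient step when curvature is the wrong sign.
            step = np.sign(g)
        # Step-halving: accept only non-decreasing posterior values.
        accepted = False
        for _ in range(max_halvings):
            eta_new = float(np.clip(eta + step, np.log(PHI_MIN), np.log(PHI_MAX)))
            f_new = f(eta_new)
            if f_new >= f_eta - 1e-12:
                eta, f_eta = eta_new, f_new
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break

    if ok:
        return ShrunkenDispersion(phi_tilde=float(np.exp(eta)),
                                  optim_status="converged")

    res = minimize_scalar(lambda e: -f(e), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    eta_fb = float(res.x)
    # Keep whichever point is better; the fallback is bounded, the Newton
    # iterate may legitimately sit outside [lo, hi] for likelihood-dominated
    # peaks.
    if f_eta > f(eta_fb):
        return ShrunkenDispersion(phi_tilde=float(np.exp(eta)),
                                  optim_status="fallback")
    return ShrunkenDispersion(phi_tilde=float(np.exp(eta_fb)),
                              optim_status="fallback")
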