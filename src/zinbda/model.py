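"""Zero-inflated negative binomial (ZINB) model for per-peak scATAC-seq counts.

The read count of peak g in cell i is modelled as a two-component mixture

    f_ZINB(y | mu, phi, p) = p * I(y = 0) + (1 - p) * f_NB(y | mu, phi),

where ``p`` is the prevalence of excess (structural) zeros and f_NB is the
negative binomial under the Gamma-Poisson parameterization with mean ``mu``
and dispersion ``phi`` (Var = mu + mu^2 * phi, i.e. size = 1/phi and success
probability 1/(1 + mu*phi)).

This module provides the log-pmf, the factorized log-likelihood over one
peak's cells, and an EM algorithm for initial estimation of (p, mu, phi)
using a latent indicator for whether each zero arose from the point mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._kernels import em_kernel, zinb_loglik_kernel

__all__ = [
    "PHI_MIN",
    "PHI_MAX",
    "P_FLOOR",
    "ZINBParams",
    "PeakCounts",
    "EMFit",
    "zinb_logpmf",
    "zinb_loglik",
    "em_fit",
    "em_logphi_variance",
]

# Dispersion floor/cap: the floor is the near-Poisson limit, the cap keeps
# the Gamma terms of the NB pmf finite in double precision.
PHI_MIN = 1e-6
PHI_MAX = 1e3
# Prevalence floor used when the data carry no evidence of zero inflation.
P_FLOOR = 1e-6


@dataclass(frozen=True)
class ZINBParams:
    """Per-peak parameter triple (p, mu, phi).

    p : probability of an excess zero, in [0, 1]
    mu : NB mean (counts), > 0
    phi : NB dispersion, > 0; implied NB variance is mu + mu**2 * phi
    """

    p: float
    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (self.mu > 0.0) or not np.isfinite(self.mu):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (self.phi > 0.0) or not np.isfinite(self.phi):
            raise ValueError(f"phi must be positive and finite, got {self.phi}")

    @property
    def nb_variance(self) -> float:
        return self.mu + self.mu**2 * self.phi


class PeakCounts:
    """Counts of one peak across cells, with cached sufficient statistics.

    Zero and non-zero cells enter the ZINB likelihood differently, so the
    vector is stored together with the zero count and the aggregated
    (value, multiplicity) table of the non-zero counts; the latter makes
    repeated likelihood evaluations cheap.
    """

    __slots__ = ("y", "n", "n_zero", "n_nonzero", "values", "counts", "total",
                 "_sum_glnv1")

    def __init__(self, y) -> None:
        arr = np.asarray(y)
        if arr.size == 0:
            raise ValueError("count vector must be non-empty")
        if arr.ndim != 1:
            raise ValueError("count vector must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("counts must be non-negative integers")
        arr = arr.astype(np.int64)
        self.y = arr
        self.n = int(arr.size)
        self.n_zero = int(np.count_nonzero(arr == 0))
        self.n_nonzero = self.n - self.n_zero
        nz = arr[arr > 0]
        values, counts = np.unique(nz, return_counts=True)
        self.values = values.astype(np.float64)
        self.counts = counts.astype(np.float64)
        self.total = float(nz.sum())
        # sum of gammaln(y + 1) over non-zero cells: constant across
        # likelihood evaluations, precomputed once per peak.
        self._sum_glnv1 = float(self.counts @ gammaln(self.values + 1.0))

    @classmethod
    def pooled(cls, a: "PeakCounts", b: "PeakCounts") -> "PeakCounts":
        return cls(np.concatenate([a.y, b.y]))

    def __len__(self) -> int:
        return self.n


def _nb_logpmf(y, mu: float, phi: float):
    """NB log-pmf under the Gamma-Poisson (mean, dispersion) form."""
    a = 1.0 / phi
    l1p = np.log1p(mu * phi)
    return (gammaln(y + a) - gammaln(y + 1.0) - gammaln(a)
            + y * (np.log(mu * phi) - l1p) - a * l1p)


def zinb_logpmf(y, params: ZINBParams):
    """Log-probability of counts under the ZINB mixture.

    Accepts a scalar or array of non-negative integers; returns matching
    shape. Exponentiated values sum to one over the support.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("y must contain non-negative integers")
    p, mu, phi = params.p, params.mu, params.phi
    with np.errstate(divide="ignore"):
        logp = np.log(p)
        log1mp = np.log1p(-p)
    nb = _nb_logpmf(arr, mu, phi)
    out = log1mp + nb
    zero_mask = arr == 0
    if np.any(zero_mask):
        nb0 = -(1.0 / phi) * np.log1p(mu * phi)
        zero_val = np.logaddexp(logp, log1mp + nb0)
        out = np.where(zero_mask, zero_val, out)
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out)
    return out


def _loglik_agg(pc: PeakCounts, p: float, mu: float, phi: float) -> float:
    """ZINB log-likelihood using the zero/non-zero factorization.

    Zero cells contribute n1 * log(p + (1-p) * (1 + mu*phi)^(-1/phi));
    non-zero cells contribute through the aggregated value table.
    """
    return float(zinb_loglik_kernel(pc.n_zero, pc.values, pc.counts,
                                    pc.total, pc._sum_glnv1, pc.n_nonzero,
                                    p, mu, phi))


def zinb_loglik(y, params: ZINBParams) -> float:
    """Log-likelihood of one peak's counts; equals the sum of per-cell
    ``zinb_logpmf`` values but evaluated via the factorized form."""
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)
    return _loglik_agg(pc, params.p, params.mu, params.phi)


@dataclass
class EMFit:
    """Result of the EM initial estimation for one peak."""

    params: ZINBParams | None
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def em_fit(y, tol: float = 1e-8, max_iter: int = 500,
           min_nonzero: int = 3) -> EMFit:
    """EM estimation of (p, mu, phi) for one peak.

    A latent indicator r_i marks whether cell i's zero arose from the point
    mass; the E-step computes its posterior for the zero cells, the M-step
    updates p as the mean responsibility and (mu, phi) by maximizing the
    responsibility-weighted NB likelihood (mu in closed form as the weighted
    mean, phi by bounded 1-D search). Stops when the relative change of the
    observed-data log-likelihood drops below ``tol``.

    Peaks with fewer than ``min_nonzero`` non-zero cells are flagged
    degenerate and carry no parameters.
    """
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)
    if pc.n_nonzero < min_nonzero:
        return EMFit(params=None, loglik=np.nan, n_iter=0, converged=False,
                     degenerate=True)

    # Moment-based initialization.
    ybar = pc.total / pc.n
    s2 = float(np.var(pc.y, ddof=1)) if pc.n > 1 else ybar
    phi = float(np.clip((s2 - ybar) / max(ybar**2, 1e-12), 0.01, PHI_MAX))
    zero_frac = pc.n_zero / pc.n
    nb_zero_mom = float((1.0 + ybar * phi) ** (-1.0 / phi))
    p = max(0.01, zero_frac - nb_zero_mom)
    p = min(p, 1.0 - 1e-6)
    mu = ybar / (1.0 - p)

    trace_buf = np.empty(max_iter + 1)
    p, mu, phi, ll, it, converged = em_kernel(
        pc.n, pc.n_zero, pc.values, pc.counts, pc.total, pc._sum_glnv1,
        pc.n_nonzero, p, mu, phi, tol, max_iter, P_FLOOR, trace_buf)
    trace = trace_buf[:it + 1].tolist()

    params = ZINBParams(p=p, mu=mu, phi=max(phi, PHI_MIN))
    return EMFit(params=params, loglik=ll, n_iter=it, converged=converged,
                 degenerate=False, loglik_trace=trace)


def em_logphi_variance(y, fit: EMFit, h: float = 1e-3) -> float:
    """Delta-method sampling variance of log(phi-hat) from the observed
    information: minus the inverse second derivative of the profile
    log-likelihood in eta = log phi at the EM estimate (p, mu fixed).

    Returns ``nan`` when the numeric curvature is non-negative (flat or
    ill-conditioned peaks); callers should drop such peaks from prior
    hyperparameter estimation.
    """
    if fit.degenerate or fit.params is None:
        return float("nan")
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)
    p, mu = fit.params.p, fit.params.mu
    eta = np.log(fit.params.phi)

    def f(e: float) -> float:
        return _loglik_agg(pc, p, mu, float(np.exp(e)))

    d2 = (f(eta + h) - 2.0 * f(eta) + f(eta - h)) / h**2
    if not np.isfinite(d2) or d2 >= -1e-10:
        return float("nan")
    return float(-1.0 / d2)
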