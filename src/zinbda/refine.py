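"""Iterative re-optimization of the mean and prevalence at the shrunken
dispersion.

After the dispersion is replaced by its empirical-Bayes posterior mode, the
full ZINB likelihood is re-maximized over mu and p by bounded coordinate
updates: per outer iteration, mu is maximized at (p_prev, phi_tilde) and p
is maximized at (mu_prev, phi_tilde) — both conditioning on the previous
iterate (Jacobi-style) — until the relative change of both falls below a
tolerance. Bounds are [0.01, mu_max] x [0.01, p_max], with mu_max and p_max
taken as the maxima of the EM estimates across all peaks in the calling
context (p_max additionally capped at 0.99 to keep the mixture
identifiable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import golden_max_coord
from .model import EMFit, PeakCounts, ZINBParams, _loglik_agg

__all__ = ["MU_LOWER", "P_LOWER", "P_CAP", "RefinedFit", "refine"]

MU_LOWER = 0.01
P_LOWER = 0.01
P_CAP = 0.99
XATOL = 1e-8


@dataclass
class RefinedFit:
    params: ZINBParams | None
    loglik: float
    n_outer_iter: int
    converged: bool


def _max_coord(pc: PeakCounts, mode: int, lo: float, hi: float,
               other: float, phi: float) -> tuple[float, float]:
    """Bounded golden-section maximization of the log-likelihood over one
    coordinate (mode 0: mu, mode 1: p)."""
    x, fx = golden_max_coord(mode, lo, hi, other, phi, pc.n_zero, pc.values,
                             pc.counts, pc.total, pc._sum_glnv1,
                             pc.n_nonzero, XATOL)
    return float(x), float(fx)


def _max_coord_windowed(pc, mode, lo, hi, other, phi, center, width):
    """Golden search restricted to a window around the previous iterate;
    re-runs on the full bounds when the optimum lands on a window edge
    (the window is a speed device, never a constraint)."""
    wlo = max(lo, center - width)
    whi = min(hi, center + width)
    x, fx = _max_coord(pc, mode, wlo, whi, other, phi)
    edge = min(x - wlo, whi - x) < 2.0 * XATOL
    hit_lo = edge and x - wlo < whi - x and wlo > lo
    hit_hi = edge and whi - x <= x - wlo and whi < hi
    if hit_lo or hit_hi:
        return _max_coord(pc, mode, lo, hi, other, phi)
    return x, fx


def refine(y, em: EMFit, phi_tilde: float,
           bounds: tuple[float, float] = (1e3, P_CAP),
           tol: float = 1e-6, max_iter: int = 100) -> RefinedFit:
    """Refined estimates (mu-tilde, p-tilde) at fixed shrunken dispersion.

    Returns the best (highest-likelihood) iterate encountered, which
    guarantees the refined likelihood is never below the likelihood at the
    EM estimates evaluated at phi_tilde.
    """
    if em.degenerate or em.params is None:
        return RefinedFit(params=None, loglik=np.nan, n_outer_iter=0,
                          converged=False)
    if not (phi_tilde > 0):
        raise ValueError("phi_tilde must be positive")
    pc = y if isinstance(y, PeakCounts) else PeakCounts(y)
    mu_max, p_max = bounds
    p_max = min(p_max, P_CAP)
    mu_max = max(mu_max, MU_LOWER)

    mu_prev = float(np.clip(em.params.mu, MU_LOWER, mu_max))
    p_prev = float(np.clip(em.params.p, P_LOWER, p_max))

    best_ll = _loglik_agg(pc, p_prev, mu_prev, phi_tilde)
    best = (mu_prev, p_prev)

    converged = False
    it = 0
    mu_w = p_w = None   # search-window half-widths, set after 2 iterations
    for it in range(1, max_iter + 1):
        if mu_w is None:
            mu_new, _ = _max_coord(pc, 0, MU_LOWER, mu_max, p_prev, phi_tilde)
            p_new, _ = _max_coord(pc, 1, P_LOWER, p_max, mu_prev, phi_tilde)
        else:
            mu_new, _ = _max_coord_windowed(pc, 0, MU_LOWER, mu_max, p_prev,
                                            phi_tilde, mu_prev, mu_w)
            p_new, _ = _max_coord_windowed(pc, 1, P_LOWER, p_max, mu_prev,
                                           phi_tilde, p_prev, p_w)

        ll_new = _loglik_agg(pc, p_new, mu_new, phi_tilde)
        if ll_new > best_ll:
            best_ll, best = ll_new, (mu_new, p_new)
        # Guard the relative-change denominators at the lower bound.
        dmu_abs = abs(mu_prev - mu_new)
        dp_abs = abs(p_prev - p_new)
        dmu = dmu_abs / max(mu_prev, MU_LOWER)
        dp = dp_abs / max(p_prev, P_LOWER)
        if it >= 2:
            mu_w = max(8.0 * dmu_abs, 1e-4)
            p_w = max(8.0 * dp_abs, 1e-4)
        mu_prev, p_prev = mu_new, p_new
        if dmu <= tol and dp <= tol:
            converged = True
            break

    mu_t, p_t = best
    params = ZINBParams(p=p_t, mu=mu_t, phi=phi_tilde)
    return RefinedFit(params=params, loglik=best_ll, n_outer_iter=it,
                      converged=converged)
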