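"""Per-peak differential accessibility tests.

The composite test ("shrunken" method) fits the full estimation pipeline —
EM initial estimation, empirical-Bayes dispersion shrinkage, iterative
refinement of mean and prevalence — three times per peak: on the pooled
cells (the reduced model, H0: identical parameter triples) and on each
group separately (the full model). The likelihood-ratio statistic

    lambda_LR = -2 log( L(H0) / L(Ha) )

is referred to a chi-square distribution with 3 degrees of freedom.

Plain ZINB LRT variants test a chosen subset of {mu, p, phi}: the full
model fits each group by maximum likelihood (EM, no shrinkage or
refinement) and the reduced model shares the tested subset between groups
while the remaining parameters stay group-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .model import (PHI_MAX, PHI_MIN, EMFit, PeakCounts, ZINBParams, em_fit,
                    em_logphi_variance, _loglik_agg)
from .refine import P_CAP, refine
from .shrinkage import ShrinkagePrior, estimate_prior, posterior_mode_phi

logger = logging.getLogger(__name__)

__all__ = [
    "DAResult",
    "FittingContext",
    "build_context",
    "scada_test",
    "zinb_lrt_variant",
    "bh_adjust",
    "call_differential",
    "ZINBDifferentialTest",
    "test_peaks",
]

PARAM_ORDER = ("mu", "p", "phi")
RESULT_COLUMNS = ["peak_id", "lambda_lr", "df", "pvalue", "fdr",
                  "log2fc_mu", "log2fc_p", "log2fc_phi", "status"]


@dataclass
class DAResult:
    """Outcome of one per-peak test."""

    peak_id: object
    lambda_lr: float
    df: int
    pvalue: float
    fdr: float = np.nan
    log2fc_mu: float = np.nan
    log2fc_p: float = np.nan
    log2fc_phi: float = np.nan
    status: str = "tested"   # "tested" or "degenerate"
    params_g1: ZINBParams | None = field(default=None, repr=False)
    params_g2: ZINBParams | None = field(default=None, repr=False)
    params_pooled: ZINBParams | None = field(default=None, repr=False)
    clipped: bool = field(default=False, repr=False)


@dataclass
class FittingContext:
    """Genome-wide quantities shared by all per-peak composite tests.

    Each fitting context (group 1, group 2, pooled) carries its own prior
    hyperparameters (estimated from that context's EM dispersion estimates)
    and its own refinement bounds (maxima of the EM estimates across peaks).
    """

    prior_g1: ShrinkagePrior
    prior_g2: ShrinkagePrior
    prior_pooled: ShrinkagePrior
    bounds_g1: tuple[float, float]
    bounds_g2: tuple[float, float]
    bounds_pooled: tuple[float, float]
    min_nonzero: int = 3


def _prior_and_bounds(pcs, ems, min_peaks=50):
    """Prior hyperparameters and refinement bounds from one context's EM
    fits across all peaks; falls back to a weak default prior on tiny
    peak sets (toy inputs) with a warning."""
    phis, evs, mus, ps = [], [], [], []
    for pc, em in zip(pcs, ems):
        if em.degenerate or em.params is None:
            continue
        phis.append(em.params.phi)
        evs.append(em_logphi_variance(pc, em))
        mus.append(em.params.mu)
        ps.append(em.params.p)
    try:
        prior = estimate_prior(phis, evs, min_peaks=min_peaks)
    except ValueError:
        theta = float(np.median(np.log(phis))) if phis else 0.0
        logger.warning(
            "fewer than %d valid peaks for prior estimation; using weak "
            "default prior (theta=%.3f, sigma=1.0)", min_peaks, theta)
        prior = ShrinkagePrior(theta=theta, sigma=1.0)
    mu_max = max(max(mus, default=1.0), 1.0)
    p_max = min(max(ps, default=P_CAP), P_CAP)
    p_max = max(p_max, 0.02)
    return prior, (mu_max, p_max)


def build_context(pcs_g1, pcs_g2, min_nonzero: int = 3,
                  min_peaks: int = 50):
    """EM fits and a FittingContext from all peaks of a two-group dataset.

    Returns (ctx, ems_g1, ems_g2, ems_pooled); the EM fits are reused by
    the per-peak tests so each peak is EM-fitted only once per context.
    """
    pcs_pool = [PeakCounts.pooled(a, b) for a, b in zip(pcs_g1, pcs_g2)]
    ems_g1 = [em_fit(pc, min_nonzero=min_nonzero) for pc in pcs_g1]
    ems_g2 = [em_fit(pc, min_nonzero=min_nonzero) for pc in pcs_g2]
    ems_pool = [em_fit(pc, min_nonzero=min_nonzero) for pc in pcs_pool]
    prior1, b1 = _prior_and_bounds(pcs_g1, ems_g1, min_peaks)
    prior2, b2 = _prior_and_bounds(pcs_g2, ems_g2, min_peaks)
    priorp, bp = _prior_and_bounds(pcs_pool, ems_pool, min_peaks)
    ctx = FittingContext(prior_g1=prior1, prior_g2=prior2,
                         prior_pooled=priorp, bounds_g1=b1, bounds_g2=b2,
                         bounds_pooled=bp, min_nonzero=min_nonzero)
    return ctx, ems_g1, ems_g2, ems_pool


def _shrunken_fit(pc: PeakCounts, em: EMFit, prior: ShrinkagePrior,
                  bounds) -> tuple[ZINBParams, float]:
    """Full pipeline for one peak in one context: shrink phi, refine
    (mu, p), return final parameters and their log-likelihood."""
    sd = posterior_mode_phi(pc, em.params.p, em.params.mu, prior,
                            phi_init=em.params.phi)
    rf = refine(pc, em, sd.phi_tilde, bounds=bounds)
    return rf.params, rf.loglik


def _degenerate_result(peak_id, df) -> DAResult:
    return DAResult(peak_id=peak_id, lambda_lr=np.nan, df=df,
                    pvalue=np.nan, status="degenerate")


def _log2_ratio(a: float, b: float) -> float:
    if a > 0 and b > 0:
        return float(np.log2(a / b))
    return np.nan


def scada_test(y1, y2, ctx: FittingContext, peak_id=0,
               em1: EMFit | None = None, em2: EMFit | None = None,
               em_pooled: EMFit | None = None) -> DAResult:
    """Composite shrunken LRT for one peak (3 degrees of freedom).

    ``ctx`` supplies the genome-wide prior hyperparameters and refinement
    bounds; precomputed EM fits may be passed to avoid refitting.
    """
    pc1 = y1 if isinstance(y1, PeakCounts) else PeakCounts(y1)
    pc2 = y2 if isinstance(y2, PeakCounts) else PeakCounts(y2)
    if pc1.n_nonzero < ctx.min_nonzero or pc2.n_nonzero < ctx.min_nonzero:
        return _degenerate_result(peak_id, df=3)
    pcp = PeakCounts.pooled(pc1, pc2)
    em1 = em1 or em_fit(pc1, min_nonzero=ctx.min_nonzero)
    em2 = em2 or em_fit(pc2, min_nonzero=ctx.min_nonzero)
    em_pooled = em_pooled or em_fit(pcp, min_nonzero=ctx.min_nonzero)
    if em1.degenerate or em2.degenerate or em_pooled.degenerate:
        return _degenerate_result(peak_id, df=3)

    th1, ll1 = _shrunken_fit(pc1, em1, ctx.prior_g1, ctx.bounds_g1)
    th2, ll2 = _shrunken_fit(pc2, em2, ctx.prior_g2, ctx.bounds_g2)
    th0, _ = _shrunken_fit(pcp, em_pooled, ctx.prior_pooled,
                           ctx.bounds_pooled)
    # L(H0): the pooled parameter triple scored on each group's cells.
    ll0 = (_loglik_agg(pc1, th0.p, th0.mu, th0.phi)
           + _loglik_agg(pc2, th0.p, th0.mu, th0.phi))
    lam = -2.0 * (ll0 - (ll1 + ll2))
    clipped = lam < 0
    if clipped:
        logger.debug("peak %s: negative LRT statistic %.3g clipped to 0",
                     peak_id, lam)
        lam = 0.0
    pval = float(stats.chi2.sf(lam, df=3))
    return DAResult(peak_id=peak_id, lambda_lr=float(lam), df=3,
                    pvalue=pval,
                    log2fc_mu=_log2_ratio(th1.mu, th2.mu),
                    log2fc_p=_log2_ratio(th1.p, th2.p),
                    log2fc_phi=_log2_ratio(th1.phi, th2.phi),
                    params_g1=th1, params_g2=th2, params_pooled=th0,
                    clipped=clipped)


# ---------------------------------------------------------------------------
# Plain ZINB LRT variants (no shrinkage, no refinement)

def _pack(which, shared, free1, free2):
    x = []
    for name in PARAM_ORDER:
        if name in which:
            x.append(shared[name])
        else:
            x.append(free1[name])
            x.append(free2[name])
    return np.array(x, dtype=float)


def _unpack(which, x):
    g1, g2 = {}, {}
    i = 0
    for name in PARAM_ORDER:
        if name in which:
            g1[name] = g2[name] = x[i]
            i += 1
        else:
            g1[name] = x[i]
            g2[name] = x[i + 1]
            i += 2
    return g1, g2


def _to_natural(d):
    return {
        "mu": float(np.exp(d["mu"])),
        "p": float(expit(d["p"])),
        "phi": float(np.clip(np.exp(d["phi"]), PHI_MIN, PHI_MAX)),
    }


def _transform(params: ZINBParams) -> dict:
    p = float(np.clip(params.p, 1e-6, 1 - 1e-6))
    return {"mu": np.log(params.mu), "p": logit(p),
            "phi": np.log(np.clip(params.phi, PHI_MIN, PHI_MAX))}


def _constrained_loglik(pc1, pc2, which, x) -> float:
    d1, d2 = _unpack(which, x)
    n1, n2 = _to_natural(d1), _to_natural(d2)
    return (_loglik_agg(pc1, n1["p"], n1["mu"], n1["phi"])
            + _loglik_agg(pc2, n2["p"], n2["mu"], n2["phi"]))


def _reduced_fit(pc1, pc2, which, em1, em2, em_pooled) -> float:
    """Log-likelihood of the reduced model sharing the tested subset.

    When all three parameters are shared this is the pooled plain fit;
    otherwise the shared/free parameterization is maximized numerically,
    initialized from the pooled and per-group EM estimates.
    """
    if set(which) == set(PARAM_ORDER):
        th = em_pooled.params
        return (_loglik_agg(pc1, th.p, th.mu, th.phi)
                + _loglik_agg(pc2, th.p, th.mu, th.phi))
    shared = _transform(em_pooled.params)
    f1 = _transform(em1.params)
    f2 = _transform(em2.params)
    x0 = _pack(which, shared, f1, f2)

    def nll(x):
        return -_constrained_loglik(pc1, pc2, which, x)

    best_x, best_nll = x0, nll(x0)
    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    if np.isfinite(res.fun) and res.fun < best_nll:
        best_x, best_nll = res.x, res.fun
    # Second start from the group-1 values for the shared block guards
    # against a poor pooled initialization.
    x0b = _pack(which, f1, f1, f2)
    res_b = optimize.minimize(nll, x0b, method="L-BFGS-B")
    if np.isfinite(res_b.fun) and res_b.fun < best_nll:
        best_nll = res_b.fun
    return -best_nll


def zinb_lrt_variant(y1, y2, which=("mu", "p", "phi"), peak_id=0,
                     min_nonzero: int = 3,
                     em1: EMFit | None = None, em2: EMFit | None = None,
                     em_pooled: EMFit | None = None) -> DAResult:
    """Plain ZINB likelihood-ratio test on a subset of {mu, p, phi}.

    The full model fits each group by unpenalized maximum likelihood; the
    reduced model shares the tested parameters between groups. Degrees of
    freedom equal the size of the tested subset.
    """
    which = tuple(w for w in PARAM_ORDER if w in set(which))
    if not which:
        raise ValueError("must test at least one of 'mu', 'p', 'phi'")
    df = len(which)
    pc1 = y1 if isinstance(y1, PeakCounts) else PeakCounts(y1)
    pc2 = y2 if isinstance(y2, PeakCounts) else PeakCounts(y2)
    if pc1.n_nonzero < min_nonzero or pc2.n_nonzero < min_nonzero:
        return _degenerate_result(peak_id, df=df)
    pcp = PeakCounts.pooled(pc1, pc2)
    em1 = em1 or em_fit(pc1, min_nonzero=min_nonzero)
    em2 = em2 or em_fit(pc2, min_nonzero=min_nonzero)
    em_pooled = em_pooled or em_fit(pcp, min_nonzero=min_nonzero)
    if em1.degenerate or em2.degenerate or em_pooled.degenerate:
        return _degenerate_result(peak_id, df=df)

    ll_full = em1.loglik + em2.loglik
    ll_red = _reduced_fit(pc1, pc2, which, em1, em2, em_pooled)
    lam = 2.0 * (ll_full - ll_red)
    clipped = lam < 0
    if clipped:
        logger.debug("peak %s: negative LRT statistic %.3g clipped to 0",
                     peak_id, lam)
        lam = 0.0
    pval = float(stats.chi2.sf(lam, df=df))
    th1, th2 = em1.params, em2.params
    return DAResult(peak_id=peak_id, lambda_lr=float(lam), df=df,
                    pvalue=pval,
                    log2fc_mu=_log2_ratio(th1.mu, th2.mu),
                    log2fc_p=_log2_ratio(th1.p, th2.p),
                    log2fc_phi=_log2_ratio(th1.phi, th2.phi),
                    params_g1=th1, params_g2=th2, clipped=clipped)


# ---------------------------------------------------------------------------
# Multiple testing and calling

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Missing entries (NaN) propagate as NaN and are excluded from the
    ranking denominator.
    """
    pvals = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(pvals)
    if np.any((pvals[mask] < 0) | (pvals[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(pvals.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return out


def call_differential(results: pd.DataFrame, fdr_cut: float = 0.05,
                      lfc_cut: float = 0.5) -> np.ndarray:
    """Differential call: FDR below ``fdr_cut`` and |log2 fold change of the
    mean| above ``lfc_cut``; peaks with missing FDR are never called."""
    fdr = np.asarray(results["fdr"], dtype=float)
    lfc = np.asarray(results["log2fc_mu"], dtype=float)
    with np.errstate(invalid="ignore"):
        return (np.isfinite(fdr) & (fdr < fdr_cut)
                & np.isfinite(lfc) & (np.abs(lfc) > lfc_cut))


def _results_frame(results: list[DAResult]) -> pd.DataFrame:
    df = pd.DataFrame({
        "peak_id": [r.peak_id for r in results],
        "lambda_lr": [r.lambda_lr for r in results],
        "df": [r.df for r in results],
        "pvalue": [r.pvalue for r in results],
        "fdr": np.nan,
        "log2fc_mu": [r.log2fc_mu for r in results],
        "log2fc_p": [r.log2fc_p for r in results],
        "log2fc_phi": [r.log2fc_phi for r in results],
        "status": [r.status for r in results],
    })
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Estimator

_METHODS = ("shrunken", "mu", "p", "mu,p", "mu,phi,p")


class ZINBDifferentialTest(BaseEstimator):
    """Two-group differential accessibility test over a peak matrix.

    Follows the scikit-learn estimator contract: ``fit(X, y)`` takes a
    cells-by-peaks count matrix ``X`` (dense or sparse, non-negative
    integers) and a two-level group label per cell ``y``; per-peak test
    results are exposed in ``results_``.

    Parameters
    ----------
    method : {"shrunken", "mu", "p", "mu,p", "mu,phi,p"}
        "shrunken" (default) is the composite 3-d.f. test with
        empirical-Bayes dispersion shrinkage and mean/prevalence
        refinement. The other options are plain ZINB LRTs on the named
        parameter subset, without shrinkage or refinement.
    min_nonzero : minimum non-zero cells per group for a peak to be tested.
    fdr_threshold, lfc_threshold : calling thresholds used by
        ``differential_`` (BH FDR and |log2 fold change of the mean|).
    n_jobs : parallelism over peaks (joblib); results are independent of
        the worker count.

    Attributes
    ----------
    results_ : DataFrame with one row per peak: peak_id, lambda_lr, df,
        pvalue, fdr, log2fc_mu, log2fc_p, log2fc_phi, status.
    differential_ : boolean array of per-peak differential calls.
    classes_ : the two group labels (group 1 = classes_[0]).
    context_ : FittingContext (shrunken method only).
    n_clipped_ : number of peaks whose LRT statistic was clipped at zero.
    """

    def __init__(self, method: str = "shrunken", min_nonzero: int = 3,
                 fdr_threshold: float = 0.05, lfc_threshold: float = 0.5,
                 n_jobs: int | None = None):
        self.method = method
        self.min_nonzero = min_nonzero
        self.fdr_threshold = fdr_threshold
        self.lfc_threshold = lfc_threshold
        self.n_jobs = n_jobs

    def _validate(self, X, y):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, "
                             f"got {self.method!r}")
        X = check_array(X, accept_sparse="csc", dtype=None,
                        ensure_2d=True)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y carry different numbers of cells")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"exactly two group labels required, got {classes.size}")
        return X, y, classes

    def fit(self, X, y, peak_ids=None):
        X, y, classes = self._validate(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        if peak_ids is None:
            peak_ids = np.arange(X.shape[1])

        from scipy import sparse
        mask1 = y == classes[0]
        X1 = X[mask1]
        X2 = X[~mask1]
        if sparse.issparse(X):
            X1, X2 = X1.tocsc(), X2.tocsc()

        def col(M, j):
            if sparse.issparse(M):
                return np.asarray(M[:, j].todense()).ravel()
            return np.asarray(M[:, j]).ravel()

        pcs1 = [PeakCounts(col(X1, j)) for j in range(X.shape[1])]
        pcs2 = [PeakCounts(col(X2, j)) for j in range(X.shape[1])]

        if self.method == "shrunken":
            ctx, ems1, ems2, emsp = build_context(
                pcs1, pcs2, min_nonzero=self.min_nonzero)
            self.context_ = ctx

            def run(j):
                return scada_test(pcs1[j], pcs2[j], ctx,
                                  peak_id=peak_ids[j], em1=ems1[j],
                                  em2=ems2[j], em_pooled=emsp[j])
        else:
            which = tuple(self.method.split(","))

            def run(j):
                return zinb_lrt_variant(pcs1[j], pcs2[j], which=which,
                                        peak_id=peak_ids[j],
                                        min_nonzero=self.min_nonzero)

        idx = range(X.shape[1])
        if self.n_jobs and self.n_jobs != 1:
            from joblib import Parallel, delayed
            results = Parallel(n_jobs=self.n_jobs)(
                delayed(run)(j) for j in idx)
        else:
            results = [run(j) for j in idx]

        self.n_clipped_ = sum(r.clipped for r in results)
        if self.n_clipped_:
            logger.info("%d of %d peaks had a negative LRT statistic "
                        "clipped at zero", self.n_clipped_, len(results))
        self.results_ = _results_frame(results)
        self.differential_ = call_differential(
            self.results_, self.fdr_threshold, self.lfc_threshold)
        return self

    def fit_predict(self, X, y, peak_ids=None):
        return self.fit(X, y, peak_ids=peak_ids).differential_

    @property
    def pvalues_(self):
        check_is_fitted(self, "results_")
        return self.results_["pvalue"].to_numpy()


def estimate_parameters(counts, min_nonzero: int = 3,
                        min_peaks: int = 50) -> pd.DataFrame:
    """Per-peak parameter estimation for one cell population.

    Runs EM initial estimation on every peak of a peaks-by-cells matrix,
    estimates the dispersion prior genome-wide, and returns EM, shrunken
    and refined estimates in one table.
    """
    from scipy import sparse
    if sparse.issparse(counts):
        counts = counts.tocsr()
        rows = (np.asarray(counts.getrow(i).todense()).ravel()
                for i in range(counts.shape[0]))
    else:
        counts = np.asarray(counts)
        rows = (counts[i] for i in range(counts.shape[0]))
    pcs = [PeakCounts(r) for r in rows]
    ems = [em_fit(pc, min_nonzero=min_nonzero) for pc in pcs]
    prior, bounds = _prior_and_bounds(pcs, ems, min_peaks=min_peaks)
    records = []
    for i, (pc, em) in enumerate(zip(pcs, ems)):
        rec = {"peak_id": i, "degenerate": em.degenerate,
               "em_converged": em.converged,
               "p_em": np.nan, "mu_em": np.nan, "phi_em": np.nan,
               "phi_shrunk": np.nan, "p_refined": np.nan,
               "mu_refined": np.nan, "optim_status": ""}
        if not em.degenerate:
            sd = posterior_mode_phi(pc, em.params.p, em.params.mu, prior,
                                    phi_init=em.params.phi)
            rf = refine(pc, em, sd.phi_tilde, bounds=bounds)
            rec.update(p_em=em.params.p, mu_em=em.params.mu,
                       phi_em=em.params.phi, phi_shrunk=sd.phi_tilde,
                       p_refined=rf.params.p, mu_refined=rf.params.mu,
                       optim_status=sd.optim_status)
        records.append(rec)
    df = pd.DataFrame(records)
    df.attrs["prior_theta"] = prior.theta
    df.attrs["prior_sigma"] = prior.sigma
    return df


def test_peaks(counts, groups, method: str = "shrunken",
               peak_ids=None, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: differential test of a peaks-by-cells matrix.

    ``counts`` has peaks as rows and cells as columns (the field's usual
    orientation); ``groups`` labels each cell with one of two groups.
    """
    est = ZINBDifferentialTest(method=method, **kwargs)
    est.fit(counts.T, np.asarray(groups), peak_ids=peak_ids)
    return est.results_
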