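"""Shared fixtures and independent oracle helpers for the test suite.

The oracles here are written from the model definitions directly (scipy
distributions, naive per-cell sums, hand-rolled step-up rule) so they share
no code with the package's own likelihood/adjustment paths.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def draw_zinb(rng, n, p, mu, phi):
    """Independent ZINB sampler: scipy nbinom with size=1/phi and
    success probability 1/(1+mu*phi), zeroed by a Bernoulli(p) mask."""
    r = 1.0 / phi
    q = 1.0 / (1.0 + mu * phi)
    y = stats.nbinom.rvs(r, q, size=n, random_state=rng)
    y[rng.random(n) < p] = 0
    return y.astype(np.int64)


def naive_zinb_logpmf(y, p, mu, phi):
    """Per-value ZINB log-pmf via scipy.stats.nbinom (independent of the
    package's log-Gamma expansion). Works in log space so deep NB tails
    keep full precision."""
    y = np.asarray(y)
    r = 1.0 / phi
    q = 1.0 / (1.0 + mu * phi)
    log_nb = stats.nbinom.logpmf(y, r, q)
    with np.errstate(divide="ignore"):
        out = np.log1p(-p) + log_nb
        zero_val = np.logaddexp(np.log(p), np.log1p(-p)
                                + stats.nbinom.logpmf(0, r, q))
    return np.where(y == 0, zero_val, out)


def naive_zinb_loglik(y, p, mu, phi):
    """Naive per-cell summed log-likelihood."""
    return float(np.sum(naive_zinb_logpmf(np.asarray(y), p, mu, phi)))


def nb_logpmf_gammaln(y, mu, phi):
    """NB log-pmf assembled term-by-term from log-Gamma functions, written
    separately from the package code path."""
    a = 1.0 / phi
    return (gammaln(y + a) - gammaln(y + 1) - gammaln(a)
            + a * np.log(a / (a + mu)) + y * np.log(mu / (a + mu)))


def bh_stepup(pvals):
    """Hand-rolled Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
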