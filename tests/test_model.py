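"""Unit tests for the ZINB model, likelihood, and EM estimation."""

import numpy as np
import pytest
from scipy import stats

from zinbda import PeakCounts, ZINBParams, em_fit, zinb_loglik, zinb_logpmf
from zinbda.model import P_FLOOR, em_logphi_variance

from conftest import (bh_stepup, draw_zinb, naive_zinb_loglik,
                      naive_zinb_logpmf, nb_logpmf_gammaln)  # noqa: F401


class TestZINBParams:
    def test_valid(self):
        pr = ZINBParams(p=0.3, mu=2.0, phi=0.5)
        assert pr.nb_variance == pytest.approx(2.0 + 4.0 * 0.5)

    @pytest.mark.parametrize("kw", [
        dict(p=-0.1, mu=1, phi=1),
        dict(p=1.1, mu=1, phi=1),
        dict(p=0.5, mu=0.0, phi=1),
        dict(p=0.5, mu=-1, phi=1),
        dict(p=0.5, mu=1, phi=0.0),
        dict(p=0.5, mu=np.inf, phi=1),
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ZINBParams(**kw)


class TestPeakCounts:
    def test_partition(self):
        pc = PeakCounts([0, 0, 1, 3, 0, 2])
        assert pc.n_zero == 3
        assert pc.n_nonzero == 3
        assert pc.n_zero + pc.n_nonzero == len(pc)
        assert pc.total == 6.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            PeakCounts([])
        with pytest.raises(ValueError):
            PeakCounts([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            PeakCounts([1, -1])
        with pytest.raises(ValueError):
            PeakCounts([1.5, 2.0])
        with pytest.raises(ValueError):
            PeakCounts([np.nan, 1.0])


class TestLogpmf:
    def test_closed_form_zero(self):
        # NB(0) = (1+mu*phi)^(-1/phi) = 0.5 at mu=phi=1, so the mixture
        # zero mass is 0.5 + 0.5*0.5 = 0.75.
        params = ZINBParams(p=0.5, mu=1.0, phi=1.0)
        assert np.exp(zinb_logpmf(0, params)) == pytest.approx(0.75, abs=1e-12)

    def test_pure_zero_mass(self):
        params = ZINBParams(p=1.0, mu=3.7, phi=0.2)
        assert np.exp(zinb_logpmf(0, params)) == pytest.approx(1.0, abs=1e-12)

    def test_nonzero_oracle_y7(self):
        # Independent term-by-term log-Gamma evaluation of the NB pmf.
        p, mu, phi = 0.2, 3.4, 0.6
        params = ZINBParams(p=p, mu=mu, phi=phi)
        expected = np.log1p(-p) + nb_logpmf_gammaln(7, mu, phi)
        assert zinb_logpmf(7, params) == pytest.approx(expected, abs=1e-10)
        # And against scipy's nbinom as a second route.
        assert zinb_logpmf(7, params) == pytest.approx(
            naive_zinb_logpmf(7, p, mu, phi), abs=1e-10)

    def test_rejects_bad_y(self):
        params = ZINBParams(p=0.2, mu=1.0, phi=1.0)
        with pytest.raises(ValueError):
            zinb_logpmf(-1, params)
        with pytest.raises(ValueError):
            zinb_logpmf(1.5, params)

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.9])
    @pytest.mark.parametrize("mu", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("phi", [0.05, 1.0, 5.0])
    def test_normalization_grid(self, p, mu, phi):
        params = ZINBParams(p=p, mu=mu, phi=phi)
        # Support cutoff chosen so the NB tail mass is < 1e-10.
        r, q = 1.0 / phi, 1.0 / (1.0 + mu * phi)
        ymax = int(stats.nbinom.ppf(1 - 1e-11, r, q)) + 10
        total = np.exp(zinb_logpmf(np.arange(ymax + 1), params)).sum()
        assert 1.0 - 1e-8 <= total <= 1.0 + 1e-12

    def test_array_shape(self):
        params = ZINBParams(p=0.3, mu=2.0, phi=0.5)
        out = zinb_logpmf(np.array([0, 1, 2]), params)
        assert out.shape == (3,)
        assert np.isscalar(zinb_logpmf(2, params))


class TestLoglik:
    def test_all_zero_p_one(self):
        params = ZINBParams(p=1.0, mu=1.0, phi=1.0)
        assert zinb_loglik(np.zeros(10, dtype=int), params) == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_per_cell_sum(self, rng):
        # Factorized form equals the naive per-cell sum on 50 random
        # instances within 1e-10 (relative to its magnitude).
        for _ in range(50):
            p = rng.uniform(0.0, 0.95)
            mu = rng.uniform(0.1, 20.0)
            phi = rng.uniform(0.05, 5.0)
            y = draw_zinb(rng, 40, p, mu, phi)
            params = ZINBParams(p=p, mu=mu, phi=phi)
            got = zinb_loglik(y, params)
            want = naive_zinb_loglik(y, p, mu, phi)
            assert got == pytest.approx(want, abs=1e-10 * max(1, abs(want)))

    def test_p_zero_reduces_to_nb(self, rng):
        y = draw_zinb(rng, 30, 0.0, 3.0, 0.4)
        params = ZINBParams(p=0.0, mu=3.0, phi=0.4)
        want = float(nb_logpmf_gammaln(y, 3.0, 0.4).sum())
        assert zinb_loglik(y, params) == pytest.approx(want, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zinb_loglik([], ZINBParams(p=0.1, mu=1, phi=1))


class TestEMFit:
    def test_no_zeros_floors_p(self, rng):
        y = draw_zinb(rng, 400, 0.0, 8.0, 0.3)
        y = y[y > 0][:200]
        fit = em_fit(y)
        assert not fit.degenerate
        assert fit.params.p <= 10 * P_FLOOR
        # mu close to a plain NB fit's mean (the sample mean).
        assert fit.params.mu == pytest.approx(float(np.mean(y)), rel=0.05)

    def test_degenerate_flag(self):
        fit = em_fit(np.zeros(50, dtype=int))
        assert fit.degenerate and fit.params is None
        fit = em_fit(np.array([0] * 48 + [1, 2]))
        assert fit.degenerate

    def test_monotone_loglik_trace(self, rng):
        for _ in range(10):
            y = draw_zinb(rng, 150, rng.uniform(0.05, 0.6),
                          rng.uniform(0.5, 8.0), rng.uniform(0.1, 2.0))
            fit = em_fit(y)
            if fit.degenerate:
                continue
            trace = np.asarray(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_recovery_2000_cells(self, rng):
        y = draw_zinb(rng, 2000, 0.3, 5.0, 0.5)
        fit = em_fit(y)
        assert fit.converged
        assert abs(fit.params.p - 0.3) < 0.05
        assert abs(fit.params.mu - 5.0) / 5.0 < 0.10
        assert abs(fit.params.phi - 0.5) / 0.5 < 0.30

    def test_mle_dominates_truth(self, rng):
        # Log-likelihood at the EM solution >= at the generating truth.
        for _ in range(10):
            p, mu, phi = 0.3, 5.0, 0.5
            y = draw_zinb(rng, 500, p, mu, phi)
            fit = em_fit(y)
            ll_true = zinb_loglik(y, ZINBParams(p=p, mu=mu, phi=phi))
            assert fit.loglik >= ll_true - 1e-6

    def test_consistency_over_n(self, rng):
        # Median absolute errors shrink as cells increase.
        p, mu, phi = 0.3, 5.0, 0.5
        med_err = {}
        for n in (100, 500, 2000):
            errs = []
            for _ in range(30):
                y = draw_zinb(rng, n, p, mu, phi)
                fit = em_fit(y)
                if fit.degenerate:
                    continue
                errs.append([abs(fit.params.p - p),
                             abs(fit.params.mu - mu),
                             abs(np.log(fit.params.phi) - np.log(phi))])
            med_err[n] = np.median(np.asarray(errs), axis=0)
        for j in range(3):
            assert med_err[2000][j] <= med_err[100][j]


class TestLogphiVariance:
    def test_positive_on_informative_peak(self, rng):
        y = draw_zinb(rng, 500, 0.2, 5.0, 0.5)
        fit = em_fit(y)
        v = em_logphi_variance(y, fit)
        assert np.isfinite(v) and v > 0

    def test_nan_on_degenerate(self):
        fit = em_fit(np.zeros(20, dtype=int))
        assert np.isnan(em_logphi_variance(np.zeros(20, dtype=int), fit))
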