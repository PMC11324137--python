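"""Unit tests for the differential accessibility tests, BH adjustment and
calling rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zinbda import (SimConfig, ZINBDifferentialTest, bh_adjust,
                    build_context, call_differential, scada_test,
                    simulate_dataset, zinb_lrt_variant)
from zinbda import test_peaks as da_test_peaks
from zinbda.model import PeakCounts

from conftest import bh_stepup, draw_zinb  # noqa: F401


def two_group_dataset(rng, n_peaks=60, n_cells=80):
    """Small null two-group dataset plus its per-group PeakCounts lists."""
    pcs1, pcs2 = [], []
    for _ in range(n_peaks):
        p = rng.uniform(0.05, 0.5)
        mu = rng.uniform(0.5, 6.0)
        phi = float(np.exp(rng.normal(0.0, 0.5)))
        pcs1.append(PeakCounts(draw_zinb(rng, n_cells, p, mu, phi)))
        pcs2.append(PeakCounts(draw_zinb(rng, n_cells, p, mu, phi)))
    return pcs1, pcs2


class TestScadaTest:
    def test_identical_groups(self, rng):
        pcs1, pcs2 = two_group_dataset(rng)
        ctx, e1, e2, ep = build_context(pcs1, pcs2)
        y = draw_zinb(rng, 100, 0.2, 3.0, 0.5)
        res = scada_test(y, y.copy(), ctx)
        # The two groups carry slightly different genome-wide priors, so
        # the statistic is near but not exactly zero.
        assert res.lambda_lr == pytest.approx(0.0, abs=0.1)
        assert res.pvalue == pytest.approx(1.0, abs=0.01)
        assert res.df == 3

    def test_chi2_quantile(self):
        # lambda = 7.8147 is the chi-square(3) upper 5% point.
        assert stats.chi2.sf(7.8147, 3) == pytest.approx(0.05, abs=1e-4)

    def test_degenerate_group(self, rng):
        pcs1, pcs2 = two_group_dataset(rng)
        ctx, *_ = build_context(pcs1, pcs2)
        y1 = draw_zinb(rng, 100, 0.2, 3.0, 0.5)
        y2 = np.zeros(100, dtype=int)
        res = scada_test(y1, y2, ctx)
        assert res.status == "degenerate"
        assert np.isnan(res.pvalue)

    def test_lambda_nonnegative_and_fc_reported(self, rng):
        pcs1, pcs2 = two_group_dataset(rng)
        ctx, e1, e2, ep = build_context(pcs1, pcs2)
        for j in range(0, 20):
            res = scada_test(pcs1[j], pcs2[j], ctx, peak_id=j,
                             em1=e1[j], em2=e2[j], em_pooled=ep[j])
            if res.status != "tested":
                continue
            assert res.lambda_lr >= 0.0
            assert 0.0 <= res.pvalue <= 1.0
            assert np.isfinite(res.log2fc_mu)
            assert np.isfinite(res.log2fc_p)
            assert np.isfinite(res.log2fc_phi)


class TestVariants:
    def test_identical_groups_all_params(self, rng):
        y = draw_zinb(rng, 120, 0.25, 4.0, 0.6)
        res = zinb_lrt_variant(y, y.copy(), which=("mu", "p", "phi"))
        assert res.lambda_lr == pytest.approx(0.0, abs=1e-3)
        assert res.pvalue == pytest.approx(1.0, abs=1e-3)
        assert res.df == 3

    def test_df_matches_subset(self, rng):
        y1 = draw_zinb(rng, 100, 0.2, 3.0, 0.5)
        y2 = draw_zinb(rng, 100, 0.2, 3.0, 0.5)
        assert zinb_lrt_variant(y1, y2, which=("mu",)).df == 1
        assert zinb_lrt_variant(y1, y2, which=("mu", "p")).df == 2
        assert zinb_lrt_variant(y1, y2, which=("p",)).df == 1

    def test_nesting_lambda_nonnegative(self, rng):
        # L(reduced) <= L(full) by construction, so lambda >= 0.
        for _ in range(20):
            y1 = draw_zinb(rng, 80, rng.uniform(0.1, 0.5),
                           rng.uniform(0.5, 5.0), rng.uniform(0.2, 1.5))
            y2 = draw_zinb(rng, 80, rng.uniform(0.1, 0.5),
                           rng.uniform(0.5, 5.0), rng.uniform(0.2, 1.5))
            for which in (("mu",), ("p",), ("mu", "p"), ("mu", "p", "phi")):
                res = zinb_lrt_variant(y1, y2, which=which)
                if res.status == "tested":
                    assert res.lambda_lr >= 0.0

    def test_mu_variant_weak_on_prevalence_shift(self, rng):
        # On data where only p differs strongly, ZINB(mu) rejects less
        # often than ZINB(p) at matched alpha.
        rej_mu, rej_p, n = 0, 0, 0
        for _ in range(40):
            y1 = draw_zinb(rng, 100, 0.10, 3.0, 0.5)
            y2 = draw_zinb(rng, 100, 0.60, 3.0, 0.5)
            rm = zinb_lrt_variant(y1, y2, which=("mu",))
            rp = zinb_lrt_variant(y1, y2, which=("p",))
            if rm.status != "tested" or rp.status != "tested":
                continue
            n += 1
            rej_mu += rm.pvalue < 0.05
            rej_p += rp.pvalue < 0.05
        assert n >= 30
        assert rej_p > rej_mu

    def test_empty_subset_rejected(self, rng):
        y = draw_zinb(rng, 50, 0.2, 2.0, 0.5)
        with pytest.raises(ValueError):
            zinb_lrt_variant(y, y, which=())


class TestBHAdjust:
    def test_hand_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        got = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(got, 0.2)

    def test_single_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 200))
            assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_nan_propagates_and_reduces_m(self):
        p = np.array([0.01, np.nan, 0.02, 0.03, 0.04])
        got = bh_adjust(p)
        assert np.isnan(got[1])
        keep = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got[[0, 2, 3, 4]], bh_stepup(keep))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestCallDifferential:
    def frame(self, fdr, lfc):
        return pd.DataFrame({"fdr": [fdr], "log2fc_mu": [lfc]})

    def test_called(self):
        assert call_differential(self.frame(0.04, 0.6))[0]

    def test_small_lfc_not_called(self):
        assert not call_differential(self.frame(0.04, 0.3))[0]

    def test_missing_fdr_not_called(self):
        assert not call_differential(self.frame(np.nan, 2.0))[0]

    def test_negative_lfc_called(self):
        assert call_differential(self.frame(0.01, -1.2))[0]


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.utils.estimator_checks import check_estimator  # noqa
        est = ZINBDifferentialTest()
        params = est.get_params()
        assert params["method"] == "shrunken"
        est2 = ZINBDifferentialTest(**params)
        assert est2.get_params() == params

    def test_fit_on_simulated_data(self):
        cfg = SimConfig(n_peaks=60, n_cells_per_group=50, scenario="mean",
                        log2fc=2.0, seed=7)
        counts, groups, truth = simulate_dataset(cfg)
        est = ZINBDifferentialTest()
        est.fit(counts.T, groups)
        assert est.results_.shape[0] == 60
        assert set(est.classes_) == {"group1", "group2"}
        assert est.n_features_in_ == 60
        assert est.differential_.dtype == bool
        pv = est.pvalues_
        ok = np.isfinite(pv)
        assert ok.sum() > 30
        assert np.all((pv[ok] >= 0) & (pv[ok] <= 1))

    def test_rejects_bad_labels(self, rng):
        X = rng.integers(0, 5, size=(20, 10))
        est = ZINBDifferentialTest()
        with pytest.raises(ValueError, match="two group"):
            est.fit(X, np.repeat("a", 20))
        with pytest.raises(ValueError):
            est.fit(X, np.array(["a"] * 19))

    def test_rejects_bad_method(self, rng):
        X = rng.integers(0, 5, size=(20, 10))
        y = np.array(["a", "b"] * 10)
        with pytest.raises(ValueError, match="method"):
            ZINBDifferentialTest(method="bogus").fit(X, y)

    def test_parallel_matches_serial(self):
        cfg = SimConfig(n_peaks=30, n_cells_per_group=40, scenario="mean",
                        log2fc=1.5, seed=11)
        counts, groups, _ = simulate_dataset(cfg)
        r1 = da_test_peaks(counts, groups, method="mu")
        r2 = da_test_peaks(counts, groups, method="mu", n_jobs=2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sparse_input(self):
        from scipy import sparse
        cfg = SimConfig(n_peaks=25, n_cells_per_group=40, scenario="mean",
                        log2fc=1.0, seed=13)
        counts, groups, _ = simulate_dataset(cfg)
        dense = da_test_peaks(counts, groups, method="mu")
        sp = da_test_peaks(sparse.csr_matrix(counts), groups, method="mu")
        pd.testing.assert_frame_equal(dense, sp)
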