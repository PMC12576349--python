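"""Phi-K, IRLS logistic regression and decile curves."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit
from scipy.stats import spearmanr

from cserisk import decile_curve, fit_logistic, phik, phik_from_table
from cserisk.association import bvn_cdf
from cserisk.errors import InputError, SeparationError
from tests._oracles import newton_logistic, phik_grid_scan


def planted_table(n=2000, beta0=-3.0, beta1=0.05, seed=17, n_bins=10):
    """2 x n_bins contingency table from a planted logistic model on ADI."""
    rng = np.random.default_rng(seed)
    adi = rng.integers(1, 101, size=n)
    y = rng.random(n) < expit(beta0 + beta1 * adi)
    table = np.zeros((2, n_bins))
    np.add.at(table, (y.astype(int), (adi - 1) // n_bins), 1.0)
    return table


class TestBvnCdf:
    @pytest.mark.parametrize("h,k,rho", [(0.0, 0.0, 0.5), (1.0, -0.5, 0.3), (-1.2, 0.7, -0.6), (2.0, 2.0, 0.9)])
    def test_against_scipy_multivariate_normal(self, h, k, rho):
        ref = stats.multivariate_normal.cdf([h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        assert bvn_cdf(h, k, rho) == pytest.approx(float(ref), abs=1e-7)

    def test_closed_form_at_origin(self):
        # Phi2(0, 0, rho) = 1/4 + asin(rho) / (2 pi)
        for rho in (-0.8, 0.0, 0.25, 0.99):
            assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-10)

    def test_infinite_limits(self):
        assert bvn_cdf(np.inf, 0.3, 0.5) == pytest.approx(stats.norm.cdf(0.3))
        assert bvn_cdf(-np.inf, 0.3, 0.5) == 0.0
        assert bvn_cdf(np.inf, np.inf, 0.5) == 1.0


class TestPhik:
    def test_independent_table_gives_zero(self):
        # exact outer product of margins: chi2 = 0, below the pedestal
        table = np.outer([40, 60], [10, 20, 30, 40])
        assert phik_from_table(table) == 0.0

    def test_diagonal_table_gives_one(self):
        assert phik_from_table(np.array([[50, 0], [0, 50]])) == 1.0

    def test_matches_grid_scan_oracle_on_planted_table(self):
        table = planted_table(seed=17)
        assert phik_from_table(table) == pytest.approx(phik_grid_scan(table), abs=1e-6)

    def test_matches_oracle_on_2x2(self):
        table = np.array([[30.0, 10.0], [12.0, 28.0]])
        assert phik_from_table(table) == pytest.approx(phik_grid_scan(table), abs=1e-6)

    def test_invariant_under_outcome_relabeling(self):
        rng = np.random.default_rng(4)
        adi = rng.integers(1, 101, size=800)
        y = (rng.random(800) < expit(-2 + 0.04 * adi)).astype(int)
        assert phik(y, adi) == pytest.approx(phik(1 - y, adi), abs=1e-9)

    def test_invariant_under_bin_preserving_transform(self):
        rng = np.random.default_rng(5)
        adi = rng.integers(1, 101, size=800)
        y = (rng.random(800) < expit(-2 + 0.04 * adi)).astype(int)
        # jitter within the decile preserves bin membership
        jittered = ((adi - 1) // 10) * 10 + rng.integers(1, 11, size=800)
        assert phik(y, adi) == pytest.approx(phik(y, jittered), abs=1e-9)

    def test_degenerate_margin_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert phik(np.zeros(50, dtype=int), np.arange(1, 51)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            phik([0, 1], [1, 2, 3])


class TestFitLogistic:
    def test_null_model_no_association(self):
        rng = np.random.default_rng(6)
        x = rng.integers(1, 101, size=10_000).astype(float)
        y = (rng.random(10_000) < 0.5).astype(int)
        fit = fit_logistic(x, y)
        assert abs(fit.beta1) < 3 * fit.se1

    def test_planted_slope_recovery(self):
        rng = np.random.default_rng(11)
        n = 20_000
        x = rng.integers(1, 101, size=n).astype(float)
        y = (rng.random(n) < expit(-3 + 0.05 * x)).astype(int)
        fit = fit_logistic(x, y)
        assert fit.beta1 == pytest.approx(0.05, abs=0.005)
        assert abs(fit.beta1 - 0.05) < 3 * fit.se1

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.integers(1, 101, size=3_000).astype(float)
        y = (rng.random(3_000) < expit(-1.5 + 0.03 * x)).astype(int)
        fit = fit_logistic(x, y)
        params, bse = newton_logistic(x, y)
        np.testing.assert_allclose([fit.beta0, fit.beta1], params, atol=1e-6)
        np.testing.assert_allclose([fit.se0, fit.se1], bse, atol=1e-6)
        np.testing.assert_allclose(fit.predict_proba(x), expit(params[0] + params[1] * x), atol=1e-6)

    def test_complete_separation_raises(self):
        x = np.arange(1, 101, dtype=float)
        y = (x > 50).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            fit_logistic(np.arange(10, dtype=float), np.zeros(10, dtype=int))

    def test_positive_planted_slope_recovered_positive_across_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.integers(1, 101, size=20_000).astype(float)
            y = (rng.random(20_000) < expit(-3 + 0.05 * x)).astype(int)
            assert fit_logistic(x, y).beta1 > 0


class TestDecileCurve:
    def test_single_occupied_bin_matches_population_risk(self):
        adi = np.full(40, 15)
        flags = np.r_[np.ones(10, bool), np.zeros(30, bool)]
        dc = decile_curve(adi, flags)
        assert dc.loc[1, "pct_at_risk"] == 25.0
        assert dc.drop(index=1)["pct_at_risk"].isna().all()
        assert dc["n"].sum() == 40

    def test_all_flagged_gives_100_in_occupied_bins(self):
        rng = np.random.default_rng(0)
        adi = rng.integers(1, 101, size=300)
        dc = decile_curve(adi, np.ones(300, bool))
        occupied = dc[dc["n"] > 0]
        assert (occupied["pct_at_risk"] == 100.0).all()

    def test_out_of_range_adi_rejected(self):
        with pytest.raises(InputError):
            decile_curve([0, 50], [True, False])

    def test_planted_gradient_gives_increasing_curve(self):
        rng = np.random.default_rng(9)
        adi = rng.integers(1, 101, size=4_000)
        flags = rng.random(4_000) < expit(-3 + 0.05 * adi)
        dc = decile_curve(adi, flags).dropna(subset=["pct_at_risk"])
        assert spearmanr(dc["decile"], dc["pct_at_risk"]).statistic > 0
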