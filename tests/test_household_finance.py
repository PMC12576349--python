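"""Income imputation and subsistence arithmetic."""

import numpy as np
import pandas as pd
import pytest

from cserisk import IncomeDrawConfig, PovertyGuideline, compute_profiles, draw_income, moe_to_sd, population_summary
from cserisk.errors import InputError, LinkageError
from tests.conftest import make_profiles_from_nse


def bg_frame(income=30_000.0, moe=0.0, rent=1_000.0, food=8_000.0, bg_id="g"):
    return pd.DataFrame(
        {
            "bg_id": [bg_id],
            "adi": [50],
            "income_median": [income],
            "income_moe": [moe],
            "rent_monthly_median": [rent],
            "food_annual": [food],
        }
    )


def hh_frame(size=2, bg_id="g", n=1):
    return pd.DataFrame(
        {"hh_id": [f"h{i}" for i in range(n)], "bg_id": [bg_id] * n, "size": [size] * n, "insured": [False] * n}
    )


class TestMoeToSd:
    @pytest.mark.parametrize("moe,expected", [(0.0, 0.0), (1645.0, 1000.0), (3290.0, 2000.0)])
    def test_acs_convention(self, moe, expected):
        assert moe_to_sd(moe) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            moe_to_sd(-1.0)


class TestDrawIncome:
    def test_degenerate_interval_returns_median(self):
        rng = np.random.default_rng(0)
        assert draw_income(30_000.0, 0.0, 2, rng) == pytest.approx(30_000.0)

    def test_draws_bounded_and_centered(self):
        # uniform on [m - s, m + s]: all draws inside, mean near m
        rng = np.random.default_rng(1)
        m, s, n = 30_000.0, 5_000.0, 10_000
        cfg = IncomeDrawConfig(moe_convention="sd", size_adjust=False)
        draws = draw_income(np.full(n, m), np.full(n, s), np.full(n, 2), rng, cfg)
        assert draws.min() >= m - s and draws.max() <= m + s
        se = s / np.sqrt(3) / np.sqrt(n)
        assert abs(draws.mean() - m) < 3 * se

    def test_equivalence_scale_evaluation(self):
        # base draw 30000, size 4, beta 0.56 -> 30000 * 2**0.56
        rng = np.random.default_rng(0)
        got = draw_income(30_000.0, 0.0, 4, rng)
        assert got == pytest.approx(30_000.0 * 2.0**0.56)
        assert got == pytest.approx(44_228.08, abs=0.01)

    def test_monotone_in_size_for_same_base_draw(self):
        rng = np.random.default_rng(0)
        incomes = [draw_income(30_000.0, 0.0, s, rng) for s in range(1, 16)]
        assert np.all(np.diff(incomes) > 0)

    def test_truncated_normal_option_respects_bounds(self):
        rng = np.random.default_rng(2)
        cfg = IncomeDrawConfig(distribution="truncated_normal", moe_convention="sd", size_adjust=False)
        draws = draw_income(np.full(2000, 30_000.0), np.full(2000, 5_000.0), np.full(2000, 2), rng, cfg)
        assert draws.min() >= 25_000.0 and draws.max() <= 35_000.0


class TestComputeProfiles:
    def test_subsistence_and_nse_arithmetic(self):
        rng = np.random.default_rng(0)
        prof = compute_profiles(hh_frame(), bg_frame(income=27_043.50), PovertyGuideline(), rng)
        assert prof.loc[0, "subsistence_annual"] == pytest.approx(20_000.0)
        assert prof.loc[0, "nse"] == pytest.approx(7_043.50)

    def test_negative_nse_is_legal(self):
        rng = np.random.default_rng(0)
        prof = compute_profiles(hh_frame(), bg_frame(income=10_000.0, rent=313.25, food=8_000.0), PovertyGuideline(), rng)
        assert prof.loc[0, "nse"] == pytest.approx(-1_759.0)

    def test_poverty_flag_2018_guideline(self):
        # size 2 threshold = 12140 + 4320 = 16460; income 15000 is below
        rng = np.random.default_rng(0)
        prof = compute_profiles(hh_frame(size=2), bg_frame(income=15_000.0), PovertyGuideline(), rng)
        assert bool(prof.loc[0, "below_poverty"])
        prof2 = compute_profiles(hh_frame(size=2), bg_frame(income=17_000.0), PovertyGuideline(), rng)
        assert not bool(prof2.loc[0, "below_poverty"])

    def test_unknown_blockgroup_raises_linkage_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(LinkageError):
            compute_profiles(hh_frame(bg_id="missing"), bg_frame(), PovertyGuideline(), rng)

    def test_nse_identity_and_determinism_with_zero_moe(self):
        hh = pd.concat([hh_frame(size=s, n=3) for s in (1, 2, 5)], ignore_index=True)
        hh["hh_id"] = [f"h{i}" for i in range(len(hh))]
        p1 = compute_profiles(hh, bg_frame(), PovertyGuideline(), np.random.default_rng(1))
        p2 = compute_profiles(hh, bg_frame(), PovertyGuideline(), np.random.default_rng(99))
        # moe 0 -> deterministic regardless of rng state
        pd.testing.assert_frame_equal(p1, p2)
        np.testing.assert_array_equal(
            p1["nse"].to_numpy() + p1["subsistence_annual"].to_numpy(), p1["income_annual"].to_numpy()
        )


def test_poverty_threshold_nondecreasing_in_size():
    g = PovertyGuideline()
    thresholds = g.threshold(np.arange(1, 16))
    assert np.all(np.diff(thresholds) > 0)


class TestPopulationSummary:
    def test_median_and_mean_of_small_set(self):
        s = population_summary(make_profiles_from_nse([10.0, 20.0, 30.0]))
        assert s.loc["nse", "median"] == 20.0
        assert s.loc["nse", "mean"] == 20.0

    def test_poverty_percentage_rounding(self):
        prof = make_profiles_from_nse(np.arange(758, dtype=float))
        prof["below_poverty"] = np.arange(758) < 314
        s = population_summary(prof)
        assert s.attrs["below_poverty_n"] == 314
        assert s.attrs["below_poverty_pct"] == 41.42

    def test_iqr_identity(self):
        nse = [16_864.0, 16_864.0, 27_043.5, 38_955.75, 38_955.75]
        s = population_summary(make_profiles_from_nse(nse))
        assert s.loc["nse", "q25"] == pytest.approx(16_864.0)
        assert s.loc["nse", "q75"] == pytest.approx(38_955.75)
        assert s.attrs["nse_iqr"] == pytest.approx(22_091.75)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            population_summary(make_profiles_from_nse([]))
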