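import numpy as np
import pytest
from scipy import stats

import ringanchor as ra
from ringanchor.chisq import pad_ring_window
from ringanchor.errors import CoverageError


@pytest.fixture
def flat_reference():
    years = np.arange(980, 1041)
    return ra.AnnualReference(years, np.full(years.shape, 1050.0), np.full(years.shape, 8.0))


class TestChi2Quantile:
    def test_six_ring_critical_value(self):
        assert ra.chi2_quantile(0.95, 5) == pytest.approx(11.07, abs=0.005)

    def test_one_dof_is_squared_normal_quantile(self):
        assert ra.chi2_quantile(0.95, 1) == pytest.approx(1.96**2, abs=0.01)

    @pytest.mark.parametrize("level,dof", [(0.5, 1), (0.95, 5), (0.99, 12)])
    def test_quantile_cdf_round_trip(self, level, dof):
        assert stats.chi2.cdf(ra.chi2_quantile(level, dof), dof) == pytest.approx(
            level, abs=1e-10
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ra.chi2_quantile(1.5, 5)
        with pytest.raises(ValueError):
            ra.chi2_quantile(0.95, 0)


class TestChiSquare:
    def test_zero_at_perfect_match(self, spike_reference, series_factory):
        x = 1021
        rings = np.arange(-31, -25)
        ages, _ = spike_reference.at(x + rings)
        series = series_factory("X", rings, ages, np.full(6, 12.0))
        assert ra.chi_square(series, spike_reference, x) == pytest.approx(0.0)

    def test_uniform_k_sigma_residuals(self, series_factory):
        # residual k * combined sigma per ring over n = 6 rings -> chi2 = 6 k^2
        years = np.arange(1000, 1011)
        tiny = 1e-6
        ref = ra.AnnualReference(years, np.full(11, 1000.0), np.full(11, tiny))
        k = 2.5
        series = series_factory(
            "X", np.arange(-5, 1), np.full(6, 1000.0 + k * 4.0), np.full(6, 4.0)
        )
        chi2 = ra.chi_square(series, ref, 1008)
        assert chi2 == pytest.approx(6 * k**2, rel=1e-9)

    def test_three_ring_hand_oracle(self, series_factory):
        years = np.arange(990, 996)
        ref = ra.AnnualReference(years, [1060.0, 1058, 990, 995, 999, 1002], np.full(6, 8.0))
        series = series_factory("X", [-2, -1, 0], [1055.0, 1000.0, 990.0], [10.0, 12.0, 9.0])
        x = 993
        # independent term-by-term sum: rings grew in 991, 992, 993
        expected = (
            (1055.0 - 1058.0) ** 2 / (10.0**2 + 8.0**2)
            + (1000.0 - 990.0) ** 2 / (12.0**2 + 8.0**2)
            + (990.0 - 995.0) ** 2 / (9.0**2 + 8.0**2)
        )
        assert ra.chi_square(series, ref, x) == pytest.approx(expected, rel=1e-12)

    def test_coverage_error_lists_rings(self, flat_reference, series_factory):
        series = series_factory("X", [-50, 0], [1050.0, 1050.0], [10.0, 10.0])
        with pytest.raises(CoverageError, match="-50"):
            ra.chi_square(series, flat_reference, 1020)


class TestChiSquareProfile:
    def test_profile_equals_per_year_evaluation(self, spike_reference, series_factory):
        rng = np.random.default_rng(8)
        rings = np.arange(-31, -25)
        ages, _ = spike_reference.at(1021 + rings)
        series = series_factory("X", rings, ages + rng.normal(0, 12, 6), np.full(6, 12.0))
        profile = ra.chi_square_profile(series, spike_reference, (1016, 1026))
        for year, value in zip(profile.trial_years, profile.chi2):
            assert value == pytest.approx(
                ra.chi_square(series, spike_reference, int(year)), rel=1e-12
            )
        assert profile.chi2[profile.trial_years == profile.best_year][0] == min(profile.chi2)
        assert profile.dof == 5
        assert profile.critical == pytest.approx(11.07, abs=0.005)
        assert set(profile.accepted) <= set(profile.trial_years.tolist())

    def test_zero_noise_accepts_only_truth(self, spike_reference, series_factory):
        truth = 1021
        rings = np.arange(-31, -25)
        ages, _ = spike_reference.at(truth + rings)
        series = series_factory("X", rings, ages, np.full(6, 1e-6))
        profile = ra.chi_square_profile(series, spike_reference, (1016, 1026))
        assert profile.best_year == truth
        assert profile.accepted == (truth,)
        assert not profile.tied

    def test_flat_data_ties_flagged_earliest_reported(self, flat_reference, series_factory):
        series = series_factory("X", np.arange(-5, 1), np.full(6, 1050.0), np.full(6, 10.0))
        profile = ra.chi_square_profile(series, flat_reference, (1010, 1020))
        assert profile.tied
        assert profile.best_year == 1010
        assert len(profile.accepted) == 11

    def test_ring_window_subset(self, spike_reference, series_factory):
        rings = np.arange(-40, 1)
        ages, _ = spike_reference.at(1021 + rings)
        series = series_factory("X", rings, ages, np.full(41, 12.0))
        profile = ra.chi_square_profile(
            series, spike_reference, (1016, 1026), rings=(-31, -26)
        )
        assert profile.n_rings == 6 and profile.dof == 5

    def test_too_few_rings_rejected(self, flat_reference, series_factory):
        series = series_factory("X", [0], [1050.0], [10.0])
        with pytest.raises(ValueError, match="at least 2"):
            ra.chi_square_profile(series, flat_reference, (1010, 1020))


class TestRingArithmetic:
    def test_event_window_from_stage1_interval(self):
        assert ra.anomaly_ring_window((1019, 1024), 993) == (-31, -26)

    @pytest.mark.parametrize(
        "interval, event, expected",
        [((1000, 1000), 993, (-7, -7)), ((994, 995), 993, (-2, -1))],
    )
    def test_window_arithmetic(self, interval, event, expected):
        assert ra.anomaly_ring_window(interval, event) == expected

    def test_event_after_felling_rejected(self):
        with pytest.raises(ValueError, match="event"):
            ra.anomaly_ring_window((990, 995), 993)

    @pytest.mark.parametrize(
        "ring, event, felling",
        [(-28, 993, 1021), (0, 993, 993), (-29, 992, 1021)],
    )
    def test_date_waney_edge(self, ring, event, felling):
        assert ra.date_waney_edge(ring, event) == felling

    def test_window_and_dating_mutually_consistent(self):
        event = 993
        interval = (1019, 1024)
        lo, hi = ra.anomaly_ring_window(interval, event)
        for waney in range(interval[0], interval[1] + 1):
            ring = event - waney
            assert lo <= ring <= hi
            assert ra.date_waney_edge(ring, event) == waney


class TestPadRingWindow:
    def test_narrow_window_padded_to_six_straddling(self):
        padded = pad_ring_window((-28, -28), 6, (-44, 0))
        assert padded[1] - padded[0] + 1 == 6
        assert padded[0] < -28 < padded[1]

    def test_wide_window_unchanged(self):
        assert pad_ring_window((-31, -26), 6, (-44, 0)) == (-31, -26)

    def test_clipped_to_span(self):
        assert pad_ring_window((-10, -5), 6, (-7, 0)) == (-7, -2)

    def test_window_outside_span_is_none(self):
        assert pad_ring_window((-30, -20), 6, (-8, 0)) is None
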