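import numpy as np
import pytest

import ringanchor as ra
from ringanchor.wigglematch import hpd


def brute_force_wiggle(series, curve, years):
    """Independent linear-space evaluation of the wiggle-match posterior."""
    p = np.empty(len(years), dtype=float)
    for j, x in enumerate(years):
        acc = 1.0
        for r, age, sigma in zip(series.ring_index, series.age, series.sigma):
            mu, sc = curve.at(x + r)
            var = sigma**2 + sc**2
            acc *= np.exp(-((age - mu) ** 2) / (2 * var))
        p[j] = acc
    return p / p.sum()


class TestHPD:
    def test_point_mass(self):
        intervals = hpd([1000, 1001, 1002], [0.0, 1.0, 0.0], 0.95)
        assert intervals == ((1001, 1001),)

    def test_hand_built_density_level_80(self):
        # descending masses: top three years reach 0.85 >= 0.8
        intervals = hpd([1, 2, 3, 4, 5], [0.4, 0.3, 0.15, 0.1, 0.05], 0.8)
        assert intervals == ((1, 3),)

    def test_symmetric_gaussian_interval_symmetric_about_mode(self):
        years = np.arange(980, 1021)
        p = np.exp(-0.5 * ((years - 1000) / 4.0) ** 2)
        p /= p.sum()
        (lo, hi), = hpd(years, p, 0.95)
        # symmetric up to the one-cell asymmetry of the earlier-year tie-break
        assert abs((lo + hi) - 2000) <= 1

    def test_tie_broken_toward_earlier_year(self):
        # years 1 and 2 tie at 0.25; the earlier year is taken first
        intervals = hpd([1, 2, 3], [0.25, 0.25, 0.5], 0.7)
        assert intervals == ((1, 1), (3, 3))

    def test_mass_between_level_and_level_plus_one_cell(self):
        years = np.arange(50)
        p = np.full(50, 1 / 50)
        (lo, hi), = hpd(years, p, 0.95)
        mass = (hi - lo + 1) / 50
        assert 0.95 <= mass <= 0.95 + 1 / 50 + 1e-12


class TestCalibrate:
    def test_constant_curve_gives_uniform_posterior(self):
        grid = np.arange(1000, 1021)
        curve = ra.CalCurve(grid, np.full(21, 1000.0), np.full(21, 5.0))
        density = ra.calibrate(1000.0, 10.0, curve)
        np.testing.assert_allclose(density.p, 1 / 21, rtol=1e-12)
        assert any("flat-posterior" in w for w in density.warnings)

    def test_linear_curve_gaussian_in_theta(self, linear_curve):
        # C(theta) = 2000 - theta: date 1000+-8 calibrates to theta = 1000
        density = ra.calibrate(1000.0, 8.0, linear_curve)
        assert density.mode == 1000
        sigma_comb = np.sqrt(8.0**2 + 10.0**2)
        expected = np.exp(-0.5 * ((density.years - 1000.0) / sigma_comb) ** 2)
        np.testing.assert_allclose(density.p, expected / expected.sum(), rtol=1e-9)

    def test_matches_direct_formula_on_toy_curve(self):
        curve = ra.CalCurve([1000, 1001, 1002], [980.0, 996.0, 1004.0], [6.0, 8.0, 5.0])
        density = ra.calibrate(995.0, 7.0, curve)
        expected = np.exp(
            -((995.0 - curve.age) ** 2) / (2 * (7.0**2 + curve.sigma**2))
        )
        np.testing.assert_allclose(density.p, expected / expected.sum(), rtol=1e-12)

    def test_out_of_range_warning(self, linear_curve):
        density = ra.calibrate(5000.0, 10.0, linear_curve)
        assert any("out-of-range" in w for w in density.warnings)


class TestWiggleMatch:
    def test_single_ring_equals_shifted_calibration(self, linear_curve, series_factory):
        series = series_factory("X", [-5], [1000.0], [8.0])
        joint = ra.wiggle_match(series, linear_curve)
        single = ra.calibrate(1000.0, 8.0, linear_curve)
        # ring -5 grew in year x - 5: posterior for x is calibrate shifted +5
        np.testing.assert_allclose(joint.p, single.p[: len(joint.p)], rtol=1e-9)
        assert joint.mode == single.mode + 5

    def test_zero_noise_spike_series_pins_true_year(self, spike_reference):
        tree = ra.TreeScenario(noise_sigma=0.0, seed=5)
        measurements, truth = ra.sample_tree(tree, spike_reference)
        series = ra.series_from_measurements(measurements)[tree.item_id]
        density = ra.wiggle_match(series, spike_reference.to_curve())
        assert density.mode == truth.felling_year
        assert density.p[density.years == truth.felling_year][0] > 0.999

    def test_matches_brute_force_product(self, linear_curve, series_factory):
        rng = np.random.default_rng(99)
        rings = [-8, -5, -4, -1, 0]
        ages = [2000.0 - (1010 + r) + rng.normal(0, 5) for r in rings]
        series = series_factory("X", rings, ages, [6.0] * 5)
        density = ra.wiggle_match(series, linear_curve, trial=(990, 1030))
        expected = brute_force_wiggle(series, linear_curve, density.years)
        np.testing.assert_allclose(density.p, expected, rtol=1e-9)

    def test_translation_invariance(self, series_factory):
        grid = np.arange(900, 1101)
        rng = np.random.default_rng(3)
        age = 1100 - 0.8 * (grid - 900) + np.cumsum(rng.normal(0, 2, grid.size))
        sigma = np.full(grid.size, 9.0)
        series = series_factory(
            "X", [-10, -6, -2, 0], [1030.0, 1027.0, 1019.0, 1015.0], [10.0] * 4
        )
        k = 37
        base = ra.wiggle_match(series, ra.CalCurve(grid, age, sigma))
        shifted = ra.wiggle_match(series, ra.CalCurve(grid + k, age, sigma))
        assert shifted.mode == base.mode + k
        np.testing.assert_allclose(shifted.p, base.p, rtol=1e-9)

    def test_more_rings_never_widen_hpd_on_clean_data(self, spike_reference):
        tree = ra.TreeScenario(noise_sigma=0.0, seed=1, n_rings=40)
        measurements, _ = ra.sample_tree(tree, spike_reference)
        series = ra.series_from_measurements(measurements)[tree.item_id]
        curve = spike_reference.to_curve()
        widths = []
        for n in (5, 10, 20, 40):
            keep = series.ring_index >= -(n - 1)
            sub = ra.RingSeries(
                "X", series.ring_index[keep], series.age[keep], series.sigma[keep]
            )
            lo, hi = ra.wiggle_match(sub, curve).bounding_interval()
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True) or all(
            a >= b for a, b in zip(widths, widths[1:])
        )


class TestSumDensities:
    def _point(self, year):
        return ra.PosteriorDensity([year], [1.0], hpd95=((year, year),))

    def test_sum_of_identical_densities_is_identity(self, linear_curve):
        d = ra.calibrate(1000.0, 8.0, linear_curve)
        total = ra.sum_densities([d, d, d])
        np.testing.assert_allclose(total.p, d.p, rtol=1e-12)

    def test_two_disjoint_point_masses_split_evenly(self):
        total = ra.sum_densities([self._point(1000), self._point(1010)])
        assert total.p[total.years == 1000][0] == pytest.approx(0.5)
        assert total.p[total.years == 1010][0] == pytest.approx(0.5)
        assert any("disjoint" in w for w in total.warnings)

    def test_matches_brute_force_average(self, linear_curve):
        dates = [(1000.0, 8.0), (1012.0, 10.0), (995.0, 12.0)]
        densities = [ra.calibrate(a, s, linear_curve) for a, s in dates]
        total = ra.sum_densities(densities)
        expected = np.mean([d.p for d in densities], axis=0)
        np.testing.assert_allclose(total.p, expected / expected.sum(), rtol=1e-12)
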