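"""Hellinger distance / ToR statistics and the two-Gaussian mixture."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mqpi.heterogeneity import (KDEParams, control_threshold,
                                fit_mixture_sequence, fit_two_gaussians,
                                hellinger_distance, hellinger_from_samples,
                                kde_density, time_of_response)
from mqpi.synthetic_data import sample_sgr_mixture


def _gauss(grid, mu, sd):
    d = np.exp(-0.5 * ((grid - mu) / sd) ** 2)
    return d / np.trapezoid(d, grid)


class TestHellinger:
    def test_identical_densities_zero(self):
        grid = np.linspace(-5, 5, 400)
        p = _gauss(grid, 0, 1)
        assert hellinger_distance(p, p, grid) == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_supports_one(self):
        grid = np.linspace(0, 10, 1000)
        p = np.where(grid < 4, 1.0, 0.0)
        q = np.where(grid > 6, 1.0, 0.0)
        p /= np.trapezoid(p, grid)
        q /= np.trapezoid(q, grid)
        assert hellinger_distance(p, q, grid) == pytest.approx(1.0, abs=1e-6)

    def test_equal_variance_gaussian_closed_form(self):
        """H = sqrt(1 - exp(-d^2 / (8 sigma^2))); means 0,2 -> 0.62727."""
        grid = np.linspace(-8, 10, 4000)
        h = hellinger_distance(_gauss(grid, 0, 1), _gauss(grid, 2, 1), grid)
        assert h == pytest.approx(np.sqrt(1 - np.exp(-0.5)), abs=1e-6)
        assert h == pytest.approx(0.62727, abs=1e-4)

    @given(st.integers(0, 1000))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.linspace(-3, 3, 200)
        p = rng.random(200) + 1e-6
        q = rng.random(200) + 1e-6
        p /= np.trapezoid(p, grid)
        q /= np.trapezoid(q, grid)
        h_pq = hellinger_distance(p, q, grid)
        assert h_pq == pytest.approx(hellinger_distance(q, p, grid))
        assert 0.0 <= h_pq <= 1.0

    def test_triangle_inequality_spot(self):
        grid = np.linspace(-6, 8, 2000)
        p, q, r = (_gauss(grid, m, 1) for m in (0.0, 1.0, 2.5))
        assert hellinger_distance(p, r, grid) <= \
            hellinger_distance(p, q, grid) + hellinger_distance(q, r, grid) + 1e-9

    def test_unnormalized_renormalized_with_warning(self, caplog):
        grid = np.linspace(-5, 5, 500)
        p = _gauss(grid, 0, 1)
        with caplog.at_level("WARNING", logger="mqpi.heterogeneity"):
            h = hellinger_distance(2.0 * p, p, grid)
        assert h == pytest.approx(0.0, abs=1e-8)
        assert "renormalizing" in caplog.text


class TestKDE:
    def test_normalized_to_one(self, rng):
        grid, dens = kde_density(rng.normal(0, 0.01, 500),
                                 KDEParams(bandwidth=0.0025))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_mode_near_truth(self, rng):
        grid, dens = kde_density(rng.normal(0, 0.01, 10_000),
                                 KDEParams(bandwidth=0.0025))
        assert abs(grid[np.argmax(dens)]) < 0.002

    def test_bandwidth_monotone_smoothing(self, rng):
        x = rng.normal(0, 0.01, 2000)
        grid = np.linspace(-0.06, 0.06, 800)
        vars_ = []
        for bw in (0.002, 0.005, 0.01):
            _, dens = kde_density(x, KDEParams(bandwidth=bw), grid=grid)
            mu = np.trapezoid(grid * dens, grid)
            vars_.append(np.trapezoid((grid - mu) ** 2 * dens, grid))
        assert vars_[0] < vars_[1] < vars_[2]

    def test_degenerate_samples_warn(self, caplog):
        with caplog.at_level("WARNING", logger="mqpi.heterogeneity"):
            grid, dens = kde_density(np.zeros(10), KDEParams(bandwidth=0.001))
        assert "degenerate" in caplog.text

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kde_density(np.array([1.0]))


class TestControlThreshold:
    KDE = KDEParams(bandwidth=0.0025)

    def _windows(self, rng, n, shift=0.0):
        return {c: rng.normal(0.01 + shift, 0.005, n)
                for c in (6.0, 12.0, 18.0)}

    def test_identical_groups_zero(self, rng):
        w = self._windows(rng, 200)
        assert control_threshold(w, w, self.KDE) == pytest.approx(0.0, abs=1e-7)

    def test_sampling_consistency_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        t_small = control_threshold(self._windows(rng, 100),
                                    self._windows(rng, 100), self.KDE)
        t_big = control_threshold(self._windows(rng, 20_000),
                                  self._windows(rng, 20_000), self.KDE)
        assert t_big < t_small < 0.5

    def test_distinct_distributions_equals_max_h(self, rng):
        a = self._windows(rng, 400)
        b = self._windows(rng, 400, shift=0.004)
        thr = control_threshold(a, b, self.KDE)
        direct = max(hellinger_from_samples(a[c], b[c], self.KDE) for c in a)
        assert thr == pytest.approx(direct)

    def test_requires_common_centers(self, rng):
        a = {6.0: rng.normal(0, 1, 50)}
        b = {8.0: rng.normal(0, 1, 50)}
        with pytest.raises(ValueError):
            control_threshold(a, b, self.KDE)
        with pytest.raises(ValueError):
            control_threshold({}, a, self.KDE)


class TestTimeOfResponse:
    KDE = KDEParams(bandwidth=0.0025)
    CENTERS = np.arange(6.0, 43.0, 2.0)

    def _null(self, rng, n=300):
        return {c: rng.normal(0.02, 0.005, n) for c in self.CENTERS}

    def test_identical_treated_and_control_undefined(self, rng):
        ctrl = self._null(rng)
        series = time_of_response(self._null(rng), ctrl, threshold=0.25,
                                  params=self.KDE)
        assert series.tor_h is None and not series.responded

    def test_instantaneous_response_early_tor(self, rng):
        ctrl = self._null(rng)
        treated = {c: rng.normal(-0.01, 0.005, 300) for c in self.CENTERS}
        series = time_of_response(treated, ctrl, threshold=0.2,
                                  params=self.KDE)
        assert series.responded and series.tor_h <= self.CENTERS[1]

    def test_gradual_response_mid_assay_tor(self, rng):
        ctrl = self._null(rng)
        treated = {c: rng.normal(0.02 - 0.03 * min(c / 40, 1), 0.005, 300)
                   for c in self.CENTERS}
        series = time_of_response(treated, ctrl, threshold=0.5,
                                  params=self.KDE)
        assert series.responded and 6.0 < series.tor_h < 42.0

    def test_requires_three_windows(self, rng):
        a = {6.0: rng.normal(0, 1, 50), 8.0: rng.normal(0, 1, 50)}
        with pytest.raises(ValueError):
            time_of_response(a, a, 0.1, self.KDE)


class TestMixture:
    KDE = KDEParams(bandwidth=0.0025)

    def test_static_70_30_recovery(self, rng):
        """70/30 responsive/non-responsive at 4 sigma separation."""
        s = sample_sgr_mixture(2000, 0.30, -0.01, 0.02, 0.0075, rng)
        tc = fit_mixture_sequence({23.0: s}, self.KDE)
        row = tc.iloc[0]
        assert row["nonresponsive_fraction"] == pytest.approx(0.30, abs=0.05)
        assert row["mu_s"] < row["mu_n"]
        assert row["mu_s"] == pytest.approx(-0.01, abs=0.003)
        assert row["mu_n"] == pytest.approx(0.02, abs=0.003)
        assert row["identifiable"]

    def test_unimodal_unidentifiable(self, rng):
        s = rng.normal(0.01, 0.005, 1500)
        tc = fit_mixture_sequence({10.0: s}, self.KDE)
        row = tc.iloc[0]
        assert abs(row["mu_n"] - row["mu_s"]) < row["sigma_s"] + row["sigma_n"]
        assert not row["identifiable"]

    def test_sequential_warm_start_tracks_decay(self, rng):
        """Linearly decaying non-responsive fraction over 12 windows."""
        true_f = np.linspace(0.8, 0.25, 12)
        windows = {float(c): sample_sgr_mixture(1500, fn, -0.012, 0.018,
                                                0.0075, rng)
                   for c, fn in zip(np.arange(6, 30, 2), true_f)}
        tc = fit_mixture_sequence(windows, self.KDE)
        got = tc["nonresponsive_fraction"].to_numpy()
        assert np.abs(got - true_f).mean() < 0.05
        assert np.corrcoef(got, true_f)[0, 1] > 0.9

    def test_component_convention_sigma(self):
        """Components are exp(-((x-mu)/sigma)^2): sd = sigma/sqrt(2)."""
        grid = np.linspace(-0.04, 0.06, 600)
        sd = 0.0075
        y = (0.3 * np.exp(-((grid - 0.02) / (sd * np.sqrt(2))) ** 2)
             + 0.7 * np.exp(-((grid + 0.01) / (sd * np.sqrt(2))) ** 2))
        fit = fit_two_gaussians(grid, y)
        assert fit["sigma_s"] == pytest.approx(sd * np.sqrt(2), rel=0.01)

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture_sequence({}, self.KDE)
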