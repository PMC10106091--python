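"""Fitters: exact parameter recovery, model selection, oracle checks."""

import math

import numpy as np
import pytest

from navblock.fits import (
    fit_boltzmann,
    fit_eq1,
    fit_hill,
    fit_single_exp,
    select_time_course_model,
    time_to_fraction,
)


def gauss_time(t, A, B, tau):
    return A * np.exp(-((t / tau) ** 2)) + B


T = np.arange(0.0, 800.1, 5.0)


class TestTimeCourseFits:
    @pytest.mark.parametrize("A,B,tau", [(0.9, 0.1, 400.0), (0.65, 0.35, 567.0),
                                         (0.98, 0.02, 457.0)])
    def test_gaussian_exact_recovery(self, A, B, tau):
        f = fit_eq1(T, gauss_time(T, A, B, tau))
        assert f.converged and f.identifiable
        assert f.tau == pytest.approx(tau, rel=1e-6)
        assert f.A == pytest.approx(A, rel=1e-6)
        assert f.B == pytest.approx(B, rel=1e-6)

    def test_exponential_exact_recovery(self):
        y = 0.8 * np.exp(-T / 300.0) + 0.2
        f = fit_single_exp(T, y)
        assert f.tau == pytest.approx(300.0, rel=1e-6)

    def test_flat_series_flagged(self):
        f = fit_eq1(T, np.ones_like(T))
        assert not f.identifiable
        assert f.B == pytest.approx(1.0, abs=1e-6)

    def test_needs_six_points(self):
        with pytest.raises(ValueError):
            fit_eq1([0, 5, 10], [1, 0.9, 0.8])

    def test_time_unit_invariance(self):
        y = gauss_time(T, 0.9, 0.1, 400.0)
        f_s = fit_eq1(T, y)
        f_ms = fit_eq1(T * 1000.0, y)
        assert f_ms.tau == pytest.approx(1000.0 * f_s.tau, rel=1e-6)

    def test_exp_misfits_gaussian_with_structured_residuals(self):
        y = gauss_time(T, 0.9, 0.1, 400.0)
        f = fit_single_exp(T, y)
        resid = y - (f.A * np.exp(-T / f.tau) + f.B)
        signs = np.sign(resid[np.abs(resid) > 1e-6])
        runs = 1 + int(np.sum(np.diff(signs) != 0))
        # systematic misfit: far fewer sign changes than random residuals
        assert runs <= 8
        assert f.rss > 100 * fit_eq1(T, y).rss + 1e-12


class TestModelSelection:
    def test_correct_selection_both_directions(self):
        rng = np.random.default_rng(2024)
        n_rep, correct_g, correct_e = 200, 0, 0
        for _ in range(n_rep):
            noise = rng.normal(0, 0.02, T.shape)  # 2% of unit amplitude
            yg = gauss_time(T, 0.9, 0.1, 400.0) + noise
            ye = 0.9 * np.exp(-T / 400.0) + 0.1 + rng.normal(0, 0.02, T.shape)
            if select_time_course_model(T, yg)["selected"] == "eq1":
                correct_g += 1
            if select_time_course_model(T, ye)["selected"] == "exponential":
                correct_e += 1
        assert correct_g >= 0.95 * n_rep
        assert correct_e >= 0.95 * n_rep

    def test_flat_series_abstains(self):
        out = select_time_course_model(T, np.ones_like(T))
        assert out["selected"] is None


class TestBoltzmann:
    V = np.arange(-130.0, -29.9, 5.0)

    def test_exact_recovery(self):
        y = 1.0 / (1.0 + np.exp((self.V + 65.0) / 6.0))
        f = fit_boltzmann(self.V, y)
        assert f.V05 == pytest.approx(-65.0, abs=1e-6)
        assert f.slope_k == pytest.approx(6.0, abs=1e-6)
        assert f.spans_transition

    def test_midpoint_value(self):
        y = 0.1 + 0.8 / (1.0 + np.exp((self.V + 70.0) / 5.0))
        f = fit_boltzmann(self.V, y)
        assert f.predict(f.V05) == pytest.approx(0.5 * (f.floor + f.ceiling))

    def test_shift_passthrough(self):
        y1 = 1.0 / (1.0 + np.exp((self.V + 65.0) / 6.0))
        y2 = 1.0 / (1.0 + np.exp((self.V + 98.0) / 6.0))
        d = fit_boltzmann(self.V, y2).V05 - fit_boltzmann(self.V, y1).V05
        assert d == pytest.approx(-33.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_boltzmann([-100, -80, -60, -40], [1, 0.9, 0.3, 0.0])


class TestHill:
    C = np.array([0.0, 0.3, 1.0, 3.0, 10.0, 30.0])

    def test_exact_recovery(self):
        y = 1.0 / (1.0 + (self.C / 2.1) ** 1.0)
        f = fit_hill(self.C, y)
        assert f.ec50 == pytest.approx(2.1, rel=1e-6)
        assert f.predict(0.0) == pytest.approx(1.0)

    def test_midpoint_response(self):
        y = 1.0 / (1.0 + (self.C / 2.1) ** 1.5)
        f = fit_hill(self.C, y)
        assert f.predict(f.ec50) == pytest.approx(0.5 * (1 + f.floor), rel=1e-6)

    def test_requires_zero_anchor(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 3.0, 10.0], [0.8, 0.4, 0.1])

    def test_non_monotone_flagged(self):
        y = np.array([1.0, 0.7, 0.9, 0.3, 0.1, 0.05])
        f = fit_hill(self.C, y)
        assert not f.monotone


class TestGridSearchOracle:
    """Independent coarse grid search agrees with least squares."""

    def test_eq1_grid_agreement(self):
        y = gauss_time(T, 0.8, 0.2, 350.0) + np.random.default_rng(3).normal(0, 0.01, T.shape)
        f = fit_eq1(T, y)
        A_g = np.linspace(0.5, 1.1, 13)
        B_g = np.linspace(0.0, 0.5, 11)
        tau_g = np.linspace(200, 500, 16)
        best, best_rss = None, np.inf
        for A in A_g:
            for B in B_g:
                r = y[None, :] - (A * np.exp(-(T[None, :] / tau_g[:, None]) ** 2) + B)
                rss = np.sum(r * r, axis=1)
                j = int(np.argmin(rss))
                if rss[j] < best_rss:
                    best_rss, best = rss[j], (A, B, tau_g[j])
        # least squares is at least as good as the best grid point, and
        # the grid optimum lies within one grid cell of the fit
        assert f.rss <= best_rss + 1e-12
        assert abs(best[0] - f.A) <= np.diff(A_g)[0]
        assert abs(best[1] - f.B) <= np.diff(B_g)[0]
        assert abs(best[2] - f.tau) <= np.diff(tau_g)[0]

    def test_boltzmann_grid_agreement(self):
        V = np.arange(-130.0, -29.9, 5.0)
        y = 1.0 / (1.0 + np.exp((V + 72.0) / 5.5)) \
            + np.random.default_rng(4).normal(0, 0.01, V.shape)
        f = fit_boltzmann(V, y)
        v_g = np.linspace(-90, -55, 36)
        k_g = np.linspace(3, 9, 25)
        best, best_rss = None, np.inf
        for v05 in v_g:
            for k in k_g:
                r = y - 1.0 / (1.0 + np.exp((V - v05) / k))
                rss = float(r @ r)
                if rss < best_rss:
                    best_rss, best = rss, (v05, k)
        assert abs(best[0] - f.V05) <= np.diff(v_g)[0] + 0.2
        assert abs(best[1] - f.slope_k) <= np.diff(k_g)[0] + 0.1


class TestTimeToFraction:
    def test_log_midpoint(self):
        t = time_to_fraction([1.0, 2.0], [0.4, 0.6], 0.5)
        assert t == pytest.approx(math.sqrt(2.0), rel=1e-9)

    def test_exact_sample_hit(self):
        assert time_to_fraction([1.0, 2.0, 4.0], [0.3, 0.5, 0.9], 0.5) == 2.0

    def test_outside_range_rejected(self):
        with pytest.raises(ValueError):
            time_to_fraction([1.0, 2.0], [0.4, 0.6], 0.95)

    def test_exponential_half_time(self):
        tau = 7.0
        t = np.geomspace(0.05, 100, 200)
        frac = 1.0 - np.exp(-t / tau)
        t50 = time_to_fraction(t, frac, 0.5)
        assert t50 == pytest.approx(tau * math.log(2), rel=1e-3)
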