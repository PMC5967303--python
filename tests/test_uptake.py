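import math

import numpy as np
import pytest
from scipy.optimize import curve_fit

from msnpkill import (FkillSeries, filter_eligible, fit_exponential,
                      linear_baseline_r2, load_table1_fixture,
                      predict_fkill_series, predict_theta,
                      validate_predictions)
from msnpkill.exceptions import DomainError
from msnpkill.uptake import loglinear_init


def retained_pairs():
    records, fits = load_table1_fixture()
    si = {r.subject_id: r.si_mass_percent for r in records}
    retained, _ = filter_eligible(fits)
    return ([si[f.subject_id] for f in retained],
            [f.theta_f for f in retained])


class TestFitExponential:
    def test_published_pairs_reproduce_r_squared(self):
        """The five responding mice's (Si, theta) pairs are fitted by
        theta-scale NLS; the coefficient of determination matches the
        published goodness of fit."""
        si, theta = retained_pairs()
        model = fit_exponential(si, theta)
        assert model.r_squared == pytest.approx(0.817, abs=0.005)
        assert model.n_subjects == 5

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(11)
        si = rng.uniform(0.001, 0.006, 20)
        theta = 0.001 * np.exp(500 * si)
        m = fit_exponential(si, theta)
        assert math.isclose(m.A, 0.001, rel_tol=1e-8)
        assert math.isclose(m.B, 500, rel_tol=1e-8)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_law_recovered(self):
        si = np.linspace(0.001, 0.006, 10)
        theta = np.full(10, 0.004)
        m = fit_exponential(si, theta)
        assert math.isclose(m.A, 0.004, rel_tol=1e-6)
        assert abs(m.B) < 1e-6 / 0.006

    def test_never_worse_than_loglinear_initializer(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            si = rng.uniform(0.001, 0.006, 12)
            theta = 4e-4 * np.exp(900 * si) * np.exp(rng.normal(0, 0.4, 12))
            A0, B0 = loglinear_init(si, theta)
            rss0 = float(((theta - A0 * np.exp(B0 * si)) ** 2).sum())
            m = fit_exponential(si, theta)
            rss = float(np.asarray(m.residuals) @ np.asarray(m.residuals))
            assert rss <= rss0 * (1 + 1e-12)

    def test_agrees_with_independent_optimizer(self):
        """Cross-check the damped Gauss-Newton fit against scipy's
        Levenberg-Marquardt on noisy data."""
        rng = np.random.default_rng(21)
        si = rng.uniform(0.001, 0.006, 30)
        theta = 5e-4 * np.exp(1200 * si) * np.exp(rng.normal(0, 0.2, 30))
        m = fit_exponential(si, theta)
        popt, _ = curve_fit(lambda x, a, b: a * np.exp(b * x), si, theta,
                            p0=loglinear_init(si, theta), maxfev=10000)
        assert math.isclose(m.A, popt[0], rel_tol=1e-6)
        assert math.isclose(m.B, popt[1], rel_tol=1e-6)

    def test_si_unit_rescaling_equivariance(self):
        si, theta = retained_pairs()
        m1 = fit_exponential(si, theta)
        c = 1e4  # e.g. mass % -> ppm-like unit
        m2 = fit_exponential([s * c for s in si], theta)
        assert math.isclose(m2.B, m1.B / c, rel_tol=1e-6)
        assert math.isclose(m2.A, m1.A, rel_tol=1e-6)
        assert math.isclose(m2.r_squared, m1.r_squared, abs_tol=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(DomainError):
            fit_exponential([0.001, 0.002], [0.01, 0.02])

    def test_nonpositive_theta_raises(self):
        with pytest.raises(DomainError):
            fit_exponential([0.001, 0.002, 0.003], [0.01, 0.0, 0.02])


class TestPrediction:
    def test_predict_theta_at_zero_si_returns_A(self):
        from msnpkill import UptakeModel
        m = UptakeModel(A=0.000172, B=1664.39, r_squared=0.817, n_subjects=5,
                        fit_method="fixed")
        assert predict_theta(m, 0.0) == 0.000172
        # adding ln2/B to Si doubles the prediction
        assert predict_theta(m, math.log(2) / m.B) == pytest.approx(
            2 * 0.000172, rel=1e-12)

    def test_flat_model_predicts_A_everywhere(self):
        from msnpkill import UptakeModel
        m = UptakeModel(A=0.004, B=0.0, r_squared=1.0, n_subjects=3,
                        fit_method="fixed")
        assert predict_theta(m, 0.005) == 0.004

    def test_predicted_series_is_shifted_parabola(self):
        from msnpkill import UptakeModel
        m = UptakeModel(A=0.01, B=0.0, r_squared=1.0, n_subjects=3,
                        fit_method="fixed")
        fk = predict_fkill_series(m, si=0.0, t0=0.0, times=(0, 1, 2, 3))
        assert fk.fkill == (0.0, 0.01, 0.04, 0.09)
        assert not fk.capped

    def test_prediction_caps_at_one_with_flag(self):
        from msnpkill import UptakeModel
        m = UptakeModel(A=0.2, B=0.0, r_squared=1.0, n_subjects=3,
                        fit_method="fixed")
        fk = predict_fkill_series(m, si=0.0, t0=0.0, times=(0, 1, 2, 3))
        assert fk.capped and fk.fkill[-1] == 1.0
        assert all(0 <= v <= 1 for v in fk.fkill)
        assert all(b >= a for a, b in zip(fk.fkill, fk.fkill[1:]))


class TestValidatePredictions:
    def mk(self, fk, sid="s"):
        times = tuple(range(len(fk)))
        return FkillSeries(sid, t0=0.0, times=times, fkill=fk)

    def test_perfect_agreement_r_is_one(self):
        obs = [self.mk((0.0, 0.1, 0.4, 0.9))]
        ps = validate_predictions(obs, obs)
        assert ps.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_r_is_minus_one(self):
        obs = [self.mk((0.0, 0.1, 0.2, 0.3))]
        pred = [self.mk((0.0, -0.1, -0.2, -0.3))]
        ps = validate_predictions(obs, pred)
        assert ps.pearson_r == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        obs = [self.mk((0.0, 0.0, 0.5, 0.9))]
        pred = [self.mk((0.0, 0.1, 0.45, 0.95))]
        ps = validate_predictions(obs, pred)
        x = np.array([0.0, 0.5, 0.9])
        y = np.array([0.1, 0.45, 0.95])
        xc, yc = x - x.mean(), y - y.mean()
        r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
        assert ps.pearson_r == pytest.approx(r, rel=1e-12)

    def test_mismatched_grids_raise(self):
        obs = [self.mk((0.0, 0.1, 0.2, 0.3))]
        pred = [FkillSeries("s", t0=0.0, times=(0, 1, 2), fkill=(0, 0.1, 0.2))]
        with pytest.raises(DomainError):
            validate_predictions(obs, pred)

    def test_too_few_pairs_raise(self):
        obs = [self.mk((0.0, 0.1))]
        with pytest.raises(DomainError):
            validate_predictions(obs, obs)


def test_exponential_beats_linear_baseline_on_published_pairs():
    si, theta = retained_pairs()
    exp_r2 = fit_exponential(si, theta).r_squared
    lin_r2 = linear_baseline_r2(si, theta)
    assert exp_r2 > lin_r2
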