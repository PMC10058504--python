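import numpy as np
import pytest

import beadcolony as bc
from beadcolony.growth import GrowthCurve, smooth_curve


def _lognoise(rng, cv, size):
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2, sigma, size=size)


class TestBoltzmann:
    FIT = bc.SigmoidFit(a1=0.0, a2=100.0, t0=8.0, dt=1.0)

    def test_midpoint_and_limits(self):
        assert bc.boltzmann_eval(self.FIT, 8.0) == pytest.approx(50.0)
        assert bc.boltzmann_eval(self.FIT, -1e3) == pytest.approx(0.0, abs=1e-9)
        assert bc.boltzmann_eval(self.FIT, 1e3) == pytest.approx(100.0)
        mid = bc.boltzmann_eval(bc.SigmoidFit(10.0, 90.0, 5.0, 2.0), 5.0)
        assert mid == pytest.approx((10.0 + 90.0) / 2)

    def test_noiseless_recovery(self):
        true = bc.SigmoidFit(a1=5.0, a2=1200.0, t0=9.0, dt=1.4)
        t = np.linspace(4, 32, 10)
        fit = bc.fit_boltzmann(GrowthCurve(t, np.asarray(bc.boltzmann_eval(true, t))))
        for name in ("a1", "a2", "t0", "dt"):
            assert getattr(fit, name) == pytest.approx(getattr(true, name),
                                                       rel=1e-6, abs=1e-6)

    def test_noisy_median_a2_within_five_percent(self):
        true = bc.SigmoidFit(a1=5.0, a2=1000.0, t0=9.0, dt=1.5)
        t = np.linspace(4, 32, 8)
        clean = np.asarray(bc.boltzmann_eval(true, t))
        rng = np.random.default_rng(0)
        a2s = []
        for _ in range(50):
            fit = bc.fit_boltzmann(GrowthCurve(t, clean * _lognoise(rng, 0.05, t.size)))
            a2s.append(fit.a2)
        assert np.median(a2s) == pytest.approx(1000.0, rel=0.05)

    def test_constant_curve_flagged_degenerate(self):
        t = np.linspace(4, 32, 8)
        fit = bc.fit_boltzmann(GrowthCurve(t, np.full_like(t, 750.0)))
        assert fit.degenerate
        assert fit.a1 == pytest.approx(fit.a2)

    def test_too_few_points(self):
        with pytest.raises(bc.FitError):
            bc.fit_boltzmann(GrowthCurve([4, 6, 8], [1, 2, 3]))


class TestBaranyiRoberts:
    def test_gamma_one_is_logistic(self):
        p = bc.MonocultureParams(r=0.7, gamma=1.0, a1=10.0, a2=1000.0)
        t = np.linspace(0, 30, 40)
        logistic = p.a2 / (1 + (p.a2 / p.a1 - 1) * np.exp(-p.r * t))
        assert np.allclose(bc.baranyi_roberts_eval(p, t), logistic, rtol=1e-12)

    def test_initial_condition(self):
        p = bc.MonocultureParams(r=0.8, gamma=1.5, a1=10.0, a2=1000.0)
        assert bc.baranyi_roberts_eval(p, 0.0) == pytest.approx(10.0, rel=1e-12)

    def test_closed_form_solves_the_ode(self):
        # the closed form must agree with adaptive integration of the rate law
        p = bc.MonocultureParams(r=0.8, gamma=1.5, a1=10.0, a2=1000.0)
        t = np.linspace(0, 30, 61)
        cp = bc.CompetitionParams(b=p, y=p, c_b=0.0, c_y=0.0)
        ab, _ = bc.lv_integrate(cp, t)
        rel = np.max(np.abs(ab - bc.baranyi_roberts_eval(p, t))) / p.a2
        assert rel < 1e-6

    def test_monotone_nondecreasing_growth(self):
        p = bc.MonocultureParams(r=0.5, gamma=2.5, a1=5.0, a2=800.0)
        a = bc.baranyi_roberts_eval(p, np.linspace(0, 50, 200))
        assert np.all(np.diff(a) >= -1e-9)

    def test_rhs_sign_structure(self):
        p = bc.MonocultureParams(r=0.5, gamma=1.0, a1=5.0, a2=100.0)
        assert bc.baranyi_roberts_rhs(p, 50.0) > 0
        assert bc.baranyi_roberts_rhs(p, 100.0) == pytest.approx(0.0)
        assert bc.baranyi_roberts_rhs(p, 150.0) < 0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            bc.MonocultureParams(r=-1.0, gamma=1.0, a1=1.0, a2=10.0)
        with pytest.raises(ValueError):
            bc.MonocultureParams(r=1.0, gamma=1.0, a1=10.0, a2=5.0)


class TestFitMonoculture:
    def test_noiseless_raw_recovery(self):
        p = bc.MonocultureParams(r=0.85, gamma=1.2, a1=5.0, a2=4500.0)
        t = np.linspace(4, 32, 15)
        curve = GrowthCurve(t, np.asarray(bc.baranyi_roberts_eval(p, t)))
        fit = bc.fit_monoculture(curve, smooth=False)
        assert fit.params.r == pytest.approx(p.r, rel=1e-5)
        assert fit.params.gamma == pytest.approx(p.gamma, rel=1e-5)
        assert fit.params.a2 == pytest.approx(p.a2, rel=1e-6)

    def test_logistic_data_recovers_gamma_near_one(self):
        p = bc.MonocultureParams(r=0.7, gamma=1.0, a1=10.0, a2=1000.0)
        t = np.linspace(4, 32, 15)
        clean = np.asarray(bc.baranyi_roberts_eval(p, t))
        rng = np.random.default_rng(1)
        gammas = []
        for i in range(50):
            noisy = GrowthCurve(t, clean * _lognoise(rng, 0.05, t.size))
            gammas.append(bc.fit_monoculture(noisy, smooth=False, seed=i,
                                             n_starts=3).params.gamma)
        assert 0.8 <= np.median(gammas) <= 1.25

    def test_insufficient_data(self):
        with pytest.raises(bc.FitError):
            bc.fit_monoculture(GrowthCurve([4.0, 8.0], [1.0, 2.0]))

    def test_bootstrap_ci_covers_truth(self):
        p = bc.MonocultureParams(r=0.85, gamma=1.2, a1=5.0, a2=4500.0)
        t = np.linspace(4, 32, 15)
        rng = np.random.default_rng(3)
        curve = GrowthCurve(t, np.asarray(bc.baranyi_roberts_eval(p, t))
                            * _lognoise(rng, 0.03, t.size))
        fit = bc.fit_monoculture(curve, smooth=False)
        ci = bc.bootstrap_monoculture_ci(curve, fit, n_boot=30, seed=0)
        lo, hi = ci["a2"]
        assert lo < p.a2 * 1.1 and hi > p.a2 * 0.9


class TestCompetitionModel:
    def test_decoupled_limit_matches_monoculture(self, default_mono_params):
        b, y = default_mono_params
        t = np.linspace(0, 32, 65)
        ab, ay = bc.lv_integrate(bc.CompetitionParams(b=b, y=y), t)
        assert np.max(np.abs(ab - bc.baranyi_roberts_eval(b, t))) / b.a2 < 1e-6
        assert np.max(np.abs(ay - bc.baranyi_roberts_eval(y, t))) / y.a2 < 1e-6

    def test_symmetric_strains_stay_equal(self, default_mono_params):
        b, _ = default_mono_params
        params = bc.CompetitionParams(b=b, y=b, c_b=0.4, c_y=0.4)
        ab, ay = bc.lv_integrate(params, np.linspace(0, 32, 33))
        assert np.allclose(ab, ay, rtol=1e-9)

    def test_strong_suppression_lowers_final_size(self, default_mono_params):
        b, y = default_mono_params
        params = bc.CompetitionParams(b=b, y=y, c_b=0.0, c_y=2.0)
        ab, _ = bc.lv_integrate(params, np.linspace(0, 60, 61))
        assert ab[-1] < 0.8 * b.a2

    def test_rejects_negative_coefficients(self, default_mono_params):
        b, y = default_mono_params
        with pytest.raises(ValueError):
            bc.CompetitionParams(b=b, y=y, c_b=-0.1)


class TestFitCompetition:
    def test_noiseless_recovery_and_decomposition(self, default_mono_params,
                                                  study_time_points):
        b, y = default_mono_params
        true = bc.CompetitionParams(b=b, y=y, c_b=0.5, c_y=0.3)
        ab, ay = bc.lv_integrate(true, study_time_points)
        fit = bc.fit_competition(GrowthCurve(study_time_points, ab + ay), b, y)
        a2 = max(b.a2, y.a2)
        assert fit.rmse < 1e-6 * a2
        assert fit.params.c_b == pytest.approx(0.5, abs=0.01)
        assert fit.params.c_y == pytest.approx(0.3, abs=0.01)
        assert np.max(np.abs(fit.a_b - ab)) / ab[-1] < 0.01
        assert np.max(np.abs(fit.a_y - ay)) / ay[-1] < 0.01
        assert fit.identifiable

    def test_null_coefficients_recovered(self, default_mono_params,
                                         study_time_points):
        b, y = default_mono_params
        ab, ay = bc.lv_integrate(bc.CompetitionParams(b=b, y=y),
                                 study_time_points)
        fit = bc.fit_competition(GrowthCurve(study_time_points, ab + ay), b, y)
        assert fit.params.c_b < 1e-3 and fit.params.c_y < 1e-3
        assert np.allclose(fit.a_b, ab, rtol=1e-4)

    def test_identical_strains_flagged_as_ridge(self, default_mono_params,
                                                study_time_points):
        b, _ = default_mono_params
        true = bc.CompetitionParams(b=b, y=b, c_b=0.5, c_y=0.5)
        ab, ay = bc.lv_integrate(true, study_time_points)
        fit = bc.fit_competition(GrowthCurve(study_time_points, ab + ay), b, b)
        assert not fit.identifiable
        # the sum is still well determined on the ridge
        assert fit.params.c_b + fit.params.c_y == pytest.approx(1.0, abs=0.05)


def test_smooth_curve_reproduces_sigmoid_data():
    true = bc.SigmoidFit(a1=5.0, a2=900.0, t0=9.0, dt=1.5)
    t = np.array([4.0, 6.0, 8.0, 10.0, 12.0, 22.0, 32.0])
    smoothed = smooth_curve(GrowthCurve(t, np.asarray(bc.boltzmann_eval(true, t))), n=20)
    assert np.allclose(smoothed.values,
                       np.asarray(bc.boltzmann_eval(true, smoothed.times)),
                       rtol=1e-5)


def test_growth_curve_validation():
    with pytest.raises(ValueError):
        GrowthCurve([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        GrowthCurve([1.0, 2.0], [-1.0, 2.0])


def test_growth_curve_from_table_conditions(small_table):
    curve = bc.growth_curve_from_table(small_table, "B", condition="co")
    assert curve.times.size == 7
    assert np.all(np.diff(curve.times) > 0)
    with pytest.raises(ValueError):
        bc.growth_curve_from_table(small_table, "B", condition="mono",
                                   signal="bogus")
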