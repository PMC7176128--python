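import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fdopakin as fk
from fdopakin.fitting import (InsufficientPointsError, LoganDomainError,
                              UnderdeterminedError, FitResult)
from fdopakin.kinetic_models import (KineticParams, MODEL_1T2K, MODEL_2T3K,
                                     MODEL_2T4K)


class TestFitModel:
    @pytest.mark.parametrize("spec", fk.STUDY_SCHEDULE_SPECS)
    def test_noiseless_recovery_all_schedules(self, input_function,
                                              truth_params, spec):
        """Cohort-mean 1T2k+VB parameters refit to <1% on every schedule."""
        sched = fk.make_schedule(spec)
        tac = fk.bin_curve(fk.simulate(truth_params, input_function, 1200.0),
                           sched)
        fit = fk.fit_model(tac, input_function, MODEL_1T2K)
        assert fit.converged
        assert fit.params.K1 == pytest.approx(0.161, rel=0.01)
        assert fit.params.k2 == pytest.approx(0.087, rel=0.01)
        assert fit.params.VB == pytest.approx(0.084, rel=0.01)

    def test_init_at_truth_gives_machine_scale_ss(self, clean_tac,
                                                  input_function, truth_params):
        fit = fk.fit_model(clean_tac, input_function, MODEL_1T2K,
                           init=truth_params)
        assert fit.converged
        assert fit.ss < 1e-12 * float(np.sum(clean_tac.values ** 2))

    def test_nested_2t4k_on_1t_data_drives_k3_to_zero(self, clean_tac,
                                                      input_function):
        fit = fk.fit_model(clean_tac, input_function, MODEL_2T4K)
        assert fit.params.k3 < 5e-3
        assert fit.params.K1 == pytest.approx(0.161, rel=0.02)

    def test_underdetermined_raises(self, input_function, truth_params):
        sched = fk.make_schedule("3x400")
        tac = fk.bin_curve(fk.simulate(truth_params, input_function, 1200.0),
                           sched)
        with pytest.raises(UnderdeterminedError):
            fk.fit_model(tac, input_function, MODEL_1T2K)

    def test_duration_weighting_accepted(self, clean_tac, input_function):
        fit = fk.fit_model(clean_tac, input_function, MODEL_1T2K,
                           weights="duration")
        assert fit.params.K1 == pytest.approx(0.161, rel=0.01)

    def test_objective_never_worse_than_initial_point(self, input_function,
                                                      truth_params, rng):
        # trust-region steps are only accepted when they reduce the cost,
        # so the returned SS can never exceed the SS at the starting point
        sched = fk.make_schedule("10x30,3x300")
        tac = fk.bin_curve(fk.simulate(truth_params, input_function, 1200.0),
                           sched)
        noisy = fk.SampledTAC(schedule=sched,
                              values=tac.values + rng.normal(0, 0.5, 13))
        init = KineticParams(model_id=MODEL_1T2K, K1=0.1, k2=0.1, VB=0.05)
        model0 = fk.bin_curve(fk.simulate(init, input_function, 1200.0), sched)
        ss0 = float(np.sum((noisy.values - model0.values) ** 2))
        fit = fk.fit_model(noisy, input_function, MODEL_1T2K, init=init)
        assert fit.ss <= ss0 + 1e-12

    def test_midpoint_eval_recovers_on_fine_schedule(self, clean_tac,
                                                     input_function):
        # conventional-software convention: small but nonzero error
        fit = fk.fit_model(clean_tac, input_function, MODEL_1T2K,
                           model_eval="midpoint")
        assert fit.params.K1 == pytest.approx(0.161, rel=0.01)


class TestAicc:
    def test_stated_arithmetic(self):
        # ln term vanishes when ss == n
        assert fk.aicc(15.0, 15, 3) == pytest.approx(6 + 24 / 11)

    def test_monotone_in_ss(self):
        assert fk.aicc(5.0, 15, 3) < fk.aicc(10.0, 15, 3)

    def test_large_n_limit_is_plain_aic(self):
        n = 10_000_000
        ss = 2.0 * n
        plain = n * np.log(ss / n) + 2 * 3
        assert fk.aicc(ss, n, 3) == pytest.approx(plain, abs=1e-4)

    @pytest.mark.parametrize("n,k", [(10, 3), (12, 4), (15, 5)])
    def test_domain_error_and_formula(self, n, k):
        with pytest.raises(ValueError):
            fk.aicc(1.0, k + 1, k)
        ss = 0.37
        expected = n * np.log(ss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fk.aicc(ss, n, k) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.integers(7, 500), st.integers(1, 5))
    def test_matches_brute_force_formula(self, ss, n, k):
        expected = n * np.log(ss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fk.aicc(ss, n, k) == pytest.approx(expected, rel=1e-12)


def _fit_result(model_id, aicc_value):
    n_params = {MODEL_1T2K: 3, MODEL_2T3K: 4, MODEL_2T4K: 5}[model_id]
    p = KineticParams(model_id=model_id, K1=0.1, k2=0.1,
                      k3=0.01 if n_params > 3 else 0.0,
                      k4=0.01 if n_params > 4 else 0.0, VB=0.05)
    return FitResult(params=p, ss=1.0, n_frames=15, n_params=n_params,
                     aicc=aicc_value, converged=True, n_iter=10)


class TestSelectModel:
    def test_lowest_aicc_wins(self):
        fits = [_fit_result(MODEL_1T2K, 11.0), _fit_result(MODEL_2T3K, 8.2)]
        assert fk.select_model(fits).model_id == MODEL_2T3K

    def test_exact_tie_goes_to_fewer_parameters(self):
        fits = [_fit_result(MODEL_2T4K, 8.2), _fit_result(MODEL_1T2K, 8.2)]
        assert fk.select_model(fits).model_id == MODEL_1T2K

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fk.select_model([])


class TestLogan:
    def test_tac_equal_to_binned_plasma_gives_unit_slope(self, input_function):
        plasma = input_function.plasma_parent
        sched = fk.make_schedule("20x60")
        tac = fk.bin_curve(plasma, sched)
        res = fk.logan_vt(tac, plasma, 600.0)
        assert res.vt == pytest.approx(1.0, abs=0.02)
        assert abs(res.intercept) < 0.2

    def test_reversible_1t_vt_equals_dv(self, input_function):
        p = KineticParams(model_id=MODEL_1T2K, K1=0.161, k2=0.087, VB=0.0)
        tac = fk.bin_curve(fk.simulate(p, input_function, 1200.0),
                           fk.make_schedule("20x60"))
        res = fk.logan_vt(tac, input_function.plasma_parent, 600.0)
        assert res.vt == pytest.approx(0.161 / 0.087, rel=0.05)
        assert res.r2 > 0.999
        # for 1T kinetics the Logan intercept is -1/k2 (minutes)
        assert res.intercept == pytest.approx(-1 / 0.087, rel=0.15)

    def test_doubling_plasma_halves_slope(self, input_function):
        p = KineticParams(model_id=MODEL_1T2K, K1=0.161, k2=0.087, VB=0.0)
        tac = fk.bin_curve(fk.simulate(p, input_function, 1200.0),
                           fk.make_schedule("20x60"))
        plasma = input_function.plasma_parent
        doubled = fk.ContinuousCurve(values=2.0 * plasma.values)
        a = fk.logan_vt(tac, plasma, 600.0).vt
        b = fk.logan_vt(tac, doubled, 600.0).vt
        assert b == pytest.approx(a / 2.0, rel=1e-9)

    def test_too_few_tail_points_raises(self, clean_tac, input_function):
        # optimal schedule has only two frame midpoints at or after 600 s
        with pytest.raises(InsufficientPointsError):
            fk.logan_vt(clean_tac, input_function.plasma_parent, 600.0)

    def test_non_positive_tac_in_window_raises(self, input_function):
        sched = fk.make_schedule("20x60")
        tac = fk.SampledTAC(schedule=sched, values=np.zeros(20))
        with pytest.raises(LoganDomainError):
            fk.logan_vt(tac, input_function.plasma_parent, 600.0)

    def test_auto_t_star_agrees_for_1t(self, input_function):
        p = KineticParams(model_id=MODEL_1T2K, K1=0.161, k2=0.087, VB=0.0)
        tac = fk.bin_curve(fk.simulate(p, input_function, 1200.0),
                           fk.make_schedule("20x60"))
        res = fk.logan_auto_t_star(tac, input_function.plasma_parent)
        assert res.vt == pytest.approx(0.161 / 0.087, rel=0.05)
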