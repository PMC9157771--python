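import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import meropk as mp
from meropk.pk import concentration_batch, expand_regimen


def ode_concentration(params, doses, times):
    """Independent oracle: numeric integration of the compartmental ODEs."""
    k10 = params.cl / params.v1
    two = params.q is not None and params.q > 0
    if two:
        k12, k21 = params.q / params.v1, params.q / params.v2

    def rate_in(t):
        return sum(d.rate for d in doses
                   if d.start_time <= t < d.start_time + d.duration)

    def rhs(t, y):
        if two:
            return [rate_in(t) - (k10 + k12) * y[0] + k21 * y[1],
                    k12 * y[0] - k21 * y[1]]
        return [rate_in(t) - k10 * y[0]]

    t_events = sorted({0.0, *[d.start_time for d in doses],
                       *[d.start_time + d.duration for d in doses],
                       *np.atleast_1d(times)})
    y = [0.0, 0.0] if two else [0.0]
    out = {}
    for a, b in zip(t_events[:-1], t_events[1:]):
        sol = solve_ivp(rhs, (a, b), y, rtol=1e-11, atol=1e-13,
                        dense_output=True, max_step=(b - a) or None)
        y = sol.y[:, -1].tolist()
        for t in np.atleast_1d(times):
            if a < t <= b:
                out[t] = sol.sol(t)[0] / params.v1
    out.setdefault(0.0, 0.0)
    return np.asarray([out[t] for t in np.atleast_1d(times)])


class TestSingleProfiles:
    def test_zero_before_any_dose(self, simple_params):
        doses = [mp.DoseEvent(amount=1000, duration=1.0, start_time=5.0)]
        assert mp.concentration(simple_params, doses, 0.0) == 0.0
        assert mp.concentration(simple_params, doses, 4.9) == 0.0

    def test_one_cmt_matches_ode(self, simple_params):
        doses = [mp.DoseEvent(amount=1000, duration=1.0)]
        t = np.asarray([0.5, 1.0, 2.0, 8.0])
        closed = mp.concentration(simple_params, doses, t)
        oracle = ode_concentration(simple_params, doses, t)
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_two_cmt_irregular_doses_match_ode(self, two_cmt_params):
        doses = [mp.DoseEvent(amount=1000, duration=0.5, start_time=0.0),
                 mp.DoseEvent(amount=500, duration=2.0, start_time=7.3),
                 mp.DoseEvent(amount=2000, duration=4.0, start_time=16.9)]
        t = np.asarray([0.25, 3.0, 8.0, 17.5, 24.0, 40.0])
        closed = mp.concentration(two_cmt_params, doses, t)
        oracle = ode_concentration(two_cmt_params, doses, t)
        assert np.max(np.abs(closed / oracle - 1)) <= 1e-6

    def test_q_zero_reduces_to_one_cmt(self, simple_params):
        two = mp.PKParameters(cl=10.0, v1=20.0, q=0.0, v2=5.0)
        doses = [mp.DoseEvent(amount=750, duration=1.5)]
        t = np.linspace(0.1, 12, 40)
        assert np.allclose(mp.concentration(two, doses, t),
                           mp.concentration(simple_params, doses, t), rtol=1e-12)

    def test_superposition(self, two_cmt_params):
        d1 = [mp.DoseEvent(amount=1000, duration=1.0, start_time=0.0)]
        d2 = [mp.DoseEvent(amount=500, duration=2.0, start_time=5.0)]
        t = np.linspace(0.0, 24, 49)
        both = mp.concentration(two_cmt_params, d1 + d2, t)
        assert np.allclose(both,
                           mp.concentration(two_cmt_params, d1, t)
                           + mp.concentration(two_cmt_params, d2, t))

    def test_continuity_at_infusion_end(self, two_cmt_params):
        doses = [mp.DoseEvent(amount=1000, duration=1.0)]
        eps = 1e-9
        left = mp.concentration(two_cmt_params, doses, 1.0 - eps)
        right = mp.concentration(two_cmt_params, doses, 1.0 + eps)
        assert right == pytest.approx(left, rel=1e-6)

    def test_negative_time_rejected(self, simple_params):
        with pytest.raises(ValueError):
            mp.concentration(simple_params, [mp.DoseEvent(1000, 1.0)], -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mp.PKParameters(cl=-1.0, v1=20.0)
        with pytest.raises(ValueError):
            mp.PKParameters(cl=10.0, v1=20.0, q=5.0, v2=None)


class TestSteadyState:
    def test_matches_brute_force_superposition(self, simple_params):
        reg = mp.DoseEvent(amount=1000, duration=1.0, interval=8.0)
        t_in_cycle = np.asarray([0.5, 1.0, 4.0, 7.9])
        ss = mp.steady_state_profile(simple_params, reg, t_in_cycle)
        doses = expand_regimen(reg, 50)
        brute = mp.concentration(simple_params, doses, 49 * 8.0 + t_in_cycle)
        assert np.max(np.abs(ss / brute - 1)) <= 1e-6

    def test_two_cmt_brute_force(self, two_cmt_params):
        reg = mp.DoseEvent(amount=2000, duration=3.0, interval=12.0)
        t = np.asarray([2.0, 6.0, 11.5])
        ss = mp.steady_state_profile(two_cmt_params, reg, t)
        brute = mp.concentration(two_cmt_params, expand_regimen(reg, 80),
                                 79 * 12.0 + t)
        assert np.max(np.abs(ss / brute - 1)) <= 1e-6

    def test_long_interval_limit_is_single_dose(self, simple_params):
        reg = mp.DoseEvent(amount=1000, duration=1.0, interval=5000.0)
        t = np.asarray([0.5, 2.0, 8.0])
        single = mp.concentration(simple_params, [mp.DoseEvent(1000, 1.0)], t)
        assert np.allclose(mp.steady_state_profile(simple_params, reg, t),
                           single, rtol=1e-9)

    def test_linearity_in_dose(self, two_cmt_params):
        t = np.linspace(0.5, 7.5, 8)
        a = mp.steady_state_profile(
            two_cmt_params, mp.DoseEvent(1000, 1.0, interval=8.0), t)
        b = mp.steady_state_profile(
            two_cmt_params, mp.DoseEvent(2000, 1.0, interval=8.0), t)
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_auc_over_interval_equals_dose_over_cl(self, two_cmt_params):
        reg = mp.DoseEvent(amount=1000, duration=1.0, interval=8.0)
        auc, _ = quad(lambda t: mp.steady_state_profile(two_cmt_params, reg, t),
                      0.0, 8.0, limit=200)
        assert auc == pytest.approx(1000.0 / two_cmt_params.cl, rel=1e-4)

    def test_non_periodic_regimen_rejected(self, simple_params):
        with pytest.raises(ValueError, match="concentration"):
            mp.steady_state_profile(simple_params,
                                    mp.DoseEvent(1000, 1.0), [1.0])


class TestPredict:
    def test_pred_ignores_observed_values(self, muro):
        from conftest import trough_patient

        p1 = trough_patient(muro, np.zeros(1), n_obs=2)
        p2 = trough_patient(muro, np.zeros(1), n_obs=2)
        p2.observations = [mp.Observation(o.time, o.concentration * 7.0)
                           for o in p2.observations]
        assert np.allclose(mp.predict(muro, p1, None), mp.predict(muro, p2, None))

    def test_self_consistency_with_generator(self, muro):
        from conftest import trough_patient

        eta = np.asarray([0.3])
        p = trough_patient(muro, eta, n_obs=3, noise=0.0)
        assert np.allclose(mp.predict(muro, p, eta), p.obs_values, rtol=1e-12)

    def test_observation_before_first_dose_warns(self, muro, simple_params):
        cov = mp.CovariateRecord(age=55, sex="male", weight=70)
        p = mp.Patient(pid="X", covariates=cov,
                       doses=[mp.DoseEvent(1000, 1.0, start_time=2.0)],
                       observations=[mp.Observation(time=1.0, concentration=5.0)])
        with pytest.warns(UserWarning, match="before first dose"):
            pred = mp.predict(muro, p, None)
        assert pred[0] == 0.0


def test_batch_concentration_matches_scalar(two_cmt_params):
    doses = [mp.DoseEvent(1000, 1.0), mp.DoseEvent(500, 2.0, start_time=9.0)]
    t = np.asarray([0.5, 4.0, 9.5, 20.0])
    cl = np.asarray([5.0, 9.0, 14.0])
    v1 = np.asarray([10.0, 12.0, 30.0])
    q = np.asarray([15.0, 15.0, 8.0])
    v2 = np.asarray([25.0, 25.0, 40.0])
    batch = concentration_batch(cl, v1, q, v2, doses, t)
    for i in range(3):
        single = mp.concentration(
            mp.PKParameters(cl=cl[i], v1=v1[i], q=q[i], v2=v2[i]), doses, t)
        assert np.allclose(batch[i], single, rtol=1e-12)
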