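import numpy as np
import pytest

import meropk as mp


@pytest.fixture(scope="session")
def muro():
    return mp.get_model("muro")


@pytest.fixture(scope="session")
def li():
    return mp.get_model("li")


@pytest.fixture()
def simple_params():
    return mp.PKParameters(cl=10.0, v1=20.0)


@pytest.fixture()
def two_cmt_params():
    return mp.PKParameters(cl=9.0, v1=12.0, q=15.0, v2=25.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 40-patient synthetic cohort from the default generator."""
    cfg = mp.CohortConfig(n_patients=40, seed=11)
    patients, _ = mp.apply_lloq_filter(mp.generate_cohort(cfg))
    return patients


def trough_patient(model, eta, cov=None, n_obs=1, seed=0, noise=0.0):
    """A patient dosed 1 g q8h with trough samples simulated from ``model``."""
    rng = np.random.default_rng(seed)
    cov = cov or mp.CovariateRecord(age=55, sex="male", weight=70,
                                    serum_creatinine=120.0)
    doses = [mp.DoseEvent(amount=1000.0, duration=1.0, start_time=8.0 * k)
             for k in range(5 + n_obs)]
    times = np.asarray([8.0 * (5 + j) - 0.5 for j in range(n_obs)])
    params = mp.compute_individual_parameters(model, cov, eta)
    c = mp.concentration(params, doses, times)
    c_obs = c * (1.0 + noise * rng.standard_normal(c.shape))
    observations = [mp.Observation(time=float(t), concentration=float(v))
                    for t, v in zip(times, np.maximum(c_obs, 1e-3))]
    return mp.Patient(pid="T1", covariates=cov, doses=doses,
                      observations=observations,
                      truth={"eta": dict(zip(model.eta_names,
                                             np.atleast_1d(eta).tolist())),
                             "c_true": c.tolist()})
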