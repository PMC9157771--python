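import copy

import numpy as np
import pytest

import meropk as mp
from meropk.forecasting import MAPForecast
from meropk.registry import ModelSpec

from conftest import trough_patient


def grid_search_eta(forecaster, omega_sd, step=1e-4):
    """Independent oracle: dense 1-D scan of the posterior objective."""
    grid = np.arange(-3 * omega_sd, 3 * omega_sd + step, step)
    vals = [forecaster.objective(np.asarray([g])) for g in grid]
    return grid[int(np.argmin(vals))]


class TestMapEstimate:
    def test_no_priors_gives_a_priori(self, muro):
        p = trough_patient(muro, np.asarray([0.4]), n_obs=1)
        res = mp.map_estimate(muro, p, prior_obs=[])
        assert np.all(res.eta_map.values == 0.0)
        assert np.allclose(res.ipred, mp.predict(muro, p, None))
        assert res.n_priors_used == 0

    def test_matches_grid_search_oracle(self, muro):
        """1 random effect, 1 observation: MAP equals a dense posterior scan."""
        omega_sd = float(np.sqrt(muro.omega()[0, 0]))
        for seed, eta_true in [(1, 0.5), (2, -0.7), (3, 0.0)]:
            p = trough_patient(muro, np.asarray([eta_true]), seed=seed,
                               noise=0.15)
            f = MAPForecast(muro, p)
            res = f.fit()
            expected = grid_search_eta(f, omega_sd)
            assert res.eta_map.values[0] == pytest.approx(expected, abs=1e-3)

    def test_tiny_residual_interpolates_observation(self, muro):
        p = trough_patient(muro, np.asarray([0.5]), n_obs=1, noise=0.0)
        tight = ModelSpec.from_dict(muro.to_dict())
        tight.sigma = {"kind": "proportional", "proportional": 1e-4,
                       "additive": 0.0, "provenance": "placeholder"}
        res = MAPForecast(tight, p).fit()
        obs = p.observations[0]
        assert res.predict([obs.time])[0] == pytest.approx(obs.concentration,
                                                           rel=1e-3)

    def test_map_never_worse_than_prior_mode(self, muro, small_cohort):
        for p in small_cohort[:10]:
            f = MAPForecast(muro, p)
            res = f.fit()
            assert res.objective <= f.objective(np.zeros(1)) + 1e-9

    def test_deterministic(self, muro):
        p = trough_patient(muro, np.asarray([0.3]), noise=0.1, seed=9)
        a = mp.map_estimate(muro, p).eta_map.values
        b = mp.map_estimate(muro, p).eta_map.values
        assert np.array_equal(a, b)

    def test_prior_obs_must_belong_to_patient(self, muro):
        p = trough_patient(muro, np.asarray([0.0]))
        alien = mp.Observation(time=1.0, concentration=5.0)
        with pytest.raises(ValueError, match="not one of"):
            MAPForecast(muro, p, [alien])

    def test_two_random_effects(self, li):
        p = trough_patient(li, np.asarray([0.4, -0.3]), n_obs=3, noise=0.1)
        res = MAPForecast(li, p).fit()
        assert res.eta_map.values.shape == (2,)
        assert np.isfinite(res.objective)

    def test_summary_mentions_model_and_patient(self, muro):
        p = trough_patient(muro, np.asarray([0.2]))
        text = mp.map_estimate(muro, p).summary()
        assert "muro" in text and "T1" in text


class TestThirdIntervalForecast:
    def test_mode_none_is_population_prediction(self, muro):
        p = trough_patient(muro, np.asarray([0.6]), n_obs=3, noise=0.1)
        res = mp.forecast_third_interval(muro, p, "none")
        t3 = p.sorted_observations()[2].time
        assert res.predict([t3])[0] == pytest.approx(
            mp.predict(muro, p, None)[2])

    def test_most_recent_only_ignores_first_observation(self, muro):
        p = trough_patient(muro, np.asarray([0.6]), n_obs=3, noise=0.1)
        q = copy.copy(p)
        obs = p.sorted_observations()
        q.observations = [mp.Observation(obs[0].time, obs[0].concentration * 3),
                          obs[1], obs[2]]
        t3 = obs[2].time
        a = mp.forecast_third_interval(muro, p, "most_recent_only")
        b = mp.forecast_third_interval(muro, q, "most_recent_only")
        assert a.predict([t3])[0] == pytest.approx(b.predict([t3])[0])
        # while first_and_second does react to it
        c = mp.forecast_third_interval(muro, p, "first_and_second")
        d = mp.forecast_third_interval(muro, q, "first_and_second")
        assert c.predict([t3])[0] != pytest.approx(d.predict([t3])[0])

    def test_requires_three_observations(self, muro):
        p = trough_patient(muro, np.asarray([0.0]), n_obs=2)
        with pytest.raises(ValueError, match="three"):
            mp.forecast_third_interval(muro, p)

    def test_unknown_mode_rejected(self, muro):
        p = trough_patient(muro, np.asarray([0.0]), n_obs=3)
        with pytest.raises(ValueError):
            mp.forecast_third_interval(muro, p, "everything")

    def test_one_prior_improves_over_a_priori(self, muro):
        """Conditioning on the previous level reduces mean squared IPE%
        when the model generated the data (replicated synthetic patients)."""
        rng = np.random.default_rng(42)
        omega_sd = float(np.sqrt(muro.omega()[0, 0]))
        sq = {"none": [], "most_recent_only": []}
        for i in range(60):
            eta = rng.normal(0, omega_sd)
            p = trough_patient(muro, np.asarray([eta]), n_obs=3, noise=0.15,
                               seed=1000 + i)
            t3, o3 = p.observations[2].time, p.observations[2].concentration
            for mode in sq:
                pred = mp.forecast_third_interval(muro, p, mode).predict([t3])[0]
                sq[mode].append(mp.ipe_percent(max(pred, 1e-9), o3) ** 2)
        assert np.mean(sq["most_recent_only"]) <= np.mean(sq["none"])


class TestEbeAdequacy:
    def test_zero_observation_patients_fully_shrunk(self, muro, small_cohort):
        pts = [copy.copy(p) for p in small_cohort[:20]]
        for p in pts:
            p.observations = []
        res = mp.ebe_adequacy(muro, pts)
        assert np.all(res.parameters["cl"]["sample"] == 0.0)

    def test_sparse_sampling_shrinks_variance(self, muro):
        """One trough per patient: the EBE sample is narrower than N(0, ω²)."""
        rng = np.random.default_rng(1)
        w = float(np.sqrt(muro.omega()[0, 0]))
        pts = [trough_patient(muro, np.asarray([rng.normal(0, w)]), n_obs=1,
                              noise=0.2, seed=3000 + i) for i in range(120)]
        res = mp.ebe_adequacy(muro, pts)
        d = res.parameters["cl"]
        assert np.var(d["sample"], ddof=1) < d["omega_sd"] ** 2
        assert 0 < d["shrinkage"] < 1

    def test_rich_sampling_recovers_percentiles(self, muro):
        rng = np.random.default_rng(7)
        omega_sd = float(np.sqrt(muro.omega()[0, 0]))
        true_eta = rng.normal(0, omega_sd, size=300)
        pts = [
            trough_patient(muro, np.asarray([e]), n_obs=6, noise=0.1,
                           seed=2000 + i)
            for i, e in enumerate(true_eta)
        ]
        res = mp.ebe_adequacy(muro, pts)
        d = res.parameters["cl"]
        # with 6 samples per patient the EBEs track the generator draw closely
        assert np.corrcoef(true_eta, d["sample"])[0, 1] >= 0.95
        # and their 20th/80th percentiles sit near the theoretical N(0, ω²)
        # ones, up to the Monte-Carlo noise of 300 draws
        assert d["est_p20"] == pytest.approx(d["theo_p20"], rel=0.2)
        assert d["est_p80"] == pytest.approx(d["theo_p80"], rel=0.2)

    def test_needs_enough_patients(self, muro, small_cohort):
        with pytest.raises(ValueError, match="20"):
            mp.ebe_adequacy(muro, small_cohort[:5])

    def test_parameters_without_iiv_are_noted(self, muro, small_cohort):
        res = mp.ebe_adequacy(muro, small_cohort)
        assert "v1" in res.skipped  # the model prints IIV for CL only
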