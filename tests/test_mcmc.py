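import numpy as np
import pandas as pd
import pytest

from ntrace.mcmc import (ParameterSpec, log_prior, log_probability,
                         metropolis_accept, perturb_observations, propose,
                         run_mcmc)
from ntrace.observations import ObservationSet


def _tiny_obs(values=(1.0, 2.0), sd=0.2, ef=(3.0,), ef_sd=0.4):
    series = pd.DataFrame({
        "group": ["mr"] * len(values) + ["d15n"] * len(values)
        + ["sp"] * len(values),
        "bin_left": list(range(len(values))) * 3,
        "bin_right": [v + 1 for v in range(len(values))] * 3,
        "mean": list(values) * 3,
        "sd": [sd] * (3 * len(values)),
        "n": [4] * (3 * len(values)),
    })
    zone = pd.DataFrame({"zone": range(len(ef)), "mean": ef,
                         "sd": [ef_sd] * len(ef), "n": [5] * len(ef)})
    floors = {"mr": 0.0, "d15n": 0.0, "sp": 0.0, "ef": 0.0}
    return ObservationSet(series, zone, floors)


class TestPropose:
    def test_zero_stepsize_is_identity(self, rng):
        specs = [ParameterSpec("a", "gaussian", 1.0, 0.5),
                 ParameterSpec("b", "uniform", 0.0, 1.0)]
        cur = {"a": 1.2, "b": 0.4}
        assert propose(cur, specs, 0.0, rng) == cur

    def test_gaussian_step_rule(self):
        # shift = sigma * stepsize * r with r ~ U(-1, 1)
        spec = ParameterSpec("a", "gaussian", 0.0, 2.0)
        rng = np.random.default_rng(5)
        r = np.random.default_rng(5).uniform(-1.0, 1.0)
        out = propose({"a": 1.0}, [spec], 0.5, rng)
        assert out["a"] == pytest.approx(1.0 + 2.0 * 0.5 * r)

    def test_uniform_step_rule_quarter_range(self):
        spec = ParameterSpec("b", "uniform", 0.0, 1.0)
        rng = np.random.default_rng(9)
        r = np.random.default_rng(9).uniform(-1.0, 1.0)
        out = propose({"b": 0.5}, [spec], 0.25, rng)
        assert out["b"] == pytest.approx(0.5 + 0.25 * 0.25 * r)
        # worst case |shift| = range/4 * stepsize
        assert abs(out["b"] - 0.5) <= 0.0625

    def test_independent_draws_per_parameter(self, rng):
        specs = [ParameterSpec(n, "gaussian", 0.0, 1.0) for n in "abcd"]
        cur = {n: 0.0 for n in "abcd"}
        shifts = np.array([[propose(cur, specs, 1.0, rng)[n] for n in "abcd"]
                           for _ in range(2000)])
        corr = np.corrcoef(shifts.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpec("x", "uniform", 1.0, 0.5)
        with pytest.raises(ValueError):
            ParameterSpec("x", "gaussian", 0.0, 0.0)
        with pytest.raises(ValueError):
            ParameterSpec("x", "lognormal", 0.0, 1.0)


class TestLogPrior:
    def test_gaussian_quadratic(self):
        specs = [ParameterSpec("a", "gaussian", 2.0, 0.5)]
        assert log_prior({"a": 2.0}, specs) == 0.0
        assert log_prior({"a": 2.5}, specs) == pytest.approx(-0.5)

    def test_uniform_bounds(self):
        specs = [ParameterSpec("b", "uniform", 0.3, 1.0)]
        assert log_prior({"b": 0.7}, specs) == 0.0
        assert log_prior({"b": 1.5}, specs) == -np.inf


class TestPerturbObservations:
    def test_zero_stepsize_unchanged(self, rng):
        obs = _tiny_obs()
        shifted, draws, logp = perturb_observations(obs, 0.0, rng)
        assert np.allclose(shifted.series["mean"], obs.series["mean"])
        assert logp == 0.0

    def test_shared_draw_within_group(self, rng):
        obs = _tiny_obs(values=(1.0, 2.0), sd=0.5)
        shifted, draws, _ = perturb_observations(obs, 1.0, rng)
        m = obs.series["group"] == "mr"
        delta = (shifted.series.loc[m, "mean"]
                 - obs.series.loc[m, "mean"]).to_numpy()
        # same sign and same scale factor (sd is uniform within the group)
        assert np.allclose(delta, delta[0])
        assert delta[0] == pytest.approx(0.5 * draws["mr"])

    def test_groups_independent_over_many_iterations(self):
        obs = _tiny_obs()
        rng = np.random.default_rng(0)
        draws = np.array([[perturb_observations(obs, 1.0, rng)[1][g]
                           for g in ("mr", "d15n", "sp", "ef")]
                          for _ in range(4000)])
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.06


class TestLogProbability:
    def test_exact_match_zero_misfit(self):
        obs = _tiny_obs()
        assert log_probability(obs.values_vector(), obs) == 0.0

    def test_one_sigma_contributes_half(self):
        obs = _tiny_obs(values=(1.0,), sd=0.2, ef=(3.0,), ef_sd=0.4)
        vals = obs.values_vector()
        vals["mr"] = vals["mr"] + 0.2
        assert log_probability(vals, obs) == pytest.approx(-0.5)

    def test_total_matches_brute_force_sum(self, rng):
        obs = _tiny_obs(values=(1.0, 2.0, 3.0), sd=0.3, ef=(2.0, 4.0), ef_sd=0.5)
        vals = obs.values_vector()
        noisy = {g: v + rng.normal(0, 0.5, size=len(v))
                 for g, v in vals.items()}
        expect = 0.0
        for g in ("mr", "d15n", "sp", "ef"):
            sig = obs.total_sigma()[g]
            expect += -0.5 * np.sum(((noisy[g] - vals[g]) / sig) ** 2)
        assert log_probability(noisy, obs) == pytest.approx(expect)

    def test_model_error_floor_enters_in_quadrature(self):
        obs = _tiny_obs(values=(1.0,), sd=0.3)
        obs.floors["mr"] = 0.4
        vals = obs.values_vector()
        vals["mr"] = vals["mr"] + 0.5  # one sigma_total = sqrt(.09+.16)
        assert log_probability(vals, obs) == pytest.approx(-0.5)


class TestMetropolisAccept:
    def test_improvement_always_accepted(self, rng):
        assert metropolis_accept(-1.0, -5.0, rng)

    def test_minus_infinity_never_accepted(self, rng):
        assert not metropolis_accept(-np.inf, -1.0, rng)

    def test_half_acceptance_at_log_two_deficit(self):
        rng = np.random.default_rng(123)
        n = 10000
        acc = sum(metropolis_accept(-np.log(2.0), 0.0, rng) for _ in range(n))
        assert abs(acc / n - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestRunMCMC:
    def test_flat_likelihood_recovers_prior(self):
        # constant likelihood: chain samples the prior; acceptance ~ 1
        specs = [ParameterSpec("a", "gaussian", 1.0, 0.2)]
        obs = _tiny_obs()

        def forward(params):
            return obs.values_vector()

        res = run_mcmc(forward, specs, obs, schedule=(0.5,), block=4000,
                       seed=1)
        assert res.acceptance_rate > 0.8
        assert res.posterior.loc["a", "mean"] == pytest.approx(1.0, abs=0.05)
        assert res.posterior.loc["a", "sd"] == pytest.approx(0.2, abs=0.05)

    def test_matches_reference_metropolis_on_gaussian_target(self):
        # 1-D Gaussian likelihood around 0.5 with sigma 0.1: compare the
        # posterior against an independent textbook random-walk Metropolis
        target_mu, target_sd = 0.5, 0.1
        series = pd.DataFrame({"group": ["mr"], "bin_left": [0],
                               "bin_right": [1], "mean": [target_mu],
                               "sd": [target_sd], "n": [10]})
        zone = pd.DataFrame({"zone": [], "mean": [], "sd": [], "n": []})
        obs = ObservationSet(series, zone,
                             {"mr": 0.0, "d15n": 0.0, "sp": 0.0, "ef": 0.0})
        spec = ParameterSpec("x", "uniform", -2.0, 3.0, init=0.5)

        def forward(params):
            return {"mr": np.array([params["x"]]), "d15n": np.array([]),
                    "sp": np.array([]), "ef": np.array([])}

        res = run_mcmc(forward, spec and [spec], obs, schedule=(0.25,),
                       block=6000, seed=2)
        acc = res.accepted()["x"].to_numpy()

        rng = np.random.default_rng(3)
        x, kept = 0.5, []
        logp = lambda v: (-0.5 * ((v - target_mu) / target_sd) ** 2
                          if -2 <= v <= 3 else -np.inf)
        lp = logp(x)
        for _ in range(20000):
            prop = x + rng.uniform(-1, 1) * (5.0 / 4) * 0.25
            lp_new = logp(prop)
            if lp_new >= lp or rng.random() < np.exp(lp_new - lp):
                x, lp = prop, lp_new
            kept.append(x)
        ref = np.asarray(kept[2000:])
        se = target_sd / np.sqrt(len(acc) / 10)  # generous autocorr penalty
        assert acc.mean() == pytest.approx(ref.mean(), abs=4 * se)
        assert acc.std() == pytest.approx(ref.std(), rel=0.3)

    def test_same_seed_reproduces_chain(self):
        specs = [ParameterSpec("a", "gaussian", 0.0, 1.0)]
        obs = _tiny_obs()

        def forward(params):
            vals = obs.values_vector()
            vals = {k: v + params["a"] * 0.1 for k, v in vals.items()}
            return vals

        r1 = run_mcmc(forward, specs, obs, schedule=(0.5, 0.25), block=200,
                      seed=7)
        r2 = run_mcmc(forward, specs, obs, schedule=(0.5, 0.25), block=200,
                      seed=7)
        pd.testing.assert_frame_equal(r1.chain, r2.chain)

    def test_stepsize_schedule_cycles_in_blocks(self):
        specs = [ParameterSpec("a", "gaussian", 0.0, 1.0)]
        obs = _tiny_obs()
        res = run_mcmc(lambda p: obs.values_vector(), specs, obs,
                       schedule=(0.75, 0.5, 0.25), block=100, seed=0)
        steps = res.chain["stepsize"].to_numpy()
        assert np.all(steps[:100] == 0.75)
        assert np.all(steps[100:200] == 0.5)
        assert np.all(steps[200:300] == 0.25)

    def test_total_must_divide_into_blocks(self):
        specs = [ParameterSpec("a", "gaussian", 0.0, 1.0)]
        obs = _tiny_obs()
        with pytest.raises(ValueError):
            run_mcmc(lambda p: obs.values_vector(), specs, obs,
                     schedule=(0.5,), block=100, total=150, seed=0)

    def test_posterior_sd_not_wider_than_prior_when_data_informative(self):
        # a tightly observed quantity shrinks the posterior
        spec = ParameterSpec("a", "gaussian", 0.0, 1.0)
        series = pd.DataFrame({"group": ["mr"], "bin_left": [0],
                               "bin_right": [1], "mean": [0.3],
                               "sd": [0.05], "n": [10]})
        zone = pd.DataFrame({"zone": [], "mean": [], "sd": [], "n": []})
        obs = ObservationSet(series, zone,
                             {"mr": 0.0, "d15n": 0.0, "sp": 0.0, "ef": 0.0})

        def forward(params):
            return {"mr": np.array([params["a"]]), "d15n": np.array([]),
                    "sp": np.array([]), "ef": np.array([])}

        res = run_mcmc(forward, [spec], obs, schedule=(0.5, 0.25), block=2000,
                       seed=4)
        assert res.posterior.loc["a", "sd"] < 1.0
        assert res.posterior.loc["a", "mean"] == pytest.approx(0.3, abs=0.05)
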