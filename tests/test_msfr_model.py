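"""Functional-response math, likelihood, availability draws, MCMC, DIC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msfr.msfr_model import (
    DietObservations,
    MSFRParams,
    compute_dic,
    dirichlet_loglik,
    draw_availability,
    fit_mcmc,
    log_likelihood,
    msfr_proportions,
    response_curves,
    subset_proportions,
    truncated_normal_mean,
)
from msfr.synthetic_data import simulate_diet_observations


def make_params(a=(1.0, 0.5, 0.25), m=1.0):
    names = ["sandeel", "whiting", "cod"][: len(a)]
    return MSFRParams(dict(zip(names, a)), shape_m=m)


class TestProportions:
    def test_symmetry_equal_inputs(self):
        p = MSFRParams({"sandeel": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        out = msfr_proportions(p, {s: 50.0 for s in p.species})
        for v in out.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_hand_evaluated_two_species_type_ii(self):
        # a=(1, 0.25), m=1, B=(80, 20): shares 80/(80+5)=0.941, 5/85=0.059
        p = MSFRParams({"sandeel": 1.0, "whiting": 0.25}, shape_m=1.0)
        out = msfr_proportions(p, {"sandeel": 80.0, "whiting": 20.0})
        assert out["sandeel"] == pytest.approx(80 / 85, abs=1e-12)
        assert out["whiting"] == pytest.approx(5 / 85, abs=1e-12)

    def test_hand_evaluated_type_iii_equal_availability(self):
        # a=(1, 0.238), m=1.5, B=(100,100): p = (1, 0.238)/1.238
        p = MSFRParams({"sandeel": 1.0, "sprat": 0.238}, shape_m=1.5)
        out = msfr_proportions(p, {"sandeel": 100.0, "sprat": 100.0})
        assert out["sandeel"] == pytest.approx(1 / 1.238, abs=1e-9)
        assert out["sprat"] == pytest.approx(0.238 / 1.238, abs=1e-9)

    def test_zero_availability_zero_share(self):
        p = make_params()
        out = msfr_proportions(p, {"sandeel": 0.0, "whiting": 30.0, "cod": 30.0})
        assert out["sandeel"] == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            msfr_proportions(make_params(), {"sandeel": 0.0, "whiting": 0.0, "cod": 0.0})

    def test_sums_to_one_and_scale_invariances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform(0.05, 5.0, 4)
            a[0] = 1.0
            m = rng.choice([1.0, 1.5, 2.0])
            B = rng.uniform(0.0, 100.0, 4)
            if (a * B**m).sum() == 0:
                continue
            names = ["sandeel", "b", "c", "d"]
            p1 = msfr_proportions(MSFRParams(dict(zip(names, a)), shape_m=m),
                                  dict(zip(names, B)))
            assert sum(p1.values()) == pytest.approx(1.0, abs=1e-12)
            # common rescaling of B leaves proportions unchanged
            p2 = msfr_proportions(MSFRParams(dict(zip(names, a)), shape_m=m),
                                  dict(zip(names, 7.3 * B)))
            for s in names:
                assert p2[s] == pytest.approx(p1[s], abs=1e-12)


class TestSubsetIdentity:
    def test_full_subset_is_identity(self):
        p = make_params((1.0, 0.5, 0.25), m=1.5)
        B = {"sandeel": 40.0, "whiting": 70.0, "cod": 10.0}
        full = msfr_proportions(p, B)
        sub = subset_proportions(p, B, p.species)
        for s in p.species:
            assert sub[s] == pytest.approx(full[s], abs=1e-15)

    def test_pairwise_ratio_preserved(self):
        p = make_params((1.0, 0.5, 0.25), m=1.5)
        B = {"sandeel": 40.0, "whiting": 70.0, "cod": 10.0}
        full = msfr_proportions(p, B)
        sub = subset_proportions(p, B, ["whiting", "cod"])
        assert sub["whiting"] / sub["cod"] == pytest.approx(
            full["whiting"] / full["cod"], rel=1e-12)

    def test_fuzz_restricted_renormalised(self):
        rng = np.random.default_rng(42)
        names = ["sandeel", "s1", "s2", "s3", "s4"]
        worst = 0.0
        for _ in range(100):
            a = np.concatenate([[1.0], rng.uniform(0.01, 8.0, 4)])
            m = float(rng.uniform(1.0, 2.0))
            B = rng.uniform(0.5, 100.0, 5)
            params = MSFRParams(dict(zip(names, a)), shape_m=m)
            Bd = dict(zip(names, B))
            k = int(rng.integers(2, 5))
            subset = list(rng.choice(names, size=k, replace=False))
            full = msfr_proportions(params, Bd)
            denom = sum(full[s] for s in subset)
            expected = {s: full[s] / denom for s in subset}
            got = subset_proportions(params, Bd, subset)
            worst = max(worst, max(abs(got[s] - expected[s]) for s in subset))
        assert worst < 1e-12


class TestSwitchingDiagnostic:
    """m=1: preference ratio constant in availability; m>1: increasing."""

    @staticmethod
    def preference_ratio(m, b1, b2=50.0, a1=1.0, a2=0.4):
        p = MSFRParams({"sandeel": a1, "whiting": a2}, shape_m=m)
        out = msfr_proportions(p, {"sandeel": b1, "whiting": b2})
        return (out["sandeel"] / out["whiting"]) / (b1 / b2)

    def test_type_ii_ratio_constant(self):
        grid = np.linspace(1.0, 100.0, 25)
        ratios = [self.preference_ratio(1.0, b) for b in grid]
        assert max(ratios) - min(ratios) < 1e-9

    def test_type_iii_ratio_strictly_increasing(self):
        grid = np.linspace(1.0, 100.0, 25)
        ratios = [self.preference_ratio(1.5, b) for b in grid]
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))


class TestLikelihood:
    def _obs(self, n=4):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(3) * 5, size=n)
        B = rng.uniform(10, 90, size=(n, 3))
        return DietObservations(["sandeel", "whiting", "cod"], P, B, 0.1 * B)

    def test_two_identical_observations_double_loglik(self):
        obs1 = self._obs(1)
        P2 = np.vstack([obs1.proportions, obs1.proportions])
        B2 = np.vstack([obs1.avail_mean, obs1.avail_mean])
        obs2 = DietObservations(obs1.species, P2, B2, 0.1 * B2)
        p = make_params()
        assert log_likelihood(p, obs2, 50.0) == pytest.approx(
            2 * log_likelihood(p, obs1, 50.0), rel=1e-12)

    def test_label_permutation_invariance(self):
        obs = self._obs()
        perm = [2, 0, 1]
        species_p = [obs.species[i] for i in perm]
        obs_p = DietObservations(species_p, obs.proportions[:, perm],
                                 obs.avail_mean[:, perm], obs.avail_sd[:, perm])
        p = make_params((1.0, 0.5, 0.25), m=1.5)
        p_perm = MSFRParams({s: p.attack_rates[s] for s in species_p}, shape_m=1.5)
        assert log_likelihood(p_perm, obs_p, 30.0) == pytest.approx(
            log_likelihood(p, obs, 30.0), rel=1e-12)

    def test_concentration_rewards_exact_fit(self):
        # observed == predicted: loglik increases monotonically in tau
        p = make_params((1.0, 0.5, 0.25), m=1.0)
        B = np.array([[60.0, 30.0, 10.0]])
        pred = np.array([list(msfr_proportions(p, dict(zip(p.species, B[0]))).values())])
        obs = DietObservations(p.species, pred, B, np.zeros_like(B))
        lls = [log_likelihood(p, obs, t) for t in (5.0, 50.0, 500.0, 5000.0)]
        assert all(b > a for a, b in zip(lls, lls[1:]))

    def test_invalid_tau_raises(self):
        with pytest.raises(ValueError):
            dirichlet_loglik(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]), 0.0)


class TestAvailabilityDraws:
    def test_zero_sd_returns_mean(self, rng):
        obs = DietObservations(["sandeel", "b"], np.array([[0.6, 0.4]]),
                               np.array([[30.0, 5.0]]), np.zeros((1, 2)))
        d = draw_availability(obs, rng)
        np.testing.assert_array_equal(d, obs.avail_mean)

    def test_draws_nonnegative(self, rng):
        n = 200
        obs = DietObservations(
            ["sandeel", "b"], np.full((n, 2), 0.5),
            np.full((n, 2), 0.5), np.full((n, 2), 2.0))
        for _ in range(20):
            assert np.all(draw_availability(obs, rng) >= 0)

    def test_truncated_mean_closed_form(self):
        # mean 1, sd 1 truncated at 0: mean = 1 + phi(-1)/(1-Phi(-1)) = 1.2876
        n = 1_000_000
        obs = DietObservations(["sandeel", "b"], np.full((n, 2), 0.5),
                               np.full((n, 2), 1.0), np.full((n, 2), 1.0))
        d = draw_availability(obs, np.random.default_rng(5))[:, 0]
        expect = truncated_normal_mean(1.0, 1.0)
        assert expect == pytest.approx(1.2876, abs=1e-4)
        se = d.std() / np.sqrt(n)
        assert abs(d.mean() - expect) < 3 * se


TRUE_A = {"sandeel": 1.0, "whiting": 0.5, "cod": 0.25, "herring": 0.1}


class TestMCMC:
    @pytest.fixture(scope="class")
    def fitted(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.5, n=300, tau=80.0, seed=3)
        sample = fit_mcmc(obs, shape_m=1.5, chains=2, iterations=1500, burn_in=300, seed=9)
        return obs, sample

    def test_parameter_recovery_single_dataset(self, fitted):
        _, sample = fitted
        for sp in sample.free_species:
            lo, hi = sample.credible_interval(sp)
            assert lo <= TRUE_A[sp] <= hi, f"{sp}: [{lo:.3f}, {hi:.3f}] misses {TRUE_A[sp]}"

    def test_chains_mix(self, fitted):
        _, sample = fitted
        assert all(r < 1.1 for r in sample.rhat.values())
        assert np.all(sample.acceptance_rate > 0.05)

    def test_determinism_under_seed(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.0, n=60, tau=60.0, seed=1)
        s1 = fit_mcmc(obs, shape_m=1.0, iterations=200, burn_in=50, seed=4)
        s2 = fit_mcmc(obs, shape_m=1.0, iterations=200, burn_in=50, seed=4)
        np.testing.assert_array_equal(s1.a_draws, s2.a_draws)
        np.testing.assert_array_equal(s1.deviance, s2.deviance)

    def test_single_free_species_self_consistency(self):
        # data generated at a = 1 for the free species: posterior near 1
        a = {"sandeel": 1.0, "whiting": 1.0}
        obs = simulate_diet_observations(a, shape_m=1.0, n=250, tau=100.0,
                                         avail_cv=0.0, seed=8)
        sample = fit_mcmc(obs, shape_m=1.0, iterations=1500, burn_in=300, seed=2)
        lo, hi = sample.credible_interval("whiting")
        assert lo <= 1.0 <= hi
        assert sample.summary().set_index("species").loc["whiting", "mean"] == pytest.approx(
            1.0, abs=0.15)

    def test_reference_validation(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.0, n=20, seed=0)
        with pytest.raises(ValueError):
            fit_mcmc(obs, shape_m=1.0, reference="not_a_species")


class TestDIC:
    def test_decomposition_identity_and_duplicate_additivity(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.0, n=80, tau=60.0, seed=5)
        sample = fit_mcmc(obs, shape_m=1.0, iterations=400, burn_in=100, seed=6)
        entry = compute_dic(sample, obs)
        assert entry.dic == pytest.approx(entry.dbar + entry.p_d, abs=1e-9)
        # doubling the dataset doubles the mean deviance at fixed draws
        P2 = np.vstack([obs.proportions, obs.proportions])
        M2 = np.vstack([obs.avail_mean, obs.avail_mean])
        S2 = np.vstack([obs.avail_sd, obs.avail_sd])
        obs2 = DietObservations(obs.species, P2, M2, S2)
        sample2 = fit_mcmc(obs2, shape_m=1.0, iterations=400, burn_in=100, seed=6)
        # same parameter draws are not guaranteed, so check the plug-in
        # deviance doubles exactly for the same parameter values
        params = sample.posterior_mean()
        tau = float(sample.tau_draws.mean())
        from msfr.msfr_model import log_likelihood as ll

        assert -2 * ll(params, obs2, tau) == pytest.approx(-4 * ll(params, obs, tau), rel=1e-12)

    def test_degenerate_posterior_pd_zero(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.0, n=40, tau=60.0, seed=5)
        sample = fit_mcmc(obs, shape_m=1.0, iterations=200, burn_in=50, seed=6)
        # collapse all draws to the posterior mean -> pD = 0, DIC = Dbar
        mean_a = sample.flat_a.mean(axis=0)
        sample.a_draws = np.tile(mean_a, (sample.a_draws.shape[0], sample.a_draws.shape[1], 1))
        sample.tau_draws = np.full_like(sample.tau_draws, sample.tau_draws.mean())
        params = sample.posterior_mean()
        tau = float(sample.tau_draws.mean())
        d = -2 * log_likelihood(params, obs, tau)
        sample.deviance = np.full_like(sample.deviance, d)
        entry = compute_dic(sample, obs)
        assert entry.p_d == pytest.approx(0.0, abs=1e-6)
        assert entry.dic == pytest.approx(entry.dbar, abs=1e-6)


class TestResponseCurves:
    @pytest.fixture(scope="class")
    def sample(self):
        obs = simulate_diet_observations(TRUE_A, shape_m=1.5, n=150, tau=80.0, seed=3)
        return obs, fit_mcmc(obs, shape_m=1.5, iterations=800, burn_in=200, seed=9)

    def test_zero_availability_zero_share(self, sample):
        obs, s = sample
        curves = response_curves(s, "whiting", obs=obs, seed=1)
        at_zero = curves[curves["availability"] == 0.0]
        assert np.allclose(at_zero["mean"], 0.0)

    def test_monotone_in_focal_availability(self, sample):
        obs, s = sample
        curves = response_curves(s, "whiting", obs=obs, seed=1)
        for _, grp in curves.groupby("alt_level"):
            m = grp.sort_values("availability")["mean"].to_numpy()
            assert np.all(np.diff(m) >= -1e-12)

    def test_more_alternative_prey_lowers_focal_share(self, sample):
        obs, s = sample
        curves = response_curves(s, "whiting",
                                 alt_levels={"min": 5.0, "mean": 50.0, "max": 100.0}, seed=1)
        wide = curves.pivot(index="availability", columns="alt_level", values="mean")
        pos = wide.index > 0
        assert np.all(wide.loc[pos, "min"] > wide.loc[pos, "mean"])
        assert np.all(wide.loc[pos, "mean"] > wide.loc[pos, "max"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=st.lists(st.floats(0.05, 5.0), min_size=2, max_size=5),
    b=st.lists(st.floats(0.1, 100.0), min_size=5, max_size=5),
    m=st.sampled_from([1.0, 1.5, 2.0]),
)
def test_proportions_property_sum_and_bounds(a, b, m):
    names = [f"s{i}" for i in range(len(a))]
    params = MSFRParams(dict(zip(names, a)), shape_m=m, reference=names[0]) \
        if abs(a[0] - 1) < 1e-12 else MSFRParams({**dict(zip(names, a)), names[0]: a[0]},
                                                 shape_m=m, reference="__none__")
    out = msfr_proportions(params, dict(zip(names, b[: len(a)])))
    assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= v <= 1.0 for v in out.values())
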