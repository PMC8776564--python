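"""The nearest-distance classifier and its exact enumeration oracle."""

import math

import numpy as np
import pytest

import whatwhere as ww
from whatwhere.classify import NonTargetPool


def make_trial(target=(100.0, 100.0), nontargets=((900.0, 900.0), (300.0, 1500.0)),
               trial_id=0):
    return ww.TrialSpec(
        trial_id=trial_id, set_size=1 + len(nontargets), delay_s=1.0,
        target_id=0, target_loc=tuple(map(float, target)),
        nontarget_locs=tuple(tuple(map(float, nt)) for nt in nontargets),
        foil_id=999,
    )


def make_pool(points, source=1):
    pts = np.asarray(points, dtype=float)
    return NonTargetPool(pts, np.full(len(pts), source))


class TestEuclidean:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((0, 0), (0, 0), 0.0),
         ((0, 0), (3, 4), 5.0),
         ((0, 0), (1536, 2048), 2560.0)],
    )
    def test_known_distances(self, a, b, expected):
        assert ww.euclidean(a, b) == pytest.approx(expected)

    def test_symmetry_and_separation(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 2000, (2, 2))
            assert ww.euclidean(a, b) == ww.euclidean(b, a) >= 0
        assert ww.euclidean((1, 2), (1, 2)) == 0.0

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            ww.euclidean((0, math.nan), (1, 1))


class TestClassifyTrial:
    def test_response_at_target_is_pure_target(self, rng):
        trial = make_trial()
        pool = make_pool([(500, 500), (1000, 2000)])
        res = ww.classify_trial(trial.target_loc, trial, pool, 100, rng)
        assert res.p_target_hat == 1.0
        assert res.d_target == 0.0

    def test_response_at_nontarget_is_pure_misbind(self, rng):
        trial = make_trial()
        pool = make_pool([(500, 500), (1400, 100)])
        res = ww.classify_trial((900, 900), trial, pool, 100, rng)
        assert res.p_misbind_hat == 1.0

    def test_probabilities_sum_to_one_exactly(self, rng):
        trial = make_trial()
        pool = make_pool(rng.uniform(0, 1500, (30, 2)))
        for _ in range(10):
            resp = rng.uniform(0, 1500, 2)
            res = ww.classify_trial(resp, trial, pool, 97, rng)
            total = res.p_target_hat + res.p_misbind_hat + res.p_guess_hat
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_set_size_one_has_zero_misbinding(self, rng):
        trial = make_trial(nontargets=())
        pool = make_pool([(50, 50), (1400, 1900)])
        res = ww.classify_trial((60, 60), trial, pool, 200, rng)
        assert res.p_misbind_hat == 0.0
        assert res.d_nearest_nontarget is None

    def test_monte_carlo_matches_enumeration_on_fixed_geometry(self):
        """Spec'd small geometry: MC within 3 binomial SE of the exact pool
        fractions at 5000 resamples."""
        trial = make_trial(target=(100, 100), nontargets=((900, 900), (1500, 2000)))
        pool = make_pool(
            [(700, 700), (800, 850), (120, 90), (1300, 200), (60, 1800),
             (850, 750), (140, 160), (900, 1000), (400, 400), (820, 820)]
        )
        response = (800.0, 800.0)
        exact = ww.classify_trial_exact(response, trial, pool)
        mc = ww.classify_trial(response, trial, pool, 5000,
                               np.random.default_rng(1))
        for pe, pm in [(exact.p_target_hat, mc.p_target_hat),
                       (exact.p_misbind_hat, mc.p_misbind_hat),
                       (exact.p_guess_hat, mc.p_guess_hat)]:
            se = math.sqrt(pe * (1 - pe) / 5000)
            assert abs(pm - pe) <= max(3 * se, 1e-12)

    def test_law_of_large_numbers_convergence(self):
        """MC at n=1e6 converges to the exact expectation within 3 SE."""
        rng = np.random.default_rng(4)
        trial = make_trial()
        pool = make_pool(rng.uniform(100, 1400, (40, 2)))
        resp = (600.0, 700.0)
        exact = ww.classify_trial_exact(resp, trial, pool)
        mc = ww.classify_trial(resp, trial, pool, 10**6, rng)
        for pe, pm in [(exact.p_target_hat, mc.p_target_hat),
                       (exact.p_misbind_hat, mc.p_misbind_hat),
                       (exact.p_guess_hat, mc.p_guess_hat)]:
            se = math.sqrt(pe * (1 - pe) / 10**6)
            assert abs(pm - pe) <= max(3 * se, 1e-12)

    def test_tie_break_prefers_target_then_misbind(self, rng):
        # response equidistant from target and non-target; pool point at the
        # same distance as well: everything resolves to target
        trial = make_trial(target=(0, 100), nontargets=((0, -100), (4000, 4000)))
        pool = make_pool([(100, 0)])  # also at distance 100 from the origin
        res = ww.classify_trial((0, 0), trial, pool, 50, rng)
        assert res.p_target_hat == 1.0
        # without the target, the displayed non-target beats the tied pool point
        exact = ww.classify_trial_exact((0, 0), make_trial(target=(0, 5000),
                                                           nontargets=((0, -100), (4000, 4000))),
                                        pool)
        assert exact.p_misbind_hat == 1.0

    def test_nontarget_order_is_irrelevant(self, rng):
        pool = make_pool(rng.uniform(0, 1500, (25, 2)))
        a = make_trial(nontargets=((900, 900), (300, 1500)))
        b = make_trial(nontargets=((300, 1500), (900, 900)))
        resp = (500.0, 800.0)
        ra = ww.classify_trial_exact(resp, a, pool)
        rb = ww.classify_trial_exact(resp, b, pool)
        assert ra == rb

    def test_empty_pool_and_nan_raise(self, rng):
        trial = make_trial()
        with pytest.raises(ValueError):
            NonTargetPool(np.empty((0, 2)), np.empty(0))
        pool = make_pool([(1, 1)], source=trial.trial_id)  # own trial only
        with pytest.raises(ValueError):
            ww.classify_trial((5, 5), trial, pool, 10, rng)
        good = make_pool([(1, 1)])
        with pytest.raises(ValueError):
            ww.classify_trial((math.nan, 5), trial, good, 10, rng)


class TestExactOracle:
    def test_all_pool_points_farther_gives_pure_target(self):
        trial = make_trial(target=(500, 500), nontargets=((1400, 1900), (100, 1900)))
        pool = make_pool([(100, 1900), (1400, 100)])
        res = ww.classify_trial_exact((510, 505), trial, pool)
        assert (res.p_target_hat, res.p_misbind_hat, res.p_guess_hat) == (1, 0, 0)

    def test_all_pool_points_nearer_gives_pure_guess(self):
        trial = make_trial(target=(100, 100), nontargets=((1400, 1900), (100, 1900)))
        pool = make_pool([(750, 1000), (760, 990), (745, 1010)])
        res = ww.classify_trial_exact((750, 1000), trial, pool)
        assert (res.p_target_hat, res.p_misbind_hat, res.p_guess_hat) == (0, 0, 1)

    def test_mixed_pool_fractions(self):
        trial = make_trial(target=(0, 0), nontargets=())
        # response at (100, 0): d_target = 100; 2 of 4 pool points nearer
        pool = make_pool([(110, 0), (250, 0), (500, 500), (90, 0)])
        res = ww.classify_trial_exact((100, 0), trial, pool)
        assert res.p_guess_hat == pytest.approx(0.5)
        assert res.p_target_hat == pytest.approx(0.5)


class TestClassifySession:
    def test_incorrect_identifications_are_excluded_by_default(
        self, simulated_session
    ):
        pt, _ = ww.classify_session(simulated_session, n_resamples=10, seed=0)
        n_correct = sum(r.identification_correct for _, r in simulated_session)
        assert len(pt) == n_correct
        pt_all, _ = ww.classify_session(simulated_session, n_resamples=10,
                                        seed=0, include_incorrect=True)
        assert len(pt_all) == len(simulated_session)

    def test_all_incorrect_yields_empty_result(self, schedule, rng):
        params = ww.MixtureParams(1.0, 0.0, 0.0, p_identify=0.5)
        responses = ww.simulate_session(schedule[:8], params, rng)
        forced = [
            (t, ww.TrialResponse(r.trial_id, t.foil_id, False, r.response_loc,
                                 r.rt_s, r.true_component))
            for t, r in zip(schedule[:8], responses)
        ]
        pt, pc = ww.classify_session(forced, n_resamples=10, seed=0)
        assert len(pt) == 0
        assert pc["n_classified"].sum() == 0
        assert pc["mean_p_misbind"].isna().all()  # missing, not zero

    def test_noiseless_pure_target_classifies_perfectly(self, schedule):
        params = ww.MixtureParams(1.0, 0.0, 0.0, sigma_px=0.0, p_identify=1.0)
        rng = np.random.default_rng(2)
        responses = ww.simulate_session(schedule, params, rng)
        pt, pc = ww.classify_session(list(zip(schedule, responses)),
                                     n_resamples=25, seed=0)
        assert (pt["p_target_hat"] == 1.0).all()
        assert (pc["mean_p_target"] == 1.0).all()

    def test_zero_noise_identifiability(self, schedule):
        """With sigma=0 and no guessing, classified probabilities equal the
        realised component frequencies exactly."""
        params = ww.MixtureParams(0.7, 0.3, 0.0, sigma_px=0.0, p_identify=1.0)
        rng = np.random.default_rng(8)
        ss3 = [t for t in schedule if t.set_size == 3]
        responses = ww.simulate_session(ss3, params, rng)
        pt, _ = ww.classify_session(list(zip(ss3, responses)), exact=True)
        realised = np.mean([r.true_component == "misbind" for r in responses])
        assert pt["p_misbind_hat"].mean() == pytest.approx(realised)
        assert pt["p_guess_hat"].sum() == 0.0

    def test_session_means_match_exact_oracle(self, rng):
        """200 set-size-3 trials at (0.6, 0.2, 0.2), sigma=30: Monte-Carlo
        session means within +/-0.05 of the exact-enumeration means."""
        params = ww.MixtureParams(0.6, 0.2, 0.2, sigma_px=30.0, p_identify=1.0)
        sched = [t for t in ww.generate_schedule(n_per_condition=100, seed=3)
                 if t.set_size == 3][:200]
        responses = ww.simulate_session(sched, params, rng)
        pairs = list(zip(sched, responses))
        mc, _ = ww.classify_session(pairs, n_resamples=5000, seed=1)
        exact, _ = ww.classify_session(pairs, exact=True)
        for col in ("p_target_hat", "p_misbind_hat", "p_guess_hat"):
            assert mc[col].mean() == pytest.approx(exact[col].mean(), abs=0.05)

    def test_guessing_estimate_increases_with_generative_guessing(self):
        """Noise monotonicity across 10 seeds at n=500 trials."""
        sched = [t for t in ww.generate_schedule(n_per_condition=250, seed=5)
                 if t.set_size == 3][:500]
        for seed in range(10):
            means = []
            for p_guess in (0.1, 0.5):
                params = ww.MixtureParams(1 - 0.1 - p_guess, 0.1, p_guess,
                                          sigma_px=40.0, p_identify=1.0)
                rng = np.random.default_rng(100 + seed)
                responses = ww.simulate_session(sched, params, rng)
                pt, _ = ww.classify_session(list(zip(sched, responses)),
                                            exact=True)
                means.append(pt["p_guess_hat"].mean())
            assert means[1] > means[0]

    def test_classified_distances_bounded_by_screen_diagonal(
        self, simulated_session, screen
    ):
        pt, _ = ww.classify_session(simulated_session, exact=True)
        assert (pt["d_target"] <= screen.diagonal_px).all()
        assert (pt["d_nearest_nontarget"].dropna() <= screen.diagonal_px).all()

    def test_master_seed_reproducible_per_participant(self, tiny_cohort):
        rec = tiny_cohort[0]
        a, _ = ww.classify_session(rec, n_resamples=50, seed=7)
        b, _ = ww.classify_session(rec, n_resamples=50, seed=7)
        assert a.equals(b)
        c, _ = ww.classify_session(rec, n_resamples=50, seed=8)
        assert not a.equals(c)

    def test_single_trial_session_rejected(self, simulated_session):
        with pytest.raises(ValueError):
            ww.classify_session(simulated_session[:1])
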