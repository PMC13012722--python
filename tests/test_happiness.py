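"""Happiness models: event regressors, decayed designs, profiled fits,
model comparison and parameter recovery."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socdec import agents, happiness, task


def _record(condition, chose_risky, safe=0, high=40, low=-20, s_out=None,
            p_out=None, index=1, session=1):
    spec = task.TrialSpec(index=index, condition=condition,
                          trial_class="mixed", safe_amount=safe,
                          lottery_high=high, lottery_low=low)
    chooser = "partner" if condition == "partner" else "participant"
    rec = task.TrialRecord(spec=spec, chooser=chooser,
                           chose_risky=chose_risky,
                           s_outcome=s_out if s_out is not None else safe,
                           p_outcome=p_out)
    return task.records_to_frame([rec], session=session)


def brute_force_decayed(events, gamma, probes):
    """Independent oracle: explicit double loop with gamma**0 == 1."""
    events = np.asarray(events, dtype=float)
    rows = []
    for t in sorted(probes):
        acc = np.zeros(events.shape[1])
        for j in range(1, t + 1):
            w = 1.0 if t == j else gamma ** (t - j)
            acc += w * events[j - 1]
        rows.append(acc)
    return np.array(rows)


class TestEventMatrix:
    def test_safe_social_trial(self):
        df = _record("social", False, safe=20, high=40, low=0, s_out=20,
                     p_out=20)
        ev = happiness.build_event_matrix(df).iloc[0]
        assert ev["CR"] == 20
        for col in ("EV", "sRPE", "abs_ineq", "adv_ineq", "disadv_ineq",
                    "social_pRPE", "partner_pRPE"):
            assert ev[col] == 0

    def test_risky_social_self_high_partner_low(self):
        df = _record("social", True, s_out=40, p_out=-20)
        ev = happiness.build_event_matrix(df).iloc[0]
        assert ev["EV"] == 10 and ev["sRPE"] == 30
        assert ev["social_pRPE"] == -30 and ev["partner_pRPE"] == 0
        assert ev["adv_ineq"] == 60 and ev["abs_ineq"] == 60
        assert ev["disadv_ineq"] == 0 and ev["CR"] == 0

    def test_risky_partner_routes_prpe(self):
        df = _record("partner", True, s_out=40, p_out=-20)
        ev = happiness.build_event_matrix(df).iloc[0]
        assert ev["partner_pRPE"] == -30 and ev["social_pRPE"] == 0

    def test_solo_has_no_partner_columns(self):
        df = _record("solo", True, s_out=40, p_out=None)
        ev = happiness.build_event_matrix(df).iloc[0]
        for col in ("abs_ineq", "adv_ineq", "disadv_ineq", "social_pRPE",
                    "partner_pRPE"):
            assert ev[col] == 0

    def test_missing_outcome_fails_with_trial_index(self):
        df = _record("social", True, s_out=40, p_out=-20)
        df.loc[0, "p_outcome"] = np.nan
        with pytest.raises(ValueError, match="trial 1"):
            happiness.build_event_matrix(df)

    def test_inequality_decomposition(self, small_cohort):
        for p in small_cohort.participants:
            ev = happiness.build_event_matrix(p.trials)
            assert np.allclose(ev["abs_ineq"],
                               ev["adv_ineq"] + ev["disadv_ineq"])
            assert np.all(ev["social_pRPE"] * ev["partner_pRPE"] == 0)
            assert np.all((ev["CR"] != 0).astype(int)
                          + (ev["EV"] != 0).astype(int) <= 1)


class TestDecayedDesign:
    def test_half_decay_example(self):
        X = np.array([[10.0], [0.0], [4.0]])
        D = happiness.decayed_design(X, 0.5, [3])
        assert D[0, 0] == pytest.approx(0.25 * 10 + 0.5 * 0 + 1 * 4)

    def test_gamma_zero_is_current_trial(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        D = happiness.decayed_design(X, 0.0, [2, 5])
        assert np.allclose(D, X[[1, 4]])

    def test_gamma_one_is_cumulative_sum(self):
        X = np.arange(12, dtype=float).reshape(6, 2)
        D = happiness.decayed_design(X, 1.0, [3, 6])
        assert np.allclose(D, np.cumsum(X, axis=0)[[2, 5]])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
    def test_matches_brute_force(self, seed, gamma):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 30))
        X = rng.normal(size=(T, 3)) * 40
        probes = sorted(rng.choice(np.arange(1, T + 1),
                                   size=min(5, T), replace=False))
        D = happiness.decayed_design(X, gamma, probes)
        assert np.allclose(D, brute_force_decayed(X, gamma, probes),
                           atol=1e-10)

    def test_grid_variant_matches_single_gamma(self, rng):
        X = rng.normal(size=(20, 4))
        gammas = np.array([0.0, 0.3, 0.99, 1.0])
        G = happiness._decayed_design_grid(X, gammas, [4, 11, 20])
        for i, g in enumerate(gammas):
            assert np.allclose(G[i], happiness.decayed_design(X, g, [4, 11, 20]),
                               atol=1e-12)

    def test_rejects_gamma_outside_unit_interval(self):
        with pytest.raises(ValueError):
            happiness.decayed_design(np.ones((3, 1)), 1.5, [1])


def test_zscore_moments_and_degenerate():
    x = np.random.default_rng(0).normal(3.0, 7.0, size=50)
    z = happiness.zscore(x)
    assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10
    with pytest.raises(ValueError):
        happiness.zscore(np.full(10, 2.0))


class TestFitModel:
    def test_noise_free_generative_round_trip(self, rng):
        true_w = {"CR": 0.05, "EV": 0.03, "sRPE": 0.08}
        agent = agents.AgentParams(happiness_model="basic", weights=true_w,
                                   gamma=0.4, noise_scale=0.0)
        sched = task.generate_session(seed=21)
        records = agents.simulate_choices(sched, agent, rng)
        trials = task.records_to_frame(records)
        trials["rating_probe"] = [int(t in sched.rating_trials)
                                  for t in trials["trial"]]
        ratings = agents.simulate_happiness(trials, agent, rng)
        fit = happiness.fit_model(trials, ratings, "basic", z_scored=True)
        for name, w in true_w.items():
            assert fit.weights[name] == pytest.approx(w, abs=1e-6)
        assert fit.gamma == pytest.approx(0.4, abs=happiness.GAMMA_GRID_STEP)
        assert fit.r2 > 1 - 1e-9

    def test_pure_noise_has_low_r2(self, rng):
        agent = agents.AgentParams()
        sched = task.generate_session(seed=8)
        records = agents.simulate_choices(sched, agent, rng)
        trials = pd.concat([
            task.records_to_frame(records, session=s).assign(
                rating_probe=[int(t in sched.rating_trials)
                              for t in range(1, 61)])
            for s in (1, 2, 3)], ignore_index=True)
        probes = trials[trials["rating_probe"] == 1][["session", "trial"]]
        ratings = probes.assign(rating=rng.normal(size=len(probes)))
        fit = happiness.fit_model(trials, ratings, "basic")
        assert fit.r2 < 0.25

    def test_profile_optimality(self, small_cohort):
        p = small_cohort.participants[0]
        fit = happiness.fit_model(p.trials, p.ratings, "responsibility_redux",
                                  store_profile=True)
        assert fit.sse <= fit.gamma_profile[:, 1].min() + 1e-12

    def test_nested_models_order_loglik(self, small_cohort):
        p = small_cohort.participants[1]
        redux = happiness.fit_model(p.trials, p.ratings, "responsibility_redux")
        full = happiness.fit_model(p.trials, p.ratings, "responsibility")
        assert full.loglik >= redux.loglik - 1e-8
        assert 0.0 <= redux.r2 <= 1.0

    def test_r2_bounds_across_cohort(self, small_cohort):
        for p in small_cohort.participants:
            for model in happiness.MODEL_SPECS:
                fit = happiness.fit_model(p.trials, p.ratings, model)
                assert 0.0 <= fit.r2 <= 1.0
                assert fit.k_weights == happiness.count_weights(model)

    def test_too_few_ratings_rejected(self, small_cohort):
        p = small_cohort.participants[0]
        with pytest.raises(ValueError, match="ratings"):
            happiness.fit_model(p.trials, p.ratings.head(4), "responsibility")


def test_count_weights_per_model():
    expected = {"basic": 3, "inequality": 4, "guilt_envy": 5,
                "responsibility": 5, "responsibility_redux": 4}
    assert {m: happiness.count_weights(m) for m in expected} == expected
    with pytest.raises(ValueError):
        happiness.count_weights("nonexistent")


class TestLRTest:
    def test_identical_fits_give_zero(self, small_cohort):
        p = small_cohort.participants[2]
        fit = happiness.fit_model(p.trials, p.ratings, "basic")
        res = happiness.lr_test(fit, fit)
        assert res["LR"] == 0.0 and res["p"] == 1.0 and res["df"] == 0

    def test_non_nested_pair_rejected(self, small_cohort):
        p = small_cohort.participants[0]
        ineq = happiness.fit_model(p.trials, p.ratings, "inequality")
        resp = happiness.fit_model(p.trials, p.ratings, "responsibility")
        with pytest.raises(ValueError, match="not nested"):
            happiness.lr_test(ineq, resp)

    def test_null_calibration_scaled(self):
        """Data generated from the redux model: LR of redux vs responsibility
        behaves like chi-square(1) (scaled-down replication count)."""
        lrs = []
        for seed in range(30):
            ds = agents.simulate_cohort(n=1, sessions=1, seed=1000 + seed)
            p = ds.participants[0]
            redux = happiness.fit_model(p.trials, p.ratings,
                                        "responsibility_redux")
            full = happiness.fit_model(p.trials, p.ratings, "responsibility")
            lrs.append(happiness.lr_test(redux, full)["LR"])
        lrs = np.array(lrs)
        assert np.all(lrs >= 0)
        # chi2(1): mean 1, P(LR > 3.84) = 0.05
        assert 0.3 < lrs.mean() < 2.5
        assert np.mean(lrs > 3.84) <= 0.25


class TestCompareCohort:
    def test_generating_model_wins(self):
        sampler = agents.default_param_sampler("responsibility", overrides={
            "noise_scale": 0.5,
            "weights_mean": {"social_pRPE": 0.012, "partner_pRPE": 0.010}})
        ds = agents.simulate_cohort(n=8, sessions=2, param_sampler=sampler,
                                    seed=42)
        fits = {m: [happiness.fit_model(p.trials, p.ratings, m)
                    for p in ds.participants]
                for m in ("basic", "guilt_envy", "responsibility")}
        table, pairwise = happiness.compare_cohort(fits)
        best = table.loc[table["mean_r2"].idxmax(), "model"]
        assert best == "responsibility"
        assert {"p_bonferroni"} <= set(pairwise.columns)

    def test_identical_models_tie(self, small_cohort):
        fits = [happiness.fit_model(p.trials, p.ratings, "basic")
                for p in small_cohort.participants]
        table, pairwise = happiness.compare_cohort({"a": fits, "b": fits})
        assert table["mean_r2"].nunique() == 1
        assert (pairwise["t"] == 0).all() and (pairwise["p"] == 1).all()

    def test_unequal_counts_rejected(self, small_cohort):
        fits = [happiness.fit_model(p.trials, p.ratings, "basic")
                for p in small_cohort.participants]
        with pytest.raises(ValueError, match="unequal"):
            happiness.compare_cohort({"a": fits, "b": fits[:-1]})


class TestParameterRecovery:
    def test_noiseless_recovery_is_exact(self, small_cohort):
        report = happiness.parameter_recovery(
            small_cohort, "responsibility_redux", nreps=2, rng=0,
            noise_scale=0.0)
        tab = report.table.set_index("parameter")
        for w in happiness.model_regressors("responsibility_redux"):
            assert tab.loc[w, "slope"] == pytest.approx(1.0, abs=1e-6)
            assert tab.loc[w, "r2"] == pytest.approx(1.0, abs=1e-6)
        assert tab.loc["gamma", "slope"] == pytest.approx(1.0, abs=1e-3)

    def test_invalid_nreps(self, small_cohort):
        with pytest.raises(ValueError):
            happiness.parameter_recovery(small_cohort, "basic", nreps=0)
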