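"""Guilt-effect inference: post-lottery table, mixed models, stratified
contrasts, Bayes factors, power."""
import numpy as np
import pandas as pd
import pytest

from socdec import agents, guilt


class TestPostLotteryTable:
    def test_filters_and_encoding(self, redux_cohort):
        rows = guilt.build_post_lottery_table(redux_cohort)
        assert set(rows["condition"]) <= {"social", "partner"}
        assert (rows["sDec"] == (rows["condition"] == "social")).all()
        merged = rows.merge(
            pd.concat(p.trials.assign(participant=p.pid)
                      for p in redux_cohort.participants),
            on=["participant", "session", "trial"])
        assert (merged["chose_risky"] == 1).all()
        assert (merged["condition_x"] == merged["condition_y"]).all()
        assert ((merged["sHigh"] == 1)
                == (merged["s_outcome"] == merged["lottery_high"])).all()
        assert ((merged["pHigh"] == 1)
                == (merged["p_outcome"] == merged["lottery_high"])).all()

    def test_strata_use_disjoint_rows(self, redux_cohort):
        rows = guilt.build_post_lottery_table(redux_cohort)
        low = rows[rows["pHigh"] == 0]
        hi_keys = set(map(tuple, low[low["sHigh"] == 1]
                          [["participant", "session", "trial"]].values))
        lo_keys = set(map(tuple, low[low["sHigh"] == 0]
                          [["participant", "session", "trial"]].values))
        assert hi_keys.isdisjoint(lo_keys)

    def test_unlinked_rating_fails(self, small_cohort):
        import copy
        ds = copy.deepcopy(small_cohort)
        ds.participants[0].ratings.loc[0, "trial"] = 999  # no such trial
        with pytest.raises(ValueError, match="no matching trial"):
            guilt.build_post_lottery_table(ds)


class TestGuiltLMM:
    def test_positive_interaction_when_social_prpe_drives_happiness(
            self, redux_cohort):
        rows = guilt.build_post_lottery_table(redux_cohort)
        table = guilt.fit_guilt_lmm(rows)
        beta = float(table.loc[table["term"] == "pHigh:sDec", "beta"].iloc[0])
        assert beta > 0

    def test_null_partner_terms_give_null_interaction(self):
        sampler = agents.default_param_sampler("basic")
        ds = agents.simulate_cohort(n=20, sessions=2, param_sampler=sampler,
                                    seed=3)
        rows = guilt.build_post_lottery_table(ds)
        table = guilt.fit_guilt_lmm(rows)
        sub = table[table["term"] == "pHigh:sDec"]
        assert abs(float(sub["beta"].iloc[0])) < 3 * float(sub["se"].iloc[0])

    def test_location_invariance_of_z_scoring(self, small_cohort):
        import copy
        shifted = copy.deepcopy(small_cohort)
        shifted.participants[0].ratings["rating"] += 42.0
        a = guilt.fit_guilt_lmm(guilt.build_post_lottery_table(small_cohort))
        b = guilt.fit_guilt_lmm(guilt.build_post_lottery_table(shifted))
        assert np.allclose(a["beta"], b["beta"], atol=1e-8)

    def test_constant_predictor_rejected(self, small_cohort):
        rows = guilt.build_post_lottery_table(small_cohort)
        rows = rows[rows["sDec"] == 1]
        with pytest.raises(ValueError, match="sDec"):
            guilt.fit_guilt_lmm(rows)


class TestGuiltEffect:
    def test_negative_effect_under_responsibility_generator(self,
                                                            redux_cohort):
        res = guilt.guilt_effect(redux_cohort)
        assert set(res.strata) == {"self_high", "self_low"}
        assert res.strata["self_high"].mean_effect < 0
        assert res.strata["self_low"].mean_effect < 0

    def test_symmetric_generator_gives_null_effect(self):
        sampler = agents.default_param_sampler(
            "responsibility",
            overrides={"weights_mean": {"social_pRPE": 0.01,
                                        "partner_pRPE": 0.01},
                       "weights_rel_sd": 0.0})
        ds = agents.simulate_cohort(n=16, sessions=3, param_sampler=sampler,
                                    seed=9)
        res = guilt.guilt_effect(ds)
        for s in ("self_high", "self_low"):
            assert res.strata[s].p > 0.01
            assert res.strata[s].bf10 < 3.0

    def test_single_participant_fails(self):
        ds = agents.simulate_cohort(n=1, sessions=3, seed=5)
        with pytest.raises((ValueError, RuntimeError)):
            guilt.guilt_effect(ds)


class TestBayesFactor:
    def test_null_favoring_at_t_zero(self):
        assert guilt.bf10_paired(0.0, 40) < 1.0

    def test_monotone_in_t(self):
        ts = np.linspace(0, 5, 11)
        bfs = [guilt.bf10_paired(t, 40) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_reference_value(self):
        # a |t| of 3.58 with 40 pairs gives strong evidence, BF10 near 32
        assert guilt.bf10_paired(3.58, 40) == pytest.approx(32.3, abs=0.5)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((1.2, 20), (3.58, 40), (2.68, 44)):
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True,
                                                   r=np.sqrt(2) / 2))
            assert guilt.bf10_paired(t, n) == pytest.approx(ref, rel=1e-6)

    def test_directional_agreement_with_p(self):
        # |t| > 3 at n = 40: both frequentist and Bayesian read favour H1
        from scipy import stats
        for t in (3.1, 3.58, 4.5):
            assert guilt.bf10_paired(t, 40) > 3
            assert 2 * stats.t.sf(t, 39) < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            guilt.bf10_paired(float("nan"), 40)
        with pytest.raises(ValueError):
            guilt.bf10_paired(1.0, 1)


class TestPower:
    def test_monotone_in_effect_size(self):
        ns = [guilt.required_sample_size_paired(d) for d in (0.4, 0.56, 0.8)]
        assert ns[0] >= ns[1] >= ns[2]

    def test_noncentral_t_exceeds_normal_approximation(self):
        from scipy import stats
        d = 0.56
        approx = ((stats.norm.ppf(0.975) + stats.norm.ppf(0.95)) / d) ** 2
        assert guilt.required_sample_size_paired(d, 0.05, 0.95) >= approx

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            guilt.required_sample_size_paired(0.0)
        with pytest.raises(ValueError):
            guilt.required_sample_size_paired(0.5, alpha=0.5, power=0.2)


class TestAgencyEffect:
    @staticmethod
    def _noise_cohort(seed, shift=0.0):
        sampler = agents.default_param_sampler("basic", overrides={
            "weights_mean": {"CR": 0.0, "EV": 0.0, "sRPE": 0.0},
            "weights_rel_sd": 0.0})
        ds = agents.simulate_cohort(n=16, sessions=2, param_sampler=sampler,
                                    seed=seed)
        rng = np.random.default_rng(seed + 1)
        for p in ds.participants:
            p.ratings["rating"] = rng.normal(size=len(p.ratings))
            if shift:
                chosen = p.trials.set_index(["session", "trial"])["chooser"]
                idx = pd.MultiIndex.from_frame(p.ratings[["session", "trial"]])
                p.ratings.loc[
                    (chosen.loc[idx] == "participant").to_numpy(),
                    "rating"] += shift
        return ds

    def test_null_agency(self):
        table = guilt.agency_effect(self._noise_cohort(100))
        row = table[table["term"] == "agency"].iloc[0]
        assert abs(row["beta"]) < 3 * row["se"]

    def test_planted_negative_shift_recovered(self):
        table = guilt.agency_effect(self._noise_cohort(200, shift=-0.2))
        row = table[table["term"] == "agency"].iloc[0]
        assert row["beta"] == pytest.approx(-0.2, abs=3 * row["se"])
        assert row["beta"] < 0 and row["p"] < 0.05

    def test_dummy_reversal_flips_sign(self):
        ds = self._noise_cohort(300, shift=-0.2)
        a = guilt.agency_effect(ds)
        import copy
        flipped = copy.deepcopy(ds)
        for p in flipped.participants:
            p.trials["chooser"] = np.where(p.trials["chooser"] == "participant",
                                           "partner", "participant")
        b = guilt.agency_effect(flipped)
        beta_a = float(a.loc[a["term"] == "agency", "beta"].iloc[0])
        beta_b = float(b.loc[b["term"] == "agency", "beta"].iloc[0])
        assert beta_b == pytest.approx(-beta_a, abs=1e-6)
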