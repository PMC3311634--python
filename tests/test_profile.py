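import numpy as np
import pytest

import implearn as il
from conftest import random_session
from implearn.agents import CONFIDENT, GUESS
from oracles import phi_contingency


class TestLagCorrelation:
    def test_matches_contingency_table_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            session = random_session(rng, n=40)
            for lag in (1, 2, 5):
                got = il.lag_correlation(session, lag)
                want = phi_contingency(
                    session.responses[lag:], session.stimuli[:-lag]
                )
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_hand_example_lag_two(self):
        session = il.Session(
            stimuli=[1, 0, 1, 1, 0, 1, 0, 0], responses=[0, 1, 1, 0, 1, 1, 0, 1]
        )
        # 6 contributing pairs: (resp_t, stim_{t-2}) for t = 3..8
        pairs_resp = [1, 0, 1, 1, 0, 1]
        pairs_stim = [1, 0, 1, 1, 0, 1]
        want = phi_contingency(pairs_resp, pairs_stim)
        assert il.lag_correlation(session, 2) == pytest.approx(want, abs=1e-12)

    def test_rate_one_learner_lag_one_is_exactly_one(self, rate1_session):
        assert il.lag_correlation(rate1_session, 1) == 1.0

    def test_pure_gambler_lag_one_is_exactly_minus_one(self, gf1_session):
        assert il.lag_correlation(gf1_session, 1) == -1.0

    def test_constant_responses_undefined(self):
        session = il.Session(stimuli=[0, 1, 0, 1, 1, 0], responses=[1] * 6)
        assert np.isnan(il.lag_correlation(session, 1))

    def test_excessive_lag_raises(self):
        session = il.Session(stimuli=[0, 1], responses=[1, 0])
        with pytest.raises(ValueError):
            il.lag_correlation(session, 2)
        with pytest.raises(ValueError):
            il.lag_correlation(session, 0)


class TestLagProfile:
    def test_rate_one_profile_shape(self, rate1_session):
        prof = il.lag_profile(rate1_session)
        assert prof.correlations[0] == 1.0
        # beyond lag 1 the rate-1 learner carries no information
        assert np.all(np.abs(prof.correlations[1:]) < 0.2)
        assert abs(prof.distant) < 0.1

    def test_summaries_follow_lag_division(self, rate1_session):
        """recent = mean(lags 1-2), distant = mean(lags 4-10), lag 3 in neither."""
        prof = il.lag_profile(rate1_session)
        c = prof.correlations
        assert prof.recent == pytest.approx(np.mean(c[:2]), abs=1e-12)
        assert prof.distant == pytest.approx(np.mean(c[3:10]), abs=1e-12)
        assert prof.overall == pytest.approx(np.mean(c), abs=1e-12)

    def test_pair_counts(self, rate1_session):
        prof = il.lag_profile(rate1_session)
        assert np.array_equal(prof.n_pairs, 300 - np.arange(1, 11))

    def test_constant_session_all_undefined(self):
        session = il.Session(
            stimuli=np.random.default_rng(0).integers(0, 2, 30),
            responses=np.ones(30, dtype=int),
        )
        prof = il.lag_profile(session)
        assert np.isnan(prof.correlations).all()
        assert np.isnan(prof.recent) and np.isnan(prof.distant) and np.isnan(prof.overall)

    def test_too_short_session_raises(self):
        session = il.Session(stimuli=[0, 1] * 5, responses=[1, 0] * 5)
        with pytest.raises(ValueError):
            il.lag_profile(session, max_lag=10)

    def test_null_agents_show_no_influence_at_any_lag(self):
        """Rate-0 agents cannot learn: every lag's mean phi is within 3 SE of 0."""
        profiles = []
        for i in range(200):
            seq = il.generate_random_sequence(300, 0.5, seed=1000 + i)
            params = il.AgentParams(
                r_learn=0.0, r_gf=0.0, p_mix=0.5, policy="probabilistic", seed=i
            )
            profiles.append(il.lag_profile(il.simulate_session(seq, params)))
        mat = np.vstack([p.correlations for p in profiles])
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        assert np.all(np.abs(mean) <= 3 * se + 1e-12)


class TestFilters:
    def test_context_filter_uses_current_trial_only(self):
        session = il.Session(
            stimuli=[1, 0, 1, 1, 0, 1],
            responses=[0, 1, 1, 0, 1, 0],
            context=["tone", "no_tone", "tone", "tone", "no_tone", "tone"],
        )
        # current trials kept: t in {3, 4, 6}; past trial may be either context
        resp, stim = [1, 0, 0], [1, 0, 1]
        want = phi_contingency(resp, stim)
        got = il.lag_correlation(session, 2, il.by_context("tone"))
        assert got == pytest.approx(want, abs=1e-12)

    def test_all_guess_split_equals_unfiltered(self):
        rng = np.random.default_rng(3)
        base = random_session(rng, n=50)
        session = base.with_attribution(np.array([GUESS] * 50, dtype=object))
        guess_prof, sure_prof = il.attribution_split(session)
        plain = il.lag_profile(session)
        np.testing.assert_allclose(
            guess_prof.correlations, plain.correlations, atol=1e-12
        )
        assert np.isnan(sure_prof.correlations).all()

    def test_alternating_labels_halve_pair_counts(self):
        rng = np.random.default_rng(4)
        base = random_session(rng, n=40)
        labels = np.array([GUESS, CONFIDENT] * 20, dtype=object)
        session = base.with_attribution(labels)
        guess_prof, sure_prof = il.attribution_split(session)
        for lag in range(1, 11):
            # guess trials sit at odd 1-based positions
            assert guess_prof.n_pairs[lag - 1] == sum(
                1 for t in range(lag + 1, 41) if t % 2 == 1
            )
            assert sure_prof.n_pairs[lag - 1] == sum(
                1 for t in range(lag + 1, 41) if t % 2 == 0
            )

    def test_missing_labels_raise(self):
        session = il.Session(stimuli=[0, 1] * 10, responses=[1, 0] * 10)
        with pytest.raises(ValueError):
            il.attribution_split(session)
        with pytest.raises(ValueError):
            il.lag_correlation(session, 1, il.by_context("tone"))


class TestBlockResponseShift:
    SPEC = il.BlockSpec(((100, 0.5), (100, 0.5)))

    def test_identical_blocks_no_shift(self):
        stim = np.tile([0, 1], 100)
        session = il.Session(stimuli=stim, responses=stim)
        assert il.block_response_shift(session, self.SPEC) == (0.0, 0.0)

    def test_partition_mismatch_raises(self):
        session = il.Session(stimuli=[0, 1] * 50, responses=[0, 1] * 50)
        with pytest.raises(ValueError):
            il.block_response_shift(session, self.SPEC)

    def test_copying_agent_matches_stimulus_shift(self):
        """A rate-1 learner copies lag 1, so its response shift tracks the
        stimulus shift up to block-boundary effects (Monte-Carlo mean)."""
        spec = il.BlockSpec(((120, 0.40), (40, 0.50), (120, 0.60)))
        stim_shifts, resp_shifts = [], []
        for i in range(100):
            seq = il.generate_block_sequence(spec, seed=500 + i)
            params = il.AgentParams(r_learn=1.0, p_mix=1.0, policy="threshold", seed=i)
            s, r = il.block_response_shift(il.simulate_session(seq, params), spec)
            stim_shifts.append(s)
            resp_shifts.append(r)
        assert np.mean(stim_shifts) == pytest.approx(0.20, abs=0.02)
        assert abs(np.mean(resp_shifts) - np.mean(stim_shifts)) < 0.01

    def test_slow_learner_tracks_partially(self):
        """A slow learner's response shift is strictly between zero and the
        stimulus shift: its strength needs ~1/r trials to track the new
        block probability, so block lengths are chosen short enough for
        that transient to be resolvable over Monte-Carlo runs."""
        spec = il.BlockSpec(((300, 0.40), (300, 0.60)))
        stim_shifts, resp_shifts = [], []
        for i in range(200):
            seq = il.generate_block_sequence(spec, seed=900 + i)
            params = il.AgentParams(
                r_learn=0.05, p_mix=1.0, policy="probabilistic", seed=i
            )
            s, r = il.block_response_shift(il.simulate_session(seq, params), spec)
            stim_shifts.append(s)
            resp_shifts.append(r)
        assert 0.0 < np.mean(resp_shifts) < np.mean(stim_shifts)
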