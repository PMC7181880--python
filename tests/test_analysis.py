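"""Bias statistics, exclusion rule, pairing, and the condition test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from allorecall import (
    ObserverParams,
    ResponseSet,
    build_session,
    centroid_distance,
    condition_test,
    distance_to_beacon_stat,
    distance_to_prior_mode,
    exclude_outlier_trials,
    make_condition,
    min_error_pairing,
    nearest_beacon,
    participant_summary,
    simulate_responses,
)
from allorecall.task import Condition, Session, Trial


def _toy_session(name, trial_targets, half="second"):
    cond = make_condition(name)
    trials = tuple(
        Trial(index=i + 1, half=half, targets=np.asarray(t), displacement_fraction=1 / 8)
        for i, t in enumerate(trial_targets)
    )
    return Session(participant_id="toy", condition=cond, trials=trials, seed=None)


class TestDistances:
    def test_gaussian_mode_distance(self):
        prior = make_condition("offset").prior
        assert distance_to_prior_mode(prior.center_point, prior) == 0.0
        assert distance_to_prior_mode((-0.65, 0.35), prior) == pytest.approx(0.10)

    def test_ring_mode_distance(self):
        prior = make_condition("beacon_donut").prior
        on_ring = np.array([-0.65 + 0.35, 0.0])
        assert distance_to_prior_mode(on_ring, prior) == pytest.approx(0.0)
        assert distance_to_prior_mode(prior.center_point, prior) == pytest.approx(0.35)

    def test_nearest_beacon_and_tie_break(self, layout):
        assert nearest_beacon((-0.60, 0.0), layout) == 0
        assert nearest_beacon((0.0, 0.60), layout) == 1
        assert nearest_beacon((0.0, -0.60), layout) == 2
        # the origin is 0.65 m from all three: lowest index wins
        assert nearest_beacon((0.0, 0.0), layout) == 0

    def test_beacon_stat_euclidean_conditions(self):
        assert distance_to_beacon_stat((-0.65, 0.0), make_condition("offset")) == 0.0
        assert distance_to_beacon_stat(
            (-0.35, 0.0), make_condition("beacon_donut")
        ) == pytest.approx(0.30)

    def test_beacon_stat_signed_x_for_non_beacon(self):
        cond = make_condition("non_beacon_normal")
        assert distance_to_beacon_stat((0.65, 0.12), cond) == pytest.approx(0.65)
        assert distance_to_beacon_stat((-0.10, 0.5), cond) == pytest.approx(-0.10)


class TestExclusionRule:
    def _near_left(self):
        return [
            [(-0.60, 0.0), (-0.70, 0.05), (-0.65, -0.1)],
            [(-0.55, 0.1), (-0.75, 0.0), (-0.65, 0.05)],
        ]

    def test_clean_trials_are_kept(self):
        session = _toy_session("beacon_normal", self._near_left())
        resp = ResponseSet.from_responses(session, np.asarray(self._near_left()))
        flagged, n = exclude_outlier_trials(session, resp)
        assert n == 0 and not flagged.excluded.any()

    def test_response_near_other_beacon_excludes_trial(self):
        session = _toy_session("beacon_normal", self._near_left())
        responses = np.asarray(self._near_left())
        responses[1, 2] = (0.0, 0.6)  # nearest the top beacon
        flagged, n = exclude_outlier_trials(
            session, ResponseSet.from_responses(session, responses)
        )
        assert n == 1
        assert list(flagged.excluded) == [False, True]

    def test_rule_never_fires_in_non_beacon_condition(self):
        session = build_session(make_condition("non_beacon_normal"), "p", seed=8)
        resp = simulate_responses(session, ObserverParams(model="null", seed=1))
        flagged, n = exclude_outlier_trials(session, resp)
        assert n == 0 and not flagged.excluded.any()

    def test_any_target_rule_is_stricter(self):
        targets = [[(-0.60, 0.0), (-0.70, 0.05), (0.0, 0.5)]]  # one off-beacon target
        session = _toy_session("beacon_normal", targets)
        responses = np.array([[(-0.6, 0.0), (0.0, 0.6), (-0.65, 0.0)]])
        rs = ResponseSet.from_responses(session, responses)
        _, n_all = exclude_outlier_trials(session, rs, target_rule="all")
        _, n_any = exclude_outlier_trials(session, rs, target_rule="any")
        assert (n_all, n_any) == (0, 1)

    def test_misaligned_inputs_error(self):
        session = _toy_session("beacon_normal", self._near_left())
        short = ResponseSet(
            participant_id="toy",
            condition_name="beacon_normal",
            responses=np.zeros((1, 3, 2)),
            excluded=np.zeros(1, dtype=bool),
        )
        with pytest.raises(ValueError, match="aligned"):
            exclude_outlier_trials(session, short)


class TestParticipantSummary:
    def test_identity_responses_have_zero_bias(self, condition):
        session = build_session(condition, "p", seed=6)
        resp = simulate_responses(session, ObserverParams(model="null", sigma_mem=0.0))
        _, biases = participant_summary(session, resp)
        assert biases.prior_mode_bias == pytest.approx(0.0, abs=1e-12)
        assert biases.beacon_bias == pytest.approx(0.0, abs=1e-12)

    def test_halfway_shrink_gives_half_bias(self):
        session = build_session(make_condition("non_beacon_normal"), "p", seed=10)
        targets = np.stack([t.targets for t in session.trials])
        mode = session.condition.prior.center_point
        resp = ResponseSet.from_responses(session, mode + 0.5 * (targets - mode))
        stats_, biases = participant_summary(session, resp)
        assert biases.prior_mode_bias == pytest.approx(0.5 * stats_.d_mode_targets)

    def test_hand_computed_toy_statistics(self):
        trials = [
            [(-0.55, 0.0), (-0.75, 0.0), (-0.65, 0.1)],
            [(-0.65, 0.2), (-0.45, 0.0), (-0.65, -0.2)],
        ]
        responses = np.array(
            [
                [(-0.60, 0.0), (-0.70, 0.0), (-0.65, 0.05)],
                [(-0.65, 0.2), (-0.45, 0.0), (-0.65, -0.2)],
            ]
        )
        session = _toy_session("beacon_normal", trials)
        stats_, biases = participant_summary(
            session, ResponseSet.from_responses(session, responses)
        )
        # distances to (-0.65, 0): targets 0.10 x6, responses 0.05 x3 + 0.20 x3
        assert stats_.d_mode_targets == pytest.approx(0.15)
        assert stats_.d_mode_responses == pytest.approx(0.125)
        assert stats_.d_beacon_targets == pytest.approx(0.15)
        assert biases.prior_mode_bias == pytest.approx(0.025)
        assert biases.beacon_bias == pytest.approx(0.025)

    def test_all_excluded_raises(self):
        session = _toy_session("beacon_normal", [[(-0.6, 0), (-0.7, 0), (-0.65, 0.1)]])
        rs = ResponseSet(
            participant_id="toy",
            condition_name="beacon_normal",
            responses=np.zeros((1, 3, 2)),
            excluded=np.ones(1, dtype=bool),
        )
        with pytest.raises(ValueError, match="no analysable trials"):
            participant_summary(session, rs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_biases_invariant_to_within_trial_relabeling(self, seed):
        """The statistics are pairing-free: permuting targets (and
        responses, independently) within trials changes nothing."""
        rng = np.random.default_rng(seed)
        session = build_session(make_condition("beacon_donut"), "p", seed=seed)
        resp = simulate_responses(
            session, ObserverParams(model="beacon_attraction", seed=seed)
        )
        _, base = participant_summary(session, resp)
        shuffled = resp.responses.copy()
        for i in range(shuffled.shape[0]):
            shuffled[i] = shuffled[i][rng.permutation(3)]
        _, perm = participant_summary(
            session, ResponseSet.from_responses(session, shuffled)
        )
        assert perm.prior_mode_bias == pytest.approx(base.prior_mode_bias)
        assert perm.beacon_bias == pytest.approx(base.beacon_bias)


class TestConditionTest:
    def test_symmetric_sample_gives_t_zero(self):
        res = condition_test([-0.02, 0.02] * 6)
        assert res.t == pytest.approx(0.0)
        assert res.p_one_tailed == pytest.approx(0.5)
        assert res.df == 11

    def test_matches_textbook_formulas(self, rng):
        x = rng.normal(0.01, 0.02, size=12)
        res = condition_test(x)
        mean, sd = x.mean(), x.std(ddof=1)
        t = mean / (sd / math.sqrt(12))
        assert res.t == pytest.approx(t)
        assert res.p_one_tailed == pytest.approx(stats.t.sf(t, 11))
        assert res.cohens_d == pytest.approx(mean / sd)
        half = stats.t.ppf(0.975, 11) * sd / math.sqrt(12)
        assert res.ci95 == pytest.approx((mean - half, mean + half))

    def test_agrees_with_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0.005, 0.03, size=12)
        res = condition_test(x)
        ref = pingouin.ttest(x, 0, alternative="greater").iloc[0]
        assert res.t == pytest.approx(float(ref["T"]))
        assert res.p_one_tailed == pytest.approx(float(ref["p_val"]))
        assert res.cohens_d == pytest.approx(abs(float(ref["cohen_d"])), abs=1e-9)

    def test_t_equals_d_times_sqrt_n(self, rng):
        for _ in range(20):
            x = rng.normal(0, 0.05, size=rng.integers(3, 30))
            res = condition_test(x)
            assert res.t == pytest.approx(res.cohens_d * math.sqrt(res.n), rel=1e-9)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            condition_test([0.01] * 12)
        with pytest.raises(ValueError, match="at least 2"):
            condition_test([0.01])


class TestPairingAndCentroid:
    def test_shuffled_identity_recovered(self, rng):
        t = rng.normal(0, 0.2, size=(3, 2))
        perm = [2, 0, 1]
        pairing, dist = min_error_pairing(t, t[perm])
        assert dist == pytest.approx(0.0)
        assert [perm[i] for i in pairing] == [0, 1, 2] or dist == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(1000):
            t = rng.normal(0, 0.3, size=(3, 2))
            r = rng.normal(0, 0.3, size=(3, 2))
            _, dist = min_error_pairing(t, r)
            brute = min(
                np.mean([np.linalg.norm(t[i] - r[p[i]]) for i in range(3)])
                for p in itertools.permutations(range(3))
            )
            assert dist == pytest.approx(brute)

    def test_collapsed_responses_are_pairing_invariant(self):
        t = np.array([[0.0, 0.0], [0.3, 0.0], [0.0, 0.4]])
        r = np.tile([0.1, 0.1], (3, 1))
        _, dist = min_error_pairing(t, r)
        assert dist == pytest.approx(
            np.mean(np.linalg.norm(t - [0.1, 0.1], axis=1))
        )

    def test_centroid_distance(self):
        t = np.array([[0.0, 0.0], [0.3, 0.0], [0.0, 0.3]])
        assert centroid_distance(t, t) == 0.0
        assert centroid_distance(t, t + [0.10, 0.0]) == pytest.approx(0.10)
        r = np.array([[0.1, 0.1], [0.4, 0.1], [0.1, 0.4]])
        assert centroid_distance(t, r) == pytest.approx(math.hypot(0.1, 0.1))
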