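"""Behavioral event extraction: interpolation, approach classification,
session metrics, and epoch speeds."""

import numpy as np
import pytest

import twocap as tc
from conftest import make_cs_plus_trial, make_mini_schedule, make_pose_from_snout
from twocap.behavior import moving_average
from twocap.simulate import HOME, LANDMARK_POSITIONS
from twocap.types import TrialEvents, ValidationError


class TestInterpolation:
    def test_linear_midpoint(self):
        pose = make_pose_from_snout([0.0, 99.0, 10.0], [0.0, 99.0, 20.0],
                                    likelihood=[0.99, 0.5, 0.99])
        out = tc.interpolate_low_confidence(pose, 0.9)
        snout = out.parts["snout"]
        assert snout.x[1] == pytest.approx(5.0)
        assert snout.y[1] == pytest.approx(10.0)
        assert snout.likelihood[1] == pytest.approx(0.9)
        assert snout.imputed.tolist() == [False, True, False]

    def test_identity_when_all_confident(self):
        pose = make_pose_from_snout([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = tc.interpolate_low_confidence(pose, 0.9)
        np.testing.assert_array_equal(out.parts["snout"].x, pose.parts["snout"].x)
        assert not out.parts["snout"].imputed.any()

    def test_edge_fill_uses_nearest_confident(self):
        pose = make_pose_from_snout([0.0, 7.0, 9.0], [1.0, 2.0, 3.0],
                                    likelihood=[0.1, 0.99, 0.99])
        out = tc.interpolate_low_confidence(pose, 0.9)
        assert out.parts["snout"].x[0] == pytest.approx(7.0)

    def test_no_confident_frames_names_part(self):
        pose = make_pose_from_snout([0.0, 1.0], [0.0, 1.0], likelihood=[0.1, 0.2])
        with pytest.raises(ValidationError, match="snout"):
            tc.interpolate_low_confidence(pose, 0.9)


def _trajectory_pose(segments, duration_s=20.0, fps=30.0):
    """Snout path through (time, x, y) waypoints, elsewhere at HOME."""
    t = np.arange(int(duration_s * fps)) / fps
    way_t = [0.0] + [s[0] for s in segments] + [duration_s]
    way_x = [HOME[0]] + [s[1] for s in segments] + [HOME[0]]
    way_y = [HOME[1]] + [s[2] for s in segments] + [HOME[1]]
    return make_pose_from_snout(np.interp(t, way_t, way_x), np.interp(t, way_t, way_y),
                                fps=fps)


LEFT = LANDMARK_POSITIONS["sipper_left"]
RIGHT = LANDMARK_POSITIONS["sipper_right"]


class TestDetectAndClassify:
    def test_correct_approach_latency(self, config):
        # sipper_in at t=5; snout jumps to the left port at t=6.5 and stays
        sched = make_mini_schedule([make_cs_plus_trial(1, 0.0, "left")])
        pose = _trajectory_pose([(6.4, HOME[0], HOME[1]), (6.5, *LEFT), (12.0, *LEFT)])
        ev = tc.detect_and_classify(pose, sched, 9.0, config)
        assert ev.outcome == ["correct"]
        assert ev.latency_correct_s[0] == pytest.approx(1.5, abs=0.05)
        assert np.isnan(ev.latency_incorrect_s[0])

    def test_incorrect_then_correct_records_both(self, config):
        sched = make_mini_schedule([make_cs_plus_trial(1, 0.0, "left")])
        pose = _trajectory_pose(
            [(5.9, HOME[0], HOME[1]), (6.0, *RIGHT), (7.5, *RIGHT), (8.0, *LEFT), (12.0, *LEFT)]
        )
        ev = tc.detect_and_classify(pose, sched, 9.0, config)
        assert ev.outcome == ["incorrect"]
        assert ev.first_port_visited == ["right"]
        assert ev.latency_incorrect_s[0] == pytest.approx(1.0, abs=0.05)
        assert ev.latency_correct_s[0] == pytest.approx(3.0, abs=0.1)

    def test_omission_when_never_in_radius(self, config):
        sched = make_mini_schedule([make_cs_plus_trial(1, 0.0, "left")])
        pose = _trajectory_pose([(6.0, HOME[0], HOME[1])])
        ev = tc.detect_and_classify(pose, sched, 9.0, config)
        assert ev.outcome == ["omission"]
        assert ev.first_port_visited == ["none"]
        assert np.isnan(ev.approach_time_correct[0])

    def test_pose_must_cover_schedule(self, config):
        sched = make_mini_schedule([make_cs_plus_trial(1, 30.0, "left")])
        pose = _trajectory_pose([], duration_s=10.0)
        with pytest.raises(ValidationError, match="cover"):
            tc.detect_and_classify(pose, sched, 9.0, config)

    def test_radius_monotonicity(self, config, default_session):
        """Enlarging the radius never converts an approach into an omission."""
        pose = tc.interpolate_low_confidence(default_session.pose,
                                             config.likelihood_floor)
        small = tc.detect_and_classify(pose, default_session.schedule, 9.0, config)
        large = tc.detect_and_classify(pose, default_session.schedule, 18.0, config)
        for o_small, o_large in zip(small.outcome, large.outcome):
            if o_small != "omission":
                assert o_large != "omission"

    def test_label_recovery_noise_free(self, clean_session, config):
        """Closed loop with the generator: noise-free sessions reproduce the
        ground-truth outcomes on 100% of trials."""
        schedule, pose, truth = clean_session
        ev = tc.detect_and_classify(pose, schedule, config.approach_radius_px, config)
        assert ev.outcome == truth.outcome
        assert ev.first_port_visited == truth.first_port
        np.testing.assert_allclose(
            ev.approach_time_correct, truth.approach_time_correct,
            atol=1e-9, equal_nan=True,
        )

    def test_outcome_partition(self, config, default_session):
        ev = default_session.events
        m = tc.session_metrics(ev, default_session.schedule)
        assert m.n_correct + m.n_incorrect + m.n_omission == 48


class TestSessionMetrics:
    def _events(self, outcomes, minus_approached):
        n = len(outcomes)
        return TrialEvents(
            trial_index=np.arange(1, n + 1),
            outcome=list(outcomes),
            first_port_visited=["left" if o == "correct" else
                                ("right" if o == "incorrect" else "none")
                                for o in outcomes],
            approach_time_correct=np.full(n, np.nan),
            approach_time_incorrect=np.full(n, np.nan),
            latency_correct_s=np.full(n, np.nan),
            latency_incorrect_s=np.full(n, np.nan),
            occupancy_correct=np.zeros((n, 4), dtype=np.int8),
            occupancy_incorrect=np.zeros((n, 4), dtype=np.int8),
            cs_minus_index=np.arange(100, 100 + len(minus_approached)),
            cs_minus_approached=np.asarray(minus_approached, bool),
        )

    def test_cs_ratio_chance_level(self, config):
        ev = self._events(["correct"] * 12 + ["omission"] * 36,
                          [True] * 12 + [False] * 36)
        m = tc.session_metrics(ev, None)
        assert m.cs_ratio == pytest.approx(0.5)

    def test_cs_ratio_quarter(self):
        ev = self._events(["correct"] * 3 + ["incorrect"] * 3 + ["omission"] * 42,
                          [True] * 18 + [False] * 30)
        m = tc.session_metrics(ev, None)
        assert m.cs_ratio == pytest.approx(0.25)

    def test_cs_ratio_undefined_flagged(self):
        ev = self._events(["omission"] * 4, [False] * 4)
        m = tc.session_metrics(ev, None)
        assert not m.cs_ratio_defined and np.isnan(m.cs_ratio)

    def test_moving_average_shrinking_edges(self):
        np.testing.assert_allclose(
            moving_average([1, 1, 0, 0]), [1.0, 2 / 3, 1 / 3, 0.0]
        )

    def test_incorrect_counts_as_cs_plus_approach(self):
        ev = self._events(["incorrect"] * 6, [True] * 6)
        m = tc.session_metrics(ev, None)
        assert m.cs_ratio == pytest.approx(0.5)


class TestEpochSpeeds:
    def test_net_displacement_speed(self, config):
        # CueOn epoch [cue_on, sipper_in) is 5 s; move 90 px toward the left port
        sched = make_mini_schedule([make_cs_plus_trial(1, 5.0, "left")])
        x0 = HOME[0]
        pose = _trajectory_pose(
            [(5.0, x0, HOME[1]), (10.0, x0 - 90.0, HOME[1]), (18.0, x0 - 90.0, HOME[1])],
            duration_s=25.0,
        )
        ev = tc.detect_and_classify(pose, sched, 9.0, config)
        sp = tc.epoch_speeds(pose, sched, ev)
        assert sp.toward_correct[0, 1] == pytest.approx(18.0, rel=0.02)

    def test_stationary_animal_zero_speed(self, config):
        sched = make_mini_schedule([make_cs_plus_trial(1, 5.0, "left")])
        pose = _trajectory_pose([], duration_s=25.0)
        ev = tc.detect_and_classify(pose, sched, 9.0, config)
        sp = tc.epoch_speeds(pose, sched, ev)
        np.testing.assert_allclose(sp.toward_correct[0], 0.0, atol=1e-9)
        np.testing.assert_allclose(sp.toward_incorrect[0], 0.0, atol=1e-9)

    def test_block_means_shape(self, config, default_session):
        ev = default_session.events
        sp = tc.epoch_speeds(default_session.pose, default_session.schedule, ev)
        assert sp.block_means_correct.shape == (3, 3)
        assert np.isfinite(sp.block_means_correct).all()

    def test_congruent_faster_than_incongruent_cueon(self, config):
        """Proactive agents: cue-onset speed toward the correct sipper is
        higher on congruent than incongruent sessions (20 seeded sessions)."""
        mean_speed = {}
        for stype in ("congruent", "incongruent"):
            vals = []
            for seed in range(10):
                sched = tc.generate_schedule(config, stype, seed=300 + seed)
                agent = tc.AgentParams(control_mode="proactive",
                                       position_noise_px=0.0,
                                       low_likelihood_frac=0.0)
                pose, _ = tc.generate_pose(sched, agent, seed=400 + seed, config=config)
                ev = tc.detect_and_classify(pose, sched, 9.0, config)
                sp = tc.epoch_speeds(pose, sched, ev)
                vals.append(np.nanmean(sp.toward_correct[:, 1]))
            mean_speed[stype] = np.mean(vals)
        assert mean_speed["congruent"] > mean_speed["incongruent"]
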