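import numpy as np
import pytest

import twocap as tc
from twocap.simulate import LANDMARK_POSITIONS
from twocap.types import BodyPartTrack, PoseTrack, TaskSchedule, Trial


@pytest.fixture(scope="session")
def config():
    cfg = tc.AnalysisConfig()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def clean_session(config):
    """Noise-free congruent session with forced-correct behavior: the
    closed-loop ground truth for label-recovery checks."""
    agent = tc.AgentParams(
        p_correct_congruent=1.0, p_omit=0.0, position_noise_px=0.0,
        low_likelihood_frac=0.0,
    )
    schedule = tc.generate_schedule(config, "congruent", seed=7)
    pose, truth = tc.generate_pose(schedule, agent, seed=8, config=config)
    return schedule, pose, truth


@pytest.fixture(scope="session")
def default_session(config):
    """One default-parameter simulated session (with noise and spikes)."""
    return tc.simulate_session(seed=21, config=config)


def make_mini_schedule(trials):
    """Schedule wrapper for hand-built trial lists (validation skipped)."""
    return TaskSchedule(
        session_id="mini", strain="wistar", session_type="congruent", trials=trials
    )


def make_cs_plus_trial(index, cue_on, alcohol_side="left", cs_side=None):
    cs_side = cs_side or alcohol_side
    return Trial(
        index=index, cs_type="CS+", cs_side=cs_side, alcohol_side=alcohol_side,
        cue_on=cue_on, cue_off=cue_on + 4.0, sipper_in=cue_on + 5.0,
        sipper_out=cue_on + 13.0,
    )


def make_pose_from_snout(snout_x, snout_y, fps=30.0, likelihood=None):
    """PoseTrack whose four body points all ride the given snout path."""
    n = len(snout_x)
    lik = np.ones(n) if likelihood is None else np.asarray(likelihood, float)
    parts = {
        name: BodyPartTrack(
            x=np.asarray(snout_x, float).copy(),
            y=np.asarray(snout_y, float).copy(),
            likelihood=lik.copy(),
        )
        for name in ("snout", "head_cap", "back", "tail")
    }
    return PoseTrack(fps=fps, parts=parts, landmarks=dict(LANDMARK_POSITIONS))
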