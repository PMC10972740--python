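"""Synthetic 2CAP sessions: schedules, pose trajectories, and spike trains.

The generator emulates the two behavioral/encoding regimes the analyses are
designed to separate:

* a **proactive** agent/population starts moving at cue onset and carries
  side information *before* the sipper approach (side-coding units ramp up
  in the seconds leading to the approach);
* a **reactive** agent/population moves once the sipper descends and carries
  side information only *after* the approach.

Every stage is deterministic given (parameters, seed) and emits the same
CSV dialects the readers in :mod:`twocap.io` consume, plus ground-truth
labels (per-trial outcomes and per-unit tuning classes) so downstream
stages can be tested closed-loop without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .types import (
    CS_MINUS,
    CS_PLUS,
    BodyPartTrack,
    PoseTrack,
    SpikeData,
    TaskSchedule,
    Trial,
    Unit,
    ValidationError,
)

# Chamber geometry (pixels; video-frame convention, 640 x 480 arena).
ARENA_W, ARENA_H = 640.0, 480.0
LANDMARK_POSITIONS = {
    "corner_tl": (5.0, 5.0),
    "corner_tr": (635.0, 5.0),
    "corner_bl": (5.0, 475.0),
    "corner_br": (635.0, 475.0),
    "sipper_left": (15.0, 240.0),
    "sipper_right": (625.0, 240.0),
}
HOME = (320.0, 240.0)  # chamber center between trials

_PART_OFFSETS = {  # body points trail the snout along x
    "snout": (0.0, 0.0),
    "head_cap": (8.0, 2.0),
    "back": (20.0, 4.0),
    "tail": (38.0, 6.0),
}


@dataclass
class AgentParams:
    """Behavioral phenotype of the simulated animal.

    ``p_follow_cue`` is the probability of approaching the CS+ side
    regardless of where alcohol is — on incongruent sessions this drives
    incorrect first approaches (the hallmark of rule-following, proactive
    behavior).  On congruent sessions the first approach is correct with
    probability ``p_correct_congruent``.  Incorrect trials visit the wrong
    port, dwell ``check_duration_s``, then proceed to the correct port, so
    both the latency-to-incorrect and the eventual drink are realized.
    """

    control_mode: str = "proactive"  # proactive | reactive
    p_correct_congruent: float = 0.90
    p_follow_cue: float = 0.90
    p_omit: float = 0.05
    p_approach_cs_minus: float = 0.25
    latency_mean_s: float = 2.0
    latency_sd_s: float = 0.5
    speed_px_s: float = 200.0
    position_noise_px: float = 2.0
    check_duration_s: float = 1.0
    low_likelihood_frac: float = 0.02
    engagement_decay: float = 0.0  # optional linear decline in approach prob.
    # deliberation: a rule-following (proactive) agent moves more slowly when
    # the session contingency conflicts with the learned rule
    incongruent_speed_factor: float = 0.7

    def validate(self) -> None:
        for name in ("p_correct_congruent", "p_follow_cue", "p_omit", "p_approach_cs_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"agent: {name} outside [0, 1]")
        if self.p_correct_congruent + self.p_omit > 1.0 + 1e-12:
            raise ValidationError("agent: p_correct_congruent + p_omit > 1")
        if self.control_mode not in ("proactive", "reactive"):
            raise ValidationError(f"agent: bad control_mode {self.control_mode!r}")
        if self.speed_px_s <= 0 or self.position_noise_px < 0:
            raise ValidationError("agent: bad kinematic parameters")


@dataclass
class PopulationParams:
    """Tuning structure of the simulated population.

    Units are inhomogeneous Poisson with a hard refractory period; gains
    multiply the gamma-distributed baseline rate inside their event windows.
    ``side_code_onset`` places side coding either in the ``side_code_lead_s``
    seconds *before* the approach (proactive regime) or the same span
    *after* it (reactive regime).
    """

    n_units: int = 40
    baseline_shape: float = 2.0
    baseline_scale_hz: float = 2.5  # mean baseline = shape * scale = 5 Hz
    frac_cue_mod: float = 0.2
    frac_sipper_mod: float = 0.2
    frac_side: float = 0.4  # split evenly between left- and right-preferring
    cue_gain: float = 3.0
    sipper_gain: float = 3.0
    side_gain: float = 3.0
    side_code_onset: str = "pre_approach"  # pre_approach | post_approach
    side_code_lead_s: float = 2.0
    refractory_s: float = 0.002

    def validate(self) -> None:
        fracs = (self.frac_cue_mod, self.frac_sipper_mod, self.frac_side)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValidationError("population: tuning fractions must be >= 0 and sum <= 1")
        if min(self.cue_gain, self.sipper_gain, self.side_gain) < 0:
            raise ValidationError("population: gains must be >= 0")
        if self.side_code_onset not in ("pre_approach", "post_approach"):
            raise ValidationError(f"population: bad side_code_onset {self.side_code_onset!r}")
        if self.n_units < 1:
            raise ValidationError("population: n_units must be >= 1")


@dataclass
class SessionTruth:
    """Ground-truth labels recorded while generating a session."""

    trial_index: np.ndarray  # CS+ trial indices
    outcome: list[str]
    first_port: list[str]
    approach_time: np.ndarray  # first port entry (s), nan on omission
    approach_side: list[str]
    approach_time_correct: np.ndarray  # entry at alcohol port, nan if never
    cs_minus_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cs_minus_approached: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def generate_schedule(
    config: AnalysisConfig,
    session_type: str,
    seed: int,
    strain: str = "wistar",
    session_id: Optional[str] = None,
) -> TaskSchedule:
    """Draw one 96-trial session: 48 CS+ (random side) and 48 CS-.

    Trial order is randomized, the cue style is counterbalanced, and on
    incongruent sessions the alcohol side is opposite the CS+ side.
    """
    rng = np.random.default_rng(seed)
    n_plus = TaskSchedule.N_CS_PLUS
    n_minus = TaskSchedule.N_TRIALS - n_plus
    cs_types = np.array([CS_PLUS] * n_plus + [CS_MINUS] * n_minus)
    rng.shuffle(cs_types)
    # counterbalanced cue styles within each CS type
    styles = {
        CS_PLUS: rng.permutation(["solid"] * (n_plus // 2) + ["blink_1Hz"] * (n_plus // 2)),
        CS_MINUS: rng.permutation(["solid"] * (n_minus // 2) + ["blink_1Hz"] * (n_minus // 2)),
    }
    counters = {CS_PLUS: 0, CS_MINUS: 0}
    slot = TaskSchedule.CS_DURATION_S + TaskSchedule.DELAY_S + TaskSchedule.ACCESS_S
    trials = []
    for i, cs_type in enumerate(cs_types):
        cue_on = config.iti_s + i * (slot + config.iti_s)
        cue_off = cue_on + TaskSchedule.CS_DURATION_S
        style = styles[cs_type][counters[cs_type]]
        counters[cs_type] += 1
        if cs_type == CS_PLUS:
            cs_side = "left" if rng.random() < 0.5 else "right"
            if session_type == "congruent":
                alcohol_side = cs_side
            else:
                alcohol_side = "right" if cs_side == "left" else "left"
            sipper_in = cue_off + TaskSchedule.DELAY_S
            sipper_out = sipper_in + TaskSchedule.ACCESS_S
        else:
            cs_side, alcohol_side = "both", "none"
            sipper_in = sipper_out = None
        trials.append(
            Trial(
                index=i + 1,
                cs_type=str(cs_type),
                cs_side=cs_side,
                alcohol_side=alcohol_side,
                cue_on=cue_on,
                cue_off=cue_off,
                sipper_in=sipper_in,
                sipper_out=sipper_out,
                cue_style=str(style),
            )
        )
    schedule = TaskSchedule(
        session_id=session_id or f"sim-{session_type}-{seed}",
        strain=strain,
        session_type=session_type,
        trials=trials,
    )
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# Pose
# ---------------------------------------------------------------------------


def _port_xy(side: str) -> tuple[float, float]:
    return LANDMARK_POSITIONS["sipper_left" if side == "left" else "sipper_right"]


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def generate_pose(
    schedule: TaskSchedule,
    agent: AgentParams,
    seed: int,
    config: Optional[AnalysisConfig] = None,
) -> tuple[PoseTrack, SessionTruth]:
    """Simulate a snout trajectory for every trial and record truth labels.

    The agent rests at the chamber center, leaves after ``cue_on + latency``
    (proactive) or ``sipper_in + latency`` (reactive), travels at constant
    speed to the chosen port, drinks until the sipper is removed, and
    returns home.  Trials whose kinematics never reach a port inside the
    access window are re-labeled omissions in the truth.
    """
    agent.validate()
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    fps = config.fps
    speed = agent.speed_px_s
    if agent.control_mode == "proactive" and schedule.session_type == "incongruent":
        speed *= agent.incongruent_speed_factor
    duration = schedule.end_time + 15.0
    n_frames = int(round(duration * fps))
    times = np.arange(n_frames) / fps

    way_t = [0.0]
    way_x = [HOME[0]]
    way_y = [HOME[1]]

    def add_waypoint(t: float, xy: tuple[float, float]) -> float:
        t = max(t, way_t[-1] + 1.0 / fps)
        way_t.append(t)
        way_x.append(xy[0])
        way_y.append(xy[1])
        return t

    plus_idx, outcomes, first_ports, approach_sides = [], [], [], []
    planned = {}  # trial index -> (first side, incorrect_first flag)
    minus_idx, minus_approached = [], []

    n_plus_seen = 0
    for trial in schedule.trials:
        if trial.cs_type == CS_PLUS:
            n_plus_seen += 1
            u = rng.random()
            omit_p = min(1.0, agent.p_omit + agent.engagement_decay * (n_plus_seen - 1))
            latency = max(0.0, rng.normal(agent.latency_mean_s, agent.latency_sd_s))
            if u < omit_p:
                planned[trial.index] = (None, False)
                continue
            if schedule.session_type == "congruent":
                # conditional-on-not-omitted probability keeps the marginal
                # P(correct) = p_correct_congruent when decay is off
                p_corr = agent.p_correct_congruent / max(1e-12, 1.0 - agent.p_omit)
                correct_first = rng.random() < min(1.0, p_corr)
                first_side = trial.alcohol_side if correct_first else _other(trial.alcohol_side)
            else:
                follow = rng.random() < agent.p_follow_cue
                first_side = trial.cs_side if follow else trial.alcohol_side
            incorrect_first = first_side != trial.alcohol_side
            planned[trial.index] = (first_side, incorrect_first)

            start_ref = trial.cue_on if agent.control_mode == "proactive" else trial.sipper_in
            t0 = add_waypoint(max(start_ref + latency, way_t[-1]), HOME)
            first_xy = _port_xy(first_side)
            t_arr1 = add_waypoint(t0 + _dist(HOME, first_xy) / speed, first_xy)
            if incorrect_first:
                # the animal keeps checking the (empty) port until the sipper
                # descends, then corrects after check_duration_s
                t_chk = add_waypoint(
                    max(t_arr1, trial.sipper_in) + agent.check_duration_s, first_xy
                )
                corr_xy = _port_xy(trial.alcohol_side)
                t_arr2 = add_waypoint(
                    t_chk + _dist(first_xy, corr_xy) / speed, corr_xy
                )
                end_xy = corr_xy
                t_leave = max(trial.sipper_out, t_arr2 + 0.2)
            else:
                end_xy = first_xy
                t_leave = max(trial.sipper_out, t_arr1 + 0.2)
            add_waypoint(t_leave, end_xy)
            add_waypoint(t_leave + _dist(end_xy, HOME) / speed, HOME)
        else:
            minus_idx.append(trial.index)
            if rng.random() < agent.p_approach_cs_minus:
                minus_approached.append(True)
                latency = max(0.0, rng.normal(agent.latency_mean_s, agent.latency_sd_s))
                side = "left" if rng.random() < 0.5 else "right"
                xy = _port_xy(side)
                t0 = add_waypoint(max(trial.cue_on + latency, way_t[-1]), HOME)
                t_arr = add_waypoint(t0 + _dist(HOME, xy) / speed, xy)
                t_leave = add_waypoint(t_arr + 1.0, xy)
                add_waypoint(t_leave + _dist(xy, HOME) / speed, HOME)
            else:
                minus_approached.append(False)

    add_waypoint(duration + 1.0, HOME)
    snout_x = np.interp(times, way_t, way_x)
    snout_y = np.interp(times, way_t, way_y)

    # Truth timing from the noiseless kinematics, on the frame grid, using
    # the same <= radius rule the event detector applies.
    radius = config.approach_radius_px
    left_xy, right_xy = _port_xy("left"), _port_xy("right")
    d_left = np.hypot(snout_x - left_xy[0], snout_y - left_xy[1])
    d_right = np.hypot(snout_x - right_xy[0], snout_y - right_xy[1])

    approach_time = []
    approach_time_correct = []
    for trial in schedule.cs_plus_trials:
        plus_idx.append(trial.index)
        planned_side, _ = planned[trial.index]
        lo = int(np.ceil(trial.sipper_in * fps))
        hi = int(np.floor(trial.sipper_out * fps)) + 1
        in_l = d_left[lo:hi] <= radius
        in_r = d_right[lo:hi] <= radius
        hit_l = int(np.argmax(in_l)) if in_l.any() else None
        hit_r = int(np.argmax(in_r)) if in_r.any() else None
        if planned_side is None or (hit_l is None and hit_r is None):
            outcomes.append("omission")
            first_ports.append("none")
            approach_sides.append("none")
            approach_time.append(np.nan)
            approach_time_correct.append(np.nan)
            continue
        if hit_r is None or (hit_l is not None and hit_l <= hit_r):
            side, hit = "left", hit_l
        else:
            side, hit = "right", hit_r
        t_app = times[lo + hit]
        first_ports.append(side)
        approach_sides.append(side)
        approach_time.append(t_app)
        if side == trial.alcohol_side:
            outcomes.append("correct")
            approach_time_correct.append(t_app)
        else:
            outcomes.append("incorrect")
            corr_hits = in_l if trial.alcohol_side == "left" else in_r
            later = np.flatnonzero(corr_hits)
            approach_time_correct.append(times[lo + later[0]] if later.size else np.nan)

    truth = SessionTruth(
        trial_index=np.asarray(plus_idx, dtype=int),
        outcome=outcomes,
        first_port=first_ports,
        approach_time=np.asarray(approach_time),
        approach_side=approach_sides,
        approach_time_correct=np.asarray(approach_time_correct),
        cs_minus_index=np.asarray(minus_idx, dtype=int),
        cs_minus_approached=np.asarray(minus_approached, dtype=bool),
    )

    parts = {}
    for name, (dx, dy) in _PART_OFFSETS.items():
        x = snout_x + dx + rng.normal(0.0, agent.position_noise_px, n_frames)
        y = snout_y + dy + rng.normal(0.0, agent.position_noise_px, n_frames)
        lik = np.full(n_frames, 0.99)
        if agent.low_likelihood_frac > 0:
            n_low = int(round(agent.low_likelihood_frac * n_frames))
            low = rng.choice(n_frames, size=n_low, replace=False)
            lik[low] = 0.5
            x[low] += rng.normal(0.0, 50.0, n_low)  # corrupted, to be interpolated
            y[low] += rng.normal(0.0, 50.0, n_low)
        parts[name] = BodyPartTrack(x=x, y=y, likelihood=lik)

    pose = PoseTrack(fps=fps, parts=parts, landmarks=dict(LANDMARK_POSITIONS))
    pose.validate()
    return pose, truth


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.array([]), np.array([])
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _gain_intervals(
    unit_class: str,
    schedule: TaskSchedule,
    truth: SessionTruth,
    pop: PopulationParams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Windows in which this unit's rate is multiplied by its gain."""
    iv: list[tuple[float, float]] = []
    if unit_class == "cue_mod":
        iv = [(t.cue_on, t.cue_off) for t in schedule.trials]
        gain = pop.cue_gain
    elif unit_class == "sipper_mod":
        for t in schedule.cs_plus_trials:
            iv.append((t.sipper_in, t.sipper_in + 1.0))
            iv.append((t.sipper_out - 1.0, t.sipper_out))
        gain = pop.sipper_gain
    elif unit_class in ("side_left", "side_right"):
        pref = "left" if unit_class == "side_left" else "right"
        for side, t_app in zip(truth.approach_side, truth.approach_time):
            if side != pref or not np.isfinite(t_app):
                continue
            if pop.side_code_onset == "pre_approach":
                iv.append((t_app - pop.side_code_lead_s, t_app))
            else:
                iv.append((t_app, t_app + pop.side_code_lead_s))
        gain = pop.side_gain
    else:  # untuned
        gain = 1.0
    starts, ends = _merge_intervals(iv)
    return starts, ends, gain


def generate_spikes(
    schedule: TaskSchedule,
    truth: SessionTruth,
    pop: PopulationParams,
    seed: int,
    duration_s: Optional[float] = None,
) -> SpikeData:
    """Simulate each unit as an inhomogeneous Poisson process with a hard
    refractory period (thinning), with event-locked gain windows per the
    unit's tuning class.  ISI violations are zero by construction."""
    pop.validate()
    rng = np.random.default_rng(seed)
    T = duration_s if duration_s is not None else schedule.end_time + 15.0

    n = pop.n_units
    n_cue = int(round(pop.frac_cue_mod * n))
    n_sip = int(round(pop.frac_sipper_mod * n))
    n_side = int(round(pop.frac_side * n))
    classes = (
        ["cue_mod"] * n_cue
        + ["sipper_mod"] * n_sip
        + ["side_left"] * (n_side // 2 + n_side % 2)
        + ["side_right"] * (n_side // 2)
    )
    classes += ["untuned"] * (n - len(classes))
    classes = [classes[i] for i in rng.permutation(n)]

    units = []
    for i, unit_class in enumerate(classes):
        baseline = rng.gamma(pop.baseline_shape, pop.baseline_scale_hz)
        starts, ends, gain = _gain_intervals(unit_class, schedule, truth, pop)
        rate_max = baseline * max(1.0, gain)
        n_cand = rng.poisson(rate_max * T)
        cand = np.sort(rng.uniform(0.0, T, n_cand))
        rate = np.full(cand.shape, baseline)
        if starts.size:
            pos = np.searchsorted(starts, cand, side="right") - 1
            inside = (pos >= 0) & (cand < ends[np.clip(pos, 0, len(ends) - 1)])
            rate[inside] = baseline * gain
        keep = rng.uniform(0.0, rate_max, n_cand) < rate
        spikes = cand[keep]
        # hard refractory: drop spikes closer than refractory_s to the last kept
        if spikes.size:
            kept = [spikes[0]]
            for t in spikes[1:]:
                if t - kept[-1] >= pop.refractory_s:
                    kept.append(t)
            spikes = np.asarray(kept)
        isi = np.diff(spikes)
        viol = float(np.mean(isi < pop.refractory_s)) if isi.size else 0.0
        units.append(
            Unit(
                unit_id=f"u{i:03d}",
                spike_times=spikes,
                isi_violation_fraction=viol,
                truth_class=unit_class,
            )
        )
    data = SpikeData(session_id=schedule.session_id, units=units)
    data.validate()
    return data
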