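"""Domain types for 2CAP session analysis.

The two-way cued access protocol (2CAP) is a shuttle-box task in which a
visual CS+ predicts timed sipper access to 10% alcohol on one side of the
chamber; the CS- illuminates both sides and predicts no access.  A session
interleaves 48 CS+ and 48 CS- trials.  These dataclasses carry a session's
trial schedule, the pose-tracking output, and the sorted spike data, plus
the result containers produced by the analysis stages.

All event times are seconds from session start (one clock for pose and
spikes); coordinates are pixels with origin top-left, x rightward, y
downward.  "left"/"right" are chamber-fixed (camera view).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

CS_PLUS = "CS+"
CS_MINUS = "CS-"

BODY_PARTS = ("snout", "head_cap", "back", "tail")
LANDMARKS = (
    "corner_tl",
    "corner_tr",
    "corner_bl",
    "corner_br",
    "sipper_left",
    "sipper_right",
)

STRAINS = ("wistar", "prat")
SESSION_TYPES = ("congruent", "incongruent")


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    """One trial of a 2CAP session.

    CS+ trials: 4 s cue, 1 s delay, then 8 s of sipper access.  CS- trials
    illuminate both sides and have no sipper events (``sipper_in`` and
    ``sipper_out`` are None).
    """

    index: int  # 1-based
    cs_type: str  # CS+ or CS-
    cs_side: str  # left / right / both
    alcohol_side: str  # left / right / none
    cue_on: float
    cue_off: float
    sipper_in: Optional[float]
    sipper_out: Optional[float]
    cue_style: str = "solid"  # solid or blink_1Hz

    def validate(self) -> None:
        if self.cs_type not in (CS_PLUS, CS_MINUS):
            raise ValidationError(f"trial {self.index}: bad cs_type {self.cs_type!r}")
        if self.cue_style not in ("solid", "blink_1Hz"):
            raise ValidationError(f"trial {self.index}: bad cue_style {self.cue_style!r}")
        if not self.cue_on < self.cue_off:
            raise ValidationError(f"trial {self.index}: cue_on >= cue_off")
        if self.cs_type == CS_PLUS:
            if self.cs_side not in ("left", "right"):
                raise ValidationError(f"trial {self.index}: CS+ cs_side {self.cs_side!r}")
            if self.alcohol_side not in ("left", "right"):
                raise ValidationError(
                    f"trial {self.index}: CS+ alcohol_side {self.alcohol_side!r}"
                )
            if self.sipper_in is None or self.sipper_out is None:
                raise ValidationError(f"trial {self.index}: CS+ trial missing sipper events")
            if not self.cue_off < self.sipper_in < self.sipper_out:
                raise ValidationError(f"trial {self.index}: sipper times not increasing")
        else:
            if self.cs_side != "both":
                raise ValidationError(f"trial {self.index}: CS- cs_side must be 'both'")
            if self.alcohol_side != "none":
                raise ValidationError(f"trial {self.index}: CS- alcohol_side must be 'none'")
            if self.sipper_in is not None or self.sipper_out is not None:
                raise ValidationError(f"trial {self.index}: CS- trial has sipper events")


@dataclass
class TaskSchedule:
    """Per-trial contingency and event-time table for one session."""

    session_id: str
    strain: str
    session_type: str
    trials: list[Trial]

    N_TRIALS = 96
    N_CS_PLUS = 48
    CS_DURATION_S = 4.0
    DELAY_S = 1.0
    ACCESS_S = 8.0

    def validate(self, require_full: bool = True) -> None:
        if self.strain not in STRAINS:
            raise ValidationError(f"unknown strain {self.strain!r}")
        if self.session_type not in SESSION_TYPES:
            raise ValidationError(f"unknown session_type {self.session_type!r}")
        seen: set[int] = set()
        for t in self.trials:
            if t.index in seen:
                raise ValidationError(f"duplicate trial index {t.index}")
            seen.add(t.index)
            t.validate()
            if t.cs_type == CS_PLUS:
                if abs((t.cue_off - t.cue_on) - self.CS_DURATION_S) > 1e-9:
                    raise ValidationError(f"trial {t.index}: cue duration != 4 s")
                if abs((t.sipper_in - t.cue_off) - self.DELAY_S) > 1e-9:
                    raise ValidationError(f"trial {t.index}: sipper delay != 1 s")
                if abs((t.sipper_out - t.sipper_in) - self.ACCESS_S) > 1e-9:
                    raise ValidationError(f"trial {t.index}: access != 8 s")
                if self.session_type == "congruent" and t.alcohol_side != t.cs_side:
                    raise ValidationError(
                        f"trial {t.index}: congruent session but alcohol_side != cs_side"
                    )
                if self.session_type == "incongruent" and t.alcohol_side == t.cs_side:
                    raise ValidationError(
                        f"trial {t.index}: incongruent session but alcohol_side == cs_side"
                    )
        if require_full:
            n_plus = sum(1 for t in self.trials if t.cs_type == CS_PLUS)
            if len(self.trials) != self.N_TRIALS:
                raise ValidationError(
                    f"expected {self.N_TRIALS} trials, got {len(self.trials)}"
                )
            if n_plus != self.N_CS_PLUS:
                raise ValidationError(f"expected {self.N_CS_PLUS} CS+ trials, got {n_plus}")

    @property
    def cs_plus_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.cs_type == CS_PLUS]

    @property
    def cs_minus_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.cs_type == CS_MINUS]

    @property
    def end_time(self) -> float:
        ends = [t.sipper_out if t.sipper_out is not None else t.cue_off for t in self.trials]
        return max(ends) if ends else 0.0


# ---------------------------------------------------------------------------
# Pose
# ---------------------------------------------------------------------------


@dataclass
class BodyPartTrack:
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    imputed: np.ndarray = None  # bool mask of interpolated frames

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.x.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)


@dataclass
class PoseTrack:
    """Time-stamped body-part coordinates plus the six static landmarks.

    ``parts`` maps each of the four tracked body points (snout, head cap,
    back, tail) to per-frame (x, y, likelihood); ``landmarks`` maps the four
    chamber corners and two sipper ports to static (x, y) pixels.
    """

    fps: float
    parts: dict[str, BodyPartTrack]
    landmarks: dict[str, tuple[float, float]]

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        missing = [p for p in BODY_PARTS if p not in self.parts]
        if missing:
            raise ValidationError(f"missing body parts: {missing}")
        unknown = [p for p in self.parts if p not in BODY_PARTS]
        if unknown:
            raise ValidationError(f"unknown body-part name(s): {unknown}")
        missing_lm = [m for m in LANDMARKS if m not in self.landmarks]
        if missing_lm:
            raise ValidationError(f"incomplete landmark set, missing: {missing_lm}")
        n = self.n_frames
        for name, tr in self.parts.items():
            if len(tr.x) != n or len(tr.y) != n or len(tr.likelihood) != n:
                raise ValidationError(f"{name}: ragged frame arrays")
            bad = np.flatnonzero((tr.likelihood < 0) | (tr.likelihood > 1))
            if bad.size:
                raise ValidationError(
                    f"{name}: likelihood outside [0, 1] at frame {int(bad[0])}"
                )

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.parts.values())).x)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------


@dataclass
class Unit:
    unit_id: str
    spike_times: np.ndarray  # seconds, ascending
    isi_violation_fraction: float = 0.0
    truth_class: Optional[str] = None  # cue_mod/sipper_mod/side_left/side_right/untuned

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self) -> None:
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not non-decreasing")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if not 0.0 <= self.isi_violation_fraction <= 1.0:
            raise ValidationError(f"unit {self.unit_id}: bad isi_violation_fraction")


@dataclass
class SpikeData:
    """Unit-labeled spike times for one session (sorted, QC'd output)."""

    session_id: str
    units: list[Unit]

    def validate(self) -> None:
        seen: set[str] = set()
        for u in self.units:
            if u.unit_id in seen:
                raise ValidationError(f"duplicate unit_id {u.unit_id}")
            seen.add(u.unit_id)
            u.validate()

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]


# ---------------------------------------------------------------------------
# Behavioral results
# ---------------------------------------------------------------------------


@dataclass
class TrialEvents:
    """Per-trial behavioral outcomes for the CS+ trials of a session.

    An approach is the first frame the snout comes within the approach
    radius of a sipper port while the sipper is in the chamber; a trial is
    correct iff the first port visited is the alcohol side, an omission iff
    neither port is visited.  Latencies are seconds from sipper descent.
    """

    trial_index: np.ndarray  # CS+ trial indices (1-based, session order)
    outcome: list[str]  # correct / incorrect / omission
    first_port_visited: list[str]  # left / right / none
    approach_time_correct: np.ndarray  # seconds or nan
    approach_time_incorrect: np.ndarray
    latency_correct_s: np.ndarray
    latency_incorrect_s: np.ndarray
    occupancy_correct: np.ndarray  # trials x frames, binary
    occupancy_incorrect: np.ndarray
    cs_minus_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cs_minus_approached: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_trials(self) -> int:
        return len(self.outcome)


@dataclass
class SessionMetrics:
    n_correct: int
    n_incorrect: int
    n_omission: int
    cs_ratio: float  # nan when undefined
    cs_ratio_defined: bool
    mean_latency_correct_s: float
    mean_latency_incorrect_s: float
    approach_prob_correct: np.ndarray  # 3-trial moving average per CS+ trial
    approach_prob_incorrect: np.ndarray
    occupancy_prob_correct: np.ndarray  # mean over trials, per frame
    occupancy_prob_incorrect: np.ndarray


@dataclass
class EpochSpeeds:
    """Per-trial epoch speeds (px/s) toward the correct/incorrect sipper.

    Epochs: PreCue = [cue_on-4, cue_on), CueOn = [cue_on, sipper_in),
    SipIn = [sipper_in, sipper_out).  Block means cover CS+ trials 1-5,
    6-10, 11-15.
    """

    epochs: tuple[str, ...]
    toward_correct: np.ndarray  # trials x epochs, nan when undefined
    toward_incorrect: np.ndarray
    block_means_correct: np.ndarray  # 3 x epochs
    block_means_incorrect: np.ndarray


# ---------------------------------------------------------------------------
# Firing-rate results
# ---------------------------------------------------------------------------


@dataclass
class ISIStats:
    mean_isi_s: float
    cv: float
    n_isi: int


@dataclass
class RateTensor:
    """Event-aligned smoothed firing rates, units x bins x trials (Hz).

    Bin centers sit on the bin-width grid and span both window endpoints
    inclusively, so [-4, 18] s at 0.1 s gives 221 bins.
    """

    unit_ids: list[str]
    alignment_event: str  # cue_on or approach
    window_s: tuple[float, float]
    bin_width_s: float
    bins: np.ndarray  # centers, seconds relative to event
    rates: np.ndarray  # units x bins x trials
    trial_indices: np.ndarray  # schedule trial indices used

    @property
    def n_bins(self) -> int:
        return len(self.bins)


# ---------------------------------------------------------------------------
# Population-geometry results
# ---------------------------------------------------------------------------


@dataclass
class BrokenStick:
    """Broken-stick expected variance fractions b_k = (1/p) sum_{i=k..p} 1/i."""

    p: int
    thresholds: np.ndarray


@dataclass
class PCAResult:
    coefficients: np.ndarray  # units x components (unit-norm columns)
    scores: np.ndarray  # timepoints x components
    explained_fraction: np.ndarray
    column_means: np.ndarray  # per-unit means removed before decomposition
    retained: int


@dataclass
class SideProjection:
    left_scores: np.ndarray  # timepoints x retained components
    right_scores: np.ndarray
    approach_index: int


@dataclass
class PermDistanceResult:
    """Mean left/right separation per 3-D PC subspace for one condition."""

    condition: str
    subspaces: list[tuple[int, ...]]
    mean_distances: np.ndarray  # one per subspace
    n_bootstrap: int
    pre_approach_only: bool
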