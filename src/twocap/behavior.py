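"""Trial-resolved behavioral events and session metrics from pose tables.

The scoring rules: an approach is the first frame the snout marker comes
within the approach radius (default 9 px) of a sipper-port landmark while
the sipper is in the chamber; a trial is correct when the alcohol port is
visited first, incorrect when the other port is visited first, and an
omission when neither port is visited.  Latency runs from sipper descent.
The CS discrimination ratio counts both correct and incorrect approaches as
CS+ approaches; 0.5 is chance.  Port visits during the cue but before the
sipper descends are ignored for latency but a CS- trial is still scored as
approached for the ratio.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import (
    CS_PLUS,
    EpochSpeeds,
    PoseTrack,
    SessionMetrics,
    TaskSchedule,
    TrialEvents,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Interpolation of low-confidence frames
# ---------------------------------------------------------------------------


def interpolate_low_confidence(pose: PoseTrack, floor: float = 0.90) -> PoseTrack:
    """Replace frames whose tracker likelihood is below ``floor`` by linear
    interpolation between the nearest flanking confident frames.

    Edge frames with no confident neighbor on one side take the nearest
    confident value.  Replaced frames get likelihood = ``floor`` and are
    flagged in the ``imputed`` mask.  A body part with zero confident
    frames raises an error naming the part.
    """
    pose.validate()
    new_parts = {}
    idx = np.arange(pose.n_frames)
    for name, tr in pose.parts.items():
        good = tr.likelihood >= floor
        if not good.any():
            raise ValidationError(f"body part {name!r} has no frames with likelihood >= {floor}")
        if good.all():
            new_parts[name] = type(tr)(
                x=tr.x.copy(), y=tr.y.copy(), likelihood=tr.likelihood.copy()
            )
            continue
        gi = idx[good]
        x = np.interp(idx, gi, tr.x[good])  # np.interp clamps at the edges
        y = np.interp(idx, gi, tr.y[good])
        lik = tr.likelihood.copy()
        lik[~good] = floor
        new_parts[name] = type(tr)(x=x, y=y, likelihood=lik, imputed=~good)
    return PoseTrack(fps=pose.fps, parts=new_parts, landmarks=dict(pose.landmarks))


# ---------------------------------------------------------------------------
# Event detection and trial classification
# ---------------------------------------------------------------------------


def _port_distances(pose: PoseTrack) -> tuple[np.ndarray, np.ndarray]:
    snout = pose.parts["snout"]
    lx, ly = pose.landmarks["sipper_left"]
    rx, ry = pose.landmarks["sipper_right"]
    return (
        np.hypot(snout.x - lx, snout.y - ly),
        np.hypot(snout.x - rx, snout.y - ry),
    )


def detect_and_classify(
    pose: PoseTrack,
    schedule: TaskSchedule,
    radius_px: float = 9.0,
    config: Optional[AnalysisConfig] = None,
) -> TrialEvents:
    """Scan each CS+ trial's access window for port entries and classify.

    Occupancy vectors mark, at frame resolution over the behavioral window
    around cue onset, the frames the snout spends within the radius of the
    correct/incorrect port.  CS- trials are scored approached/not for the
    CS discrimination ratio using the equivalent (virtual) access window.
    """
    if radius_px <= 0:
        raise ValidationError("radius_px must be positive")
    config = config or AnalysisConfig()
    fps = pose.fps
    last_needed = schedule.end_time
    if pose.duration_s + 1.0 / fps < last_needed:
        raise ValidationError(
            f"pose ({pose.duration_s:.2f} s) does not cover schedule ({last_needed:.2f} s)"
        )
    d_left, d_right = _port_distances(pose)
    times = pose.times
    win_lo, win_hi = config.behavior_window_s
    n_win = int(round((win_hi - win_lo) * fps))

    trial_index, outcomes, first_ports = [], [], []
    app_corr, app_inc, lat_corr, lat_inc = [], [], [], []
    occ_corr, occ_inc = [], []
    minus_idx, minus_app = [], []

    for trial in schedule.trials:
        if trial.cs_type == CS_PLUS:
            lo = int(np.ceil(trial.sipper_in * fps))
            hi = min(int(np.floor(trial.sipper_out * fps)) + 1, len(times))
            alc = trial.alcohol_side
            d_alc = d_left if alc == "left" else d_right
            d_oth = d_right if alc == "left" else d_left
            in_alc = d_alc[lo:hi] <= radius_px
            in_oth = d_oth[lo:hi] <= radius_px
            hit_alc = int(np.argmax(in_alc)) if in_alc.any() else None
            hit_oth = int(np.argmax(in_oth)) if in_oth.any() else None

            t_corr = times[lo + hit_alc] if hit_alc is not None else np.nan
            t_inc = times[lo + hit_oth] if hit_oth is not None else np.nan
            if hit_alc is None and hit_oth is None:
                outcome, first = "omission", "none"
            elif hit_oth is None or (hit_alc is not None and hit_alc <= hit_oth):
                outcome, first = "correct", alc
            else:
                outcome, first = "incorrect", "left" if alc == "right" else "right"

            trial_index.append(trial.index)
            outcomes.append(outcome)
            first_ports.append(first)
            app_corr.append(t_corr)
            app_inc.append(t_inc)
            lat_corr.append(t_corr - trial.sipper_in if np.isfinite(t_corr) else np.nan)
            lat_inc.append(t_inc - trial.sipper_in if np.isfinite(t_inc) else np.nan)

            w0 = int(round((trial.cue_on + win_lo) * fps))
            occ_c = np.zeros(n_win, dtype=np.int8)
            occ_i = np.zeros(n_win, dtype=np.int8)
            sl = slice(max(w0, 0), min(w0 + n_win, len(times)))
            off = max(w0, 0) - w0
            occ_c[off : off + (sl.stop - sl.start)] = d_alc[sl] <= radius_px
            occ_i[off : off + (sl.stop - sl.start)] = d_oth[sl] <= radius_px
            occ_corr.append(occ_c)
            occ_inc.append(occ_i)
        else:
            v_in = trial.cue_off + TaskSchedule.DELAY_S
            v_out = v_in + TaskSchedule.ACCESS_S
            lo = int(np.ceil(v_in * fps))
            hi = min(int(np.floor(v_out * fps)) + 1, len(times))
            approached = bool(
                (d_left[lo:hi] <= radius_px).any() or (d_right[lo:hi] <= radius_px).any()
            )
            minus_idx.append(trial.index)
            minus_app.append(approached)

    return TrialEvents(
        trial_index=np.asarray(trial_index, dtype=int),
        outcome=outcomes,
        first_port_visited=first_ports,
        approach_time_correct=np.asarray(app_corr),
        approach_time_incorrect=np.asarray(app_inc),
        latency_correct_s=np.asarray(lat_corr),
        latency_incorrect_s=np.asarray(lat_inc),
        occupancy_correct=np.asarray(occ_corr),
        occupancy_incorrect=np.asarray(occ_inc),
        cs_minus_index=np.asarray(minus_idx, dtype=int),
        cs_minus_approached=np.asarray(minus_app, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Session metrics
# ---------------------------------------------------------------------------


def moving_average(indicator: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    s = pd.Series(np.asarray(indicator, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def session_metrics(events: TrialEvents, schedule: TaskSchedule) -> SessionMetrics:
    """Counts, CS discrimination ratio, latencies, smoothed approach
    probabilities, and occupancy probabilities for one session."""
    outcomes = np.asarray(events.outcome)
    n_correct = int(np.sum(outcomes == "correct"))
    n_incorrect = int(np.sum(outcomes == "incorrect"))
    n_omission = int(np.sum(outcomes == "omission"))

    plus_approaches = n_correct + n_incorrect  # both count as CS+ approaches
    minus_approaches = int(np.sum(events.cs_minus_approached))
    total = plus_approaches + minus_approaches
    if total == 0:
        cs_ratio, defined = float("nan"), False
    else:
        cs_ratio, defined = plus_approaches / total, True

    lat_c = events.latency_correct_s[np.isfinite(events.latency_correct_s)]
    lat_i = events.latency_incorrect_s[np.isfinite(events.latency_incorrect_s)]
    correct_ind = (outcomes == "correct").astype(float)
    incorrect_ind = (outcomes == "incorrect").astype(float)

    occ_c = events.occupancy_correct
    occ_i = events.occupancy_incorrect
    return SessionMetrics(
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_omission=n_omission,
        cs_ratio=cs_ratio,
        cs_ratio_defined=defined,
        mean_latency_correct_s=float(np.mean(lat_c)) if lat_c.size else float("nan"),
        mean_latency_incorrect_s=float(np.mean(lat_i)) if lat_i.size else float("nan"),
        approach_prob_correct=moving_average(correct_ind),
        approach_prob_incorrect=moving_average(incorrect_ind),
        occupancy_prob_correct=occ_c.mean(axis=0) if len(occ_c) else np.array([]),
        occupancy_prob_incorrect=occ_i.mean(axis=0) if len(occ_i) else np.array([]),
    )


# ---------------------------------------------------------------------------
# Epoch speeds
# ---------------------------------------------------------------------------

EPOCH_NAMES = ("PreCue", "CueOn", "SipIn")


def epoch_speeds(
    pose: PoseTrack,
    schedule: TaskSchedule,
    events: TrialEvents,
    block_size: int = 5,
    n_block_trials: int = 15,
) -> EpochSpeeds:
    """Net speed toward each sipper per trial epoch, plus 5-trial block means.

    Speed is |change in snout-to-sipper distance| over the epoch divided by
    its duration.  Epochs: PreCue = [cue_on-4, cue_on), CueOn = [cue_on,
    sipper_in), SipIn = [sipper_in, sipper_out).  Epochs shorter than two
    frames are flagged undefined (nan).  Blocks average CS+ trials 1-5,
    6-10, 11-15.
    """
    fps = pose.fps
    d_left, d_right = _port_distances(pose)
    n_plus = len(events.trial_index)
    toward_c = np.full((n_plus, len(EPOCH_NAMES)), np.nan)
    toward_i = np.full((n_plus, len(EPOCH_NAMES)), np.nan)
    by_index = {t.index: t for t in schedule.trials}

    for row, tidx in enumerate(events.trial_index):
        trial = by_index[int(tidx)]
        epochs = (
            (trial.cue_on - 4.0, trial.cue_on),
            (trial.cue_on, trial.sipper_in),
            (trial.sipper_in, trial.sipper_out),
        )
        d_alc = d_left if trial.alcohol_side == "left" else d_right
        d_oth = d_right if trial.alcohol_side == "left" else d_left
        for e, (t0, t1) in enumerate(epochs):
            f0 = max(int(np.ceil(t0 * fps)), 0)
            f1 = min(int(np.floor(t1 * fps)), len(d_left) - 1)
            if f1 - f0 < 1:  # fewer than 2 frames: undefined
                continue
            dt = (f1 - f0) / fps
            toward_c[row, e] = abs(d_alc[f1] - d_alc[f0]) / dt
            toward_i[row, e] = abs(d_oth[f1] - d_oth[f0]) / dt

    n_blocks = n_block_trials // block_size
    blocks_c = np.full((n_blocks, len(EPOCH_NAMES)), np.nan)
    blocks_i = np.full((n_blocks, len(EPOCH_NAMES)), np.nan)
    for b in range(n_blocks):
        sel = slice(b * block_size, (b + 1) * block_size)
        if sel.start < n_plus:
            with np.errstate(invalid="ignore"):
                blocks_c[b] = np.nanmean(toward_c[sel], axis=0)
                blocks_i[b] = np.nanmean(toward_i[sel], axis=0)
    return EpochSpeeds(
        epochs=EPOCH_NAMES,
        toward_correct=toward_c,
        toward_incorrect=toward_i,
        block_means_correct=blocks_c,
        block_means_incorrect=blocks_i,
    )
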