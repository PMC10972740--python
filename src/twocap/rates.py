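"""Unit QC, ISI statistics, and adaptive Gaussian-kernel rate estimation.

Spike counts are binned at 100 ms and smoothed with a per-neuron Gaussian
kernel whose width is sqrt(mean ISI) * (1 / CV) seconds, where CV is the
coefficient of variation of the unit's inter-spike intervals.  Regular
units (CV near 0) are capped at ``sigma_max_s``.  The kernel is truncated
at +/-3 sigma with its mass renormalized, so smoothing conserves spike
count away from the window edges.

Bin centers sit on the bin-width grid and include both window endpoints,
so the cue-centered [-4, 18] s window yields 221 bins.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.stats import wilcoxon

from .config import AnalysisConfig
from .types import (
    ISIStats,
    RateTensor,
    SpikeData,
    TaskSchedule,
    TrialEvents,
    Unit,
    ValidationError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC and ISI statistics
# ---------------------------------------------------------------------------


def qc_filter(
    spikes: SpikeData,
    max_violation: float = 0.05,
    refractory_s: float = 0.002,
) -> SpikeData:
    """Retain units whose ISI-violation fraction is strictly below the cap.

    The violation fraction (ISIs shorter than the refractory period) is
    recomputed from the spike times.  Units with fewer than two spikes are
    excluded and logged.  Idempotent.
    """
    kept = []
    for u in spikes.units:
        if u.spike_times.size < 2:
            log.info("qc_filter: unit %s excluded (<2 spikes)", u.unit_id)
            continue
        isi = np.diff(u.spike_times)
        viol = float(np.mean(isi < refractory_s))
        if viol < max_violation:
            kept.append(
                Unit(
                    unit_id=u.unit_id,
                    spike_times=u.spike_times,
                    isi_violation_fraction=viol,
                    truth_class=u.truth_class,
                )
            )
        else:
            log.info("qc_filter: unit %s excluded (violation %.3f)", u.unit_id, viol)
    return SpikeData(session_id=spikes.session_id, units=kept)


def isi_stats(spike_times: np.ndarray) -> ISIStats:
    """Mean and coefficient of variation (sample sd / mean) of the ISIs."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise ValidationError("isi_stats requires at least 3 spikes")
    isi = np.diff(spike_times)
    mean = float(np.mean(isi))
    if mean <= 0:
        raise ValidationError("isi_stats: non-positive mean ISI")
    sd = float(np.std(isi, ddof=1))
    return ISIStats(mean_isi_s=mean, cv=sd / mean, n_isi=int(isi.size))


def kernel_sigma(stats: ISIStats, sigma_max_s: float = 2.0) -> float:
    """Per-neuron kernel width: sqrt(mean ISI) / CV seconds, capped.

    A CV of 0 (perfectly regular unit) falls back to the cap.
    """
    if stats.cv <= 0:
        return sigma_max_s
    return min(float(np.sqrt(stats.mean_isi_s) / stats.cv), sigma_max_s)


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------


def bin_centers(window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Centers on the bin-width grid spanning both endpoints inclusive."""
    lo, hi = window
    n = int(round((hi - lo) / bin_width)) + 1
    return lo + bin_width * np.arange(n)


def _gauss_kernel(sigma_s: float, bin_width: float) -> np.ndarray:
    """Unit-mass discrete Gaussian truncated at +/-3 sigma."""
    if sigma_s <= 0:
        return np.array([1.0])
    half = max(int(np.ceil(3.0 * sigma_s / bin_width)), 1)
    x = np.arange(-half, half + 1) * bin_width
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / k.sum()


def estimate_rates(
    spikes: SpikeData,
    align_times: Sequence[float],
    alignment_event: str,
    window: tuple[float, float],
    config: Optional[AnalysisConfig] = None,
    trial_indices: Optional[Sequence[int]] = None,
    recording_duration_s: Optional[float] = None,
    sigma_per_unit: Optional[dict] = None,
) -> RateTensor:
    """Event-aligned smoothed firing rates (units x bins x trials, Hz).

    Per unit: spike counts in 100 ms bins aligned to each event, converted
    to Hz, convolved with that unit's adaptive Gaussian.  Trials whose
    window extends beyond the recording are dropped and logged.
    ``sigma_per_unit`` overrides the per-unit kernel width (seconds).
    """
    config = config or AnalysisConfig()
    bw = config.bin_width_s
    centers = bin_centers(window, bw)
    edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])

    align_times = np.asarray(align_times, dtype=float)
    if trial_indices is None:
        trial_indices = np.arange(1, len(align_times) + 1)
    trial_indices = np.asarray(trial_indices, dtype=int)

    ok = np.isfinite(align_times)
    ok &= align_times + window[0] >= -bw  # window must start inside the recording
    if recording_duration_s is not None:
        ok &= align_times + window[1] <= recording_duration_s + bw
    if not ok.all():
        log.info("estimate_rates: dropped %d trial(s) outside recording", int(np.sum(~ok)))
    align_times = align_times[ok]
    trial_indices = trial_indices[ok]
    if align_times.size == 0:
        raise ValidationError("estimate_rates: no usable trials")

    rates = np.zeros((len(spikes.units), len(centers), len(align_times)))
    for ui, unit in enumerate(spikes.units):
        if unit.spike_times.size >= 3:
            if sigma_per_unit and unit.unit_id in sigma_per_unit:
                sigma = sigma_per_unit[unit.unit_id]
            else:
                sigma = kernel_sigma(isi_stats(unit.spike_times), config.sigma_max_s)
            kern = _gauss_kernel(sigma, bw)
        else:
            kern = np.array([1.0])
        half = (len(kern) - 1) // 2
        for ti, t0 in enumerate(align_times):
            counts, _ = np.histogram(unit.spike_times - t0, bins=edges)
            hz = counts / bw
            # center slice of the full convolution: correct also when the
            # kernel is longer than the window
            rates[ui, :, ti] = np.convolve(hz, kern, mode="full")[half : half + len(hz)]

    return RateTensor(
        unit_ids=spikes.unit_ids,
        alignment_event=alignment_event,
        window_s=(float(window[0]), float(window[1])),
        bin_width_s=bw,
        bins=centers,
        rates=rates,
        trial_indices=trial_indices,
    )


def cue_aligned_rates(
    spikes: SpikeData,
    schedule: TaskSchedule,
    config: Optional[AnalysisConfig] = None,
) -> RateTensor:
    """Cue-centered tensor: [-4, 18] s around cue onset, first 15 CS+ trials."""
    config = config or AnalysisConfig()
    trials = schedule.cs_plus_trials[: config.n_trials_used]
    return estimate_rates(
        spikes,
        [t.cue_on for t in trials],
        "cue_on",
        config.cue_window_s,
        config,
        trial_indices=[t.index for t in trials],
    )


def approach_aligned_rates(
    spikes: SpikeData,
    events: TrialEvents,
    config: Optional[AnalysisConfig] = None,
    side: Optional[str] = None,
    correct_only: bool = True,
    max_trials: Optional[int] = None,
) -> RateTensor:
    """Approach-centered tensor: [-2, 2] s around the (correct) approach.

    ``side`` restricts to trials whose first port was left or right; the
    first ``max_trials`` qualifying trials are used when given.
    """
    config = config or AnalysisConfig()
    sel_times, sel_idx = [], []
    for i, tidx in enumerate(events.trial_index):
        if correct_only and events.outcome[i] != "correct":
            continue
        if side is not None and events.first_port_visited[i] != side:
            continue
        t = events.approach_time_correct[i]
        if not np.isfinite(t):
            continue
        sel_times.append(t)
        sel_idx.append(int(tidx))
    if max_trials is not None:
        sel_times, sel_idx = sel_times[:max_trials], sel_idx[:max_trials]
    if not sel_times:
        raise ValidationError("approach_aligned_rates: no qualifying trials")
    return estimate_rates(
        spikes,
        sel_times,
        "approach",
        config.approach_window_s,
        config,
        trial_indices=sel_idx,
    )


# ---------------------------------------------------------------------------
# Modulation index (cue / sipper responsiveness)
# ---------------------------------------------------------------------------


def modulation_index(
    spikes: SpikeData,
    schedule: TaskSchedule,
    event: str = "cue_on",
    pre_s: float = 1.0,
    post_s: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Per-unit event modulation: (post - pre) / (post + pre) of the
    trial-pooled mean rates around the event, with a Wilcoxon signed-rank
    test across trials at ``alpha``.

    Returns ``{"units": {unit_id: {...}}, "prop_positive", "prop_negative"}``
    where the proportions count significantly modulated units among those
    testable.  Units with no spikes in either window are flagged untested.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValidationError("modulation_index: pre_s and post_s must be positive")
    if event == "cue_on":
        times = [t.cue_on for t in schedule.cs_plus_trials]
    elif event == "sipper_in":
        times = [t.sipper_in for t in schedule.cs_plus_trials]
    else:
        raise ValidationError(f"modulation_index: unknown event {event!r}")
    times = np.asarray(times, dtype=float)

    out = {}
    n_pos = n_neg = n_tested = 0
    for unit in spikes.units:
        st = unit.spike_times
        pre = np.array([np.sum((st >= t - pre_s) & (st < t)) for t in times]) / pre_s
        post = np.array([np.sum((st >= t) & (st < t + post_s)) for t in times]) / post_s
        r_pre, r_post = float(pre.mean()), float(post.mean())
        if r_pre + r_post == 0:
            out[unit.unit_id] = {"index": None, "significant": False, "sign": 0, "tested": False}
            continue
        index = (r_post - r_pre) / (r_post + r_pre)
        diff = post - pre
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(wilcoxon(diff, zero_method="wilcox").pvalue)
        sig = p < alpha
        sign = int(np.sign(index)) if sig else 0
        out[unit.unit_id] = {
            "index": float(index),
            "significant": bool(sig),
            "sign": sign,
            "p_value": p,
            "tested": True,
        }
        n_tested += 1
        n_pos += sign > 0
        n_neg += sign < 0
    return {
        "units": out,
        "n_tested": n_tested,
        "prop_positive": n_pos / n_tested if n_tested else float("nan"),
        "prop_negative": n_neg / n_tested if n_tested else float("nan"),
        "magnitudes": [v["index"] for v in out.values() if v["tested"] and v["significant"]],
    }
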