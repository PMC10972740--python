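"""End-to-end convenience flows over the analysis stages.

These functions wire the generator, event detection, rate estimation, and
population geometry together for the common experiment shapes: a full
synthetic session, and the proactive-versus-reactive regime contrast (side
coding placed before versus after the approach) that the left/right
subspace distance statistic is designed to separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .behavior import detect_and_classify, interpolate_low_confidence, session_metrics
from .config import AnalysisConfig
from .geometry import (
    permutation_distance,
    prepost_side_difference,
    project_trials,
    side_concatenated_pca,
    split_by_loading,
    subspace_permutations,
    trial_mean_matrix,
)
from .rates import approach_aligned_rates, qc_filter
from .simulate import (
    AgentParams,
    PopulationParams,
    SessionTruth,
    generate_pose,
    generate_schedule,
    generate_spikes,
)
from .stats import rm_time_side_anova
from .types import PoseTrack, SpikeData, TaskSchedule, TrialEvents


@dataclass
class SimulatedSession:
    schedule: TaskSchedule
    pose: PoseTrack
    truth: SessionTruth
    spikes: SpikeData
    events: TrialEvents


def simulate_session(
    seed: int,
    session_type: str = "congruent",
    strain: str = "wistar",
    agent: Optional[AgentParams] = None,
    pop: Optional[PopulationParams] = None,
    config: Optional[AnalysisConfig] = None,
) -> SimulatedSession:
    """Generate one full session and run event detection on it.

    Sub-stage seeds are derived from ``seed`` so a single integer fixes the
    whole session.
    """
    config = config or AnalysisConfig()
    agent = agent or AgentParams()
    pop = pop or PopulationParams()
    schedule = generate_schedule(config, session_type, seed, strain=strain)
    pose, truth = generate_pose(schedule, agent, seed + 1, config)
    spikes = generate_spikes(schedule, truth, pop, seed + 2)
    clean = interpolate_low_confidence(pose, config.likelihood_floor)
    events = detect_and_classify(clean, schedule, config.approach_radius_px, config)
    return SimulatedSession(schedule, pose, truth, spikes, events)


@dataclass
class SideAnalysis:
    """Left/right geometry of one session: PCA, subspace distances, and the
    loading-split pre/post rate differences for the strongest
    side-interacting component."""

    retained: int
    n_subspace_components: int
    pre_distance_mean: float
    post_distance_mean: float
    selected_pc: int
    pre_diff: float  # largest-|.| group-mean left-right diff before approach
    post_diff: float  # same after approach


def side_analysis(
    session: SimulatedSession,
    config: Optional[AnalysisConfig] = None,
    max_trials_per_side: Optional[int] = None,
    seed: int = 0,
) -> SideAnalysis:
    """Run the approach-centered left/right analysis on one session.

    Correct left and right approaches are trial-averaged (up to
    ``n_trials_used`` per side), decomposed with the side-concatenated PCA,
    single trials projected into the space, and the bootstrap distance
    statistic evaluated over every 3-D subspace of the retained set (the
    top three components when the broken-stick point falls below three).
    The loading split is then applied to the component with the strongest
    time-by-side interaction.
    """
    config = config or AnalysisConfig()
    max_trials = max_trials_per_side or config.n_trials_used
    spikes = qc_filter(session.spikes, config.max_isi_violation, config.refractory_s)
    left = approach_aligned_rates(spikes, session.events, config, side="left",
                                  max_trials=max_trials)
    right = approach_aligned_rates(spikes, session.events, config, side="right",
                                   max_trials=max_trials)
    left_mat = trial_mean_matrix(left)
    right_mat = trial_mean_matrix(right)
    pca, proj = side_concatenated_pca([left_mat], [right_mat],
                                      [session.schedule.session_id])

    n_comp = max(pca.retained, config.subspace_dim)
    n_comp = min(n_comp, pca.coefficients.shape[1])
    subspaces = subspace_permutations(n_comp, config.subspace_dim)
    left_scores = project_trials(pca, np.moveaxis(left.rates, 2, 0))
    right_scores = project_trials(pca, np.moveaxis(right.rates, 2, 0))
    pre = permutation_distance(
        left_scores, right_scores, subspaces, proj.approach_index,
        n_bootstrap=config.n_bootstrap, pre_approach_only=True, seed=seed,
        condition=session.schedule.session_id,
    )
    post = permutation_distance(
        left_scores, right_scores, subspaces, proj.approach_index,
        n_bootstrap=config.n_bootstrap, pre_approach_only=False, seed=seed,
        condition=session.schedule.session_id,
    )

    # loading-split analysis on the component with the strongest
    # time-by-side interaction among the enumerated components
    best_pc, best_p = 0, np.inf
    for pc in range(n_comp):
        split = split_by_loading(pca, pc, config.loading_threshold)
        for sign in ("positive", "negative"):
            rows = split[sign]
            if len(rows) < 3:
                continue
            res = rm_time_side_anova(left_mat[rows], right_mat[rows])
            if res["p_interaction"] < best_p:
                best_p, best_pc = res["p_interaction"], pc
    split = split_by_loading(pca, best_pc, config.loading_threshold)
    diffs = prepost_side_difference(split, left_mat, right_mat, proj.approach_index)
    pre_diff = max(
        (abs(d["pre_diff"]) for d in diffs.values() if d is not None), default=0.0
    )
    post_diff = max(
        (abs(d["post_diff"]) for d in diffs.values() if d is not None), default=0.0
    )
    return SideAnalysis(
        retained=pca.retained,
        n_subspace_components=n_comp,
        pre_distance_mean=float(pre.mean_distances.mean()),
        post_distance_mean=float(post.mean_distances.mean()),
        selected_pc=best_pc,
        pre_diff=pre_diff,
        post_diff=post_diff,
    )


def regime_contrast(
    seed: int,
    config: Optional[AnalysisConfig] = None,
    pop_kwargs: Optional[dict] = None,
) -> dict[str, SideAnalysis]:
    """Run the full pipeline under the proactive (pre-approach side coding)
    and reactive (post-approach) regimes with matched seeds."""
    config = config or AnalysisConfig()
    pop_kwargs = dict(pop_kwargs or {})
    out = {}
    for regime, onset in (("proactive", "pre_approach"), ("reactive", "post_approach")):
        pop = PopulationParams(side_code_onset=onset, **pop_kwargs)
        session = simulate_session(seed, pop=pop, config=config)
        out[regime] = side_analysis(session, config, seed=seed)
    return out
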