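"""Population geometry: PCA strategies, broken-stick retention, and the
left/right subspace permutation-distance statistic.

Two decompositions are used.  The **cue-centered** strategy trial-averages
each session's smoothed rates over the [-4, 18] s window (first 15 CS+
trials), stacks the unit rows of one strain's congruent and incongruent
sessions into an N x M matrix, and decomposes with units as variables.
The **side-concatenated** strategy trial-averages up to 15 correct left and
15 correct right approaches per session over [-2, 2] s, concatenates left
and right means in time (N x 2M), stacks both strains' units within a
session type, decomposes, and splits the scores back into left and right
halves.

Component retention uses the broken-stick rule: keep the leading components
whose explained-variance fraction exceeds the expected fraction from random
partitioning, b_k = (1/p) sum_{i=k..p} 1/i.  Left/right separation is then
quantified in every 3-component subspace of the retained set: bootstrap
pairs of single left and right trials are projected, their Euclidean
distance taken at each time sample (optionally restricted to pre-approach
bins), and the mean over samples and pairs reported per subspace.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .types import (
    BrokenStick,
    PCAResult,
    PermDistanceResult,
    RateTensor,
    SideProjection,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Broken stick
# ---------------------------------------------------------------------------


def broken_stick(p: int) -> BrokenStick:
    """Expected variance fractions under random partitioning of unit
    variance into ``p`` pieces: b_k = (1/p) sum_{i=k..p} 1/i."""
    if p < 1:
        raise ValidationError("broken_stick requires p >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    thresholds = np.cumsum(inv[::-1])[::-1] / p
    return BrokenStick(p=p, thresholds=thresholds)


def retain_components(explained_fraction: np.ndarray, stick: BrokenStick) -> int:
    """Largest K such that the first K components each exceed their
    broken-stick threshold (stop at the first failure)."""
    explained = np.asarray(explained_fraction, dtype=float)
    if len(explained) != stick.p:
        raise ValidationError("retain_components: length mismatch with stick")
    k = 0
    for ef, bk in zip(explained, stick.thresholds):
        if ef > bk:
            k += 1
        else:
            break
    return k


# ---------------------------------------------------------------------------
# Core decomposition (units as variables, timepoints as samples)
# ---------------------------------------------------------------------------


def population_pca(matrix_units_by_time: np.ndarray) -> PCAResult:
    """PCA of an N x M (units x timepoints) matrix.

    Each unit's mean over timepoints is removed, the decomposition is run
    with units as variables, and every component's sign is fixed by forcing
    its largest-magnitude loading positive (sign indeterminacy would
    otherwise break left-minus-right difference tests downstream).
    Retention is set by the broken-stick rule on the explained fractions.
    """
    X = np.asarray(matrix_units_by_time, dtype=float).T  # samples x units
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("population_pca: need a 2-D matrix with >= 2 timepoints")
    if np.allclose(X, X[0]):
        raise ValidationError("population_pca: matrix has zero variance")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    coeff = pca.components_.T  # units x components
    flip = np.sign(coeff[np.abs(coeff).argmax(axis=0), np.arange(coeff.shape[1])])
    flip[flip == 0] = 1.0
    coeff = coeff * flip
    scores = scores * flip
    explained = pca.explained_variance_ratio_
    stick = broken_stick(len(explained))
    return PCAResult(
        coefficients=coeff,
        scores=scores,
        explained_fraction=explained,
        column_means=pca.mean_,
        retained=retain_components(explained, stick),
    )


def trial_mean_matrix(tensor: RateTensor, n_trials: Optional[int] = None) -> np.ndarray:
    """Units x bins mean over (the first ``n_trials``) trials."""
    r = tensor.rates if n_trials is None else tensor.rates[:, :, :n_trials]
    return r.mean(axis=2)


def cue_centered_pca(
    session_matrices: Sequence[np.ndarray],
) -> PCAResult:
    """Cue-centered strategy: vertically stack each session's trial-mean
    units x bins matrix (congruent and incongruent sessions of one strain
    together) and decompose.  All sessions must share the bin grid."""
    if not session_matrices:
        raise ValidationError("cue_centered_pca: no sessions")
    widths = {m.shape[1] for m in session_matrices}
    if len(widths) != 1:
        raise ValidationError(f"cue_centered_pca: inconsistent bin grids {sorted(widths)}")
    stacked = np.vstack(session_matrices)
    return population_pca(stacked)


def side_concatenated_pca(
    left_matrices: Sequence[np.ndarray],
    right_matrices: Sequence[np.ndarray],
    condition_names: Optional[Sequence[str]] = None,
) -> tuple[PCAResult, SideProjection]:
    """Side-concatenated strategy for one session type.

    ``left_matrices[i]`` / ``right_matrices[i]`` are session i's units x M
    trial-mean matrices for correct left / right approaches (both strains'
    sessions together).  Left and right are concatenated in time (units x
    2M), sessions stacked vertically, decomposed, and the scores split back
    into the left and right halves.  The approach falls at the midpoint bin
    of each half.
    """
    if len(left_matrices) != len(right_matrices) or not left_matrices:
        raise ValidationError("side_concatenated_pca: mismatched or empty session lists")
    names = condition_names or [f"session{i}" for i in range(len(left_matrices))]
    for name, lm, rm in zip(names, left_matrices, right_matrices):
        if lm.size == 0 or rm.size == 0:
            raise ValidationError(f"condition {name!r} has zero correct trials on one side")
        if lm.shape != rm.shape:
            raise ValidationError(f"condition {name!r}: left/right shape mismatch")
    m = left_matrices[0].shape[1]
    stacked = np.vstack(
        [np.hstack([lm, rm]) for lm, rm in zip(left_matrices, right_matrices)]
    )
    pca = population_pca(stacked)
    proj = SideProjection(
        left_scores=pca.scores[:m],
        right_scores=pca.scores[m:],
        approach_index=m // 2,
    )
    return pca, proj


def project_trials(
    pca: PCAResult,
    trial_matrices: np.ndarray,
    unit_rows: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Project single-trial units x bins matrices into the PC space.

    ``trial_matrices`` is (trials, units, bins).  The PCA column means are
    subtracted and the centered matrix multiplied by the coefficient
    loadings (the standard score map).  ``unit_rows`` selects the loading
    rows when the trials carry a subset of the pooled units.
    """
    tm = np.asarray(trial_matrices, dtype=float)
    if tm.ndim == 2:
        tm = tm[None]
    rows = np.arange(pca.coefficients.shape[0]) if unit_rows is None else np.asarray(unit_rows)
    if tm.shape[1] != len(rows):
        raise ValidationError("project_trials: unit-row count mismatch")
    centered = tm - pca.column_means[rows][None, :, None]
    # (trials, units, bins) x (units, comps) -> (trials, bins, comps)
    return np.einsum("tub,uc->tbc", centered, pca.coefficients[rows])


# ---------------------------------------------------------------------------
# Subspace enumeration and permutation distance
# ---------------------------------------------------------------------------


def subspace_permutations(n: int, k: int = 3) -> list[tuple[int, ...]]:
    """All C(n, k) unordered component-index sets, lexicographic order."""
    if n < k:
        raise ValidationError(f"subspace_permutations: n={n} < k={k}")
    if k < 1:
        raise ValidationError("subspace_permutations: k must be >= 1")
    return list(itertools.combinations(range(n), k))


def permutation_distance(
    left_trial_scores: np.ndarray,
    right_trial_scores: np.ndarray,
    subspaces: Sequence[tuple[int, ...]],
    approach_index: int,
    n_bootstrap: int = 1000,
    pre_approach_only: bool = True,
    seed: int = 0,
    condition: str = "",
) -> PermDistanceResult:
    """Mean left/right Euclidean separation per 3-D PC subspace.

    ``left_trial_scores``/``right_trial_scores`` are (trials, bins,
    components) single-trial projections.  Per subspace, ``n_bootstrap``
    (left, right) trial pairs are drawn with replacement, the distance taken
    at each time sample (restricted to bins before ``approach_index`` when
    ``pre_approach_only``) and averaged over samples and pairs.
    """
    L = np.asarray(left_trial_scores, dtype=float)
    R = np.asarray(right_trial_scores, dtype=float)
    if L.ndim != 3 or R.ndim != 3:
        raise ValidationError("permutation_distance: scores must be (trials, bins, comps)")
    if L.shape[0] == 0 or R.shape[0] == 0:
        raise ValidationError("permutation_distance: empty trial pool")
    bins = np.arange(L.shape[1])
    if pre_approach_only:
        bins = bins[bins < approach_index]
        if bins.size == 0:
            raise ValidationError("permutation_distance: no pre-approach bins")
    rng = np.random.default_rng(seed)
    means = np.empty(len(subspaces))
    for si, sub in enumerate(subspaces):
        sub = list(sub)
        il = rng.integers(0, L.shape[0], n_bootstrap)
        ir = rng.integers(0, R.shape[0], n_bootstrap)
        diff = L[il][:, bins][:, :, sub] - R[ir][:, bins][:, :, sub]
        means[si] = np.linalg.norm(diff, axis=2).mean()
    return PermDistanceResult(
        condition=condition,
        subspaces=[tuple(s) for s in subspaces],
        mean_distances=means,
        n_bootstrap=n_bootstrap,
        pre_approach_only=pre_approach_only,
    )


# ---------------------------------------------------------------------------
# Loading-sign splits and pre/post side differences
# ---------------------------------------------------------------------------


def split_by_loading(
    pca: PCAResult, component: int, threshold: float = 0.01
) -> dict[str, np.ndarray]:
    """Partition units by their loading sign on one component (0-based).

    positive: loading >= +threshold; negative: loading <= -threshold; the
    middle band is excluded from analysis.
    """
    if component >= pca.coefficients.shape[1]:
        raise ValidationError("split_by_loading: component out of range")
    loadings = pca.coefficients[:, component]
    return {
        "positive": np.flatnonzero(loadings >= threshold),
        "negative": np.flatnonzero(loadings <= -threshold),
        "excluded": np.flatnonzero(np.abs(loadings) < threshold),
    }


def prepost_side_difference(
    split: dict[str, np.ndarray],
    left_rates: np.ndarray,
    right_rates: np.ndarray,
    approach_index: int,
) -> dict[str, Optional[dict[str, float]]]:
    """Group-mean left-minus-right rate difference before and after approach.

    ``left_rates``/``right_rates`` are units x bins mean rates over the
    [-2, 2] s window.  For each sign group the unit-mean traces are
    differenced (left - right; positive = skewed toward encoding left) and
    averaged over the bins before / after ``approach_index``.  Empty sign
    groups map to None.
    """
    out: dict[str, Optional[dict[str, float]]] = {}
    for sign in ("positive", "negative"):
        rows = split.get(sign, np.array([], dtype=int))
        if len(rows) == 0:
            out[sign] = None
            continue
        diff = left_rates[rows].mean(axis=0) - right_rates[rows].mean(axis=0)
        out[sign] = {
            "pre_diff": float(diff[:approach_index].mean()),
            "post_diff": float(diff[approach_index + 1 :].mean()),
        }
    return out


def select_interaction_pc(
    interaction_p: dict[int, dict[str, float]], alpha: float = 0.05
) -> list[int]:
    """Components with a significant time-by-side interaction in every
    session type.  Returns all candidates (possibly empty); no tie-break."""
    selected = []
    for pc, by_type in sorted(interaction_p.items()):
        if by_type and all(p < alpha for p in by_type.values()):
            selected.append(pc)
    return selected
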