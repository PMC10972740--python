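"""Population geometry: broken stick, PCA strategies, subspace distances,
and loading splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twocap as tc
from twocap.geometry import population_pca
from twocap.types import ValidationError


class TestBrokenStick:
    def test_p7_first_threshold(self):
        bs = tc.broken_stick(7)
        assert bs.thresholds[0] == pytest.approx(0.3704, abs=5e-4)

    def test_p3_exact(self):
        np.testing.assert_allclose(
            tc.broken_stick(3).thresholds, [11 / 18, 5 / 18, 2 / 18], atol=1e-12
        )

    def test_p1_identity(self):
        np.testing.assert_allclose(tc.broken_stick(1).thresholds, [1.0])

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            tc.broken_stick(0)

    @given(st.integers(min_value=1, max_value=300))
    @settings(deadline=None, max_examples=40)
    def test_thresholds_sum_to_one_and_decrease(self, p):
        bs = tc.broken_stick(p)
        assert bs.thresholds.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(bs.thresholds) < 0) or p == 1


class TestRetainComponents:
    def test_example_two_components(self):
        bs = tc.broken_stick(7)
        explained = np.array([0.5, 0.3, 0.1, 0.05, 0.03, 0.015, 0.005])
        assert tc.retain_components(explained, bs) >= 2

    def test_uniform_spectrum_retains_none(self):
        p = 6
        assert tc.retain_components(np.full(p, 1 / p), tc.broken_stick(p)) == 0

    def test_rank_one_retains_one(self):
        explained = np.array([1.0, 0.0, 0.0])
        assert tc.retain_components(explained, tc.broken_stick(3)) == 1

    def test_stops_at_first_failure(self):
        bs = tc.broken_stick(4)
        # component 2 fails, component 3 would pass: retention still stops at 1
        explained = np.array([0.6, 0.1, 0.2, 0.1])
        assert tc.retain_components(explained, bs) == 1


class TestSubspacePermutations:
    @pytest.mark.parametrize("n,expected", [(9, 84), (8, 56), (3, 1)])
    def test_printed_counts(self, n, expected):
        assert len(tc.subspace_permutations(n)) == expected

    def test_n3_is_single_triple(self):
        assert tc.subspace_permutations(3) == [(0, 1, 2)]

    def test_counts_match_binomial_oracle(self):
        for n in range(3, 13):
            for k in range(3, n + 1):
                subs = tc.subspace_permutations(n, k)
                assert len(subs) == math.comb(n, k)
                assert len(set(subs)) == len(subs)
                assert subs == sorted(subs)  # lexicographic

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValidationError):
            tc.subspace_permutations(2, 3)


class TestPopulationPCA:
    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 50))  # units x time
        pca = population_pca(X)
        recon = pca.column_means[None, :] + pca.scores @ pca.coefficients.T
        np.testing.assert_allclose(recon, X.T, atol=1e-8)
        assert np.all(np.diff(pca.explained_fraction) <= 1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(pca.coefficients, axis=0), 1.0, atol=1e-9
        )

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 40))
        pca = population_pca(X)
        for j in range(pca.coefficients.shape[1]):
            col = pca.coefficients[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_duplicated_units_keep_spectrum(self):
        """Duplicating every unit row leaves the explained fractions
        unchanged and rescales each score column uniformly."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 30))
        a = population_pca(X)
        b = population_pca(np.vstack([X, X]))
        k = min(a.scores.shape[1], b.scores.shape[1])
        np.testing.assert_allclose(
            a.explained_fraction[:k], b.explained_fraction[:k], atol=1e-9
        )
        for j in range(min(k, 4)):
            ratio = b.scores[:, j] / a.scores[:, j]
            np.testing.assert_allclose(ratio, np.sqrt(2.0), atol=1e-6)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            population_pca(np.ones((5, 20)))


class TestCueCenteredPCA:
    def test_transient_unit_dominates_pc1(self, config):
        """One unit with a strong cue-locked transient among flat-noise
        units: PC1 peaks near cue onset and beats the broken stick."""
        rng = np.random.default_rng(8)
        bins = tc.bin_centers(config.cue_window_s, config.bin_width_s)
        n_units = 12
        mats = []
        for _ in range(2):  # two "sessions"
            m = rng.normal(5.0, 0.05, size=(n_units, len(bins)))
            m[0] += 8.0 * np.exp(-0.5 * (bins / 0.3) ** 2)  # transient at cue
            mats.append(m)
        pca = tc.cue_centered_pca(mats)
        stick = tc.broken_stick(len(pca.explained_fraction))
        assert pca.explained_fraction[0] > stick.thresholds[0]
        assert abs(bins[np.abs(pca.scores[:, 0]).argmax()]) <= 0.5
        assert pca.retained >= 1

    def test_inconsistent_bin_grids_rejected(self):
        with pytest.raises(ValidationError):
            tc.cue_centered_pca([np.zeros((3, 10)), np.zeros((3, 11))])


class TestSideConcatenatedPCA:
    def test_identical_halves_have_identical_scores(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(10, 41))
        pca, proj = tc.side_concatenated_pca([m], [m.copy()])
        np.testing.assert_allclose(proj.left_scores, proj.right_scores, atol=1e-9)
        assert proj.approach_index == 20

    def test_constant_offset_gives_constant_score_difference(self):
        rng = np.random.default_rng(10)
        right = rng.normal(size=(10, 41))
        offset = rng.normal(size=10)
        left = right + offset[:, None]
        _, proj = tc.side_concatenated_pca([left], [right])
        diff = proj.left_scores - proj.right_scores
        np.testing.assert_allclose(diff - diff[0][None, :], 0.0, atol=1e-8)

    def test_empty_side_names_condition(self):
        with pytest.raises(ValidationError, match="wistar_cong"):
            tc.side_concatenated_pca(
                [np.zeros((3, 0))], [np.ones((3, 5))], ["wistar_cong"]
            )

    def test_regime_divergence_timing(self, config):
        """Proactive populations: left/right score divergence grows before
        the approach; reactive: after (matched seeds)."""
        sep = {}
        for regime, onset in (("pro", "pre_approach"), ("rea", "post_approach")):
            pop = tc.PopulationParams(side_code_onset=onset)
            session = tc.simulate_session(61, pop=pop, config=config)
            spikes = tc.qc_filter(session.spikes)
            left = tc.approach_aligned_rates(spikes, session.events, config,
                                             side="left", max_trials=15)
            right = tc.approach_aligned_rates(spikes, session.events, config,
                                              side="right", max_trials=15)
            lm, rm = tc.trial_mean_matrix(left), tc.trial_mean_matrix(right)
            pca, proj = tc.side_concatenated_pca([lm], [rm])
            k = max(pca.retained, 1)
            gap = np.linalg.norm(
                proj.left_scores[:, :k] - proj.right_scores[:, :k], axis=1
            )
            ai = proj.approach_index
            sep[regime] = (gap[:ai].mean(), gap[ai + 1 :].mean())
        assert sep["pro"][0] > sep["rea"][0]  # pre-approach separation
        assert sep["rea"][1] > sep["rea"][0]  # reactive separates after


class TestPermutationDistance:
    def _pools(self, n=6, bins=41, comps=5, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, bins, comps))

    def test_identical_pools_zero_distance(self):
        # both pools hold the same single trial, duplicated
        one = np.random.default_rng(0).normal(size=(1, 41, 5))
        left = np.repeat(one, 4, axis=0)
        res = tc.permutation_distance(
            left, left.copy(), tc.subspace_permutations(5), approach_index=20, seed=1
        )
        np.testing.assert_allclose(res.mean_distances, 0.0, atol=1e-12)

    def test_single_component_offset_geometry(self):
        left = np.zeros((4, 41, 5))
        right = left.copy()
        right[:, :, 2] += 3.0  # shift on component 2 only
        subs = tc.subspace_permutations(5)
        res = tc.permutation_distance(left, right, subs, approach_index=20, seed=2)
        for sub, d in zip(res.subspaces, res.mean_distances):
            assert d == pytest.approx(3.0 if 2 in sub else 0.0, abs=1e-12)

    def test_rigid_rotation_invariance(self):
        left = self._pools(seed=3)
        right = self._pools(seed=4)
        subs = [(0, 1, 2)]
        base = tc.permutation_distance(left, right, subs, 20, seed=5)
        theta = 0.7
        rot3 = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        rot = np.eye(5)
        rot[:3, :3] = rot3
        rotated = tc.permutation_distance(left @ rot, right @ rot, subs, 20, seed=5)
        np.testing.assert_allclose(
            rotated.mean_distances, base.mean_distances, atol=1e-9
        )

    def test_seed_determinism_and_pre_restriction(self):
        left = self._pools(seed=6)
        right = self._pools(seed=7)
        subs = tc.subspace_permutations(5)
        a = tc.permutation_distance(left, right, subs, 20, seed=8, pre_approach_only=True)
        b = tc.permutation_distance(left, right, subs, 20, seed=8, pre_approach_only=True)
        np.testing.assert_array_equal(a.mean_distances, b.mean_distances)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            tc.permutation_distance(
                np.zeros((0, 41, 5)), self._pools(), [(0, 1, 2)], 20
            )


class TestLoadingSplit:
    def _pca_with_loadings(self, loadings):
        loadings = np.asarray(loadings, float)[:, None]
        return tc.PCAResult(
            coefficients=loadings,
            scores=np.zeros((4, 1)),
            explained_fraction=np.array([1.0]),
            column_means=np.zeros(len(loadings)),
            retained=1,
        )

    def test_threshold_partition(self):
        split = tc.split_by_loading(self._pca_with_loadings([0.05, -0.02, 0.005]), 0)
        assert split["positive"].tolist() == [0]
        assert split["negative"].tolist() == [1]
        assert split["excluded"].tolist() == [2]

    def test_all_zero_loadings_excluded(self):
        split = tc.split_by_loading(self._pca_with_loadings([0.0, 0.0]), 0)
        assert len(split["positive"]) == len(split["negative"]) == 0
        assert len(split["excluded"]) == 2

    def test_sign_flip_swaps_sets(self):
        lo = [0.4, -0.3, 0.02, -0.015, 0.001]
        a = tc.split_by_loading(self._pca_with_loadings(lo), 0)
        b = tc.split_by_loading(self._pca_with_loadings([-v for v in lo]), 0)
        assert a["positive"].tolist() == b["negative"].tolist()
        assert a["negative"].tolist() == b["positive"].tolist()
        assert a["excluded"].tolist() == b["excluded"].tolist()


class TestPrePostSideDifference:
    def test_identical_sides_zero(self):
        rates = np.random.default_rng(11).normal(size=(6, 41))
        split = {"positive": np.arange(3), "negative": np.arange(3, 6)}
        out = tc.prepost_side_difference(split, rates, rates.copy(), 20)
        for sign in ("positive", "negative"):
            assert out[sign]["pre_diff"] == pytest.approx(0.0)
            assert out[sign]["post_diff"] == pytest.approx(0.0)

    def test_constant_difference_sign_convention(self):
        left = np.full((4, 41), 5.0)
        right = np.full((4, 41), 3.0)
        split = {"positive": np.arange(4), "negative": np.array([], dtype=int)}
        out = tc.prepost_side_difference(split, left, right, 20)
        assert out["positive"]["pre_diff"] == pytest.approx(2.0)
        assert out["positive"]["post_diff"] == pytest.approx(2.0)
        assert out["negative"] is None  # empty group flagged


class TestSelectInteractionPC:
    def test_unique_pc_returned(self):
        screen = {
            0: {"congruent": 0.2, "incongruent": 0.6},
            3: {"congruent": 0.01, "incongruent": 0.002},
        }
        assert tc.select_interaction_pc(screen) == [3]

    def test_no_signal_empty(self):
        assert tc.select_interaction_pc({0: {"congruent": 0.8, "incongruent": 0.9}}) == []

    def test_ties_returned_without_tiebreak(self):
        screen = {
            1: {"congruent": 0.01, "incongruent": 0.02},
            2: {"congruent": 0.03, "incongruent": 0.01},
        }
        assert tc.select_interaction_pc(screen) == [1, 2]
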