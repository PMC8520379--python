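import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endostitch.match_filtering as mf
from endostitch.errors import ConfigurationError, ParameterError
from endostitch.keypoint_features import Keypoint
from oracles import (
    brute_force_ratio_match,
    disparity_filter_oracle,
    disparity_gradient_oracle,
    prescreen_oracle,
)


def make_match(sx, sy, dx, dy, status=mf.STATUS_COARSE):
    return mf.MatchPair(
        src=Keypoint(x=float(sx), y=float(sy)),
        dst=Keypoint(x=float(dx), y=float(dy)),
        distance=0.0,
        status=status,
    )


def matches_from_points(src_pts, dst_pts, status=mf.STATUS_COARSE):
    return [make_match(*s, *d, status=status) for s, d in zip(src_pts, dst_pts)]


class TestCoarseMatch:
    def test_identity_sets_match_each_point_to_its_copy(self, rng):
        desc = rng.random((20, 128))
        desc /= np.linalg.norm(desc, axis=1, keepdims=True)
        matches = mf.coarse_match(desc, desc, ratio=0.8)
        assert len(matches) == 20
        for m in matches:
            assert m.src_index == m.dst_index
            assert m.distance == 0.0

    def test_ratio_threshold_rejects_ambiguous_match(self):
        src = np.zeros((1, 3))
        src[0] = [1.0, 0.0, 0.0]
        dst = np.array([[1.0, 0.9, 0.0], [1.0, 0.0, 1.0]])  # d1/d2 = 0.9
        assert mf.coarse_match(src, dst, ratio=0.8) == []
        assert len(mf.coarse_match(src, dst, ratio=0.95)) == 1

    def test_agrees_with_brute_force_oracle(self, rng):
        src = rng.random((50, 128))
        dst = rng.random((60, 128))
        got = {(m.src_index, m.dst_index) for m in mf.coarse_match(src, dst, 0.8)}
        assert got == brute_force_ratio_match(src, dst, 0.8)

    def test_all_degenerate_descriptors_warn_and_return_empty(self):
        with pytest.warns(UserWarning):
            assert mf.coarse_match(np.zeros((3, 128)), np.zeros((4, 128))) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            mf.coarse_match(np.zeros((0, 128)), np.ones((2, 128)))


class TestCompositeSlopes:
    def test_pure_horizontal_translation_gives_zero_slopes(self):
        src = [(10, 40), (50, 80), (100, 20)]
        dst = [(30, 40), (70, 80), (120, 20)]
        matches = matches_from_points(src, dst)
        mf.composite_slopes(matches, mf.PrescreenParams(composite_offset=200.0))
        assert all(m.slope == 0.0 for m in matches)

    def test_pure_vertical_translation_closed_form(self):
        d, W = 12.0, 200.0
        matches = matches_from_points([(30, 10), (90, 50)], [(30, 22), (90, 62)])
        mf.composite_slopes(matches, mf.PrescreenParams(composite_offset=W))
        assert all(m.slope == pytest.approx(d / W, abs=1e-15) for m in matches)

    def test_agrees_with_direct_formula_under_similarity(self, rng):
        theta, s, tx, ty = 0.1, 1.05, 8.0, -4.0
        src = rng.uniform(10, 240, size=(20, 2))
        R = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        dst = src @ R.T + [tx, ty]
        matches = matches_from_points(src, dst)
        offset = 256.0
        mf.composite_slopes(matches, mf.PrescreenParams(composite_offset=offset), 256.0)
        for m, p, q in zip(matches, src, dst):
            expect = (q[1] - p[1]) / ((q[0] + offset) - p[0])
            assert abs(m.slope - expect) < 1e-12

    def test_offset_smaller_than_source_width_rejected(self):
        matches = matches_from_points([(0, 0)], [(5, 5)])
        with pytest.raises(ConfigurationError):
            mf.composite_slopes(
                matches, mf.PrescreenParams(composite_offset=100.0), src_width=256.0
            )


class TestPrescreen:
    @staticmethod
    def _with_slopes(slopes):
        matches = matches_from_points([(0, 0)] * len(slopes), [(0, 0)] * len(slopes))
        for m, s in zip(matches, slopes):
            m.slope = float(s)
        return matches

    def test_single_cluster_all_preselected(self):
        matches = self._with_slopes([0.01] * 20)
        mf.prescreen(matches, mf.PrescreenParams(t=0.02))
        assert all(m.status == mf.STATUS_PRESELECTED for m in matches)

    def test_outliers_rejected_inliers_kept(self, rng):
        inliers = list(rng.uniform(-0.005, 0.005, size=15))
        outliers = [0.3, -0.4, 0.9, -0.7, 0.5]
        matches = self._with_slopes(inliers + outliers)
        mf.prescreen(matches, mf.PrescreenParams(t=0.02))
        statuses = [m.status for m in matches]
        assert statuses[:15] == [mf.STATUS_PRESELECTED] * 15
        assert statuses[15:] == [mf.STATUS_REJECTED_SLOPE] * 5
        # exhaustive neighbourhood-count oracle over all 20 candidate centres
        keep = prescreen_oracle(inliers + outliers, 0.02)
        assert [m.status == mf.STATUS_PRESELECTED for m in matches] == keep

    def test_equal_clusters_tie_break_is_order_invariant(self, rng):
        slopes = [0.1, 0.1, 0.1, -0.1, -0.1, -0.1]
        matches = self._with_slopes(slopes)
        mf.prescreen(matches, mf.PrescreenParams(t=0.02))
        kept_slopes = {m.slope for m in matches if m.status == mf.STATUS_PRESELECTED}
        assert kept_slopes == {0.1}  # positive cluster wins the |k| tie
        for _ in range(5):
            perm = rng.permutation(len(slopes))
            shuffled = self._with_slopes([slopes[i] for i in perm])
            mf.prescreen(shuffled, mf.PrescreenParams(t=0.02))
            kept = {m.slope for m in shuffled if m.status == mf.STATUS_PRESELECTED}
            assert kept == kept_slopes

    def test_fewer_than_three_matches_pass_through(self):
        matches = self._with_slopes([0.5, -0.5])
        with pytest.warns(UserWarning):
            mf.prescreen(matches, mf.PrescreenParams(t=0.02))
        assert all(m.status == mf.STATUS_PRESELECTED for m in matches)

    def test_preselection_monotone_in_t(self, rng):
        slopes = list(rng.normal(0.0, 0.004, size=30))
        small = self._with_slopes(slopes)
        large = self._with_slopes(slopes)
        mf.prescreen(small, mf.PrescreenParams(t=0.01))
        mf.prescreen(large, mf.PrescreenParams(t=0.02))
        kept_small = {i for i, m in enumerate(small) if m.status == mf.STATUS_PRESELECTED}
        kept_large = {i for i, m in enumerate(large) if m.status == mf.STATUS_PRESELECTED}
        assert kept_small <= kept_large

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        slopes=st.lists(
            st.floats(min_value=-1.0, max_value=1.0, allow_nan=False), min_size=3, max_size=40
        )
    )
    def test_matches_oracle_on_arbitrary_slope_sets(self, slopes):
        matches = self._with_slopes(slopes)
        mf.prescreen(matches, mf.PrescreenParams(t=0.02))
        keep = prescreen_oracle(slopes, 0.02)
        assert [m.status == mf.STATUS_PRESELECTED for m in matches] == keep


class TestDisparityGradient:
    def test_pure_translation_gives_zero(self):
        m = make_match(0, 0, 5, 3)
        n = make_match(10, 10, 15, 13)
        assert mf.disparity_gradient(m, n) == 0.0

    def test_hand_computed_half(self):
        # d(m) = (2, 0), d(n) = (0, 0), midpoints 4 px apart -> 2/4 = 0.5
        m = make_match(0, 0, 2, 0)  # midpoint (1, 0)
        n = make_match(5, 0, 5, 0)  # midpoint (5, 0)
        assert mf.disparity_gradient(m, n) == pytest.approx(0.5)

    def test_identical_match_rejected(self):
        m = make_match(1, 2, 3, 4)
        with pytest.raises(ParameterError):
            mf.disparity_gradient(m, m)
        with pytest.raises(ParameterError):
            mf.disparity_gradient(m, make_match(1, 2, 3, 4))

    def test_coincident_midpoints_give_infinity(self):
        m = make_match(0, 0, 4, 0)  # midpoint (2, 0)
        n = make_match(4, 0, 0, 0)  # midpoint (2, 0), different disparity
        assert mf.disparity_gradient(m, n) == math.inf

    def test_agrees_with_brute_force_oracle_under_homography(self, rng):
        H = np.array([[1.02, 0.01, 5.0], [-0.01, 0.99, -3.0], [1e-5, 0.0, 1.0]])
        src = rng.uniform(10, 240, size=(30, 2))
        hom = np.hstack([src, np.ones((30, 1))]) @ H.T
        dst = hom[:, :2] / hom[:, 2:3]
        matches = matches_from_points(src, dst)
        for i in range(30):
            for j in range(i + 1, 30):
                got = mf.disparity_gradient(matches[i], matches[j])
                want = disparity_gradient_oracle(src[i], dst[i], src[j], dst[j])
                assert abs(got - want) < 1e-12


class TestDisparityFilter:
    def test_global_translation_retains_everything(self, rng):
        src = rng.uniform(0, 200, size=(25, 2))
        matches = matches_from_points(src, src + [7.0, -2.0], mf.STATUS_PRESELECTED)
        mf.disparity_filter(matches, K=4)
        assert all(m.status == mf.STATUS_RETAINED for m in matches)

    def test_inconsistent_injected_match_rejected(self):
        gx, gy = np.mgrid[0:50:10, 0:50:10]
        src = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
        dst = src + [5.0, 0.0]
        matches = matches_from_points(src, dst, mf.STATUS_PRESELECTED)
        bad = make_match(25, 25, 5, 25, status=mf.STATUS_PRESELECTED)  # d = (-20, 0)
        matches.append(bad)
        mf.disparity_filter(matches, K=4)
        assert bad.status == mf.STATUS_REJECTED_DISPARITY
        assert all(m.status == mf.STATUS_RETAINED for m in matches[:-1])
        keep = disparity_filter_oracle(
            [tuple(p) for p in src] + [(25.0, 25.0)],
            [tuple(p) for p in dst] + [(5.0, 25.0)],
            K=4,
        )
        assert [m.status == mf.STATUS_RETAINED for m in matches] == keep

    def test_gradient_exactly_two_is_rejected(self):
        # |d(m) - d(n)| = 8, midpoint separation 4 -> gradient exactly 2
        m = make_match(0, 0, 8, 0)
        n = make_match(8, 0, 8, 0)
        assert mf.disparity_gradient(m, n) == 2.0
        m.status = n.status = mf.STATUS_PRESELECTED
        mf.disparity_filter([m, n], K=4)
        assert m.status == mf.STATUS_REJECTED_DISPARITY
        assert n.status == mf.STATUS_REJECTED_DISPARITY

    def test_fewer_than_two_preselected_pass_through(self):
        m = make_match(0, 0, 5, 5, status=mf.STATUS_PRESELECTED)
        with pytest.warns(UserWarning):
            mf.disparity_filter([m], K=4)
        assert m.status == mf.STATUS_RETAINED

    def test_small_k_reduction_matches_oracle(self, rng):
        src = rng.uniform(0, 100, size=(4, 2))
        dst = src + rng.normal(0, 1, size=(4, 2))
        matches = matches_from_points(src, dst, mf.STATUS_PRESELECTED)
        mf.disparity_filter(matches, K=10)  # K reduced to 3
        keep = disparity_filter_oracle([tuple(p) for p in src], [tuple(p) for p in dst], K=10)
        assert [m.status == mf.STATUS_RETAINED for m in matches] == keep


class TestOrderInvariance:
    def test_full_filter_chain_is_permutation_invariant(self, rng):
        src = rng.uniform(10, 240, size=(40, 2))
        dst = src + [10.0, 3.0] + rng.normal(0, 0.5, size=(40, 2))
        dst[35:] = rng.uniform(10, 240, size=(5, 2))  # mismatches

        def run(order):
            matches = matches_from_points(src[order], dst[order])
            params = mf.PrescreenParams(t=0.02, composite_offset=256.0)
            mf.composite_slopes(matches, params)
            mf.prescreen(matches, params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mf.disparity_filter(matches, K=4)
            return {
                (m.src.x, m.src.y)
                for m in matches
                if m.status == mf.STATUS_RETAINED
            }

        base = run(np.arange(40))
        for _ in range(5):
            assert run(rng.permutation(40)) == base
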