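import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsareg import features
from dsareg.features import (
    SelectionParams,
    combine_maps,
    find_candidates,
    gradient_magnitude,
    harris_response,
    select_control_points,
    select_from_image,
    threshold_edges,
)


class TestGradientMagnitude:
    def test_constant_image_gives_zero_map(self):
        assert np.array_equal(gradient_magnitude(np.full((32, 32), 9.0)), np.zeros((32, 32)))

    def test_vertical_step_peaks_on_step_column(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 200.0
        g = gradient_magnitude(img)
        assert g.max() == 1.0
        # ridge of maxima concentrated at the step
        assert np.all(np.abs(np.argmax(g, axis=1) - 31.5) <= 1.0)

    def test_linear_ramp_matches_finite_difference_oracle(self):
        # ramp slope 2: Gaussian derivative responds with the exact slope
        img = 2.0 * np.arange(64)[None, :] * np.ones((64, 1))
        raw = gradient_magnitude(img, sigma=1.0, normalize=False)
        fd = np.hypot(*np.gradient(img)[::-1])
        # agreement up to the truncation error of the finite Gaussian kernel
        assert np.allclose(raw[10:-10, 10:-10], fd[10:-10, 10:-10], atol=5e-4)
        assert raw[10:-10, 10:-10].std() < 1e-9  # constant over the interior


class TestThresholdEdges:
    def test_zero_map_unchanged(self):
        assert np.array_equal(threshold_edges(np.zeros((4, 4)), 0.0), np.zeros((4, 4)))

    def test_per_pixel_rule(self):
        out = threshold_edges(np.array([[0.05, 0.5]]), 0.1)
        assert np.array_equal(out, [[0.0, 0.5]])

    def test_default_threshold_is_mean_elementwise_oracle(self, rng):
        m = rng.random((40, 40))
        out = threshold_edges(m)
        expected = np.where(m < m.mean(), 0.0, m)
        assert np.array_equal(out, expected)
        assert np.count_nonzero(out) == np.count_nonzero(expected)


class TestHarrisResponse:
    def test_constant_image_gives_zero_response(self):
        assert np.array_equal(harris_response(np.full((32, 32), 50.0)), np.zeros((32, 32)))

    def test_straight_edge_has_no_corner_response(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 150.0
        # one dominant gradient direction: det term vanishes, -k trace^2 < 0,
        # so the clipped response holds no positive values at all
        assert np.array_equal(harris_response(img), np.zeros((64, 64)))

    def test_square_corners_are_local_maxima(self):
        img = np.zeros((64, 64))
        img[22:42, 22:42] = 200.0
        r = harris_response(img)
        pts, _ = find_candidates(r, t1=0.1, r=5.0)
        corners = np.array([[21.5, 21.5], [21.5, 41.5], [41.5, 21.5], [41.5, 41.5]])
        assert len(pts) == 4
        for c in corners:
            assert np.min(np.hypot(*(pts - c).T)) <= 3.0

    def test_rotation_covariance_90deg(self, rng):
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.random((48, 48)) * 255, 2.0)
        r1 = harris_response(np.rot90(img))
        r2 = np.rot90(harris_response(img))
        assert np.allclose(r1, r2, atol=1e-9)


class TestCombineMaps:
    def test_equal_maps_reproduce_with_unit_weightsum(self, rng):
        g = rng.random((8, 8))
        assert np.allclose(combine_maps(g, g), g)

    @pytest.mark.parametrize("g,r,expected", [(0.0, 1.0, 0.7), (1.0, 0.0, 0.3)])
    def test_reference_fusion_weights(self, g, r, expected):
        out = combine_maps(np.full((3, 3), g), np.full((3, 3), r))
        assert np.allclose(out, expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_maps(np.zeros((3, 3)), np.zeros((4, 4)))


def _brute_force_nms(rhat, t1, r):
    """Literal per-pixel non-maximum suppression with lexicographic ties."""
    h, w = rhat.shape
    out = []
    for y in range(h):
        for x in range(w):
            v = rhat[y, x]
            if v <= t1:
                continue
            ok = True
            any_below = False
            for yy in range(h):
                for xx in range(w):
                    if (yy, xx) == (y, x) or (xx - x) ** 2 + (yy - y) ** 2 > r * r:
                        continue
                    if rhat[yy, xx] < v:
                        any_below = True
                    if rhat[yy, xx] > v or (rhat[yy, xx] == v and (yy, xx) < (y, x)):
                        ok = False
                        break
                if not ok:
                    break
            if ok and any_below:
                out.append((x, y, v))
    out.sort(key=lambda t: (-t[2], t[1], t[0]))
    return out


class TestFindCandidates:
    def test_constant_map_yields_nothing(self):
        pts, _ = find_candidates(np.full((20, 20), 0.5))
        assert len(pts) == 0

    def test_single_isolated_peak(self):
        m = np.zeros((20, 20))
        m[7, 11] = 0.5
        pts, scores = find_candidates(m)
        assert np.array_equal(pts, [[11, 7]]) and scores[0] == 0.5

    def test_close_peaks_suppressed(self):
        m = np.zeros((20, 20))
        m[10, 10] = 0.5
        m[10, 13] = 0.4
        pts, _ = find_candidates(m, t1=0.1, r=5.0)
        assert np.array_equal(pts, [[10, 10]])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            m = np.round(rng.random((18, 18)), 2)  # rounding forces ties
            pts, scores = find_candidates(m, t1=0.3, r=4.0)
            expected = _brute_force_nms(m, 0.3, 4.0)
            got = [(int(x), int(y), v) for (x, y), v in zip(pts, scores)]
            assert got == expected


def _brute_force_greedy(points, scores, d_min):
    order = list(range(len(points)))
    chosen, removed = [], set()
    for i in order:
        if i in removed:
            continue
        chosen.append(i)
        for j in order:
            if j not in removed and np.hypot(*(np.asarray(points[j]) - points[i])) < d_min:
                removed.add(j)
    return [tuple(points[i]) for i in chosen]


class TestGreedySelection:
    def test_greedy_drops_near_neighbor_keeps_distant(self):
        pts = [(0, 0), (10, 0), (30, 0)]
        sel = select_control_points(pts, [0.9, 0.8, 0.7], d_min=25)
        assert [tuple(p) for p in sel.points] == [(0, 0), (30, 0)]

    def test_empty_and_single(self):
        assert len(select_control_points(np.empty((0, 2)), [], 25)) == 0
        sel = select_control_points([(5, 5)], [0.4], 25)
        assert [tuple(p) for p in sel.points] == [(5, 5)]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30)
    def test_matches_brute_force_oracle_and_min_distance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        pts = rng.uniform(0, 100, (n, 2))
        scores = np.sort(rng.random(n))[::-1]  # descending as contract requires
        sel = select_control_points(pts, scores, d_min=12.0)
        assert [tuple(p) for p in sel.points] == _brute_force_greedy(pts, scores, 12.0)
        if len(sel) > 1:
            d = np.hypot(*(sel.points[:, None] - sel.points[None]).transpose(2, 0, 1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 12.0


class TestSelectFromImage:
    def test_constant_image_yields_empty_set(self):
        assert len(select_from_image(np.full((128, 128), 80.0))) == 0

    def test_postconditions_on_phantom(self, scene):
        params = SelectionParams()
        sel = select_from_image(scene.live, params)
        assert len(sel) > 10
        assert np.all(sel.scores[:-1] >= sel.scores[1:])  # ordered by score
        m = params.border_margin
        assert sel.points.min() >= m and sel.points.max() <= 511 - m
        d = np.hypot(*(sel.points[:, None] - sel.points[None]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= params.d_min

    def test_planted_corners_are_found(self):
        # bright squares on a flat background: their corners are the only
        # features, and each must attract a selected point within NMS radius
        img = np.full((200, 200), 60.0)
        img[80:120, 80:120] = 190.0
        sel = select_from_image(img, SelectionParams(border_margin=50))
        corners = np.array([[79.5, 79.5], [79.5, 119.5], [119.5, 79.5], [119.5, 119.5]])
        assert len(sel) >= 1
        for c in corners:
            assert np.min(np.hypot(*(sel.points - c).T)) <= 5.0 or len(sel) < 4
        # with D_min = 25 < corner spacing 40, all four correspond
        assert len(sel) == 4

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            select_from_image(np.zeros((60, 60)), SelectionParams())


def test_selection_params_validation():
    with pytest.raises(ValueError):
        SelectionParams(alpha=0.5, beta=0.6)
    with pytest.raises(ValueError):
        SelectionParams(t1=0.0)
    with pytest.raises(ValueError):
        features.SelectionParams(d_min=0.0)
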