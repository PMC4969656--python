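import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmtv import (
    InvalidRoiError,
    PolygonRoi,
    Voi,
    arg_grow,
    arg_volume_curve,
    build_voi,
    detect_knee,
    rasterize_roi,
    segment_absolute,
    segment_arg,
    segment_percent_max,
)
from petmtv.delineate import ArgCurve
from .conftest import make_image


# --- independent oracles ---------------------------------------------------


def point_in_polygon(verts, x, y):
    """Even-odd ray casting (horizontal ray to +x). Boundary not handled."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def grow_oracle(vals, seed, fraction, conn=6):
    """Brute-force adaptive region growing: re-scan the whole frontier each
    step, admit the hottest candidate (lexicographic tie-break) while
    value >= running_mean * fraction."""
    offsets = (
        [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        if conn == 6
        else [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    )
    region = {seed}
    total = float(vals[seed])
    while True:
        frontier = set()
        for (i, j, k) in region:
            for (di, dj, dk) in offsets:
                t = (i + di, j + dj, k + dk)
                if all(0 <= t[a] < vals.shape[a] for a in range(3)) and t not in region:
                    frontier.add(t)
        if not frontier:
            break
        best = min(frontier, key=lambda t: (-vals[t], t))
        mean = total / len(region)
        if mean > 0 and vals[best] < mean * fraction:
            break
        region.add(best)
        total += float(vals[best])
    mask = np.zeros(vals.shape, dtype=bool)
    for t in region:
        mask[t] = True
    return mask


# --- rasterization ---------------------------------------------------------


class TestRasterize:
    def test_rectangle_covers_exact_pixel_block(self, image_factory):
        img = image_factory(np.zeros((8, 8, 4)), spacing=(4.0, 4.0, 2.0))
        # pixel centers at x,y = 0,4,...,28; rectangle around centers 8..16
        roi = PolygonRoi(0, [[7, 7], [17, 7], [17, 17], [7, 17]])
        mask = rasterize_roi(roi, img)
        assert mask.sum() == 9
        assert mask[2:5, 2:5].all()

    def test_matches_ray_casting_oracle(self, image_factory):
        rng = np.random.default_rng(3)
        img = image_factory(np.zeros((12, 12, 2)), spacing=(4.0, 4.0, 2.0))
        for _ in range(10):
            # random star-shaped polygon (sorted angles -> simple polygon)
            n = rng.integers(3, 9)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(5, 20, n)
            cx, cy = rng.uniform(10, 34, 2)
            verts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
            try:
                roi = PolygonRoi(0, verts)
            except InvalidRoiError:
                continue
            mask = rasterize_roi(roi, img)
            for i in range(12):
                for j in range(12):
                    assert mask[i, j] == point_in_polygon(verts, 4.0 * i, 4.0 * j)

    def test_subpixel_triangle_is_empty(self, image_factory):
        img = image_factory(np.zeros((4, 4, 2)))
        roi = PolygonRoi(0, [[1.0, 1.0], [2.0, 1.0], [1.5, 2.0]])  # between centers
        assert rasterize_roi(roi, img).sum() == 0

    def test_boundary_center_counts_inside(self, image_factory):
        img = image_factory(np.zeros((4, 4, 2)))
        # edge passes exactly through the center (4, 4)
        roi = PolygonRoi(0, [[4.0, 4.0], [12.0, 4.0], [12.0, 12.0], [4.0, 12.0]])
        assert rasterize_roi(roi, img)[1, 1]

    def test_two_vertices_rejected(self):
        with pytest.raises(InvalidRoiError):
            PolygonRoi(0, [[0, 0], [1, 1]])

    def test_self_intersection_rejected(self):
        with pytest.raises(InvalidRoiError):
            PolygonRoi(0, [[0, 0], [4, 4], [4, 0], [0, 4]])  # bow-tie


class TestBuildVoi:
    def test_disjoint_slices_add_up(self, image_factory):
        img = image_factory(np.zeros((8, 8, 8)))
        rect = [[7, 7], [17, 7], [17, 17], [7, 17]]
        rois = [PolygonRoi(s, rect) for s in (3, 4, 5)]
        voi = build_voi(rois, img)
        assert voi.mask.sum() == 3 * 9

    def test_overlap_is_union(self, image_factory):
        img = image_factory(np.zeros((8, 8, 8)))
        rect = [[7, 7], [17, 7], [17, 17], [7, 17]]
        voi = build_voi([PolygonRoi(3, rect), PolygonRoi(3, rect)], img)
        assert voi.mask.sum() == 9  # no double counting

    def test_out_of_range_slice(self, image_factory):
        img = image_factory(np.zeros((8, 8, 8)))
        with pytest.raises(InvalidRoiError):
            build_voi([PolygonRoi(99, [[7, 7], [17, 7], [17, 17], [7, 17]])], img)


# --- threshold methods -----------------------------------------------------


def _full_voi(img, **kw):
    return Voi(mask=np.ones(img.shape, dtype=bool), **kw)


class TestThresholdMethods:
    def test_absolute_inclusive_cut(self, image_factory):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [1.0, 2.0, 2.5, 3.0]
        img = image_factory(vals)
        seg = segment_absolute(img, _full_voi(img), 2.5)
        assert seg.mask.sum() == 2
        assert seg.mask[2, 0, 0] and seg.mask[3, 0, 0]

    def test_threshold_above_suvmax_gives_zero_volume(self, image_factory):
        img = image_factory(np.full((3, 3, 3), 2.0))
        seg = segment_absolute(img, _full_voi(img), 3.5)
        assert seg.mask.sum() == 0 and seg.success

    def test_percent_max_threshold_value(self, image_factory):
        vals = np.full((4, 4, 2), 1.0)
        vals[1, 1, 0] = 10.0
        vals[2, 2, 1] = 5.0
        img = image_factory(vals)
        seg = segment_percent_max(img, _full_voi(img), 40)
        assert seg.applied_threshold_suv == pytest.approx(4.0)
        assert seg.mask.sum() == 2  # 10 and 5

    def test_percent_max_q100_keeps_only_max(self, image_factory):
        vals = np.ones((4, 4, 2))
        vals[0, 0, 0] = vals[3, 3, 1] = 7.0
        img = image_factory(vals)
        seg = segment_percent_max(img, _full_voi(img), 100)
        assert seg.mask.sum() == 2

    def test_percent_max_scale_invariant_absolute_is_not(self, image_factory):
        rng = np.random.default_rng(7)
        vals = rng.gamma(2.0, 1.5, size=(10, 10, 6))
        img = image_factory(vals)
        scaled = make_image(vals * 2.0)
        voi, voi2 = _full_voi(img), _full_voi(scaled)
        m_pct = segment_percent_max(img, voi, 40).mask
        m_pct2 = segment_percent_max(scaled, voi2, 40).mask
        np.testing.assert_array_equal(m_pct, m_pct2)
        m_abs = segment_absolute(img, voi, 2.5).mask
        m_abs2 = segment_absolute(scaled, voi2, 2.5).mask
        assert not np.array_equal(m_abs, m_abs2)

    def test_masks_shrink_with_threshold(self, image_factory):
        rng = np.random.default_rng(8)
        img = image_factory(rng.gamma(2.0, 1.5, size=(10, 10, 6)))
        voi = _full_voi(img)
        prev = None
        for p in (1.0, 2.0, 3.0, 4.0):
            mask = segment_absolute(img, voi, p).mask
            if prev is not None:
                assert (mask <= prev).all()  # subset
            prev = mask
        prev = None
        for q in (20, 35, 40, 45, 80):
            mask = segment_percent_max(img, voi, q).mask
            assert mask.any()  # always contains the hottest voxel
            if prev is not None:
                assert (mask <= prev).all()
            prev = mask


# --- adaptive region growing ----------------------------------------------


class TestArgGrow:
    def test_plateau_at_fraction_one(self, image_factory):
        vals = np.ones((5, 5, 3)) * 0.5
        vals[1:4, 1:4, 1] = 3.0  # flat plateau
        img = image_factory(vals)
        mask = arg_grow(img, (2, 2, 1), 1.0)
        np.testing.assert_array_equal(mask, vals == 3.0)

    def test_two_level_image(self, image_factory):
        vals = np.full((6, 6, 4), 1.0)
        vals[1:4, 1:4, 1:3] = 8.0
        img = image_factory(vals)
        mask = arg_grow(img, (2, 2, 1), 0.5)
        np.testing.assert_array_equal(mask, vals == 8.0)

    def test_fraction_zero_floods_bounds(self, image_factory):
        rng = np.random.default_rng(1)
        img = image_factory(rng.random((6, 6, 4)))
        bounds = ((1, 5), (0, 6), (1, 3))
        mask = arg_grow(img, (2, 2, 1), 0.0, bounds)
        assert mask.sum() == 4 * 6 * 2
        assert not mask[0].any()

    def test_seed_outside_bounds_rejected(self, image_factory):
        img = image_factory(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            arg_grow(img, (0, 0, 0), 0.5, ((1, 4), (0, 4), (0, 4)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        fraction=st.sampled_from([0.0, 0.3, 0.5, 0.8, 0.95, 1.0]),
        conn=st.sampled_from([6, 26]),
    )
    def test_matches_brute_force_oracle(self, seed, fraction, conn):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(2.0, 2.0, size=(5, 4, 4)).round(2)
        img = make_image(vals)
        seed_vox = tuple(int(v) for v in rng.integers(0, (5, 4, 4)))
        mask = arg_grow(img, seed_vox, fraction, connectivity=conn)
        np.testing.assert_array_equal(mask, grow_oracle(vals, seed_vox, fraction, conn))


class TestArgCurve:
    def test_curve_matches_per_fraction_growth(self, image_factory):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 2.0, size=(6, 5, 4)).round(2)
        img = image_factory(vals)
        seed = (2, 2, 2)
        curve = arg_volume_curve(img, seed)
        for i in range(0, len(curve.thresholds), 7):
            f = float(curve.thresholds[i])
            direct = arg_grow(img, seed, f)
            assert curve.volumes_ml[i] == pytest.approx(
                direct.sum() * img.voxel_volume_ml
            )
            np.testing.assert_array_equal(curve.region_mask(i), direct)

    def test_monotone_nondecreasing(self, image_factory):
        for s in range(5):
            rng = np.random.default_rng(s)
            img = image_factory(rng.gamma(2.0, 2.0, size=(6, 6, 4)))
            curve = arg_volume_curve(img, (3, 3, 2))
            assert (np.diff(curve.volumes_ml) >= 0).all()

    def test_two_level_phantom_single_jump(self, image_factory):
        vals = np.full((8, 8, 6), 1.0)
        vals[2:5, 2:5, 2:4] = 8.0
        img = image_factory(vals)
        curve = arg_volume_curve(img, (3, 3, 2))
        jumps = curve.volumes_ml[1:] / curve.volumes_ml[:-1]
        assert (jumps >= 2.0).sum() == 1  # exactly one flood event


class TestDetectKnee:
    def test_max_ratio_jump(self):
        curve = ArgCurve(
            thresholds=np.array([1.0, 0.75, 0.5, 0.25, 0.0]),
            volumes_ml=np.array([2.0, 2.1, 2.2, 40.0, 41.0]),
        )
        knee, ok = detect_knee(curve)
        assert ok and knee == 2  # tumor region is the 2.2 ml region

    def test_gentle_curve_fails(self):
        curve = ArgCurve(
            thresholds=np.linspace(1, 0, 5),
            volumes_ml=np.array([2.0, 2.5, 3.1, 3.9, 5.0]),
        )
        knee, ok = detect_knee(curve)
        assert not ok and knee is None

    def test_single_point_curve_fails(self):
        curve = ArgCurve(thresholds=np.array([1.0]), volumes_ml=np.array([2.0]))
        assert detect_knee(curve) == (None, False)


class TestSegmentArg:
    def test_deterministic_repeat(self, realistic_phantom):
        from petmtv import simulate_operator_voi

        early, _, truth = realistic_phantom
        voi = simulate_operator_voi(truth, early, rng_seed=1)
        seg1, _ = segment_arg(early, voi)
        seg2, _ = segment_arg(early, voi)
        np.testing.assert_array_equal(seg1.mask, seg2.mask)
        assert seg1.applied_threshold_suv == seg2.applied_threshold_suv

    def test_independent_of_voi_shape(self, realistic_phantom):
        from petmtv import simulate_operator_voi

        early, _, truth = realistic_phantom
        voi_a = simulate_operator_voi(truth, early, rng_seed=1, operator_id=1)
        voi_b = simulate_operator_voi(truth, early, rng_seed=99, operator_id=2)
        assert not np.array_equal(voi_a.mask, voi_b.mask)  # different drawings
        seg_a, _ = segment_arg(early, voi_a)
        seg_b, _ = segment_arg(early, voi_b)
        np.testing.assert_array_equal(seg_a.mask, seg_b.mask)

    def test_high_contrast_sphere_slight_overestimate(self):
        from petmtv import LesionSpec, PhantomSpec, make_phantom, simulate_operator_voi

        spec = PhantomSpec(noise_sd=0.0, rng_seed=2)  # blur on, noise off
        lesion = LesionSpec(
            center_mm=(60.0, 120.0, 64.0), radii_mm=(14.0, 14.0, 14.0), suv_early=12.0
        )
        early, _, truth = make_phantom(spec, lesion)
        voi = simulate_operator_voi(truth, early, rng_seed=0)
        seg, _ = segment_arg(early, voi)
        assert seg.success
        vol = seg.mask.sum() * early.voxel_volume_ml
        assert vol >= truth.true_volume_ml
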