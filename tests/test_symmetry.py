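"""Reflection, landmark registration, symmetrization and compositing."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from cephalon.metrics import dice
from cephalon.plate import DensityMap, LandmarkSet
from cephalon.isolation import isolate_traces
from cephalon.symmetry import (
    CompositeParams,
    composite_specimens,
    mirror_tracings,
    reflect_across,
    reflect_points,
    register_landmarks,
    resample_closed,
    symmetrize,
)
from cephalon.synthetic import TaphonomyParams, render_plate

VAX = np.array([[29.5, 0.0], [29.5, 49.0]])  # vertical axis between columns


class TestReflect:
    def test_involution(self):
        arr = np.random.default_rng(0).random((50, 60))
        assert np.allclose(reflect_across(reflect_across(arr, VAX), VAX), arr, atol=1e-6)

    def test_integer_aligned_axis_reverses_columns_exactly(self):
        arr = np.random.default_rng(1).random((20, 31))
        axis = np.array([[15.0, 0.0], [15.0, 19.0]])  # center column of 31
        assert np.array_equal(reflect_across(arr, axis), arr[:, ::-1])

    def test_point_signed_distance_negates(self):
        p = np.array([[40.0, 10.0]])  # distance +10.5 from x=29.5
        q = reflect_points(p, VAX)[0]
        assert q[0] == pytest.approx(19.0)
        assert q[1] == pytest.approx(10.0)

    def test_diagonal_axis_reflection_is_transposition(self):
        # the 45-degree axis through the origin corner swaps x and y exactly
        axis = np.array([[0.0, 0.0], [59.0, 59.0]])
        arr = np.random.default_rng(7).random((60, 60))
        assert np.allclose(reflect_across(arr, axis), arr.T, atol=1e-9)


class TestRegisterLandmarks:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(2).uniform(0, 100, (12, 2))
        tf = register_landmarks(pts, pts)
        assert tf.rotation == pytest.approx(0.0, abs=1e-12)
        assert tf.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rigid_transform(self):
        pts = np.random.default_rng(3).uniform(0, 100, (20, 2))
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + [5.0, -3.0]
        tf = register_landmarks(pts, moved)
        assert tf.rotation == pytest.approx(th, abs=1e-6)
        assert tf.translation[0] == pytest.approx(5.0, abs=1e-6)
        assert tf.translation[1] == pytest.approx(-3.0, abs=1e-6)
        assert tf.residual_rms < 1e-6

    def test_random_rigid_recovery_100_trials(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pts = rng.uniform(0, 200, (10, 2))
            th = rng.uniform(np.deg2rad(-30), np.deg2rad(30))
            shift = rng.uniform(-20, 20, 2)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            tf = register_landmarks(pts, pts @ R.T + shift)
            assert tf.residual_rms <= 1e-6

    def test_noise_floor_matches_rigid_dof(self):
        # RMS^2 of a rigid LSQ fit to sigma-noised targets has expectation
        # sigma^2 (2n - 3) / n  (2n residual coordinates minus 3 parameters)
        rng = np.random.default_rng(5)
        n, sigma = 15, 1.0
        rms2 = []
        for _ in range(100):
            pts = rng.uniform(0, 300, (n, 2))
            tf = register_landmarks(pts, pts + rng.normal(0, sigma, (n, 2)))
            rms2.append(tf.residual_rms**2)
        expect = sigma**2 * (2 * n - 3) / n
        se = np.std(rms2, ddof=1) / np.sqrt(len(rms2))
        assert abs(np.mean(rms2) - expect) < 3 * se

    def test_degenerate_points_rejected(self):
        same = np.zeros((5, 2))
        with pytest.raises(ValueError):
            register_landmarks(same, same + 1.0)

    def test_similarity_recovers_scale(self):
        pts = np.random.default_rng(6).uniform(0, 100, (8, 2))
        tf = register_landmarks(pts, pts * 1.7 + [2.0, 1.0], allow_scale=True)
        assert tf.scale == pytest.approx(1.7, abs=1e-9)


class TestResampleClosed:
    def test_reflected_outline_corresponds_pointwise(self):
        theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        # start vertex on the axis (top point), like annotated outlines
        outline = np.stack([29.5 + 8 * np.sin(theta), 40 - 6 * np.cos(theta)], axis=1)
        refl = reflect_points(outline, VAX)
        a = resample_closed(outline, 32)
        b = resample_closed(refl, 32)
        assert np.allclose(a, b, atol=1e-6)


class TestSymmetrize:
    def test_recovery_beats_both_raw_halves(self, template, recovery_density):
        truth = template.region_mask()
        recon = symmetrize(recovery_density, template.landmarks())
        fg = recon.map.pixels > threshold_otsu(recon.map.pixels)
        d_sym = dice(fg, truth)
        raw = recovery_density.pixels
        raw_fg = raw > threshold_otsu(raw)
        ax = template.axis_x
        cols = np.arange(raw.shape[1])
        left = raw_fg.copy()
        left[:, cols > ax] = False
        right = raw_fg.copy()
        right[:, cols <= ax] = False
        d_left, d_right = dice(left, truth), dice(right, truth)
        assert d_sym >= 0.85
        assert d_sym > max(d_left, d_right)

    def test_reflection_invariance_postcondition(self, template, recovery_density):
        recon = symmetrize(recovery_density, template.landmarks())
        assert recon.reflection_error() <= 2.0 / 255.0

    def test_symmetric_input_is_fixed_point(self, template, recovery_density):
        lm = template.landmarks()
        once = symmetrize(recovery_density, lm)
        twice = symmetrize(once.map, lm)
        assert np.allclose(twice.map.pixels, once.map.pixels, atol=1e-6)

    def test_recovery_improves_across_seeds(self, template):
        """Merged-halves recovery >= the best single half, 20 taphonomy seeds."""
        lm = template.landmarks()
        truth = template.region_mask()
        wins = 0
        for seed in range(20):
            plate, _ = render_plate(
                template,
                taphonomy=TaphonomyParams(
                    rotation_asymmetry=0.5, speckle_rate=0.0005, seed=seed
                ),
            )
            dens = isolate_traces(plate)
            recon = symmetrize(dens, lm)
            fg = recon.map.pixels > threshold_otsu(recon.map.pixels)
            raw_fg = dens.pixels > threshold_otsu(dens.pixels)
            cols = np.arange(dens.shape[1])
            left = raw_fg.copy()
            left[:, cols > template.axis_x] = False
            right = raw_fg.copy()
            right[:, cols <= template.axis_x] = False
            if dice(fg, truth) >= max(dice(left, truth), dice(right, truth)):
                wins += 1
        assert wins == 20

    def test_bad_reference_side_rejected(self, template, recovery_density):
        with pytest.raises(ValueError):
            symmetrize(recovery_density, template.landmarks(), reference_side="up")


class TestComposite:
    def test_four_identical_layers_additive(self, template, recovery_density):
        lm = template.landmarks()
        layer = DensityMap(recovery_density.pixels)
        comp = composite_specimens([(layer, lm)] * 4, CompositeParams(alpha=1 / 3))
        v = recovery_density.pixels
        assert np.allclose(comp.pixels, np.minimum(4 * v / 3, 1.0), atol=1e-12)

    def test_single_layer_is_alpha_scaled_copy(self, template, recovery_density):
        lm = template.landmarks()
        comp = composite_specimens(
            [(DensityMap(recovery_density.pixels), lm)], CompositeParams(alpha=0.4)
        )
        assert np.allclose(comp.pixels, 0.4 * recovery_density.pixels)

    def test_overlap_brighter_than_single_coverage(self, template, recovery_density):
        # a pixel present in 3 layers is brighter than one present in 1
        lm = template.landmarks()
        layer = DensityMap(recovery_density.pixels)
        comp3 = composite_specimens([(layer, lm)] * 3, CompositeParams(alpha=1 / 3))
        comp1 = composite_specimens([(layer, lm)], CompositeParams(alpha=1 / 3))
        hot = recovery_density.pixels > 0.5
        assert np.all(comp3.pixels[hot] > comp1.pixels[hot])

    def test_registered_offset_layer_realigns(self, template, recovery_density):
        lm = template.landmarks()
        # second specimen: same map shifted and scaled, landmarks transformed
        th, s, shift = 0.05, 1.1, np.array([6.0, -4.0])
        R = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

        def tf_pts(p):
            return p @ R.T + shift

        from skimage.transform import SimilarityTransform, warp

        T = SimilarityTransform(scale=s, rotation=th, translation=shift)
        moved = warp(recovery_density.pixels, T.inverse, preserve_range=True)
        lm2 = LandmarkSet(
            midline=tf_pts(lm.midline),
            foramen_outline=tf_pts(lm.foramen_outline),
            ocellar_nerves=tf_pts(lm.ocellar_nerves),
        )
        comp = composite_specimens(
            [(DensityMap(recovery_density.pixels), lm), (DensityMap(moved), lm2)],
            CompositeParams(alpha=0.5),
        )
        # peak of the realigned composite coincides with the reference peak
        ref_peak = np.unravel_index(np.argmax(recovery_density.pixels), comp.shape)
        assert comp.pixels[ref_peak] > 0.9 * comp.pixels.max()


class TestMirrorTracings:
    def test_vertex_multiset_closed_under_reflection(self):
        polys = [np.array([[10.0, 10.0], [25.0, 12.0], [20.0, 30.0]])]
        out = mirror_tracings(polys, VAX)
        verts = {tuple(np.round(v, 6)) for p in out for v in p}
        reflected = {
            tuple(np.round(v, 6)) for p in out for v in reflect_points(p, VAX)
        }
        assert verts == reflected

    def test_axis_straddling_polygon_overlaps_its_mirror(self):
        from shapely.geometry import Polygon

        poly = np.array([[25.0, 5.0], [34.0, 5.0], [34.0, 20.0], [25.0, 20.0]])
        a, b = mirror_tracings([poly], VAX)
        assert Polygon(a).intersection(Polygon(b)).area > 0

    def test_filled_area_at_most_doubles(self):
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        disjoint = np.array([[5.0, 5.0], [15.0, 5.0], [15.0, 15.0], [5.0, 15.0]])
        overlap = np.array([[25.0, 5.0], [34.0, 5.0], [34.0, 15.0], [25.0, 15.0]])
        for poly in (disjoint, overlap):
            pair = [Polygon(p) for p in mirror_tracings([poly], VAX)]
            union = unary_union(pair).area
            single = pair[0].area
            assert union <= 2 * single + 1e-9
            touches_axis = Polygon(poly).bounds[2] > VAX[0][0]
            assert (union < 2 * single) == touches_axis

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ValueError):
            mirror_tracings([bowtie], VAX)
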