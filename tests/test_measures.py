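"""Geometry of the dense contour and the 16 tongue measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguespace import (
    HEIGHT_SHAPE_MEASURES,
    MEASURE_COLUMNS,
    POSITION_MEASURES,
    DenseContour,
    KnotContour,
    TongueMeasureExtractor,
    circular_arc,
    curvature_ratios,
    densify,
    extract_measures,
    extract_measures_table,
    highest_point,
    highest_vertex,
    mci,
)


def _contour(knots, token="t1", vowel="bid"):
    return KnotContour(speaker_id="S1", token_id=token, vowel=vowel,
                       repetition=1, knots=np.asarray(knots, float))


def _random_contour(seed):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 50, 11))
    x += np.arange(11) * 1e-3  # guard against coincident knots
    y = 20 * np.exp(-0.5 * ((x - rng.uniform(15, 35)) / 8) ** 2) + rng.uniform(0, 2, 11)
    return _contour(np.c_[x, y])


def _similarity(points, angle, scale, shift):
    c, s = np.cos(angle), np.sin(angle)
    return scale * points @ np.array([[c, s], [-s, c]]) + shift


class TestDensify:
    def test_collinear_knots_stay_collinear(self):
        c = _contour(np.c_[np.linspace(0, 10, 11), np.zeros(11)])
        dense = densify(c)
        assert len(dense) == 100
        assert np.max(np.abs(dense.points[:, 1])) < 1e-9

    def test_all_knots_reproduced(self):
        c = _random_contour(5)
        dense = densify(c, n=100)
        for knot in c.knots:
            d = np.min(np.linalg.norm(dense.points - knot, axis=1))
            assert d < 1e-9

    def test_semicircle_knots_yield_near_unit_radius(self):
        ang = np.linspace(np.pi, 0, 11)
        dense = densify(np.c_[np.cos(ang), np.sin(ang)])
        radii = np.linalg.norm(dense.points, axis=1)
        # ends flatten slightly (natural boundary), interior hugs the circle
        assert np.max(np.abs(radii - 1.0)) < 0.01

    def test_zero_chord_rejected(self):
        knots = np.c_[np.linspace(0, 10, 11), np.zeros(11)]
        knots[4] = knots[3]
        with pytest.raises(ValueError, match="coincident"):
            densify(_contour(knots))


class TestHighestPoint:
    def test_semicircle_apex(self):
        hp = highest_point(circular_arc(np.pi))
        assert abs(hp[0]) < 0.02 and abs(hp[1] - 1.0) < 0.02

    def test_strictly_rising_contour_picks_last_point(self):
        pts = np.c_[np.linspace(0, 10, 100), np.linspace(0, 5, 100)]
        hp = highest_point(DenseContour(pts))
        np.testing.assert_allclose(hp, pts[-1])

    def test_two_bump_contour_matches_brute_force(self, fixtures):
        dense = fixtures["two_bump"].dense
        hp = highest_point(dense)
        brute = max(dense.points, key=lambda p: p[1])
        np.testing.assert_allclose(hp, brute)
        assert abs(hp[0] - fixtures["two_bump"].expected["hp_x_near"]) < 0.5

    def test_tie_broken_posteriorly(self):
        pts = np.zeros((10, 2))
        pts[:, 0] = np.arange(10)
        pts[[2, 7], 1] = 3.0
        hp = highest_point(DenseContour(pts))
        assert hp[0] == 2.0


class TestHighestVertex:
    def test_triangle_fixture_exact(self, fixtures):
        tri = highest_vertex(fixtures["triangle"].dense)
        exp = fixtures["triangle"].expected
        np.testing.assert_allclose(tri.HV, exp["hv"], atol=1e-12)
        np.testing.assert_allclose(tri.D, exp["d"], atol=1e-12)
        assert tri.HVD == pytest.approx(exp["hvd"], abs=1e-12)
        assert tri.AB == pytest.approx(exp["ab"], abs=1e-12)
        assert tri.AD == pytest.approx(exp["ad"], abs=1e-12)
        assert tri.DB == pytest.approx(exp["db"], abs=1e-12)
        assert tri.AD + tri.DB == pytest.approx(tri.AB, abs=1e-9)

    def test_chord_relative_lengths_rotation_invariant(self, fixtures):
        dense = fixtures["triangle"].dense
        tri = highest_vertex(dense)
        rot = highest_vertex(DenseContour(_similarity(dense.points, np.pi / 6, 1.0, [3, -2])))
        for attr in ("AB", "AD", "DB", "HVD"):
            assert getattr(rot, attr) == pytest.approx(getattr(tri, attr), abs=1e-9)

    def test_matches_brute_force_on_random_bump(self):
        dense = densify(_random_contour(11))
        tri = highest_vertex(dense)
        a, b = dense.points[0], dense.points[-1]
        u = (b - a) / np.linalg.norm(b - a)
        rel = dense.points - a
        dists = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
        assert tri.hv_index == int(np.argmax(dists))
        assert tri.HVD == pytest.approx(dists.max())

    def test_degenerate_chord_rejected(self):
        pts = np.c_[np.cos(np.linspace(0, 2 * np.pi, 50)),
                    np.sin(np.linspace(0, 2 * np.pi, 50))]
        with pytest.raises(ValueError, match="chord"):
            highest_vertex(DenseContour(pts))


class TestCurvatureRatios:
    def test_direct_ratios(self, fixtures):
        tri = highest_vertex(fixtures["triangle"].dense)
        r = curvature_ratios(tri)
        assert r.tcp == pytest.approx(0.3, abs=1e-12)
        assert r.tc == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert not r.degenerate

    def test_symmetric_arch_tc_is_one(self):
        r = curvature_ratios(highest_vertex(circular_arc(np.pi, 101)))
        assert r.tc == pytest.approx(1.0, abs=1e-9)

    def test_flat_contour_degenerate(self, fixtures):
        tri = highest_vertex(fixtures["line"].dense)
        r = curvature_ratios(tri)
        assert r.tcp == 0.0
        assert np.isnan(r.tc)
        assert r.degenerate


class TestMCI:
    def test_straight_line_zero(self, fixtures):
        assert mci(fixtures["line"].dense) < 1e-6

    @pytest.mark.parametrize("theta", [np.pi / 6, np.pi / 2, np.pi])
    def test_arc_mci_equals_subtended_angle(self, theta):
        assert mci(circular_arc(theta)) == pytest.approx(theta, rel=0.02)

    def test_scale_free(self):
        for radius in (0.5, 10.0, 200.0):
            assert mci(circular_arc(np.pi, radius=radius)) == pytest.approx(np.pi, rel=0.02)

    def test_quarter_circle_plus_segment(self, fixtures):
        assert mci(fixtures["quarter_segment"].dense) == pytest.approx(np.pi / 2, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            mci(DenseContour(np.c_[np.arange(4.0), np.zeros(4)]))


class TestExtractMeasures:
    def test_knot_measures_are_raw_coordinates(self):
        c = _random_contour(2)
        c.knots[4] = (42.0, 31.5)
        rec = extract_measures(c)
        assert rec.values["K5_X"] == 42.0
        assert rec.values["K5_Y"] == 31.5
        for i, name in zip((1, 2, 3, 5, 6), ("K2_X", "K3_X", "K4_X", "K6_X", "K7_X")):
            assert rec.values[name] == c.knots[i, 0]

    def test_unrotated_contour_rejected(self):
        c = _random_contour(3)
        c.rotated = False
        with pytest.raises(ValueError, match="rotated"):
            extract_measures(c)

    def test_batch_extraction_no_unexpected_nan(self, small_cohort):
        dataset, _ = small_cohort
        df = extract_measures_table(dataset)
        assert len(df) == len(dataset)
        non_tc = [c for c in MEASURE_COLUMNS if c != "TC"]
        assert df[non_tc].notna().all().all()

    def test_measure_battery_is_8_by_8(self):
        assert len(POSITION_MEASURES) == 8
        assert len(HEIGHT_SHAPE_MEASURES) == 8
        assert len(MEASURE_COLUMNS) == 16
        assert len(POSITION_MEASURES) * len(HEIGHT_SHAPE_MEASURES) == 64

    def test_transformer_aliases_swap_names_only(self, small_cohort):
        dataset, _ = small_cohort
        plain = TongueMeasureExtractor().fit_transform(dataset)
        swapped = TongueMeasureExtractor(
            name_aliases={"TCP": "TC", "TC": "TCP"}
        ).fit_transform(dataset)
        np.testing.assert_allclose(plain["TCP"], swapped["TC"])
        np.testing.assert_allclose(
            plain["TC"].dropna(), swapped["TCP"].dropna()
        )


class TestInvariances:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 5000), angle=st.floats(-np.pi, np.pi),
           scale=st.floats(0.2, 5.0), tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_shape_measures_similarity_invariant(self, seed, angle, scale, tx, ty):
        """TCP, TC and MCI are ratios/turning: blind to pose and size."""
        c = _random_contour(seed)
        moved = _contour(_similarity(c.knots, angle, scale, [tx, ty]))
        r0 = extract_measures(c)
        r1 = extract_measures(moved)
        assert r1.values["TCP"] == pytest.approx(r0.values["TCP"], abs=1e-6)
        if np.isfinite(r0.values["TC"]):
            assert r1.values["TC"] == pytest.approx(r0.values["TC"], abs=1e-6)
        assert r1.values["MCI"] == pytest.approx(r0.values["MCI"], abs=1e-3)

    def test_hp_moves_under_rotation_while_hvd_does_not(self):
        """HP is frame-bound (occlusal y), HV chord-relative."""
        c = _random_contour(21)
        rot = _contour(_similarity(c.knots, np.deg2rad(15), 1.0, [0, 0]))
        tri0 = highest_vertex(densify(c))
        tri1 = highest_vertex(densify(rot))
        assert tri1.HVD == pytest.approx(tri0.HVD, abs=1e-6)
        hp0 = highest_point(densify(c))
        hp1 = highest_point(densify(rot))
        assert abs(hp1[1] - hp0[1]) > 0.01
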