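"""Segment decomposition, branch orders, and per-cell branch metrics."""
import math

import numpy as np
import pytest

import arbormetry.branches as br
from arbormetry.morphology import Morphology, MorphologyError, SomaContour, SomaContourStack
from arbormetry.synthetic import generate_aii, make_fixture

from conftest import build_path_morphology


def semicircle_path(radius=5.0, n=2000):
    theta = np.linspace(0, math.pi, n + 1)
    xyz = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n + 1)])
    return Morphology(
        ids=np.arange(1, n + 2), parents=np.concatenate([[-1], np.arange(n)]),
        xyz=xyz, radius=np.full(n + 1, 0.3), labels=np.zeros(n + 1, int),
    )


class TestDecomposition:
    @pytest.mark.parametrize(
        "name,kwargs,nodes,endings,segments",
        [
            ("balanced_tree", {"depth": 2}, 3, 4, 7),
            ("balanced_tree", {"depth": 3}, 7, 8, 15),
            ("caterpillar", {"k": 5}, 5, 6, 11),
            ("cylinder", {}, 0, 1, 1),
        ],
    )
    def test_counts(self, name, kwargs, nodes, endings, segments):
        d = br.decompose_segments(make_fixture(name, **kwargs))
        assert (d.n_nodes, d.n_endings, d.n_segments) == (nodes, endings, segments)

    def test_segments_equal_nodes_plus_endings(self, aii_population_small):
        for morph, _ in aii_population_small:
            d = br.decompose_segments(morph)
            assert d.n_segments == d.n_nodes + d.n_endings

    def test_every_point_owned_once(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        owned = np.concatenate([s.points[1:] for s in d.segments])
        assert len(owned) == len(set(owned.tolist()))
        assert len(owned) == morph.n_points - len(morph.root_indices())

    def test_single_tree_endings_equal_nodes_plus_one(self):
        # a single purely bifurcating tree
        for depth in (1, 2, 4):
            d = br.decompose_segments(make_fixture("balanced_tree", depth=depth))
            assert d.n_endings == d.n_nodes + 1


class TestBranchOrders:
    def test_y_tree_orders(self, y_tree):
        d = br.decompose_segments(y_tree)
        cf = br.assign_branch_orders(y_tree, d, "centrifugal")
        sh = br.assign_branch_orders(y_tree, d, "central_shaft")
        assert sorted(cf.tolist()) == [1, 2, 2]
        assert sorted(sh.tolist()) == [1, 1, 2]
        # the thicker daughter continues the shaft
        thick = max(
            (s for s in d.segments if s.parent is not None),
            key=lambda s: y_tree.radius[s.points[1]],
        )
        assert sh[thick.index] == 1

    def test_caterpillar_orders(self):
        m = make_fixture("caterpillar", k=5)
        d = br.decompose_segments(m)
        assert br.assign_branch_orders(m, d, "central_shaft").max() == 2
        assert br.assign_branch_orders(m, d, "centrifugal").max() == 6

    def test_shaft_never_exceeds_centrifugal(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        cf = br.assign_branch_orders(morph, d, "centrifugal")
        sh = br.assign_branch_orders(morph, d, "central_shaft")
        assert (sh <= cf).all()

    def test_centrifugal_order_counts_ancestor_bifurcations(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        cf = br.assign_branch_orders(morph, d, "centrifugal")
        for seg in d.segments[:50]:
            depth, cur = 0, seg
            while cur.parent is not None:
                cur = d.segments[cur.parent]
                depth += 1
            assert cf[seg.index] == depth + 1

    def test_generator_ground_truth_orders(self, aii_cell):
        # the generator records the order of every segment it creates under
        # both schemes; the order assignment must reproduce them exactly
        morph, gt = aii_cell
        d = br.decompose_segments(morph)
        cf = br.assign_branch_orders(morph, d, "centrifugal")
        sh = br.assign_branch_orders(morph, d, "central_shaft")
        checked = 0
        for seg in d.segments:
            end = int(seg.points[-1])
            if end in gt.segment_orders:
                gcf, gsh = gt.segment_orders[end]
                assert cf[seg.index] == gcf
                assert sh[seg.index] == gsh
                checked += 1
        assert checked > 0.9 * d.n_segments


class TestSegmentGeometry:
    def test_cylinder_closed_form(self, cylinder):
        d = br.decompose_segments(cylinder)
        g = br.segment_geometry(cylinder, d.segments[0])
        assert g["surface"] == pytest.approx(2 * math.pi * 0.5 * 10, rel=1e-9)
        assert g["volume"] == pytest.approx(math.pi * 0.25 * 10, rel=1e-9)
        assert g["contraction"] == pytest.approx(1.0, abs=1e-12)

    def test_cone_frustum_closed_form(self):
        m = build_path_morphology([2.0, 1.0], spacing=4.0)
        d = br.decompose_segments(m)
        g = br.segment_geometry(m, d.segments[0])
        assert g["volume"] == pytest.approx(math.pi * 4 / 3 * (1 + 0.5 + 0.25), rel=1e-9)
        slant = math.hypot(4.0, 0.5)
        assert g["surface"] == pytest.approx(math.pi * 1.5 * slant, rel=1e-9)

    def test_semicircle_contraction(self):
        m = semicircle_path()
        d = br.decompose_segments(m)
        g = br.segment_geometry(m, d.segments[0])
        assert g["contraction"] == pytest.approx(2 / math.pi, rel=1e-6)

    def test_zero_length_edges_skipped(self):
        m = build_path_morphology([1.0, 1.0, 1.0])
        m.xyz[1] = m.xyz[0]  # coincident points: only the 2 µm edge remains
        d = br.decompose_segments(m)
        g = br.segment_geometry(m, d.segments[0])
        assert g["path_length"] == pytest.approx(2.0)

    def test_contraction_bounded(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        for g in br.all_segment_geometry(morph, d):
            if g["contraction"] is not None:
                assert 0 < g["contraction"] <= 1 + 1e-12


def stub_tree():
    """Root bifurcation with one terminal daughter and one deeper subtree."""
    m = make_fixture("caterpillar", k=2)
    return m


class TestPartitionAsymmetry:
    def test_tip_bifurcation_is_zero(self, y_tree):
        d = br.decompose_segments(y_tree)
        assert br.partition_asymmetry(d) == pytest.approx(0.0)

    def test_stub_bifurcation_is_one(self):
        # caterpillar nodes all have one terminal daughter and a deeper
        # continuation, i.e. stub bifurcations with asymmetry 1, except the
        # last node which is a tip bifurcation (asymmetry 0)
        d = br.decompose_segments(make_fixture("caterpillar", k=2))
        mean, per_node = br.partition_asymmetry(d, per_node=True)
        values = sorted(per_node.values())
        assert values == [0.0, 1.0]

    def test_two_tip_three_stub_tree_averages_point_six(self):
        # forest with exactly 2 tip bifurcations and 3 stub bifurcations:
        # a caterpillar chain of 3 stubs ending in a tip bifurcation, plus a
        # separate Y tree (one tip bifurcation); mean = (0+0+1+1+1)/5
        pts, parents = [], []

        def add(x, y, parent):
            pts.append([x, y, 0.0])
            parents.append(parent)
            return len(pts) - 1

        node = add(0, 0, -1)
        for i in range(1, 4):       # three stub bifurcations
            node = add(0, i, node)
            add(1, i, node)
        tipbif = add(0, 4, node)    # tip bifurcation closing the chain
        add(1, 5, tipbif)
        add(-1, 5, tipbif)
        r2 = add(10, 0, -1)         # second tree: a single tip bifurcation
        y2 = add(10, 1, r2)
        add(11, 2, y2)
        add(9, 2, y2)
        m = Morphology(
            ids=np.arange(1, len(pts) + 1), parents=np.array(parents),
            xyz=np.array(pts, float), radius=np.full(len(pts), 0.3),
            labels=np.zeros(len(pts), int),
        )
        d = br.decompose_segments(m)
        mean, per_node = br.partition_asymmetry(d, per_node=True)
        assert sorted(per_node.values()) == [0.0, 0.0, 1.0, 1.0, 1.0]
        assert mean == pytest.approx(0.6)

    def test_no_bifurcations_reported_absent(self, cylinder):
        d = br.decompose_segments(cylinder)
        assert br.partition_asymmetry(d) is None


class TestBifurcationAngles:
    def test_planar_y_is_ninety(self, y_tree):
        d = br.decompose_segments(y_tree)
        res = br.bifurcation_angles(y_tree, d)
        assert res["mean"] == pytest.approx(90.0, abs=1e-9)

    def test_collinear_opposite_daughters(self):
        m = build_path_morphology([1.0, 1.0])
        # add two daughters straight up and straight down from the end
        xyz = np.vstack([m.xyz, [[1.0, 1.0, 0.0], [1.0, -1.0, 0.0]]])
        m2 = Morphology(
            ids=np.arange(1, 5), parents=np.array([-1, 0, 1, 1]),
            xyz=xyz, radius=np.full(4, 0.3), labels=np.zeros(4, int),
        )
        d = br.decompose_segments(m2)
        res = br.bifurcation_angles(m2, d)
        assert res["mean"] == pytest.approx(180.0, abs=1e-9)

    def test_population_sd_convention(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        res = br.bifurcation_angles(morph, d)
        assert res["sd"] == pytest.approx(float(np.std(res["values"])))


class TestBifurcationTilts:
    def _tree_with_daughters(self, d1, d2):
        pts = np.array([[0, 0, 0], [0, 1, 0], [0, 2, 0]], float)
        pts = np.vstack([pts, pts[2] + d1, pts[2] + d2])
        return Morphology(
            ids=np.arange(1, 6), parents=np.array([-1, 0, 1, 2, 2]),
            xyz=pts, radius=np.full(5, 0.3), labels=np.zeros(5, int),
        )

    def test_straight_ahead_is_180(self):
        m = self._tree_with_daughters([0, 1, 0], [1, 1, 0])
        d = br.decompose_segments(m)
        res = br.bifurcation_tilts(m, d)
        # the most backward daughter is the oblique one (135°), not 180°
        assert res["values"][0] == pytest.approx(135.0, abs=1e-9)
        m2 = self._tree_with_daughters([0, 1, 0], [0, 1, 1])
        res2 = br.bifurcation_tilts(m2, br.decompose_segments(m2))
        assert max(res2["values"]) <= 180.0

    def test_doubling_back_is_zero(self):
        m = self._tree_with_daughters([0, -1, 0.0], [1, 1, 0])
        d = br.decompose_segments(m)
        res = br.bifurcation_tilts(m, d)
        assert res["values"][0] == pytest.approx(0.0, abs=1e-9)


class TestPathShape:
    def test_straight_branch_dimension_one(self):
        m = build_path_morphology([0.5] * 20)
        d = br.decompose_segments(m)
        res = br.fractal_dimension(m, d)
        assert res["mean"] == pytest.approx(1.0, abs=1e-9)

    def test_random_walk_dimension_two(self):
        # a 3D random walk's path length grows quadratically with the
        # distance from its start; individual 10⁴-step walks fluctuate, so
        # the dimension is pooled (harmonically, i.e. on the slope scale)
        # over an ensemble of seeded walks
        rng = np.random.default_rng(12)
        inv = []
        for _ in range(200):
            walk = np.cumsum(rng.normal(size=(10_000, 3)), axis=0)
            d = br.polyline_fractal_dimension(walk)
            if d is not None:
                inv.append(1.0 / d)
        assert 1.0 / np.mean(inv) == pytest.approx(2.0, abs=0.1)

    def test_helix_dimension_between_extremes(self):
        m = make_fixture("helix")
        d = br.decompose_segments(m)
        res = br.fractal_dimension(m, d)
        assert 1.0 < res["mean"] < 2.0

    def test_planar_zigzag_has_zero_helicity(self):
        xyz = np.array([[i, i % 2, 0.0] for i in range(10)])
        h = br.polyline_helicity(xyz)
        assert np.allclose(h, 0.0)

    def test_helix_handedness_constant_and_mirrored(self):
        right = make_fixture("helix", handedness=1)
        left = make_fixture("helix", handedness=-1)
        hr = br.polyline_helicity(right.xyz)
        hl = br.polyline_helicity(left.xyz)
        assert (np.sign(hr) == np.sign(hr[0])).all()
        np.testing.assert_allclose(hl, -hr, atol=1e-12)


class TestEuclideanDistance:
    def test_single_ray(self):
        m = make_fixture("radial_ray", length=10.0, spacing=0.5)
        stats = br.euclidean_distance_stats(m)
        assert stats["max"] == pytest.approx(10.0)
        assert stats["mean"] == pytest.approx(5.0)

    def test_brute_force_oracle(self, aii_cell):
        morph, _ = aii_cell
        stats = br.euclidean_distance_stats(morph)
        center = morph.soma_centroid()
        d = [np.linalg.norm(p - center) for p in morph.xyz[morph.neurite_mask()]]
        assert stats["mean"] == pytest.approx(np.mean(d))
        assert stats["max"] == pytest.approx(np.max(d))


def circle_contour(r, z, n=128):
    th = np.linspace(0, 2 * math.pi, n + 1)[:-1]
    return SomaContour(depth=z, vertices=np.column_stack([r * np.cos(th), r * np.sin(th)]))


class TestSomaMetrics:
    def test_sphere_volume_within_two_percent(self):
        zs = np.linspace(-4.9, 4.9, 50)
        stack = SomaContourStack([circle_contour(math.sqrt(25 - z * z), z) for z in zs])
        sm = br.soma_metrics(stack)
        assert sm["volume"] == pytest.approx(4 / 3 * math.pi * 125, rel=0.02)
        assert sm["surface_area"] == pytest.approx(4 * math.pi * 25, rel=0.05)

    def test_cylinder_stack(self):
        zs = np.linspace(0, 10, 21)
        stack = SomaContourStack([circle_contour(2.0, z) for z in zs])
        sm = br.soma_metrics(stack)
        assert sm["volume"] == pytest.approx(math.pi * 4 * 10, rel=1e-3)

    def test_single_contour_projection_only(self):
        stack = SomaContourStack([circle_contour(3.0, 0.0, n=256)])
        sm = br.soma_metrics(stack)
        assert sm["volume"] is None and sm["surface_area"] is None
        assert sm["projection_area"] == pytest.approx(math.pi * 9, rel=1e-3)
        assert sm["projection_perimeter"] == pytest.approx(2 * math.pi * 3, rel=1e-3)
        assert sm["feret_max"] == pytest.approx(6.0, rel=1e-3)
        assert sm["feret_min"] == pytest.approx(6.0, rel=1e-3)


class TestDiameterCorrection:
    def test_shift_arithmetic_and_exact_postcondition(self, aii_cell):
        morph, _ = aii_cell
        before = br.thinnest_point_mean(morph)
        corrected, shift = br.correct_diameters(morph, target=0.23)
        assert shift == pytest.approx(0.23 - before)
        assert br.thinnest_point_mean(corrected) == pytest.approx(0.23, abs=1e-12)

    def test_negative_shift_supported(self, aii_cell):
        # a reconstruction whose thinnest points average above the target
        # is corrected by subtraction
        morph, _ = aii_cell
        fat = morph.copy()
        fat.radius = morph.radius + 0.1
        corrected, shift = br.correct_diameters(fat, target=0.23)
        assert shift < 0
        assert br.thinnest_point_mean(corrected) == pytest.approx(0.23, abs=1e-12)

    def test_idempotent(self, aii_cell):
        morph, _ = aii_cell
        once, _ = br.correct_diameters(morph)
        twice, shift2 = br.correct_diameters(once)
        assert shift2 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(twice.radius, once.radius, atol=1e-12)

    def test_too_few_segments_rejected(self, cylinder):
        with pytest.raises(MorphologyError):
            br.correct_diameters(cylinder)

    def test_nonpositive_result_rejected(self, aii_cell):
        from arbormetry.morphology import ValidationError

        morph, _ = aii_cell
        with pytest.raises(ValidationError):
            br.correct_diameters(morph, target=-1.0)


class TestCapacitance:
    def test_area_product(self):
        assert br.capacitance_from_area(1000.0) == pytest.approx(10.0)

    def test_cylinder_cell(self, cylinder):
        c = br.estimate_capacitance(cylinder)
        assert c == pytest.approx(0.01 * 2 * math.pi * 0.5 * 10, rel=1e-9)

    def test_published_mean_areas(self):
        # soma 197 µm² plus dendrites 1770 µm² at 0.01 pF/µm²
        assert br.capacitance_from_area(197 + 1770) == pytest.approx(19.67)


class TestOrderProfiles:
    def test_caterpillar_side_branches_order_two(self):
        m = make_fixture("caterpillar", k=5)
        d = br.decompose_segments(m)
        prof = br.order_profiles(m, d, "central_shaft")
        assert prof.loc[2, "n_segments"] == 5
        assert prof.loc[1, "n_segments"] == 6

    def test_length_conserved_across_orders(self, aii_cell):
        morph, _ = aii_cell
        d = br.decompose_segments(morph)
        total = sum(g["path_length"] for g in br.all_segment_geometry(morph, d))
        for scheme in ("central_shaft", "centrifugal"):
            prof = br.order_profiles(morph, d, scheme)
            assert prof["length"].sum() == pytest.approx(total, rel=1e-9)
            assert prof["n_segments"].sum() == d.n_segments
            assert prof["n_nodes"].sum() == d.n_nodes
            assert prof["n_endings"].sum() == d.n_endings

    def test_generated_cells_contain_orders_one_to_ten(self, aii_population_small):
        for morph, _ in aii_population_small:
            d = br.decompose_segments(morph)
            orders = set(br.assign_branch_orders(morph, d, "centrifugal").tolist())
            assert set(range(1, 11)) <= orders


class TestCellSummary:
    def test_cylinder_summary(self, cylinder):
        cs = br.cell_summary(cylinder)
        assert cs["n_primary_dendrites"] == 1
        assert cs["n_nodes"] == 0
        assert cs["n_endings"] == 1
        assert cs["soma_volume"] is None  # no contour stack

    def test_deterministic(self):
        a = br.cell_summary(generate_aii(seed=3)[0], y_split=22.0)
        b = br.cell_summary(generate_aii(seed=3)[0], y_split=22.0)
        assert a == b

    def test_segment_identity_for_generated_cells(self, aii_population_small):
        for morph, _ in aii_population_small:
            cs = br.cell_summary(morph)
            assert cs["n_segments"] == cs["n_nodes"] + cs["n_endings"]
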