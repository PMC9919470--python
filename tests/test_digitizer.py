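import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from phytomer3d.digitizer import (
    CSV_COLUMNS,
    LeafSurfaceTrace,
    StemTrace,
    internode_lengths,
    leaf_mesh_from_trace,
    node_diameter,
    read_digitized_plant,
    read_obj,
    to_shoot,
    write_digitized_plant,
    write_obj,
)
from phytomer3d.errors import DigitizerFormatError, GeometryError
from phytomer3d.synthetic import SyntheticPlantConfig, generate_shoot

from conftest import make_leaf_trace


class TestTraces:
    def test_row_and_point_counts(self):
        t = make_leaf_trace(n_rows=2)
        assert t.n_rows == 2
        assert t.point_count == 7

    def test_needs_one_row(self):
        with pytest.raises(ValueError):
            LeafSurfaceTrace(np.zeros((0, 3, 3)), np.zeros(3))

    def test_max_width(self):
        t = make_leaf_trace(width=2.0)
        assert t.max_width() == pytest.approx(2.0)

    def test_stem_needs_two_nodes(self):
        with pytest.raises(ValueError):
            StemTrace(np.zeros((1, 3)), np.zeros((1, 3, 3)))


class TestLeafMesh:
    def test_counts_two_rows(self):
        mesh = leaf_mesh_from_trace(make_leaf_trace(n_rows=2))
        assert mesh.n_vertices == 7
        assert mesh.n_faces == 6

    def test_counts_one_row(self):
        mesh = leaf_mesh_from_trace(make_leaf_trace(n_rows=1))
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 2

    @pytest.mark.parametrize("n_rows", [1, 3, 10, 50])
    def test_count_formula(self, n_rows):
        mesh = leaf_mesh_from_trace(make_leaf_trace(n_rows=n_rows))
        assert mesh.n_vertices == 3 * n_rows + 1
        assert mesh.n_faces == 4 * (n_rows - 1) + 2
        assert set(np.unique(mesh.faces)) == set(range(mesh.n_vertices))

    def test_flat_leaf_area_matches_shoelace(self):
        # 5 rows spanning a planar 10 x 2 cm leaf with a triangular tip
        n_rows, length, width = 5, 10.0, 2.0
        xs = np.linspace(0.0, 8.0, n_rows)
        rows = np.stack(
            [
                np.column_stack([xs, np.full(n_rows, 1.0), np.zeros(n_rows)]),
                np.column_stack([xs, np.zeros(n_rows), np.zeros(n_rows)]),
                np.column_stack([xs, np.full(n_rows, -1.0), np.zeros(n_rows)]),
            ],
            axis=1,
        )
        trace = LeafSurfaceTrace(rows, np.array([length, 0.0, 0.0]))
        mesh = leaf_mesh_from_trace(trace)
        # shoelace oracle on the planar outline
        outline = (
            [(x, 1.0) for x in xs] + [(length, 0.0)] + [(x, -1.0) for x in xs[::-1]]
        )
        poly = np.array(outline)
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert mesh.area() == pytest.approx(shoelace, rel=1e-6)

    def test_degenerate_rows_error(self):
        rows = np.zeros((2, 3, 3))
        rows[1] = 1.0  # every point in each row coincides
        with pytest.raises(GeometryError):
            leaf_mesh_from_trace(LeafSurfaceTrace(rows, np.array([2.0, 2.0, 2.0])))

    def test_rigid_motion_equivariance(self, rng):
        trace = make_leaf_trace(n_rows=6)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3)
        moved = LeafSurfaceTrace(trace.rows @ rot.T + t, trace.tip @ rot.T + t)
        m1 = leaf_mesh_from_trace(trace).transformed(rot, t)
        m2 = leaf_mesh_from_trace(moved)
        np.testing.assert_allclose(m1.vertices, m2.vertices, atol=1e-12)
        np.testing.assert_array_equal(m1.faces, m2.faces)
        assert m2.area() == pytest.approx(leaf_mesh_from_trace(trace).area(), rel=1e-9)


class TestNodeDiameter:
    def test_equilateral(self):
        s = 1.0
        g = np.array(
            [[0.0, 0.0, 0.0], [s, 0.0, 0.0], [s / 2, s * math.sqrt(3) / 2, 0.0]]
        )
        assert node_diameter(g) == pytest.approx(2.0 / math.sqrt(3))

    def test_points_on_circle(self):
        r = 1.5
        ang = np.radians([10.0, 140.0, 260.0])
        g = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(3, 2.0)])
        assert node_diameter(g) == pytest.approx(3.0)

    def test_tilted_plane(self):
        r = 2.0
        ang = np.radians([0.0, 120.0, 240.0])
        flat = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)])
        rot = Rotation.from_euler("xy", [30, 40], degrees=True).as_matrix()
        assert node_diameter(flat @ rot.T + 5.0) == pytest.approx(4.0)

    def test_collinear_errors(self):
        with pytest.raises(GeometryError):
            node_diameter(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float))


class TestInternodeLengths:
    def test_axis_aligned(self):
        nodes = np.array([[0, 0, 0], [0, 0, 10], [0, 0, 18]], dtype=float)
        girths = np.stack([_girth_at(n) for n in nodes])
        np.testing.assert_allclose(internode_lengths(StemTrace(nodes, girths)), [10, 8])

    def test_345_triangle(self):
        nodes = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        girths = np.stack([_girth_at(n) for n in nodes])
        np.testing.assert_allclose(internode_lengths(StemTrace(nodes, girths)), [5])

    def test_random_matches_pairwise_oracle(self, rng):
        nodes = rng.normal(size=(6, 3)) * 5
        girths = np.stack([_girth_at(n) for n in nodes])
        got = internode_lengths(StemTrace(nodes, girths))
        expected = [np.sqrt(((nodes[i + 1] - nodes[i]) ** 2).sum()) for i in range(5)]
        np.testing.assert_allclose(got, expected, atol=1e-12)


def _girth_at(center):
    offsets = np.array([[0.2, 0, 0], [-0.1, 0.17, 0], [-0.1, -0.17, 0]])
    return center + offsets


class TestSerialization:
    def test_roundtrip_identity(self, tmp_path, small_config):
        plant, _ = generate_shoot(small_config)
        path = write_digitized_plant(plant, tmp_path / "plant.csv")
        back = read_digitized_plant(path)
        assert back.plant == plant.plant
        assert len(back.tillers) == len(plant.tillers)
        for t1, t2 in zip(plant.tillers, back.tillers):
            np.testing.assert_allclose(t1.stem.node_points, t2.stem.node_points, atol=1e-9)
            np.testing.assert_allclose(t1.stem.girths, t2.stem.girths, atol=1e-9)
            for p1, p2 in zip(t1.phytomers, t2.phytomers):
                assert p1.rank == p2.rank
                np.testing.assert_allclose(p1.surface.rows, p2.surface.rows, atol=1e-9)
                np.testing.assert_allclose(p1.vein.points, p2.vein.points, atol=1e-9)
                assert (p1.ear is None) == (p2.ear is None)

    def test_missing_tip_errors(self, tmp_path):
        rows = []
        for r in range(2):
            for role in ("left", "vein", "right"):
                rows.append([1, 1, "leaf", r, role, float(r), 0.0, 0.0])
        rows += _stem_rows()
        rows += _vein_rows()
        path = tmp_path / "bad.csv"
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        with pytest.raises(DigitizerFormatError, match="tip"):
            read_digitized_plant(path)

    def test_bad_point_count_errors(self, tmp_path):
        rows = []
        for r in range(2):
            for role in ("left", "vein", "right"):
                rows.append([1, 1, "leaf", r, role, float(r), 0.0, 0.0])
        rows.append([1, 1, "leaf", 2, "left", 2.0, 0.0, 0.0])
        rows.append([1, 1, "leaf", 3, "tip", 3.0, 0.0, 0.0])
        rows += _stem_rows()
        rows += _vein_rows()
        path = tmp_path / "bad.csv"
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        with pytest.raises(DigitizerFormatError, match="3n\\+1"):
            read_digitized_plant(path)

    def test_non_monotone_rows_error(self, tmp_path):
        rows = []
        order = [1.5, 0.5]  # second surface row sits closer to the base
        for r, x in enumerate(order):
            rows.append([1, 1, "leaf", r, "left", x, 0.3, 0.0])
            rows.append([1, 1, "leaf", r, "vein", x, 0.0, 0.0])
            rows.append([1, 1, "leaf", r, "right", x, -0.3, 0.0])
        rows.append([1, 1, "leaf", 2, "tip", 3.0, 0.0, 0.0])
        rows += _stem_rows()
        rows += _vein_rows()
        path = tmp_path / "bad.csv"
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        with pytest.raises(DigitizerFormatError, match="ordered"):
            read_digitized_plant(path)

    def test_to_shoot_structure(self, small_config):
        plant, _ = generate_shoot(small_config)
        shoot = to_shoot(plant)
        assert shoot.n_tillers == small_config.tillers
        for stem in shoot.stems:
            assert stem.n_phytomers == small_config.phytomers
            assert stem.phytomers[-1].appendage is not None


def _stem_rows():
    rows = []
    for nid, z in enumerate([0.0, 10.0], start=1):
        rows.append([1, nid, "stem", 0, "node", 0.0, 0.0, z])
        for gi, (dx, dy) in enumerate([(0.2, 0.0), (-0.1, 0.17), (-0.1, -0.17)], start=1):
            rows.append([1, nid, "stem", 0, f"girth{gi}", dx, dy, z])
    return rows


def _vein_rows():
    return [[1, 1, "vein", i, "vein", float(i), 0.0, 0.0] for i in range(4)]


class TestObj:
    def test_roundtrip(self, tmp_path):
        m1 = leaf_mesh_from_trace(make_leaf_trace(n_rows=3))
        m2 = leaf_mesh_from_trace(make_leaf_trace(n_rows=2, base=(5, 5, 5)))
        path = write_obj(tmp_path / "out.obj", [("a", m1), ("b", m2)])
        back = read_obj(path)
        assert set(back) == {"a", "b"}
        np.testing.assert_allclose(back["a"].vertices, m1.vertices, atol=1e-8)
        np.testing.assert_array_equal(back["b"].faces, m2.faces)
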