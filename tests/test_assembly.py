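import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phytomer3d.assembly import (
    AssembledShoot,
    PhytomerPlacement,
    RigidTransform,
    ShootSpec,
    TillerSpec,
    apply_transform,
    assemble_shoot,
    assemble_tiller,
    rotation_about_vertical,
    select_template_by_similarity,
    transform_shoot,
)
from phytomer3d.core import azimuth_of, normalize_phytomer
from phytomer3d.errors import InvalidCountError, SimilarityWarning, TemplateLookupError
from phytomer3d.traits import stem_vertical_angle

from conftest import make_phytomer


def _template(internode_len=10.0, leaf_angle=35.0, ear_len=0.0):
    return normalize_phytomer(
        make_phytomer(internode_len=internode_len, leaf_angle=leaf_angle, ear_len=ear_len)
    )


class TestRigidTransform:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_rejects_reflection(self):
        m = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(m, np.zeros(3))

    def test_zero_rotation_is_identity(self):
        t = rotation_about_vertical(0.0)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-15)
        np.testing.assert_allclose(t.translation, 0.0)

    def test_quarter_turn(self):
        t = rotation_about_vertical(90.0)
        np.testing.assert_allclose(t.apply(np.array([1.0, 0.0, 0.0])), [0.0, 1.0, 0.0], atol=1e-12)

    def test_full_turn_identity(self):
        t = rotation_about_vertical(360.0)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_compose_matches_sequential_application(self, rng):
        a = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        b = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        pts = rng.normal(size=(7, 3))
        np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)

    def test_inverse(self, rng):
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)

    def test_from_dict_angles(self):
        t = RigidTransform.from_dict({"azimuth_deg": 90.0, "translation": [1.0, 0.0, 0.0]})
        np.testing.assert_allclose(t.apply(np.array([1.0, 0.0, 0.0])), [1.0, 1.0, 0.0], atol=1e-12)


class TestApplyTransform:
    def test_identity(self):
        mesh = make_phytomer().leaf.mesh
        out = apply_transform(mesh, RigidTransform.identity())
        np.testing.assert_allclose(out.vertices, mesh.vertices)

    def test_translation_shifts_z(self):
        mesh = make_phytomer().leaf.mesh
        out = apply_transform(mesh, RigidTransform.translate([0.0, 0.0, 10.0]))
        np.testing.assert_allclose(out.vertices[:, 2], mesh.vertices[:, 2] + 10.0)
        np.testing.assert_allclose(out.vertices[:, :2], mesh.vertices[:, :2])

    def test_preserves_pairwise_distances(self, rng):
        mesh = make_phytomer().leaf.mesh
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 10)
        out = apply_transform(mesh, t)
        d0 = np.linalg.norm(mesh.vertices[:, None] - mesh.vertices[None], axis=-1)
        d1 = np.linalg.norm(out.vertices[:, None] - out.vertices[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestAssembleTiller:
    def test_single_identity(self):
        tpl = _template()
        spec = TillerSpec(plant=1, tiller=1, placements=[PhytomerPlacement(template="t")])
        stem = assemble_tiller(spec, {"t": tpl})
        np.testing.assert_allclose(
            stem.phytomers[0].internode.skeleton.points, tpl.internode.skeleton.points, atol=1e-12
        )

    def test_stacked_heights(self):
        db = {"a": _template(internode_len=10.0), "b": _template(internode_len=8.0)}
        spec = TillerSpec(
            plant=1,
            tiller=1,
            placements=[PhytomerPlacement(template="a"), PhytomerPlacement(template="b")],
        )
        stem = assemble_tiller(spec, db)
        assert stem.phytomers[1].internode.skeleton.base[2] == pytest.approx(10.0, abs=1e-9)
        assert stem.top_z() == pytest.approx(18.0, abs=1e-9)
        gap = np.linalg.norm(
            stem.phytomers[1].internode.skeleton.base - stem.phytomers[0].internode.skeleton.tip
        )
        assert gap < 1e-6

    def test_assembled_azimuths_match_spec(self):
        db = {"t": _template()}
        spec = TillerSpec(
            plant=1,
            tiller=1,
            placements=[PhytomerPlacement(template="t", azimuth=a) for a in (0.0, 120.0, 240.0)],
        )
        stem = assemble_tiller(spec, db)
        for p, expected in zip(stem.phytomers, (0.0, 120.0, 240.0)):
            assert azimuth_of(p) == pytest.approx(expected, abs=1e-6)

    def test_stacked_conserves_total_length(self, rng):
        lengths = rng.uniform(3.0, 20.0, size=5)
        db = {i: _template(internode_len=l) for i, l in enumerate(lengths)}
        spec = TillerSpec(
            plant=1,
            tiller=1,
            placements=[
                PhytomerPlacement(template=i, azimuth=float(rng.uniform(0, 360)))
                for i in range(5)
            ],
        )
        stem = assemble_tiller(spec, db)
        assert stem.top_z() == pytest.approx(lengths.sum(), abs=1e-6)

    def test_provenance_labels(self):
        db = {"t": _template()}
        spec = TillerSpec(
            plant=2, tiller=3, placements=[PhytomerPlacement(template="t")] * 2
        )
        stem = assemble_tiller(spec, db)
        assert [(p.id.plant, p.id.tiller, p.id.rank) for p in stem.phytomers] == [
            (2, 3, 1),
            (2, 3, 2),
        ]

    def test_unresolvable_template(self):
        spec = TillerSpec(plant=1, tiller=1, placements=[PhytomerPlacement(template="nope")])
        with pytest.raises(TemplateLookupError):
            assemble_tiller(spec, {})

    def test_empty_spec_invalid(self):
        with pytest.raises(InvalidCountError):
            TillerSpec(plant=1, tiller=1, placements=[])

    def test_decreasing_explicit_heights_invalid(self):
        with pytest.raises(ValueError):
            TillerSpec(
                plant=1,
                tiller=1,
                placements=[
                    PhytomerPlacement(template="t", height=10.0),
                    PhytomerPlacement(template="t", height=5.0),
                ],
            )


class TestAssembleShoot:
    def _spec(self, m, db_key="t"):
        tillers = []
        for j in range(1, m + 1):
            ts = TillerSpec(
                plant=1, tiller=j, placements=[PhytomerPlacement(template=db_key)] * 2
            )
            tillers.append((ts, RigidTransform.about_z(360.0 * (j - 1) / m)))
        return ShootSpec(plant=1, tillers=tillers)

    def test_single_identity_equals_tiller(self):
        db = {"t": _template()}
        ts = TillerSpec(plant=1, tiller=1, placements=[PhytomerPlacement(template="t")])
        shoot = assemble_shoot(ShootSpec(plant=1, tillers=[(ts, RigidTransform.identity())]), db)
        stem = assemble_tiller(ts, db)
        np.testing.assert_allclose(
            shoot.stems[0].phytomers[0].leaf.mesh.vertices,
            stem.phytomers[0].leaf.mesh.vertices,
            atol=1e-12,
        )

    def test_eight_tillers(self):
        shoot = assemble_shoot(self._spec(8), {"t": _template()})
        assert shoot.n_tillers == 8
        assert sorted(s.tiller for s in shoot.stems) == list(range(1, 9))

    def test_whole_shoot_rotation_preserves_theta_s(self):
        db = {"t": _template(ear_len=4.0)}
        lean = RigidTransform.from_dict({"lean_deg": 20.0})
        ts = TillerSpec(plant=1, tiller=1, placements=[PhytomerPlacement(template="t")] * 3)
        shoot = assemble_shoot(ShootSpec(plant=1, tillers=[(ts, lean)]), db)
        before = [stem_vertical_angle(s) for s in shoot.stems]
        rotated = transform_shoot(shoot, RigidTransform.about_z(37.0))
        after = [stem_vertical_angle(s) for s in rotated.stems]
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_empty_shoot_invalid(self):
        with pytest.raises(InvalidCountError):
            ShootSpec(plant=1, tillers=[])

    def test_assemble_then_transform_equals_transform_each(self, rng):
        db = {"t": _template()}
        spec = self._spec(3)
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        whole = transform_shoot(assemble_shoot(spec, db), t)
        spec2 = ShootSpec(
            plant=1, tillers=[(ts, t.compose(rt)) for ts, rt in spec.tillers]
        )
        parts = assemble_shoot(spec2, db)
        np.testing.assert_allclose(whole.all_vertices(), parts.all_vertices(), atol=1e-9)


class TestSimilarity:
    def test_exact_match(self):
        db = {
            "a": _template(internode_len=5.0, leaf_angle=30.0),
            "b": _template(internode_len=12.0, leaf_angle=60.0),
        }
        from phytomer3d.core import morph_params

        query = morph_params(db["b"])
        assert select_template_by_similarity(query, db) == "b"

    def test_tie_breaks_to_first(self):
        tpl = _template(internode_len=7.0)
        db = {"first": tpl, "second": tpl, "other": _template(internode_len=20.0)}
        query = {"L_internode": 7.0}
        with pytest.warns(SimilarityWarning):
            # theta/width params identical across templates get dropped if queried
            select_template_by_similarity({"L_internode": 7.0, "L_leaf": 8.0}, db)
        assert select_template_by_similarity(query, db) == "first"

    def test_empty_db(self):
        with pytest.raises(TemplateLookupError):
            select_template_by_similarity({"L_internode": 1.0}, {})

    def test_matches_brute_force(self, rng):
        from phytomer3d.core import morph_params

        db = {
            i: _template(
                internode_len=float(rng.uniform(3, 20)), leaf_angle=float(rng.uniform(10, 80))
            )
            for i in range(20)
        }
        params = {i: morph_params(p) for i, p in db.items()}
        keys = ["L_internode", "theta_leaf"]
        mat = np.array([[params[i][k] for k in keys] for i in range(20)])
        mean, std = mat.mean(axis=0), mat.std(axis=0)
        for _ in range(10):
            query = {
                "L_internode": float(rng.uniform(3, 20)),
                "theta_leaf": float(rng.uniform(10, 80)),
            }
            q = np.array([query[k] for k in keys])
            dist = np.linalg.norm((mat - mean) / std - (q - mean) / std, axis=1)
            assert select_template_by_similarity(query, db) == int(np.argmin(dist))
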