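"""Rigid-transform assembly of phytomer templates into tillers and shoots.

A tiller is the union of its phytomers, each placed by a vertical-axis
rotation (the phytomer azimuth) followed by a vertical translation (the
phytomer base height); a shoot is the union of its tillers, each mapped by
a general rigid transform.  Every assembled component keeps its
(plant, tiller, rank, organ) provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    MeshModel,
    Phytomer,
    PhytomerId,
    SkeletonModel,
)
from .errors import InvalidCountError, SimilarityWarning, TemplateLookupError

__all__ = [
    "RigidTransform",
    "PhytomerPlacement",
    "TillerSpec",
    "ShootSpec",
    "AssembledStem",
    "AssembledShoot",
    "rotation_about_vertical",
    "apply_transform",
    "transform_phytomer",
    "transform_stem",
    "transform_shoot",
    "assemble_tiller",
    "assemble_shoot",
    "select_template_by_similarity",
]

STACKED = "stacked"


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (3x3, proper orthonormal) plus translation (cm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation matrix must have det = +1 (no reflections)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_z(cls, degrees: float) -> "RigidTransform":
        return cls(Rotation.from_euler("z", degrees, degrees=True).as_matrix(), np.zeros(3))

    @classmethod
    def translate(cls, offset: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(offset, dtype=float))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RigidTransform":
        """Build from an explicit matrix or the convenience angles form.

        Accepted keys: ``rotation`` (3x3) / ``translation``, or any of
        ``azimuth_deg`` (spin about z), ``lean_deg`` + ``lean_azimuth_deg``
        (tilt away from vertical), plus ``translation``.
        """
        if "rotation" in d:
            return cls(np.asarray(d["rotation"], float), np.asarray(d.get("translation", [0, 0, 0]), float))
        rot = np.eye(3)
        lean = float(d.get("lean_deg", 0.0))
        if lean:
            lean_az = np.radians(float(d.get("lean_azimuth_deg", 0.0)))
            axis = np.array([-np.sin(lean_az), np.cos(lean_az), 0.0])
            rot = Rotation.from_rotvec(axis * np.radians(lean)).as_matrix() @ rot
        az = float(d.get("azimuth_deg", 0.0))
        if az:
            rot = Rotation.from_euler("z", az, degrees=True).as_matrix() @ rot
        return cls(rot, np.asarray(d.get("translation", [0.0, 0.0, 0.0]), float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation, self.rotation @ other.translation + self.translation
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rotation_about_vertical(alpha: float) -> RigidTransform:
    """CCW rotation about +z by ``alpha`` degrees, zero translation."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return RigidTransform.about_z(alpha)


def apply_transform(m: MeshModel, t: RigidTransform) -> MeshModel:
    return m.transformed(t.rotation, t.translation)


def transform_phytomer(p: Phytomer, t: RigidTransform) -> Phytomer:
    return p.transformed(t.rotation, t.translation)


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PhytomerPlacement:
    template: Union[str, int]
    azimuth: float = 0.0
    height: Union[float, str] = STACKED  # explicit base height (cm) or "stacked"

    def __post_init__(self) -> None:
        if isinstance(self.height, str) and self.height != STACKED:
            raise ValueError(f"height must be a number or '{STACKED}'")


@dataclass
class TillerSpec:
    plant: int
    tiller: int
    placements: list[PhytomerPlacement]

    def __post_init__(self) -> None:
        if len(self.placements) < 1:
            raise InvalidCountError("a tiller spec needs at least one phytomer")
        explicit = [p.height for p in self.placements if not isinstance(p.height, str)]
        if any(b < a for a, b in zip(explicit, explicit[1:])):
            raise ValueError("explicit base heights must be non-decreasing")


@dataclass
class ShootSpec:
    plant: int
    tillers: list[tuple[TillerSpec, RigidTransform]]

    def __post_init__(self) -> None:
        if len(self.tillers) < 1:
            raise InvalidCountError("a shoot spec needs at least one tiller")


# --------------------------------------------------------------------------
# assembled geometry


@dataclass
class AssembledStem:
    """One assembled tiller: phytomers in world coordinates, base to top."""

    plant: int
    tiller: int
    phytomers: list[Phytomer]

    def __post_init__(self) -> None:
        if not self.phytomers:
            raise InvalidCountError("an assembled stem needs at least one phytomer")
        self.phytomers = sorted(self.phytomers, key=lambda p: p.id.rank)

    @property
    def n_phytomers(self) -> int:
        return len(self.phytomers)

    def node_points(self) -> np.ndarray:
        """Stem node polyline: internode bases plus the top node."""
        pts = [p.internode.skeleton.base for p in self.phytomers]
        pts.append(self.phytomers[-1].internode.skeleton.tip)
        return np.array(pts)

    def stem_vector(self) -> np.ndarray:
        nodes = self.node_points()
        return nodes[-1] - nodes[0]

    def internode_lengths(self) -> np.ndarray:
        return np.array([p.internode_length() for p in self.phytomers])

    def top_z(self) -> float:
        return float(self.phytomers[-1].internode.skeleton.tip[2])


@dataclass
class AssembledShoot:
    plant: int
    stems: list[AssembledStem]

    def __post_init__(self) -> None:
        if not self.stems:
            raise InvalidCountError("an assembled shoot needs at least one tiller")

    @property
    def n_tillers(self) -> int:
        return len(self.stems)

    def iter_components(self) -> Iterator[tuple[int, int, str, Phytomer, Any]]:
        """Yield (tiller, rank, organ, phytomer, component) with provenance."""
        for stem in self.stems:
            for p in stem.phytomers:
                for organ, comp in p.components():
                    yield stem.tiller, p.id.rank, organ, p, comp

    def labeled_vertices(self) -> Iterator[tuple[int, int, str, np.ndarray]]:
        """Yield (tiller, rank, organ, points) for every mesh and skeleton."""
        for tiller, rank, organ, _p, comp in self.iter_components():
            if comp.mesh is not None:
                yield tiller, rank, organ, comp.mesh.vertices
            if comp.skeleton is not None:
                yield tiller, rank, organ, comp.skeleton.points

    def all_vertices(self) -> np.ndarray:
        chunks = [pts for _, _, _, pts in self.labeled_vertices()]
        return np.vstack(chunks)


def transform_stem(stem: AssembledStem, t: RigidTransform) -> AssembledStem:
    return AssembledStem(
        plant=stem.plant,
        tiller=stem.tiller,
        phytomers=[transform_phytomer(p, t) for p in stem.phytomers],
    )


def transform_shoot(shoot: AssembledShoot, t: RigidTransform) -> AssembledShoot:
    return AssembledShoot(plant=shoot.plant, stems=[transform_stem(s, t) for s in shoot.stems])


# --------------------------------------------------------------------------
# assembly


def _resolve(db: Any, ref: Union[str, int]) -> Phytomer:
    if hasattr(db, "load"):
        try:
            return db.load(ref)
        except KeyError as exc:  # normalize error type
            raise TemplateLookupError(f"template {ref!r} not found") from exc
    try:
        return db[ref]
    except (KeyError, IndexError, TypeError) as exc:
        raise TemplateLookupError(f"template {ref!r} not found") from exc


def assemble_tiller(spec: TillerSpec, db: Any) -> AssembledStem:
    """Place normalized templates along one stem.

    Phytomer k is spun about the vertical axis by its azimuth and raised to
    its base height; in stacked mode (the default) base heights are the
    cumulative internode lengths of the phytomers below, so consecutive
    phytomers meet node to node.
    """
    placed = []
    height = 0.0
    for idx, placement in enumerate(spec.placements):
        template = _resolve(db, placement.template)
        h = height if isinstance(placement.height, str) else float(placement.height)
        t = RigidTransform.translate([0.0, 0.0, h]).compose(
            rotation_about_vertical(placement.azimuth)
        )
        moved = transform_phytomer(template, t)
        rank = idx + 1
        moved.id = PhytomerId(spec.plant, spec.tiller, rank)
        placed.append(moved)
        height = h + template.internode_length()
    return AssembledStem(plant=spec.plant, tiller=spec.tiller, phytomers=placed)


def assemble_shoot(spec: ShootSpec, db: Any) -> AssembledShoot:
    """Assemble each tiller, then map it by its rigid transform."""
    stems = [transform_stem(assemble_tiller(ts, db), t) for ts, t in spec.tillers]
    return AssembledShoot(plant=spec.plant, stems=stems)


# --------------------------------------------------------------------------
# template selection


def select_template_by_similarity(query: Mapping[str, float], db: Any) -> Union[str, int]:
    """Nearest template under z-scored Euclidean distance on shared parameters.

    Parameters present in the query but not in every template are ignored;
    zero-variance parameters are dropped with a warning.  Exact ties break
    toward the earlier database entry.
    """
    if hasattr(db, "records"):
        items = [(rec.id, rec.params) for rec in db.records()]
    else:
        from .core import morph_params

        items = [(ref, morph_params(p)) for ref, p in db.items()]
    if not items:
        raise TemplateLookupError("template database is empty")
    shared = [k for k in query if all(k in params for _, params in items)]
    if not shared:
        raise ValueError("query and templates share no parameters")
    mat = np.array([[params[k] for k in shared] for _, params in items], dtype=float)
    mean = mat.mean(axis=0)
    std = mat.std(axis=0)
    keep = std > 1e-12
    if not np.all(keep):
        dropped = [k for k, ok in zip(shared, keep) if not ok]
        warnings.warn(
            f"zero-variance parameters dropped from similarity scoring: {dropped}",
            SimilarityWarning,
            stacklevel=2,
        )
    if not np.any(keep):
        # all parameters identical across templates: first entry wins
        return items[0][0]
    q = np.array([float(query[k]) for k in shared])
    zmat = (mat[:, keep] - mean[keep]) / std[keep]
    zq = (q[keep] - mean[keep]) / std[keep]
    dist = np.linalg.norm(zmat - zq, axis=1)
    return items[int(np.argmin(dist))][0]
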