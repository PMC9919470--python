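"""Domain types for 3D phytomers and their canonical normalization.

Conventions used throughout the package:

* right-handed coordinates, z-up, ground plane at ``z = 0``;
* all lengths in centimetres, all angles in degrees;
* azimuths measured counter-clockwise from the +x axis in the XY plane.

A phytomer bundles, per organ (leaf blade, sheath, internode, appendage),
an optional triangle mesh, an optional skeleton polyline and a morphological
parameter set.  The internode component is mandatory: its axis anchors the
canonical (normalized) pose in which templates are stored and reused.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ClassificationWarning, GeometryError, InvalidCountError

__all__ = [
    "Point3",
    "MeshModel",
    "SkeletonModel",
    "LeafParams",
    "SheathParams",
    "InternodeParams",
    "AppendageParams",
    "PhytomerId",
    "PhytomerKind",
    "Component",
    "Phytomer",
    "name_phytomers",
    "classify_phytomer",
    "normalize_phytomer",
    "azimuth_of",
    "morph_params",
]

_EPS = 1e-12


def as_point_array(points: Any, name: str = "points") -> np.ndarray:
    """Coerce to a float64 ``(n, 3)`` array and require finite coordinates."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must have shape (n, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Point3:
    """A single 3D point (cm, z-up)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError("Point3 coordinates must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "Point3":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class MeshModel:
    """Triangle mesh: ``vertices`` (n, 3) float and ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = as_point_array(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) < 1:
            raise ValueError("mesh needs at least one vertex")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            a, b, c = self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]
            if np.any(a == b) or np.any(b == c) or np.any(a == c):
                raise ValueError("face repeats a vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Total surface area (cm^2) as the sum of triangle areas."""
        if not self.faces.size:
            return 0.0
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MeshModel":
        verts = self.vertices @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return MeshModel(verts, self.faces.copy())


@dataclass
class SkeletonModel:
    """Polyline skeleton (leaf vein, sheath mid-axis, internode mid-axis)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = as_point_array(self.points, "skeleton points")
        if len(self.points) < 2:
            raise ValueError("skeleton needs at least two points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= _EPS):
            raise ValueError("consecutive skeleton points must be distinct")

    @property
    def base(self) -> np.ndarray:
        return self.points[0]

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def chord(self) -> np.ndarray:
        return self.tip - self.base

    def chord_length(self) -> float:
        return float(np.linalg.norm(self.chord()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SkeletonModel":
        pts = self.points @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return SkeletonModel(pts)


# --------------------------------------------------------------------------
# morphological parameter sets


@dataclass
class LeafParams:
    H_base: float = 0.0
    L_leaf: float = 1.0
    theta_leaf: float = 0.0
    alpha_leaf: float = 0.0
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L_leaf <= 0:
            raise ValueError("L_leaf must be positive")
        if not 0.0 <= self.theta_leaf <= 180.0:
            raise ValueError("theta_leaf must lie in [0, 180]")
        self.alpha_leaf = float(self.alpha_leaf) % 360.0


@dataclass
class SheathParams:
    H_base: float = 0.0
    L_sheath: float = 0.0
    theta_sheath: float = 0.0
    D_max: float = 0.0
    D_min: float = 0.0

    def __post_init__(self) -> None:
        if self.L_sheath < 0:
            raise ValueError("L_sheath must be non-negative")
        if self.D_min > self.D_max:
            raise ValueError("D_min must not exceed D_max")


@dataclass
class InternodeParams:
    H_base: float = 0.0
    L_internode: float = 1.0
    theta_internode: float = 0.0
    D_max: float = 0.0
    D_min: float = 0.0

    def __post_init__(self) -> None:
        if self.L_internode <= 0:
            raise ValueError("L_internode must be positive")
        if self.D_min > self.D_max:
            raise ValueError("D_min must not exceed D_max")


@dataclass
class AppendageParams:
    D_node_max: float = 0.0
    L_ear: float = 0.0
    D_ear_max: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D_node_max", "L_ear", "D_ear_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PhytomerId:
    """(plant i, tiller j, rank k); rank n is the top (spike-bearing) phytomer."""

    plant: int
    tiller: int
    rank: int

    def __post_init__(self) -> None:
        if self.plant < 1 or self.tiller < 1 or self.rank < 1:
            raise ValueError("plant, tiller and rank must be positive integers")

    def __str__(self) -> str:
        return f"Phytomer{self.plant},{self.tiller},{self.rank}"


class PhytomerKind(str, Enum):
    SPIKE_BEARING = "spike-bearing"
    MIDDLE = "middle"
    BASAL = "basal"


@dataclass
class Component:
    """One organ of a phytomer: optional mesh + skeleton + parameter set."""

    mesh: Optional[MeshModel] = None
    skeleton: Optional[SkeletonModel] = None
    params: Any = None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Component":
        return Component(
            mesh=self.mesh.transformed(rotation, translation) if self.mesh else None,
            skeleton=self.skeleton.transformed(rotation, translation) if self.skeleton else None,
            params=copy.deepcopy(self.params) if self.params is not None else None,
        )


ORGANS = ("leaf", "sheath", "internode", "appendage")


@dataclass
class Phytomer:
    """The phytomer triple (mesh models, skeleton models, parameter sets)."""

    id: PhytomerId
    kind: PhytomerKind
    internode: Component
    leaf: Optional[Component] = None
    sheath: Optional[Component] = None
    appendage: Optional[Component] = None

    def __post_init__(self) -> None:
        if self.internode is None or self.internode.skeleton is None:
            raise ValueError("internode component with a skeleton is mandatory")
        has_ear = (
            self.appendage is not None
            and self.appendage.params is not None
            and self.appendage.params.L_ear > 0
        )
        if (self.kind is PhytomerKind.SPIKE_BEARING) != has_ear:
            raise ValueError("kind is spike-bearing iff the appendage has L_ear > 0")

    def components(self) -> Iterator[tuple[str, Component]]:
        for organ in ORGANS:
            comp = getattr(self, organ)
            if comp is not None:
                yield organ, comp

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Phytomer":
        kwargs = {organ: comp.transformed(rotation, translation) for organ, comp in self.components()}
        return Phytomer(id=self.id, kind=self.kind, **kwargs)

    def internode_axis(self) -> np.ndarray:
        """Chord of the internode skeleton (base to top node)."""
        return self.internode.skeleton.chord()

    def internode_length(self) -> float:
        return self.internode.skeleton.chord_length()


# --------------------------------------------------------------------------
# operations


def name_phytomers(plant_i: int, tiller_j: int, n: int) -> list[PhytomerId]:
    """Name the ``n`` phytomers of one stem top-down: ranks n, n-1, ..., 1."""
    if n < 1:
        raise InvalidCountError(f"a stem must carry at least one phytomer, got n={n}")
    return [PhytomerId(plant_i, tiller_j, k) for k in range(n, 0, -1)]


def classify_phytomer(rank_k: int, n: int, has_ear: bool) -> PhytomerKind:
    """Classify rank ``k`` of an ``n``-phytomer stem.

    The top phytomer bearing an ear is spike-bearing, the bottom phytomer is
    basal, everything else is middle.  A top phytomer without an ear
    (vegetative tiller) is classified middle with a warning.
    """
    if not 1 <= rank_k <= n:
        raise InvalidCountError(f"rank {rank_k} outside [1, {n}]")
    if rank_k == n and has_ear:
        return PhytomerKind.SPIKE_BEARING
    if rank_k == n and not has_ear:
        warnings.warn(
            f"top phytomer (rank {rank_k}) has no ear; classified as "
            f"{'basal' if rank_k == 1 else 'middle'}",
            ClassificationWarning,
            stacklevel=2,
        )
    if rank_k == 1:
        return PhytomerKind.BASAL
    return PhytomerKind.MIDDLE


def _polyline_azimuth(points: np.ndarray) -> float:
    """Azimuth (deg, CCW from +x) of the first non-vertical polyline segment."""
    diffs = np.diff(points, axis=0)
    for d in diffs:
        if math.hypot(d[0], d[1]) > 1e-9:
            az = float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)
            return 0.0 if az >= 360.0 - 1e-9 else az
    raise GeometryError("polyline has no segment with a non-zero XY projection")


def azimuth_of(p: Phytomer) -> float:
    """Phytomer azimuth: XY direction of the leaf vein leaving the stem."""
    if p.leaf is None or p.leaf.skeleton is None:
        raise GeometryError("azimuth requires a leaf vein skeleton")
    return _polyline_azimuth(p.leaf.skeleton.points)


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking the unit vector ``axis`` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(axis, z)
    norm = np.linalg.norm(cross)
    dot = float(np.dot(axis, z))
    if norm < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about x
        return Rotation.from_rotvec([math.pi, 0.0, 0.0]).as_matrix()
    angle = math.atan2(norm, dot)
    return Rotation.from_rotvec(cross / norm * angle).as_matrix()


def _rot_z(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def normalize_phytomer(p: Phytomer) -> Phytomer:
    """Move a phytomer into its canonical template pose.

    Canonical pose: internode base at the origin, internode axis along +z,
    leaf azimuth zero.  A single rigid motion (translate, tilt-to-vertical,
    spin about z) is applied to every mesh and skeleton; stored heights and
    azimuths are updated accordingly.  Idempotent.
    """
    sk = p.internode.skeleton
    base = sk.base
    axis = sk.chord()
    norm = float(np.linalg.norm(axis))
    if norm < 1e-9:
        raise GeometryError("internode axis has zero length")
    r1 = _rotation_to_z(axis / norm)
    moved = p.transformed(r1, -r1 @ base)
    if moved.leaf is not None and moved.leaf.skeleton is not None:
        alpha = azimuth_of(moved)
        moved = moved.transformed(_rot_z(-alpha), np.zeros(3))

    # keep stored parameters consistent with the canonical pose
    if moved.internode.params is not None:
        moved.internode.params.H_base = 0.0
    for organ in ("leaf", "sheath"):
        comp = getattr(moved, organ)
        if comp is not None and comp.params is not None:
            comp.params.H_base = float(comp.skeleton.base[2]) if comp.skeleton is not None else 0.0
    if moved.leaf is not None and moved.leaf.params is not None:
        moved.leaf.params.alpha_leaf = 0.0
    return moved


def morph_params(p: Phytomer) -> dict[str, float]:
    """Flatten the numeric morphological parameters for similarity queries."""
    out: dict[str, float] = {}
    if p.leaf is not None and p.leaf.params is not None:
        lp = p.leaf.params
        out.update({"L_leaf": lp.L_leaf, "theta_leaf": lp.theta_leaf})
        for key, val in lp.extras.items():
            if isinstance(val, (int, float)):
                out[f"leaf_{key}"] = float(val)
    if p.sheath is not None and p.sheath.params is not None:
        sp = p.sheath.params
        out.update({"L_sheath": sp.L_sheath, "D_sheath_max": sp.D_max, "D_sheath_min": sp.D_min})
    if p.internode.params is not None:
        ip = p.internode.params
        out.update(
            {
                "L_internode": ip.L_internode,
                "D_internode_max": ip.D_max,
                "D_internode_min": ip.D_min,
            }
        )
    else:
        out["L_internode"] = p.internode_length()
    if p.appendage is not None and p.appendage.params is not None:
        ap = p.appendage.params
        out.update({"L_ear": ap.L_ear, "D_ear_max": ap.D_ear_max, "D_node_max": ap.D_node_max})
    return out
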