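import math

import numpy as np
import pytest

from phytomer3d.assembly import AssembledShoot, AssembledStem
from phytomer3d.core import (
    AppendageParams,
    Component,
    InternodeParams,
    LeafParams,
    MeshModel,
    Phytomer,
    PhytomerId,
    PhytomerKind,
    SkeletonModel,
)
from phytomer3d.digitizer import LeafSurfaceTrace, leaf_mesh_from_trace
from phytomer3d.synthetic import SyntheticPlantConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_leaf_trace(
    base=(0.0, 0.0, 10.0),
    direction=(1.0, 0.0, 0.0),
    length=8.0,
    width=2.0,
    n_rows=4,
):
    """Straight flat leaf along ``direction`` with constant width."""
    base = np.asarray(base, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    side = np.cross(np.array([0.0, 0.0, 1.0]), d)
    if np.linalg.norm(side) < 1e-9:
        side = np.array([0.0, 1.0, 0.0])
    side = side / np.linalg.norm(side)
    s = np.linspace(0.0, length * (n_rows / (n_rows + 1.0)), n_rows + 1)[1:]
    centers = base + s[:, None] * d
    rows = np.stack(
        [centers + 0.5 * width * side, centers, centers - 0.5 * width * side], axis=1
    )
    tip = base + length * d
    return LeafSurfaceTrace(rows, tip)


def make_phytomer(
    plant=1,
    tiller=1,
    rank=1,
    base=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    internode_len=10.0,
    leaf_azimuth=0.0,
    leaf_angle=40.0,
    leaf_len=8.0,
    leaf_width=2.0,
    ear_len=0.0,
    ear_diam=1.0,
    kind=None,
):
    """Straight-organ phytomer: vertical-ish internode, straight planar leaf."""
    base = np.asarray(base, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    top = base + internode_len * axis
    internode = Component(
        skeleton=SkeletonModel(np.array([base, top])),
        params=InternodeParams(H_base=float(base[2]), L_internode=internode_len, D_max=0.5, D_min=0.4),
    )
    az = math.radians(leaf_azimuth)
    horiz = np.array([math.cos(az), math.sin(az), 0.0])
    horiz = horiz - np.dot(horiz, axis) * axis
    if np.linalg.norm(horiz) < 1e-9:
        horiz = np.array([1.0, 0.0, 0.0])
    horiz = horiz / np.linalg.norm(horiz)
    ang = math.radians(leaf_angle)
    leaf_dir = math.cos(ang) * axis + math.sin(ang) * horiz
    n_vein = 6
    vein_pts = top + np.linspace(0.0, leaf_len, n_vein)[:, None] * leaf_dir
    trace = make_leaf_trace(base=top, direction=leaf_dir, length=leaf_len, width=leaf_width)
    leaf = Component(
        mesh=leaf_mesh_from_trace(trace),
        skeleton=SkeletonModel(vein_pts),
        params=LeafParams(
            H_base=float(top[2]),
            L_leaf=leaf_len,
            theta_leaf=leaf_angle,
            alpha_leaf=leaf_azimuth,
            extras={"max_width": leaf_width},
        ),
    )
    appendage = None
    if ear_len > 0:
        from phytomer3d.digitizer import EarTrace, _ear_mesh

        ear_pts = top + np.linspace(0.0, ear_len, 5)[:, None] * axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, axis) * axis
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        mid = top + 0.5 * ear_len * axis
        ring = mid + 0.5 * ear_diam * np.array([e1, e2, -e1, -e2])
        ear_trace = EarTrace(ear_pts, ring)
        appendage = Component(
            mesh=_ear_mesh(ear_trace),
            skeleton=SkeletonModel(ear_pts),
            params=AppendageParams(D_node_max=0.5, L_ear=ear_len, D_ear_max=ear_diam),
        )
    if kind is None:
        kind = PhytomerKind.SPIKE_BEARING if ear_len > 0 else PhytomerKind.MIDDLE
    return Phytomer(
        id=PhytomerId(plant, tiller, rank),
        kind=kind,
        internode=internode,
        leaf=leaf,
        appendage=appendage,
    )


def make_shoot(n_tillers=1, n_phytomers=2, internode_len=10.0, ear_len=5.0, leaf_angle=90.0):
    """Vertical multi-tiller shoot built from straight phytomers, in situ."""
    stems = []
    for j in range(1, n_tillers + 1):
        phys = []
        for k in range(1, n_phytomers + 1):
            phys.append(
                make_phytomer(
                    tiller=j,
                    rank=k,
                    base=(0.0, 0.0, internode_len * (k - 1)),
                    internode_len=internode_len,
                    leaf_azimuth=360.0 * (j - 1) / n_tillers + 180.0 * (n_phytomers - k),
                    leaf_angle=leaf_angle,
                    ear_len=ear_len if k == n_phytomers else 0.0,
                )
            )
        stems.append(AssembledStem(plant=1, tiller=j, phytomers=phys))
    return AssembledShoot(plant=1, stems=stems)


@pytest.fixture
def small_config():
    return SyntheticPlantConfig(
        tillers=2,
        phytomers=3,
        internode_lengths=(15.0, 12.0, 10.0),
        leaf_arc_length=18.0,
        leaf_arc_angle=1.0,
        leaf_rows=9,
        vein_points=25,
        stem_lean=10.0,
        seed=42,
    )
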