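"""Digitizer trace formats, leaf meshing and stem geometry.

The on-disk dialect is one UTF-8 CSV per plant with the mandatory header::

    tiller,phytomer_rank,organ,row_index,point_role,x,y,z

* ``organ="leaf"``  — leaf surface rows; roles ``left``/``vein``/``right``
  per row plus a single ``tip`` point, so a leaf traced with n rows carries
  3n + 1 points.
* ``organ="vein"``  — vein skeleton polyline, role ``vein``, base to tip.
* ``organ="stem"``  — per node (``phytomer_rank`` = node index, base = 1) a
  ``node`` point plus three ``girth1``..``girth3`` thickness points.
* ``organ="ear"``   — spike polyline (role ``ear``) and optional maximum
  diameter points (role ``ear_diam``) on the top phytomer.

A JSON sidecar ``<name>.json`` stores the plant id and format version.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assembly
from .core import (
    Component,
    LeafParams,
    AppendageParams,
    InternodeParams,
    MeshModel,
    PhytomerId,
    Phytomer,
    SkeletonModel,
    as_point_array,
    classify_phytomer,
    _polyline_azimuth,
)
from .errors import DigitizerFormatError, GeometryError, TipMismatchWarning

__all__ = [
    "LeafSurfaceTrace",
    "VeinTrace",
    "EarTrace",
    "StemTrace",
    "PhytomerTraces",
    "TillerTraces",
    "DigitizedPlant",
    "read_digitized_plant",
    "write_digitized_plant",
    "leaf_mesh_from_trace",
    "node_diameter",
    "internode_lengths",
    "to_shoot",
    "write_obj",
    "read_obj",
]

CSV_COLUMNS = ["tiller", "phytomer_rank", "organ", "row_index", "point_role", "x", "y", "z"]
FORMAT_VERSION = 1

#: surface tip vs vein tip coincidence tolerance (cm); warn above
TIP_TOLERANCE = 0.2


@dataclass
class LeafSurfaceTrace:
    """Leaf surface rows (left edge, vein, right edge) plus the tip point."""

    rows: np.ndarray  # (n_rows, 3, 3): [row, {left, vein, right}, xyz]
    tip: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 3 or self.rows.shape[1:] != (3, 3):
            raise ValueError(f"rows must have shape (n, 3, 3), got {self.rows.shape}")
        if len(self.rows) < 1:
            raise ValueError("a leaf surface trace needs at least one row")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("non-finite leaf surface coordinates")
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def point_count(self) -> int:
        return 3 * self.n_rows + 1

    @property
    def left(self) -> np.ndarray:
        return self.rows[:, 0]

    @property
    def vein(self) -> np.ndarray:
        return self.rows[:, 1]

    @property
    def right(self) -> np.ndarray:
        return self.rows[:, 2]

    def max_width(self) -> float:
        """Maximum leaf width across rows: largest left-to-right distance."""
        return float(np.linalg.norm(self.left - self.right, axis=1).max())


@dataclass
class VeinTrace:
    """Leaf vein skeleton polyline, base to tip."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = as_point_array(self.points, "vein points")
        if len(self.points) < 2:
            raise ValueError("vein trace needs at least two points")

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class EarTrace:
    points: np.ndarray  # spike polyline, base to tip
    diam_points: Optional[np.ndarray] = None  # ring of max-diameter points

    def __post_init__(self) -> None:
        self.points = as_point_array(self.points, "ear points")
        if len(self.points) < 2:
            raise ValueError("ear trace needs at least two points")
        if self.diam_points is not None:
            self.diam_points = as_point_array(self.diam_points, "ear diameter points")

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def max_diameter(self) -> float:
        if self.diam_points is None or len(self.diam_points) < 2:
            return 0.0
        d = self.diam_points
        diff = d[:, None, :] - d[None, :, :]
        return float(np.linalg.norm(diff, axis=-1).max())


@dataclass
class StemTrace:
    """Node points plus girth triples, ordered base to top."""

    node_points: np.ndarray  # (n_nodes, 3)
    girths: np.ndarray  # (n_nodes, 3, 3)

    def __post_init__(self) -> None:
        self.node_points = as_point_array(self.node_points, "node points")
        self.girths = np.asarray(self.girths, dtype=float)
        if self.girths.shape != (len(self.node_points), 3, 3):
            raise ValueError("girths must have shape (n_nodes, 3, 3)")
        if len(self.node_points) < 2:
            raise ValueError("stem trace needs at least two nodes (one internode)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_points)


@dataclass
class PhytomerTraces:
    rank: int
    surface: LeafSurfaceTrace
    vein: VeinTrace
    ear: Optional[EarTrace] = None

    def __post_init__(self) -> None:
        gap = float(np.linalg.norm(self.vein.points[-1] - self.surface.tip))
        if gap > TIP_TOLERANCE:
            warnings.warn(
                f"phytomer rank {self.rank}: vein tip and surface tip differ by "
                f"{gap:.3f} cm (> {TIP_TOLERANCE} cm)",
                TipMismatchWarning,
                stacklevel=2,
            )


@dataclass
class TillerTraces:
    tiller: int
    stem: StemTrace
    phytomers: list[PhytomerTraces] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_internodes = self.stem.n_nodes - 1
        ranks = sorted(p.rank for p in self.phytomers)
        if ranks != list(range(1, n_internodes + 1)):
            raise ValueError(
                f"tiller {self.tiller}: leaf count must equal internode count "
                f"({n_internodes}); got ranks {ranks}"
            )
        self.phytomers = sorted(self.phytomers, key=lambda p: p.rank)

    @property
    def n_phytomers(self) -> int:
        return self.stem.n_nodes - 1


@dataclass
class DigitizedPlant:
    plant: int
    tillers: list[TillerTraces]

    def __post_init__(self) -> None:
        if len(self.tillers) < 1:
            raise ValueError("a digitized plant needs at least one tiller")
        self.tillers = sorted(self.tillers, key=lambda t: t.tiller)


# --------------------------------------------------------------------------
# geometry operations


def leaf_mesh_from_trace(t: LeafSurfaceTrace) -> MeshModel:
    """Triangulate a surface trace: two quads per row pair, a fan at the tip.

    Vertex order is row-major (left, vein, right per row) with the tip last,
    so the mesh has 3*n_rows + 1 vertices and 4*(n_rows - 1) + 2 faces.
    Quads are split along the diagonal toward the tip for consistent winding.
    """
    n = t.n_rows
    vertices = np.vstack([t.rows.reshape(-1, 3), t.tip.reshape(1, 3)])
    tip_idx = 3 * n
    faces: list[tuple[int, int, int]] = []
    for r in range(n - 1):
        l0, v0, r0 = 3 * r, 3 * r + 1, 3 * r + 2
        l1, v1, r1 = 3 * (r + 1), 3 * (r + 1) + 1, 3 * (r + 1) + 2
        faces.extend([(l0, v0, v1), (l0, v1, l1)])  # left quad
        faces.extend([(v0, r0, r1), (v0, r1, v1)])  # right quad
    last = n - 1
    faces.extend([(3 * last, 3 * last + 1, tip_idx), (3 * last + 1, 3 * last + 2, tip_idx)])
    mesh = MeshModel(vertices, np.array(faces, dtype=np.int64))
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    if np.any(areas < 1e-12):
        raise GeometryError("leaf trace produces zero-area triangles (coincident row points)")
    return mesh


def node_diameter(girth: np.ndarray) -> float:
    """Diameter of the circumcircle through three girth points (in their plane)."""
    g = as_point_array(girth, "girth")
    if g.shape != (3, 3):
        raise ValueError("girth must be exactly three points")
    a = float(np.linalg.norm(g[1] - g[2]))
    b = float(np.linalg.norm(g[0] - g[2]))
    c = float(np.linalg.norm(g[0] - g[1]))
    area2 = float(np.linalg.norm(np.cross(g[1] - g[0], g[2] - g[0])))  # 2 * triangle area
    scale = max(a, b, c)
    if scale <= 0 or area2 < 1e-10 * scale * scale:
        raise GeometryError("girth points are collinear; circumcircle undefined")
    return a * b * c / area2


def internode_lengths(s: StemTrace) -> np.ndarray:
    """Euclidean distances between consecutive node points, base to top."""
    return np.linalg.norm(np.diff(s.node_points, axis=0), axis=1)


# --------------------------------------------------------------------------
# CSV dialect


def _leaf_rows(tiller: int, rank: int, surface: LeafSurfaceTrace) -> list[list]:
    rows = []
    for r in range(surface.n_rows):
        for role, pt in zip(("left", "vein", "right"), surface.rows[r]):
            rows.append([tiller, rank, "leaf", r, role, *pt])
    rows.append([tiller, rank, "leaf", surface.n_rows, "tip", *surface.tip])
    return rows


def write_digitized_plant(plant: DigitizedPlant, path: str | Path) -> Path:
    """Serialize a plant to the CSV dialect (plus its JSON sidecar)."""
    path = Path(path)
    records: list[list] = []
    for tt in plant.tillers:
        for node_idx in range(tt.stem.n_nodes):
            records.append([tt.tiller, node_idx + 1, "stem", 0, "node", *tt.stem.node_points[node_idx]])
            for gi in range(3):
                records.append(
                    [tt.tiller, node_idx + 1, "stem", 0, f"girth{gi + 1}", *tt.stem.girths[node_idx, gi]]
                )
        for pt in tt.phytomers:
            records.extend(_leaf_rows(tt.tiller, pt.rank, pt.surface))
            for i, p in enumerate(pt.vein.points):
                records.append([tt.tiller, pt.rank, "vein", i, "vein", *p])
            if pt.ear is not None:
                for i, p in enumerate(pt.ear.points):
                    records.append([tt.tiller, pt.rank, "ear", i, "ear", *p])
                if pt.ear.diam_points is not None:
                    for i, p in enumerate(pt.ear.diam_points):
                        records.append([tt.tiller, pt.rank, "ear", i, "ear_diam", *p])
    df = pd.DataFrame(records, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"plant": plant.plant, "format_version": FORMAT_VERSION}))
    return path


def _arc_positions(polyline: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Arc-length position along ``polyline`` of the closest point to each query."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty(len(queries))
    for qi, q in enumerate(queries):
        best_d, best_s = math.inf, 0.0
        for i in range(len(seg)):
            t = float(np.dot(q - polyline[i], seg[i]) / max(seg_len[i] ** 2, 1e-18))
            t = min(max(t, 0.0), 1.0)
            proj = polyline[i] + t * seg[i]
            d = float(np.linalg.norm(q - proj))
            if d < best_d:
                best_d, best_s = d, cum[i] + t * seg_len[i]
        out[qi] = best_s
    return out


def _parse_leaf(group: pd.DataFrame, tiller: int, rank: int) -> LeafSurfaceTrace:
    where = f"tiller {tiller}, leaf rank {rank}"
    n_pts = len(group)
    tips = group[group.point_role == "tip"]
    if len(tips) != 1:
        raise DigitizerFormatError(f"{where}: expected exactly one tip point, got {len(tips)}")
    if n_pts % 3 != 1:
        raise DigitizerFormatError(
            f"{where}: expected 3n+1 leaf points (rows of left/vein/right plus a tip), got {n_pts}"
        )
    body = group[group.point_role != "tip"]
    n_rows = n_pts // 3
    rows = np.empty((n_rows, 3, 3))
    by_row = dict(tuple(body.groupby("row_index")))
    expected = list(range(n_rows))
    if sorted(by_row) != expected:
        raise DigitizerFormatError(f"{where}: leaf row indices must be 0..{n_rows - 1}")
    for r in expected:
        sub = by_row[r]
        for ci, role in enumerate(("left", "vein", "right")):
            sel = sub[sub.point_role == role]
            if len(sel) != 1:
                raise DigitizerFormatError(f"{where}: row {r} must have one '{role}' point")
            rows[r, ci] = sel[["x", "y", "z"]].to_numpy()[0]
    tip = tips[["x", "y", "z"]].to_numpy()[0]
    return LeafSurfaceTrace(rows, tip)


def read_digitized_plant(path: str | Path) -> DigitizedPlant:
    """Read and validate a plant from the CSV dialect."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DigitizerFormatError(f"{path.name}: missing columns {missing}")
    plant_id = 1
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        plant_id = int(json.loads(sidecar.read_text()).get("plant", 1))

    tillers = []
    for tiller_id, tgroup in df.groupby("tiller"):
        stem_rows = tgroup[tgroup.organ == "stem"]
        if stem_rows.empty:
            raise DigitizerFormatError(f"tiller {tiller_id}: no stem trace")
        node_ids = sorted(stem_rows.phytomer_rank.unique())
        nodes, girths = [], []
        for nid in node_ids:
            sub = stem_rows[stem_rows.phytomer_rank == nid]
            node = sub[sub.point_role == "node"]
            if len(node) != 1:
                raise DigitizerFormatError(f"tiller {tiller_id}, node {nid}: need one node point")
            nodes.append(node[["x", "y", "z"]].to_numpy()[0])
            g = np.array(
                [
                    sub[sub.point_role == f"girth{i}"][["x", "y", "z"]].to_numpy()[0]
                    for i in (1, 2, 3)
                ]
            )
            girths.append(g)
        stem = StemTrace(np.array(nodes), np.array(girths))

        phytomers = []
        leaf_ranks = sorted(tgroup[tgroup.organ == "leaf"].phytomer_rank.unique())
        for rank in leaf_ranks:
            rank = int(rank)
            leaf = tgroup[(tgroup.organ == "leaf") & (tgroup.phytomer_rank == rank)]
            surface = _parse_leaf(leaf, int(tiller_id), rank)
            vein_rows = tgroup[(tgroup.organ == "vein") & (tgroup.phytomer_rank == rank)]
            if len(vein_rows) < 2:
                raise DigitizerFormatError(
                    f"tiller {tiller_id}, leaf rank {rank}: vein trace needs >= 2 points"
                )
            vein = VeinTrace(vein_rows.sort_values("row_index")[["x", "y", "z"]].to_numpy())
            # each surface row's vein point must advance along the vein arc
            pos = _arc_positions(vein.points, surface.vein)
            if surface.n_rows > 1 and np.any(np.diff(pos) <= 0):
                raise DigitizerFormatError(
                    f"tiller {tiller_id}, leaf rank {rank}: surface rows are not ordered "
                    "base to tip along the vein arc"
                )
            ear_rows = tgroup[(tgroup.organ == "ear") & (tgroup.phytomer_rank == rank)]
            ear = None
            if not ear_rows.empty:
                poly = ear_rows[ear_rows.point_role == "ear"].sort_values("row_index")
                diam = ear_rows[ear_rows.point_role == "ear_diam"].sort_values("row_index")
                ear = EarTrace(
                    poly[["x", "y", "z"]].to_numpy(),
                    diam[["x", "y", "z"]].to_numpy() if len(diam) else None,
                )
            phytomers.append(PhytomerTraces(rank=rank, surface=surface, vein=vein, ear=ear))
        tillers.append(TillerTraces(tiller=int(tiller_id), stem=stem, phytomers=phytomers))
    return DigitizedPlant(plant=plant_id, tillers=tillers)


# --------------------------------------------------------------------------
# digitized plant -> assembled (in situ) shoot


def _ear_mesh(ear: EarTrace) -> Optional[MeshModel]:
    """Spindle mesh from the ear polyline and its diameter ring, if any."""
    if ear.diam_points is None or len(ear.diam_points) < 3:
        return None
    base, tip = ear.points[0], ear.points[-1]
    axis = tip - base
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    centroid = ear.diam_points.mean(axis=0)
    rel = ear.diam_points - centroid
    ref = rel[0] / max(np.linalg.norm(rel[0]), 1e-12)
    other = np.cross(axis, ref)
    ang = np.arctan2(rel @ other, rel @ ref)
    order = np.argsort(ang)
    ring = ear.diam_points[order]
    k = len(ring)
    vertices = np.vstack([base.reshape(1, 3), tip.reshape(1, 3), ring])
    faces = []
    for i in range(k):
        a, b = 2 + i, 2 + (i + 1) % k
        faces.append((0, b, a))
        faces.append((1, a, b))
    return MeshModel(vertices, np.array(faces, dtype=np.int64))


def phytomers_from_tiller(plant_id: int, tt: TillerTraces) -> list[Phytomer]:
    """Build in-situ phytomers (world coordinates) from one tiller's traces."""
    n = tt.n_phytomers
    nodes = tt.stem.node_points
    stem_vec = nodes[-1] - nodes[0]
    out = []
    for pt in tt.phytomers:
        k = pt.rank
        has_ear = pt.ear is not None
        kind = classify_phytomer(k, n, has_ear)
        inter_sk = SkeletonModel(np.array([nodes[k - 1], nodes[k]]))
        d_lo = node_diameter(tt.stem.girths[k - 1])
        d_hi = node_diameter(tt.stem.girths[k])
        inter = Component(
            skeleton=inter_sk,
            params=InternodeParams(
                H_base=float(nodes[k - 1][2]),
                L_internode=float(np.linalg.norm(nodes[k] - nodes[k - 1])),
                theta_internode=_angle_from_vertical(nodes[k] - nodes[k - 1]),
                D_max=max(d_lo, d_hi),
                D_min=min(d_lo, d_hi),
            ),
        )
        vein_sk = SkeletonModel(pt.vein.points)
        chord = vein_sk.chord()
        leaf = Component(
            mesh=leaf_mesh_from_trace(pt.surface),
            skeleton=vein_sk,
            params=LeafParams(
                H_base=float(vein_sk.base[2]),
                L_leaf=vein_sk.arc_length(),
                theta_leaf=_vector_angle(stem_vec, chord),
                alpha_leaf=_polyline_azimuth(vein_sk.points),
                extras={"max_width": pt.surface.max_width()},
            ),
        )
        appendage = None
        if pt.ear is not None:
            appendage = Component(
                mesh=_ear_mesh(pt.ear),
                skeleton=SkeletonModel(pt.ear.points),
                params=AppendageParams(
                    D_node_max=d_hi,
                    L_ear=pt.ear.arc_length(),
                    D_ear_max=pt.ear.max_diameter(),
                ),
            )
        out.append(
            Phytomer(
                id=PhytomerId(plant_id, tt.tiller, k),
                kind=kind,
                internode=inter,
                leaf=leaf,
                appendage=appendage,
            )
        )
    return out


def to_shoot(plant: DigitizedPlant) -> "assembly.AssembledShoot":
    """Interpret a digitized plant as an already-assembled shoot."""
    stems = [
        assembly.AssembledStem(
            plant=plant.plant, tiller=tt.tiller, phytomers=phytomers_from_tiller(plant.plant, tt)
        )
        for tt in plant.tillers
    ]
    return assembly.AssembledShoot(plant=plant.plant, stems=stems)


def _vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero vector has no direction")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _angle_from_vertical(v: np.ndarray) -> float:
    return _vector_angle(v, np.array([0.0, 0.0, 1.0]))


# --------------------------------------------------------------------------
# OBJ export/import (ASCII, v/f records, 1-based indices)


def write_obj(path: str | Path, objects: Sequence[tuple[str, MeshModel]]) -> Path:
    path = Path(path)
    lines = ["# phytomer3d OBJ export"]
    offset = 0
    for name, mesh in objects:
        lines.append(f"o {name}")
        for v in mesh.vertices:
            lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        for f in mesh.faces:
            lines.append(f"f {f[0] + 1 + offset} {f[1] + 1 + offset} {f[2] + 1 + offset}")
        offset += mesh.n_vertices
    path.write_text("\n".join(lines) + "\n")
    return path


def read_obj(path: str | Path) -> dict[str, MeshModel]:
    """Read an ASCII OBJ into named meshes (faces triangulated by fanning)."""
    verts: list[list[float]] = []
    objects: dict[str, dict] = {}
    current: Optional[dict] = None

    def _ensure(name: str) -> dict:
        if name not in objects:
            objects[name] = {"start": len(verts), "faces": []}
        return objects[name]

    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0] == "#":
            continue
        if parts[0] == "o":
            current = _ensure(parts[1] if len(parts) > 1 else f"object{len(objects)}")
        elif parts[0] == "v":
            if current is None:
                current = _ensure("default")
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif parts[0] == "f":
            if current is None:
                current = _ensure("default")
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            for i in range(1, len(idx) - 1):
                current["faces"].append((idx[0], idx[i], idx[i + 1]))
    all_verts = np.asarray(verts, dtype=float)
    out = {}
    names = list(objects)
    for i, name in enumerate(names):
        start = objects[name]["start"]
        end = objects[names[i + 1]]["start"] if i + 1 < len(names) else len(all_verts)
        local = all_verts[start:end]
        faces = np.array(
            [[a - start, b - start, c - start] for a, b, c in objects[name]["faces"]],
            dtype=np.int64,
        ).reshape(-1, 3)
        out[name] = MeshModel(local, faces)
    return out
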