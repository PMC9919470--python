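"""Multi-scale phenotypic trait extraction from assembled or digitized shoots.

Traits, by scale:

* leaf — blade curvature ``L_bend`` (chord/arc of the vein, in (0, 1]) and
  stem-leaf angle ``theta_l`` (degrees between the stem vector and the leaf
  base-to-tip chord);
* phytomer — envelope ``S_phy`` (cm^3): internode length (plus spike length
  on the spike-bearing phytomer) x perpendicular distance from the leaf tip
  to the internode axis x maximum leaf width;
* stem — mean internode length ``N_length`` (cm) and vertical angle
  ``theta_s`` (degrees);
* plant — height ``h`` (cm, ground to spike top) and spike-layer projected
  area ``S_area`` (cm^2, convex hull of the XY projection of spike points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .assembly import AssembledShoot, AssembledStem
from .core import Phytomer, SkeletonModel
from .errors import DegenerateGeometryWarning, GeometryError, SpikeLayerWarning

__all__ = [
    "TraitRecord",
    "blade_curvature",
    "stem_leaf_angle",
    "phytomer_envelope",
    "average_internode_length",
    "stem_vertical_angle",
    "plant_height",
    "spike_layer_projected_area",
    "extract_traits",
]

TRAIT_UNITS = {
    "L_bend": "1",
    "theta_l": "deg",
    "S_phy": "cm3",
    "N_length": "cm",
    "theta_s": "deg",
    "h": "cm",
    "S_area": "cm2",
}


@dataclass
class TraitRecord:
    """Extracted traits keyed by provenance (tiller j, rank k)."""

    plant: int
    leaf_curvature: dict[tuple[int, int], float] = field(default_factory=dict)
    leaf_angle: dict[tuple[int, int], float] = field(default_factory=dict)
    envelope: dict[tuple[int, int], float] = field(default_factory=dict)
    internode_mean: dict[int, float] = field(default_factory=dict)
    stem_angle: dict[int, float] = field(default_factory=dict)
    height: float = 0.0
    spike_area: float = 0.0

    def to_rows(self) -> list[dict]:
        rows = []
        for (j, k), v in sorted(self.leaf_curvature.items()):
            rows.append(self._row(j, k, "leaf", "L_bend", v))
        for (j, k), v in sorted(self.leaf_angle.items()):
            rows.append(self._row(j, k, "leaf", "theta_l", v))
        for (j, k), v in sorted(self.envelope.items()):
            rows.append(self._row(j, k, "phytomer", "S_phy", v))
        for j, v in sorted(self.internode_mean.items()):
            rows.append(self._row(j, 0, "stem", "N_length", v))
        for j, v in sorted(self.stem_angle.items()):
            rows.append(self._row(j, 0, "stem", "theta_s", v))
        rows.append(self._row(0, 0, "plant", "h", self.height))
        rows.append(self._row(0, 0, "plant", "S_area", self.spike_area))
        return rows

    def _row(self, tiller: int, rank: int, organ: str, trait: str, value: float) -> dict:
        return {
            "plant": self.plant,
            "tiller": tiller,
            "rank": rank,
            "organ": organ,
            "trait": trait,
            "value": value,
            "units": TRAIT_UNITS[trait],
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_rows())


# --------------------------------------------------------------------------
# leaf scale


def blade_curvature(vein: SkeletonModel) -> float:
    """Chord-to-arc ratio of the vein: 1 for a straight leaf, <1 drooping."""
    arc = vein.arc_length()
    if arc <= 0:
        raise GeometryError("vein arc length must be positive")
    return vein.chord_length() / arc


def stem_leaf_angle(stem_vector: np.ndarray, leaf_vector: np.ndarray) -> float:
    """Angle (deg, [0, 180]) between the stem vector and the leaf chord."""
    u = np.asarray(stem_vector, float)
    v = np.asarray(leaf_vector, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("stem and leaf vectors must be non-zero")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


# --------------------------------------------------------------------------
# phytomer scale


def _point_line_distance(point: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    d = direction / np.linalg.norm(direction)
    rel = point - origin
    return float(np.linalg.norm(rel - np.dot(rel, d) * d))


def phytomer_envelope(
    p: Phytomer,
    spike_length: float = 0.0,
    max_leaf_width: Optional[float] = None,
) -> float:
    """Envelope volume S_phy (cm^3) of one phytomer.

    (internode length + spike length) x perpendicular distance from the leaf
    tip to the internode axis line x maximum leaf width.  The spike length is
    non-zero only for the spike-bearing phytomer.
    """
    if p.leaf is None or p.leaf.skeleton is None:
        raise GeometryError("phytomer envelope undefined without a leaf")
    sk = p.internode.skeleton
    length = sk.chord_length() + float(spike_length)
    tip = p.leaf.skeleton.tip
    dist = _point_line_distance(tip, sk.base, sk.chord())
    if dist < 1e-9:
        warnings.warn(
            "leaf tip lies on the internode axis; envelope is zero",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        return 0.0
    if max_leaf_width is None:
        params = p.leaf.params
        if params is None or "max_width" not in getattr(params, "extras", {}):
            raise ValueError("max leaf width unavailable; pass max_leaf_width")
        max_leaf_width = float(params.extras["max_width"])
    return length * dist * float(max_leaf_width)


# --------------------------------------------------------------------------
# stem scale


def average_internode_length(s: Union[AssembledStem, Sequence[float]]) -> float:
    """Arithmetic mean internode length (cm) of one stem."""
    lengths = s.internode_lengths() if isinstance(s, AssembledStem) else np.asarray(s, float)
    if len(lengths) < 1:
        raise GeometryError("at least one internode is required")
    return float(np.mean(lengths))


def stem_vertical_angle(s: Union[AssembledStem, np.ndarray]) -> float:
    """Angle (deg) between the stem base-to-top vector and the vertical."""
    vec = s.stem_vector() if isinstance(s, AssembledStem) else np.asarray(s, float)
    n = np.linalg.norm(vec)
    if n < 1e-12:
        raise GeometryError("stem base and top coincide")
    c = float(np.clip(vec[2] / n, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


# --------------------------------------------------------------------------
# plant scale


def _spike_points(shoot: AssembledShoot, fallback_fraction: float = 0.2) -> np.ndarray:
    pts = [p for t, r, organ, p in shoot.labeled_vertices() if organ == "appendage"]
    if pts:
        return np.vstack(pts)
    allv = shoot.all_vertices()
    zmin, zmax = allv[:, 2].min(), allv[:, 2].max()
    cut = zmax - fallback_fraction * (zmax - zmin)
    warnings.warn(
        f"no spike geometry; using the top {fallback_fraction:.0%} height band as the spike layer",
        SpikeLayerWarning,
        stacklevel=3,
    )
    return allv[allv[:, 2] >= cut]


def plant_height(shoot: AssembledShoot) -> float:
    """Maximum z of the spike (ground plane at z = 0)."""
    pts = [p for t, r, organ, p in shoot.labeled_vertices() if organ == "appendage"]
    if not pts:
        warnings.warn(
            "no spike geometry; plant height taken over all vertices",
            SpikeLayerWarning,
            stacklevel=2,
        )
        return float(shoot.all_vertices()[:, 2].max())
    return float(np.vstack(pts)[:, 2].max())


def spike_layer_projected_area(
    shoot: AssembledShoot, fallback_fraction: float = 0.2
) -> float:
    """Convex-hull area (cm^2) of the XY projection of the spike layer."""
    xy = _spike_points(shoot, fallback_fraction)[:, :2]
    return _hull_area(xy)


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        warnings.warn(
            "fewer than three spike-layer points; projected area is zero",
            DegenerateGeometryWarning,
            stacklevel=3,
        )
        return 0.0
    try:
        hull = ConvexHull(xy)
    except QhullError:
        warnings.warn(
            "degenerate (collinear) spike layer; projected area is zero",
            DegenerateGeometryWarning,
            stacklevel=3,
        )
        return 0.0
    return float(hull.volume)  # in 2D, .volume is the area


# --------------------------------------------------------------------------
# whole record


def extract_traits(shoot: AssembledShoot, fallback_fraction: float = 0.2) -> TraitRecord:
    """Extract the full multi-scale trait record from an assembled shoot."""
    rec = TraitRecord(plant=shoot.plant)
    for stem in shoot.stems:
        j = stem.tiller
        stem_vec = stem.stem_vector()
        rec.internode_mean[j] = average_internode_length(stem)
        rec.stem_angle[j] = stem_vertical_angle(stem)
        for p in stem.phytomers:
            k = p.id.rank
            if p.leaf is None or p.leaf.skeleton is None:
                continue
            rec.leaf_curvature[(j, k)] = blade_curvature(p.leaf.skeleton)
            rec.leaf_angle[(j, k)] = stem_leaf_angle(stem_vec, p.leaf.skeleton.chord())
            spike_len = 0.0
            if p.appendage is not None and p.appendage.skeleton is not None:
                spike_len = p.appendage.skeleton.arc_length()
            rec.envelope[(j, k)] = phytomer_envelope(p, spike_length=spike_len)
    rec.height = plant_height(shoot)
    rec.spike_area = spike_layer_projected_area(shoot, fallback_fraction)
    return rec
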