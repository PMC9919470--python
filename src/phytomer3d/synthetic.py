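"""Synthetic digitizer-format wheat plants with analytic ground truth.

Leaves are circular arcs (arc length ``L``, subtended angle ``phi``), so
blade curvature has the closed form ``sin(phi/2) / (phi/2)`` and the
stem-leaf chord angle is ``theta0 + phi/2`` where ``theta0`` is the angle
between the leaf base tangent and the stem axis.  Tillers share a basal
origin, fan uniformly in azimuth, and lean away from vertical by a common
angle; leaves alternate sides up the stem (distichous), with the flag leaf
on the tiller azimuth.  The top phytomer of every tiller carries an ear.

With zero point noise every extracted trait matches its recorded ground
truth up to polyline discretization only.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .architecture import PAVector
from .digitizer import (
    DigitizedPlant,
    EarTrace,
    LeafSurfaceTrace,
    PhytomerTraces,
    StemTrace,
    TillerTraces,
    VeinTrace,
    write_digitized_plant,
)

__all__ = [
    "SyntheticPlantConfig",
    "GroundTruth",
    "generate_leaf_trace",
    "generate_shoot",
    "generate_panel",
    "default_panel",
]


@dataclass(frozen=True)
class SyntheticPlantConfig:
    name: str = "synthetic"
    tillers: int = 3
    phytomers: int = 4
    internode_lengths: Union[float, tuple[float, ...]] = (18.0, 16.0, 14.0, 12.0)
    leaf_arc_length: float = 25.0
    leaf_arc_angle: float = 1.2  # radians subtended by the vein arc (droop)
    leaf_base_angle: float = 20.0  # degrees between base tangent and stem axis
    max_leaf_width: float = 1.8
    leaf_rows: int = 9  # odd, so the mid-length (max width) row is sampled
    vein_points: int = 25
    stem_lean: float = 8.0  # degrees from vertical
    stem_diameter: float = 0.4
    ear_length: float = 8.0
    ear_diameter: float = 1.2
    ear_points: int = 9
    noise_sd: float = 0.0  # Gaussian point noise (cm) on every emitted point
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tillers < 1 or self.phytomers < 1:
            raise ValueError("tillers and phytomers must be >= 1")
        if not 0.0 < self.leaf_arc_angle < 2.0 * math.pi:
            raise ValueError("leaf_arc_angle must lie in (0, 2*pi)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.leaf_base_angle + math.degrees(self.leaf_arc_angle) / 2.0 > 180.0:
            raise ValueError("leaf chord angle (theta0 + phi/2) exceeds 180 degrees")
        if self.leaf_rows < 1 or self.vein_points < 2:
            raise ValueError("leaf_rows >= 1 and vein_points >= 2 required")
        lengths = self.lengths()
        if len(lengths) != self.phytomers or any(l <= 0 for l in lengths):
            raise ValueError("internode_lengths must give one positive length per rank")

    def lengths(self) -> tuple[float, ...]:
        if isinstance(self.internode_lengths, (int, float)):
            return (float(self.internode_lengths),) * self.phytomers
        return tuple(float(v) for v in self.internode_lengths)

    def truth_curvature(self) -> float:
        half = self.leaf_arc_angle / 2.0
        return math.sin(half) / half

    def truth_leaf_angle(self) -> float:
        return self.leaf_base_angle + math.degrees(self.leaf_arc_angle) / 2.0


@dataclass
class GroundTruth:
    """Exact trait values implied by the generating configuration."""

    height: float
    spike_area: float
    internode_mean: dict[int, float] = field(default_factory=dict)
    theta_s: dict[int, float] = field(default_factory=dict)
    leaf_curvature: dict[tuple[int, int], float] = field(default_factory=dict)
    leaf_angle: dict[tuple[int, int], float] = field(default_factory=dict)
    envelope: dict[tuple[int, int], float] = field(default_factory=dict)
    pa: Optional[PAVector] = None


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _leaf_geometry(
    config: SyntheticPlantConfig,
    base: np.ndarray,
    stem_dir: np.ndarray,
    azimuth: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Exact (rows, tip, vein, truth) for one leaf; no noise applied."""
    L = config.leaf_arc_length
    phi = config.leaf_arc_angle
    theta0 = math.radians(config.leaf_base_angle)
    u = _unit(np.asarray(stem_dir, float))
    raw = np.array([math.cos(math.radians(azimuth)), math.sin(math.radians(azimuth)), 0.0])
    e = raw - np.dot(raw, u) * u
    if np.linalg.norm(e) < 1e-9:  # stem horizontal along the azimuth: pick any normal
        e = np.cross(u, np.array([0.0, 0.0, 1.0]))
    e = _unit(e)
    normal = np.cross(u, e)
    r = L / phi

    def pos(s: np.ndarray) -> np.ndarray:
        psi = theta0 + phi * s / L
        along = r * (np.sin(psi) - math.sin(theta0))
        out = r * (math.cos(theta0) - np.cos(psi))
        return base + along[:, None] * u + out[:, None] * e

    n_rows = config.leaf_rows
    s_rows = np.arange(1, n_rows + 1) * L / (n_rows + 1)
    widths = config.max_leaf_width * (1.0 - (2.0 * s_rows / L - 1.0) ** 2)
    centers = pos(s_rows)
    rows = np.stack(
        [
            centers + 0.5 * widths[:, None] * normal,
            centers,
            centers - 0.5 * widths[:, None] * normal,
        ],
        axis=1,
    )
    tip = pos(np.array([L]))[0]
    vein = pos(np.linspace(0.0, L, config.vein_points))

    chord_len = L * config.truth_curvature()
    theta_l = config.truth_leaf_angle()
    truth = {
        "L_bend": config.truth_curvature(),
        "theta_l": theta_l,
        "max_width": float(widths.max()),
        "tip_distance": chord_len * math.sin(math.radians(theta_l)),
    }
    return rows, tip, vein, truth


def generate_leaf_trace(
    config: SyntheticPlantConfig,
    rank: int,
    azimuth: float = 0.0,
    base: Optional[Sequence[float]] = None,
    stem_dir: Sequence[float] = (0.0, 0.0, 1.0),
    rng: Optional[np.random.Generator] = None,
) -> tuple[LeafSurfaceTrace, VeinTrace, dict[str, float]]:
    """Generate one leaf's surface and vein traces plus its ground truth.

    By default the leaf attaches at the top node of its rank on a vertical
    stem at the origin.  Point noise (``config.noise_sd``) is drawn from
    ``rng`` (seeded from the config when omitted), so identical seeds give
    identical traces.
    """
    if not 1 <= rank <= config.phytomers:
        raise ValueError(f"rank {rank} outside [1, {config.phytomers}]")
    if base is None:
        base = np.array([0.0, 0.0, float(np.cumsum(config.lengths())[rank - 1])])
    rows, tip, vein, truth = _leaf_geometry(
        config, np.asarray(base, float), np.asarray(stem_dir, float), azimuth
    )
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        rows = rows + rng.normal(0.0, config.noise_sd, rows.shape)
        tip = tip + rng.normal(0.0, config.noise_sd, 3)
        vein = vein + rng.normal(0.0, config.noise_sd, vein.shape)
    return LeafSurfaceTrace(rows, tip), VeinTrace(vein), truth


def _girth_points(center: np.ndarray, axis: np.ndarray, diameter: float) -> np.ndarray:
    u = _unit(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - np.dot(ref, u) * u)
    e2 = np.cross(u, e1)
    angles = np.radians([0.0, 120.0, 240.0])
    return center + 0.5 * diameter * (
        np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2
    )


def generate_shoot(config: SyntheticPlantConfig, plant_id: int = 1) -> tuple[DigitizedPlant, GroundTruth]:
    """Generate one digitizer-format plant and its exact ground truth."""
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd
    lengths = config.lengths()
    n = config.phytomers
    m = config.tillers
    lean = math.radians(config.stem_lean)

    def noisy(arr: np.ndarray) -> np.ndarray:
        if sd > 0:
            return arr + rng.normal(0.0, sd, np.shape(arr))
        return arr

    truth = GroundTruth(height=0.0, spike_area=0.0)
    spike_points: list[np.ndarray] = []
    tillers = []
    for j in range(1, m + 1):
        az_t = 360.0 * (j - 1) / m
        az_rad = math.radians(az_t)
        u = np.array(
            [
                math.sin(lean) * math.cos(az_rad),
                math.sin(lean) * math.sin(az_rad),
                math.cos(lean),
            ]
        )
        nodes = np.vstack([np.zeros(3), np.cumsum(lengths)[:, None] * u])
        girths = np.stack([_girth_points(nd, u, config.stem_diameter) for nd in nodes])
        stem = StemTrace(noisy(nodes), noisy(girths))

        phytomers = []
        for k in range(1, n + 1):
            leaf_az = az_t + 180.0 * ((n - k) % 2)
            rows, tip, vein, leaf_truth = _leaf_geometry(config, nodes[k], u, leaf_az)
            surface = LeafSurfaceTrace(noisy(rows), noisy(tip))
            vtrace = VeinTrace(noisy(vein))
            ear = None
            if k == n:
                poly = nodes[n] + np.linspace(0.0, config.ear_length, config.ear_points)[:, None] * u
                mid = nodes[n] + 0.5 * config.ear_length * u
                diam = _ring_points(mid, u, config.ear_diameter)
                spike_points.append(poly)
                spike_points.append(diam)
                ear = EarTrace(noisy(poly), noisy(diam))
            phytomers.append(PhytomerTraces(rank=k, surface=surface, vein=vtrace, ear=ear))

            truth.leaf_curvature[(j, k)] = leaf_truth["L_bend"]
            truth.leaf_angle[(j, k)] = leaf_truth["theta_l"]
            spike_len = config.ear_length if k == n else 0.0
            truth.envelope[(j, k)] = (
                (lengths[k - 1] + spike_len) * leaf_truth["tip_distance"] * leaf_truth["max_width"]
            )
        truth.internode_mean[j] = float(np.mean(lengths))
        truth.theta_s[j] = config.stem_lean
        tillers.append(TillerTraces(tiller=j, stem=stem, phytomers=phytomers))

    truth.height = (sum(lengths) + config.ear_length) * math.cos(lean)
    truth.spike_area = _xy_hull_area(np.vstack(spike_points))
    if truth.spike_area > 0:
        n_length = float(np.mean(lengths))
        truth.pa = PAVector(
            C=truth.height * 10.0 / truth.spike_area,
            L=float(np.mean([c * a for c, a in zip(truth.leaf_curvature.values(), truth.leaf_angle.values())])),
            PHY=float(np.mean(list(truth.envelope.values()))) / n_length,
            S=config.stem_lean,
        )
    return DigitizedPlant(plant=plant_id, tillers=tillers), truth


def _ring_points(center: np.ndarray, axis: np.ndarray, diameter: float, k: int = 4) -> np.ndarray:
    u = _unit(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - np.dot(ref, u) * u)
    e2 = np.cross(u, e1)
    angles = 2.0 * math.pi * np.arange(k) / k
    return center + 0.5 * diameter * (np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2)


def _xy_hull_area(points: np.ndarray) -> float:
    xy = np.asarray(points, float)[:, :2]
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)
    except QhullError:
        return 0.0


# --------------------------------------------------------------------------
# panels


def _jittered(config: SyntheticPlantConfig, cv: float, rng: np.random.Generator) -> SyntheticPlantConfig:
    if cv == 0:
        return config

    def j(x: float, lo: float = 1e-6) -> float:
        return max(lo, x * (1.0 + cv * rng.standard_normal()))

    return dataclasses.replace(
        config,
        internode_lengths=tuple(j(l) for l in config.lengths()),
        leaf_arc_length=j(config.leaf_arc_length),
        leaf_arc_angle=min(j(config.leaf_arc_angle), 2.0 * math.pi - 1e-6),
        max_leaf_width=j(config.max_leaf_width),
        ear_length=j(config.ear_length),
        stem_lean=max(0.0, config.stem_lean * (1.0 + cv * rng.standard_normal())),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _truth_row(name: str, replicate: int, path: Path, truth: GroundTruth) -> dict:
    row = {
        "cultivar": name,
        "replicate": replicate,
        "file": path.name,
        "h": truth.height,
        "S_area": truth.spike_area,
        "theta_s": float(np.mean(list(truth.theta_s.values()))),
        "L_bend": float(np.mean(list(truth.leaf_curvature.values()))),
        "theta_l": float(np.mean(list(truth.leaf_angle.values()))),
        "S_phy": float(np.mean(list(truth.envelope.values()))),
        "N_length": float(np.mean(list(truth.internode_mean.values()))),
    }
    if truth.pa is not None:
        row.update({"C": truth.pa.C, "L": truth.pa.L, "PHY": truth.pa.PHY, "S": truth.pa.S})
    return row


def generate_panel(
    configs: Sequence[SyntheticPlantConfig],
    replicates: int,
    outdir: str | Path,
    seed: int = 0,
    jitter_cv: float = 0.05,
) -> tuple[list[Path], pd.DataFrame]:
    """Write one digitizer file per (config, replicate) plus ``truth.csv``.

    Replicates jitter the scalar morphology parameters with a Gaussian of
    coefficient of variation ``jitter_cv``; ``jitter_cv=0`` reproduces the
    base configs exactly.  Fully deterministic under ``seed``.
    """
    if len(configs) < 1 or replicates < 1:
        raise ValueError("need at least one config and one replicate")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    rows: list[dict] = []
    plant_id = 0
    for ci, config in enumerate(configs):
        for rep in range(1, replicates + 1):
            plant_id += 1
            rng = np.random.default_rng([seed, ci, rep])
            cfg = _jittered(config, jitter_cv, rng)
            plant, truth = generate_shoot(cfg, plant_id=plant_id)
            path = outdir / f"{config.name}_rep{rep}.csv"
            write_digitized_plant(plant, path)
            paths.append(path)
            rows.append(_truth_row(config.name, rep, path, truth))
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(outdir / "truth.csv", index=False, float_format="%.12g")
    return paths, truth_df


def default_panel() -> list[SyntheticPlantConfig]:
    """Ten demo cultivar configs spanning loose to compact architectures."""
    configs = []
    leans = [28.0, 24.0, 20.0, 18.0, 15.0, 12.0, 10.0, 8.0, 6.0, 4.0]
    heights = [100.0, 80.4, 76.4, 89.4, 80.0, 75.0, 78.9, 74.0, 75.0, 72.6]
    for i, (lean, h) in enumerate(zip(leans, heights), start=1):
        total = h - 8.0  # ear adds ~8 cm
        lengths = tuple(round(total * w / 10.0, 2) for w in (4.0, 3.0, 2.0, 1.0))
        configs.append(
            SyntheticPlantConfig(
                name=f"D{i}",
                tillers=3,
                phytomers=4,
                internode_lengths=lengths,
                leaf_arc_length=22.0 + i,
                leaf_arc_angle=0.5 + 0.12 * (10 - i),
                leaf_base_angle=15.0 + 1.5 * (10 - i),
                max_leaf_width=1.4 + 0.08 * i,
                stem_lean=lean,
                ear_length=8.0,
                seed=100 + i,
            )
        )
    return configs
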