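"""Plant architecture vector PA = (C, L, PHY, S) and classification.

* C   — convergence index: plant height x 10 / spike-layer projected area
  (the x10 scaling puts typical values in a convenient classification range);
* L   — leaf structure index: blade curvature x stem-leaf angle (degrees);
* PHY — phytomer structure index: envelope / mean internode length (cm^2);
* S   — stem structure index: the stem vertical angle (degrees).

Class thresholds sit at the midpoints of the gaps between the published
per-class index ranges: below 2.41 loose, 6.04 and above compact,
semi-compact in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assembly import AssembledShoot
from .traits import TraitRecord, extract_traits

__all__ = [
    "PAVector",
    "PanelSummary",
    "LOOSE_THRESHOLD",
    "COMPACT_THRESHOLD",
    "AGGREGATION_MODES",
    "convergence_index",
    "leaf_structure_index",
    "phytomer_structure_index",
    "stem_structure_index",
    "pa_from_traits",
    "plant_architecture_vector",
    "classify_architecture",
    "panel_summary",
]

LOOSE_THRESHOLD = 2.41
COMPACT_THRESHOLD = 6.04

AGGREGATION_MODES = ("mean", "flag-leaf", "top-phytomer")

PA_COLUMNS = ["C", "L", "PHY", "S"]


@dataclass(frozen=True)
class PAVector:
    C: float
    L: float
    PHY: float
    S: float

    def __post_init__(self) -> None:
        for name in PA_COLUMNS:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"PA component {name} must be finite")
        if not 0.0 <= self.S <= 180.0:
            raise ValueError("S must lie in [0, 180] degrees")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.C, self.L, self.PHY, self.S)


def convergence_index(h: float, S_area: float) -> float:
    """C = h * 10 / S_area."""
    if S_area <= 0:
        raise ValueError("S_area must be positive for the convergence index")
    if h < 0:
        raise ValueError("plant height must be non-negative")
    return h * 10.0 / S_area


def leaf_structure_index(L_bend: float, theta_l: float) -> float:
    """L = L_bend * theta_l."""
    return float(L_bend) * float(theta_l)


def phytomer_structure_index(S_phy: float, N_length: float) -> float:
    """PHY = S_phy / N_length."""
    if N_length <= 0:
        raise ValueError("N_length must be positive")
    return float(S_phy) / float(N_length)


def stem_structure_index(theta_s: float) -> float:
    """S = theta_s (identity, kept for symmetry of the index family)."""
    if not 0.0 <= theta_s <= 180.0:
        raise ValueError("theta_s must lie in [0, 180]")
    return float(theta_s)


def pa_from_traits(rec: TraitRecord, aggregation: str = "mean") -> PAVector:
    """Aggregate a trait record into the plant architecture vector.

    Aggregation modes: ``mean`` over all leaves/phytomers (default),
    ``flag-leaf`` / ``top-phytomer`` use only the top rank of each tiller.
    ``S`` is always the mean stem vertical angle over tillers.
    """
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")
    c = convergence_index(rec.height, rec.spike_area)

    leaf_keys = sorted(rec.leaf_curvature)
    phy_keys = sorted(rec.envelope)
    if aggregation in ("flag-leaf", "top-phytomer"):
        top = {}
        for j, k in leaf_keys:
            top[j] = max(top.get(j, 0), k)
        leaf_keys = [(j, k) for j, k in leaf_keys if k == top[j]]
        phy_keys = [(j, k) for j, k in phy_keys if k == top.get(j, k)]
    if not leaf_keys or not phy_keys:
        raise ValueError("no leaves/phytomers available for aggregation")
    L = float(
        np.mean([leaf_structure_index(rec.leaf_curvature[key], rec.leaf_angle[key]) for key in leaf_keys])
    )
    PHY = float(
        np.mean(
            [phytomer_structure_index(rec.envelope[(j, k)], rec.internode_mean[j]) for j, k in phy_keys]
        )
    )
    S = float(np.mean([rec.stem_angle[j] for j in sorted(rec.stem_angle)]))
    return PAVector(C=c, L=L, PHY=PHY, S=S)


def plant_architecture_vector(
    shoot: AssembledShoot,
    aggregation: str = "mean",
    fallback_fraction: float = 0.2,
) -> PAVector:
    """Extract traits from a shoot and aggregate them into PA = (C, L, PHY, S)."""
    rec = extract_traits(shoot, fallback_fraction=fallback_fraction)
    return pa_from_traits(rec, aggregation=aggregation)


def classify_architecture(
    C: float,
    loose_threshold: float = LOOSE_THRESHOLD,
    compact_threshold: float = COMPACT_THRESHOLD,
) -> str:
    """Classify by convergence index: loose / semi-compact / compact."""
    if C <= 0:
        raise ValueError("convergence index must be positive")
    if loose_threshold >= compact_threshold:
        raise ValueError("thresholds must be ordered")
    if C < loose_threshold:
        return "loose"
    if C >= compact_threshold:
        return "compact"
    return "semi-compact"


@dataclass
class PanelSummary:
    """Per-cultivar replicate statistics plus the PA correlation matrix."""

    means: pd.DataFrame  # cultivar x (C, L, PHY, S)
    sds: pd.DataFrame  # sample standard deviation (ddof=1; 0 for single replicate)
    ranges: pd.DataFrame  # max - min per cultivar, for comparison with "error" values
    correlations: pd.DataFrame  # 4x4 Pearson matrix over all replicate rows
    zero_variance: list[str]  # PA columns with no variance (correlation undefined)


def panel_summary(rows: Iterable[tuple[str, int, PAVector]]) -> PanelSummary:
    """Summarize a cultivar panel of replicate PA vectors."""
    data = [
        {"cultivar": c, "replicate": r, **dict(zip(PA_COLUMNS, pa.as_tuple()))}
        for c, r, pa in rows
    ]
    if not data:
        raise ValueError("panel is empty")
    df = pd.DataFrame(data)
    grouped = df.groupby("cultivar")[PA_COLUMNS]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    ranges = grouped.max() - grouped.min()
    zero_var = [c for c in PA_COLUMNS if df[c].std(ddof=0) < 1e-15]
    corr = df[PA_COLUMNS].corr(method="pearson")
    return PanelSummary(means=means, sds=sds, ranges=ranges, correlations=corr, zero_variance=zero_var)
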