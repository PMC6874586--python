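"""Length-derived dimensional variables: arc length, tortuosity, neck diameter.

The tortuosity index of a vessel segment is T = L1 / L2, the centreline
distance L1 between two points divided by their straight-line distance L2;
T >= 1, with T = 1 for a perfectly straight segment.  The cohort summary
variable is the mean of two indexes, lowest renal artery (P4) to right
femoral bifurcation (P9) and P4 to left femoral bifurcation (P12).

Diameters and volumes are measured on the CTA scans and validated here as
pass-through inputs; they are never derived from landmark geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .landmarks_io import CenterlineCurve, DimensionRecord, PatientRecord

logger = logging.getLogger("aaamorph")

__all__ = [
    "TortuosityResult",
    "polyline_length",
    "tortuosity_index",
    "average_tortuosity",
    "average_neck_diameter",
    "validate_dimensions",
]

#: Endograft delivery usually requires iliac arteries of at least this bore.
MIN_ILIAC_DIAMETER_MM = 7.0

# generous plausibility bounds (mm / cm^3); outside -> advisory warning
_PLAUSIBLE = {
    "average_neck_diameter": (10.0, 50.0),
    "neck_length": (1.0, 100.0),
    "max_diameter": (30.0, 120.0),
    "distal_diameter": (5.0, 60.0),
    "renal_to_bi_length": (50.0, 250.0),
    "volume": (20.0, 800.0),
    "average_tortuosity_index": (1.0, 3.0),
    "right_iliac_landing_diameter": (4.0, 40.0),
    "left_iliac_landing_diameter": (4.0, 40.0),
}


@dataclass(frozen=True)
class TortuosityResult:
    """Centreline length L1, straight-line length L2 (mm) and T = L1/L2."""

    L1: float
    L2: float
    T: float


def polyline_length(curve: CenterlineCurve | np.ndarray) -> float:
    """Arc length of an ordered polyline: the sum of segment lengths (mm)."""
    pts = curve.points if isinstance(curve, CenterlineCurve) else np.asarray(curve, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def tortuosity_index(curve: CenterlineCurve | np.ndarray) -> TortuosityResult:
    """Tortuosity T = L1/L2 of a centreline polyline between its endpoints."""
    pts = curve.points if isinstance(curve, CenterlineCurve) else np.asarray(curve, float)
    L1 = polyline_length(pts)
    L2 = float(np.linalg.norm(pts[-1] - pts[0]))
    if L2 == 0.0:
        raise ValueError("tortuosity undefined: coincident curve endpoints (L2 = 0)")
    return TortuosityResult(L1=L1, L2=L2, T=L1 / L2)


def average_tortuosity(record: PatientRecord) -> float:
    """Mean of the right (P4->P9) and left (P4->P12) tortuosity indexes.

    Requires both labelled femoral curves; if either is absent the value is
    missing (NaN), mirroring how scan coverage gaps are handled in the
    cohort statistics.
    """
    right = record.curve("renal-to-right-femoral")
    left = record.curve("renal-to-left-femoral")
    if right is None or left is None:
        missing = [
            s for s, c in (("right", right), ("left", left)) if c is None
        ]
        logger.info(
            "patient %s: %s femoral centreline absent; average tortuosity treated as missing",
            record.id, " and ".join(missing),
        )
        return math.nan
    return 0.5 * (tortuosity_index(right).T + tortuosity_index(left).T)


def average_neck_diameter(d_at_P4: float, d_at_P6: float) -> float:
    """Mean of the neck diameters at the distal renal artery (P4) and at the
    most distal extent of the proximal neck (P6), in mm."""
    if d_at_P4 <= 0 or d_at_P6 <= 0:
        raise ValueError("neck diameters must be positive")
    return 0.5 * (d_at_P4 + d_at_P6)


def validate_dimensions(record: DimensionRecord) -> list[str]:
    """Advisory plausibility checks on measured dimensions; never mutates.

    Flags iliac landing diameters below the usual 7 mm delivery minimum,
    tortuosity below its definitional lower bound of 1, and values outside
    broad plausibility ranges.
    """
    warnings: list[str] = []
    d = record.as_dict()
    for side in ("right", "left"):
        v = d[f"{side}_iliac_landing_diameter"]
        if not math.isnan(v) and v < MIN_ILIAC_DIAMETER_MM:
            warnings.append(
                f"{side} iliac landing diameter {v:g} mm is below the usual "
                f"{MIN_ILIAC_DIAMETER_MM:g} mm delivery minimum"
            )
    t = d["average_tortuosity_index"]
    if not math.isnan(t) and t < 1.0:
        warnings.append(f"average tortuosity index {t:g} violates T >= 1")
    for name, (lo, hi) in _PLAUSIBLE.items():
        v = d[name]
        if not math.isnan(v) and not (lo <= v <= hi):
            warnings.append(f"{name} = {v:g} outside plausible range [{lo:g}, {hi:g}]")
    for w in warnings:
        logger.warning("%s", w)
    return warnings
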