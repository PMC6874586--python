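"""Reading, validating and writing landmark sets, centrelines and cohorts.

Coordinate conventions
----------------------
All coordinates are millimetres.  X increases patient-right -> patient-left,
Y posterior -> anterior, Z inferior -> superior; the origin is arbitrary
(every downstream quantity is translation invariant).  Axis flips can be
applied at load time through :class:`AnalysisConfig` for data exported from
scanners with other stacking conventions.

File formats
------------
* Landmark CSV, one file per patient, header ``name,x_mm,y_mm,z_mm`` with
  rows P1..P13 (P14 is derived and always recomputed).
* Cohort manifest CSV with columns ``id,file,age,gender`` plus optional
  dimensional-variable columns.
* JSON mirror: a single object with ``id``, ``age``, ``gender``,
  ``landmarks`` (name -> [x, y, z]), optional ``curves`` and ``dimensions``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import TRIADS

logger = logging.getLogger("aaamorph")

__all__ = [
    "REQUIRED_POINTS",
    "ALL_POINTS",
    "MissingLandmarkError",
    "LandmarkValidationError",
    "LandmarkSet",
    "CenterlineCurve",
    "DimensionRecord",
    "PatientRecord",
    "Cohort",
    "AnalysisConfig",
    "load_config",
    "read_patient",
    "read_cohort",
    "write_patient",
    "write_report",
]

#: Points that must be measured; P14 is derived.
REQUIRED_POINTS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 14))
ALL_POINTS: tuple[str, ...] = REQUIRED_POINTS + ("P14",)

GENDERS = ("male", "female", "unspecified")

CURVE_LABELS = (
    "renal-to-right-femoral",
    "renal-to-left-femoral",
    "neck",
    "renal-to-bifurcation",
    "other",
)


class MissingLandmarkError(ValueError):
    """A required landmark P1..P13 is absent from the input."""


class LandmarkValidationError(ValueError):
    """A landmark set violates a structural invariant."""


@dataclass(frozen=True)
class LandmarkSet:
    """The 14 named centreline points of one patient, in mm.

    P14 is by definition the midpoint of P2 and P4 (the two renal origins);
    it is always recomputed, never trusted from a file.
    """

    points: dict[str, np.ndarray]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "LandmarkSet":
        pts: dict[str, np.ndarray] = {}
        for name in REQUIRED_POINTS:
            if name not in mapping:
                raise MissingLandmarkError(f"landmark {name} absent")
            p = np.asarray(mapping[name], dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise LandmarkValidationError(f"landmark {name} is not a finite 3D point")
            pts[name] = p
        p14 = 0.5 * (pts["P2"] + pts["P4"])
        if "P14" in mapping:
            given = np.asarray(mapping["P14"], dtype=float)
            if not np.allclose(given, p14, atol=1e-9):
                logger.warning(
                    "P14 %s does not equal midpoint(P2, P4) %s; overriding with the midpoint",
                    given.tolist(), p14.tolist(),
                )
        pts["P14"] = p14
        ls = cls(points=pts)
        ls._check_triads()
        return ls

    def _check_triads(self) -> None:
        for angle_id, triad in TRIADS.items():
            for a, b in ((0, 1), (1, 2), (0, 2)):
                pa, pb = self.points[triad[a]], self.points[triad[b]]
                if np.array_equal(pa, pb):
                    raise LandmarkValidationError(
                        f"coincident points {triad[a]} and {triad[b]} in triad {angle_id}"
                    )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def translated(self, offset: Sequence[float]) -> "LandmarkSet":
        off = np.asarray(offset, dtype=float)
        return LandmarkSet.from_mapping(
            {n: self.points[n] + off for n in REQUIRED_POINTS}
        )

    def to_mapping(self) -> dict[str, list[float]]:
        return {n: self.points[n].tolist() for n in ALL_POINTS}


@dataclass(frozen=True)
class CenterlineCurve:
    """An ordered dense polyline along a vessel centreline (mm)."""

    label: str
    points: np.ndarray  # (n, 3)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.label not in CURVE_LABELS:
            raise ValueError(f"unknown curve label {self.label!r}")
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centreline curve needs >= 2 points of 3 coordinates")
        if not np.all(np.isfinite(pts)):
            raise ValueError("centreline curve contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("centreline curve has coincident consecutive points")


#: (variable name, measurement accuracy).  Diameters are accurate to +/-1 mm
#: except the maximum one (+/-1.5 mm); neck length +/-1.5 mm; renal-to-bi
#: +/-2.5 mm; volume to 5%; tortuosity is a derived ratio.
DIMENSION_ACCURACY: dict[str, str] = {
    "average_neck_diameter": "+/-1 mm",
    "neck_length": "+/-1.5 mm",
    "max_diameter": "+/-1.5 mm",
    "distal_diameter": "+/-1 mm",
    "renal_to_bi_length": "+/-2.5 mm",
    "volume": "5% range",
    "average_tortuosity_index": "derived ratio",
    "right_iliac_landing_diameter": "+/-1 mm",
    "left_iliac_landing_diameter": "+/-1 mm",
}

DIMENSION_VARIABLES: tuple[str, ...] = tuple(DIMENSION_ACCURACY)


@dataclass
class DimensionRecord:
    """Measured dimensional variables of one patient (mm, cm^3, ratios).

    These are validated pass-through inputs measured on the CTA scans, not
    quantities the package derives from landmark geometry.  Missing values
    are NaN.
    """

    average_neck_diameter: float = math.nan
    neck_length: float = math.nan
    max_diameter: float = math.nan
    distal_diameter: float = math.nan
    renal_to_bi_length: float = math.nan
    volume: float = math.nan
    average_tortuosity_index: float = math.nan
    right_iliac_landing_diameter: float = math.nan
    left_iliac_landing_diameter: float = math.nan

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            v = math.nan if v is None else float(v)
            setattr(self, f.name, v)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"dimension {f.name} must be positive, got {v}")
        # T >= 1 by definition, but sub-1 inputs are kept so the advisory
        # validator in `dimensions` can report them instead of hard-failing
        t = self.average_tortuosity_index
        if not math.isnan(t) and t < 1.0:
            logger.warning("average_tortuosity_index %g violates T >= 1", t)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PatientRecord:
    id: str
    landmarks: LandmarkSet
    age: float | None = None
    gender: str = "unspecified"
    curves: list[CenterlineCurve] = field(default_factory=list)
    dimensions: DimensionRecord | None = None

    def __post_init__(self):
        if self.gender not in GENDERS:
            logger.warning(
                "patient %s: unknown gender token %r recorded as unspecified",
                self.id, self.gender,
            )
            self.gender = "unspecified"

    def curve(self, label: str) -> CenterlineCurve | None:
        for c in self.curves:
            if c.label == label:
                return c
        return None


@dataclass
class Cohort:
    records: list[PatientRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("cohort must contain at least one patient")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def dimensions_frame(self) -> pd.DataFrame:
        """Per-patient dimensional variables as a DataFrame indexed by id."""
        rows = {}
        for r in self.records:
            d = r.dimensions.as_dict() if r.dimensions else {}
            rows[r.id] = {v: d.get(v, math.nan) for v in DIMENSION_VARIABLES}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "id"
        return df

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": [r.age for r in self.records],
                "gender": [r.gender for r in self.records],
            },
            index=pd.Index([r.id for r in self.records], name="id"),
        )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class AnalysisConfig:
    """Run-wide conventions, loadable from YAML.

    ``axis_flips`` negates coordinates at load time (for scans stacked in the
    opposite direction); ``orientations`` holds per-plane or per-plane/angle
    sign flips for projected angles; ``quartile_method`` is a numpy
    percentile interpolation name; ``round_decimals`` applies to written
    report tables only (None keeps full precision).
    """

    axis_flips: tuple[bool, bool, bool] = (False, False, False)
    orientations: dict = field(default_factory=dict)
    quartile_method: str = "linear"
    round_decimals: int | None = None
    perturbation_mode: str = "ball"  # or "cube"
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kw = dict(d)
        if "axis_flips" in kw:
            kw["axis_flips"] = tuple(bool(v) for v in kw["axis_flips"])
        if "orientations" in kw:
            orient = {}
            for key, val in kw["orientations"].items():
                if "/" in key:  # "XZ/phi3" -> (plane, angle)
                    plane, angle = key.split("/", 1)
                    orient[(plane, angle)] = int(val)
                else:
                    orient[key] = int(val)
            kw["orientations"] = orient
        return cls(**kw)


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


# ---------------------------------------------------------------------------
# readers


def _apply_flips(mapping: dict[str, np.ndarray], cfg: AnalysisConfig | None):
    if cfg is None or not any(cfg.axis_flips):
        return mapping
    sign = np.where(np.asarray(cfg.axis_flips, dtype=bool), -1.0, 1.0)
    return {k: np.asarray(v, dtype=float) * sign for k, v in mapping.items()}


def _landmarks_from_csv(path: Path) -> dict[str, np.ndarray]:
    mapping: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"name", "x_mm", "y_mm", "z_mm"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: landmark CSV must have header name,x_mm,y_mm,z_mm"
            )
        for row in reader:
            mapping[row["name"].strip()] = np.array(
                [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
            )
    return mapping


def read_patient(
    path: str | Path,
    format: str | None = None,
    config: AnalysisConfig | None = None,
    **metadata,
) -> PatientRecord:
    """Read one patient from a landmark CSV or a JSON patient object.

    For CSV the patient id defaults to the file stem and age/gender may be
    passed as keyword metadata; JSON files carry their own metadata.  P14 is
    recomputed from P2 and P4 regardless of what the file contains.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        mapping = _landmarks_from_csv(path)
        landmarks = LandmarkSet.from_mapping(_apply_flips(mapping, config))
        return PatientRecord(
            id=str(metadata.pop("id", path.stem)),
            landmarks=landmarks,
            age=metadata.pop("age", None),
            gender=str(metadata.pop("gender", "unspecified")),
            dimensions=metadata.pop("dimensions", None),
        )
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        mapping = {k: np.asarray(v, dtype=float) for k, v in data["landmarks"].items()}
        landmarks = LandmarkSet.from_mapping(_apply_flips(mapping, config))
        curves = [
            CenterlineCurve(label=c["label"], points=np.asarray(c["points"], dtype=float))
            for c in data.get("curves", [])
        ]
        dims = data.get("dimensions")
        return PatientRecord(
            id=str(data.get("id", path.stem)),
            landmarks=landmarks,
            age=data.get("age"),
            gender=str(data.get("gender", "unspecified")),
            curves=curves,
            dimensions=DimensionRecord(**dims) if dims else None,
        )
    raise ValueError(f"unknown format {fmt!r}; expected csv or json")


def read_cohort(manifest_path: str | Path, config: AnalysisConfig | None = None) -> Cohort:
    """Read a cohort from a manifest CSV (columns id,file,age,gender,...).

    File paths are resolved relative to the manifest.  Any manifest columns
    matching dimensional variable names populate the patient's
    :class:`DimensionRecord`.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if not {"id", "file"}.issubset(table.columns):
        raise ValueError(f"{manifest_path}: manifest needs 'id' and 'file' columns")
    records = []
    for _, row in table.iterrows():
        dims_kw = {
            v: row[v] for v in DIMENSION_VARIABLES
            if v in table.columns and pd.notna(row[v])
        }
        age = row.get("age")
        rec = read_patient(
            manifest_path.parent / str(row["file"]),
            config=config,
            id=str(row["id"]),
            age=None if pd.isna(age) else float(age),
            gender=str(row.get("gender", "unspecified")),
            dimensions=DimensionRecord(**dims_kw) if dims_kw else None,
        )
        records.append(rec)
    return Cohort(records=records)


# ---------------------------------------------------------------------------
# writers


def write_patient(record: PatientRecord, path: str | Path, format: str = "csv") -> None:
    """Write one patient's landmarks (CSV) or full record (JSON)."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x_mm", "y_mm", "z_mm"])
            for name in ALL_POINTS:
                p = record.landmarks[name]
                w.writerow([name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    elif format == "json":
        payload = {
            "id": record.id,
            "age": record.age,
            "gender": record.gender,
            "landmarks": record.landmarks.to_mapping(),
            "curves": [
                {"label": c.label, "points": c.points.tolist()} for c in record.curves
            ],
            "dimensions": record.dimensions.as_dict() if record.dimensions else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_report(
    results: pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    round_decimals: int | None = None,
) -> None:
    """Write a result table (CSV or JSON records), optionally rounded.

    Round-trip stable: re-reading a written table reproduces the values at
    the declared precision.  An empty frame yields a header-only file.
    """
    df = results.copy()
    if round_decimals is not None:
        df = df.round(round_decimals)
    path = Path(path)
    if format == "csv":
        df.to_csv(path)
    elif format == "json":
        df.reset_index().to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")
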