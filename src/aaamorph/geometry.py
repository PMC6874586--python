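"""Triad angles of the aneurysmal aortic tree and their planar projections.

The shape of an abdominal aortic aneurysm (AAA) is summarised by ten angles,
each defined by an ordered triad of centreline landmarks (P1..P14): the angle
is measured at the middle (vertex) point between the rays towards the two
outer points.  Angles are computed

* in 3D space, where they are unsigned and always lie in (0, 180] degrees
  (``phi_3d``, a 1x10 vector), and
* as signed projections on the three anatomical planes -- frontal (XZ),
  sagittal (YZ) and transverse (XY) -- where they may exceed 180 degrees
  (``phi_proj``, a 3x10 matrix with entries in [0, 360)).

The projection of a triad drops the off-plane coordinate and measures the
rotation from the ray vertex->first to the ray vertex->third, counterclockwise
positive in the plane's ordered 2D axes; per-plane/per-angle orientation flags
let the caller flip that sign convention to match a particular viewing
direction.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .landmarks_io import LandmarkSet

__all__ = [
    "ANGLE_IDS",
    "TRIADS",
    "PLANES",
    "PLANE_AXES",
    "DegenerateTriadError",
    "angle_3d",
    "projected_angle",
    "compute_phi3d",
    "compute_phi_proj",
]

#: Angle identifiers in reporting order.
ANGLE_IDS: tuple[str, ...] = tuple(f"phi{i}" for i in range(1, 11))

#: The ten landmark triads (first, vertex, third) defining the angles.
TRIADS: dict[str, tuple[str, str, str]] = {
    "phi1": ("P1", "P2", "P3"),
    "phi2": ("P1", "P4", "P5"),
    "phi3": ("P1", "P14", "P6"),
    "phi4": ("P14", "P6", "P7"),
    "phi5": ("P6", "P7", "P8"),
    "phi6": ("P7", "P8", "P9"),
    "phi7": ("P8", "P9", "P10"),
    "phi8": ("P6", "P7", "P11"),
    "phi9": ("P7", "P11", "P12"),
    "phi10": ("P11", "P12", "P13"),
}

#: Projection planes in row order of the 3x10 matrix.
PLANES: tuple[str, ...] = ("XZ", "YZ", "XY")

#: In-plane 2D axis indices (ordered) for each plane; the dropped coordinate
#: is the remaining one.  Positive rotation is counterclockwise in this frame.
PLANE_AXES: dict[str, tuple[int, int]] = {
    "XZ": (0, 2),  # frontal: drop y
    "YZ": (1, 2),  # sagittal: drop x
    "XY": (0, 1),  # transverse: drop z
}


class DegenerateTriadError(ValueError):
    """A triad point coincides with its vertex (in 3D or after projection)."""


def _as_vec(p) -> np.ndarray:
    return np.asarray(p, dtype=float)


def angle_3d(a, v, c) -> float:
    """Unsigned 3D angle at vertex ``v`` between rays ``v->a`` and ``v->c``.

    Parameters
    ----------
    a, v, c
        3D points (any sequence of three coordinates, in mm).

    Returns
    -------
    float
        Angle in degrees, in [0, 180].  Symmetric in ``(a, c)`` and invariant
        to rigid motion and uniform scaling about the vertex.

    Raises
    ------
    DegenerateTriadError
        If ``a`` or ``c`` coincides with ``v``.
    """
    a, v, c = _as_vec(a), _as_vec(v), _as_vec(c)
    u = a - v
    w = c - v
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise DegenerateTriadError("degenerate triad: point coincides with vertex")
    # clamp guards arccos rounding at (anti)collinearity
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def projected_angle(a, v, c, plane: str, orientation: int = 1) -> float:
    """Signed projected angle at ``v`` on a projection plane, in [0, 360).

    The off-plane coordinate is dropped (XZ drops y, YZ drops x, XY drops z)
    and the rotation from the projected ray ``v->a`` to the projected ray
    ``v->c`` is measured counterclockwise in the plane's ordered 2D axes,
    multiplied by ``orientation`` (+1 or -1), and mapped to [0, 360).

    For a triad lying in the projection plane the result equals the 3D angle
    or its 360-degree complement, depending on winding and orientation.

    Raises
    ------
    DegenerateTriadError
        If a projected outer point coincides with the projected vertex.
    ValueError
        For an unknown plane name or orientation not in {+1, -1}.
    """
    if plane not in PLANE_AXES:
        raise ValueError(f"unknown projection plane {plane!r}; expected one of {PLANES}")
    if orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    i, j = PLANE_AXES[plane]
    a, v, c = _as_vec(a), _as_vec(v), _as_vec(c)
    u = np.array([a[i] - v[i], a[j] - v[j]])
    w = np.array([c[i] - v[i], c[j] - v[j]])
    if not np.any(u) or not np.any(w):
        raise DegenerateTriadError(
            f"degenerate projection on {plane}: point coincides with vertex"
        )
    theta = np.degrees(np.arctan2(u[0] * w[1] - u[1] * w[0], u[0] * w[0] + u[1] * w[1]))
    wrapped = (orientation * theta) % 360.0
    # x % 360 can round to exactly 360.0 for tiny negative x
    return float(0.0 if wrapped == 360.0 else wrapped)


def _resolve_orientation(orientations, plane: str, angle_id: str) -> int:
    """Look up an orientation flag: per (plane, angle), per plane, else +1."""
    if orientations is None:
        return 1
    if (plane, angle_id) in orientations:
        return orientations[(plane, angle_id)]
    return orientations.get(plane, 1)


def compute_phi3d(landmarks: "LandmarkSet | Mapping[str, Sequence[float]]") -> np.ndarray:
    """The 1x10 vector of 3D triad angles, ordered phi1..phi10 (degrees)."""
    pts = getattr(landmarks, "points", landmarks)
    out = np.empty(10)
    for k, angle_id in enumerate(ANGLE_IDS):
        fa, fv, fc = TRIADS[angle_id]
        try:
            out[k] = angle_3d(pts[fa], pts[fv], pts[fc])
        except DegenerateTriadError as exc:
            raise DegenerateTriadError(f"{angle_id} ({fa},{fv},{fc}): {exc}") from None
    return out


def compute_phi_proj(
    landmarks: "LandmarkSet | Mapping[str, Sequence[float]]",
    orientations: Mapping | None = None,
) -> np.ndarray:
    """The 3x10 matrix of signed projected angles; rows XZ, YZ, XY (degrees).

    ``orientations`` may map plane names or ``(plane, angle_id)`` pairs to
    +1/-1 sign flips (default +1 everywhere).
    """
    pts = getattr(landmarks, "points", landmarks)
    out = np.empty((3, 10))
    for r, plane in enumerate(PLANES):
        for k, angle_id in enumerate(ANGLE_IDS):
            fa, fv, fc = TRIADS[angle_id]
            sign = _resolve_orientation(orientations, plane, angle_id)
            try:
                out[r, k] = projected_angle(pts[fa], pts[fv], pts[fc], plane, sign)
            except DegenerateTriadError as exc:
                raise DegenerateTriadError(f"{plane}/{angle_id}: {exc}") from None
    return out
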