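"""Synthetic AAA landmark trees and cohorts with known statistical structure.

Two distinct jobs live here:

* **Mix-and-match case construction.**  Because the ten triad angles show no
  strong mutual correlation in real cohorts, a designer may combine extreme
  per-angle values freely.  :func:`reconstruct_landmarks` builds a 3D
  landmark tree whose ten triad angles equal a requested target vector: the
  main chain P1 -> P14 -> P6 -> P7 is grown joint by joint, then the right
  (P8, P9, P10) and left (P11, P12, P13) iliac limbs and the renal offshoots
  (P3, P5).  Ten angles do not pin down a 3D tree -- each joint retains a
  rotational degree of freedom -- so the residual freedom is an explicit
  per-joint torsion in the skeleton (default planar).

* **Cohort fixtures.**  :func:`generate_cohort` draws per-angle and
  per-dimension values from configurable distributions (defaults
  parameterised from published AAA cohort medians/IQRs), with controllable
  male:female ratio, injected gender shifts, injected pairwise correlations
  (Gaussian copula) and missing tortuosity values, all reproducible from a
  seed.  Truncated-normal marginals are re-solved numerically so the
  *truncated* distribution has exactly the requested median and IQR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .geometry import ANGLE_IDS
from .landmarks_io import (
    Cohort,
    DimensionRecord,
    LandmarkSet,
    PatientRecord,
)

__all__ = [
    "AngleDist",
    "AngleDistributionSpec",
    "DimensionSpec",
    "SkeletonSpec",
    "default_angle_spec",
    "fixed_angle_spec",
    "default_dimension_spec",
    "sample_phi",
    "reconstruct_landmarks",
    "generate_cohort",
]

# Published AAA cohort medians and IQR widths of the ten 3D angles (deg),
# used as the default generator parameterisation.
DEFAULT_ANGLE_MEDIANS: dict[str, float] = {
    "phi1": 106.0, "phi2": 98.0, "phi3": 159.0, "phi4": 120.0, "phi5": 115.0,
    "phi6": 136.0, "phi7": 134.0, "phi8": 100.0, "phi9": 149.0, "phi10": 134.0,
}
DEFAULT_ANGLE_IQRS: dict[str, float] = {
    "phi1": 28.0, "phi2": 36.0, "phi3": 21.0, "phi4": 40.0, "phi5": 34.0,
    "phi6": 40.0, "phi7": 45.0, "phi8": 38.0, "phi9": 36.0, "phi10": 36.0,
}

# Published cohort medians/IQRs of the dimensional variables
# (mm, volume cm^3, tortuosity a ratio) with generator truncation bounds.
DEFAULT_DIMENSIONS: dict[str, tuple[float, float, float, float]] = {
    # name: (median, iqr, lower bound, upper bound)
    "average_neck_diameter": (23.1, 3.9, 5.0, math.inf),
    "neck_length": (22.0, 20.0, 1.0, math.inf),
    "max_diameter": (52.0, 8.5, 30.0, math.inf),
    "distal_diameter": (18.0, 6.7, 5.0, math.inf),
    "renal_to_bi_length": (123.9, 20.3, 50.0, math.inf),
    "volume": (127.0, 55.0, 20.0, math.inf),
    "average_tortuosity_index": (1.22, 0.11, 1.0, math.inf),
    "right_iliac_landing_diameter": (13.5, 3.3, 4.0, math.inf),
    "left_iliac_landing_diameter": (13.0, 3.4, 4.0, math.inf),
}

#: IQR of a standard normal: Phi^-1(0.75) - Phi^-1(0.25).
_NORMAL_IQR = 2.0 * stats.norm.ppf(0.75)


def _solve_loc(median: float, sigma: float, lo: float, hi: float) -> float:
    """Location of a truncnorm on (lo, hi) whose *truncated* median is ``median``."""

    def trunc_median(loc: float) -> float:
        a = (lo - loc) / sigma
        b = (hi - loc) / sigma if math.isfinite(hi) else math.inf
        return float(stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=sigma))

    lo_b, hi_b = median - sigma, median + sigma
    while trunc_median(lo_b) > median:
        lo_b -= 4 * sigma
    while trunc_median(hi_b) < median:
        hi_b += 4 * sigma
    return optimize.brentq(lambda L: trunc_median(L) - median, lo_b, hi_b, xtol=1e-10)


@lru_cache(maxsize=512)
def _median_matched_truncnorm(median: float, iqr: float, lo: float, hi: float):
    """Frozen truncated normal on (lo, hi) with the given *truncated* median
    and IQR width.

    Truncation shifts the median and shrinks the IQR of a plain
    N(median, iqr/1.349), so both the location and the scale are solved
    numerically (nested bisection: scale outer, location inner).
    """
    if not lo < median < hi:
        raise ValueError(f"median {median} outside truncation bounds ({lo}, {hi})")
    span = (hi - lo) if math.isfinite(hi) else math.inf
    if iqr >= 0.5 * span:
        raise ValueError(f"requested IQR {iqr} unattainable within bounds ({lo}, {hi})")

    def frozen_for(sigma: float):
        loc = _solve_loc(median, sigma, lo, hi)
        a = (lo - loc) / sigma
        b = (hi - loc) / sigma if math.isfinite(hi) else math.inf
        return stats.truncnorm(a, b, loc=loc, scale=sigma)

    def iqr_gap(sigma: float) -> float:
        d = frozen_for(sigma)
        return float(d.ppf(0.75) - d.ppf(0.25)) - iqr

    s_lo = s_hi = iqr / _NORMAL_IQR
    while iqr_gap(s_lo) > 0:
        s_lo /= 2.0
    while iqr_gap(s_hi) < 0:
        s_hi *= 2.0
    sigma = optimize.brentq(iqr_gap, s_lo, s_hi, xtol=1e-9)
    return frozen_for(sigma)


@dataclass(frozen=True)
class AngleDist:
    """Marginal distribution of one angle (degrees), truncated to (lo, hi].

    Families: ``truncnorm`` (truncated normal re-solved so the truncated
    median and IQR match exactly), ``lognormal_reflected`` (180 - phi lognormal, for
    left-skewed angles piling up near 180), ``triangular`` (lo, median, hi)
    and ``fixed``.
    """

    median: float
    iqr: float = 0.0
    family: str = "truncnorm"
    lo: float = 0.0
    hi: float = 180.0

    def frozen(self):
        if self.family == "fixed" or self.iqr == 0.0:
            return None
        if self.family == "truncnorm":
            return _median_matched_truncnorm(self.median, self.iqr, self.lo, self.hi)
        if self.family == "lognormal_reflected":
            med_x = self.hi - self.median
            # sigma solving med_x*(e^{q s} - e^{-q s}) = iqr, q = Phi^-1(.75)
            q = stats.norm.ppf(0.75)
            s = optimize.brentq(
                lambda s_: med_x * (math.exp(q * s_) - math.exp(-q * s_)) - self.iqr,
                1e-9, 10.0,
            )
            return stats.lognorm(s, scale=med_x)
        if self.family == "triangular":
            span = self.hi - self.lo
            return stats.triang((self.median - self.lo) / span, loc=self.lo, scale=span)
        raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        dist = self.frozen()
        if dist is None:
            return np.full(size or 1, self.median) if size else self.median
        draws = dist.ppf(rng.random(size if size else 1))
        if self.family == "lognormal_reflected":
            draws = self.hi - np.clip(draws, None, self.hi - 1e-9)
        draws = np.clip(draws, np.nextafter(self.lo, self.hi), self.hi)
        return draws if size else float(draws[0])

    def ppf(self, u):
        """Quantile transform (used by the cohort copula)."""
        dist = self.frozen()
        if dist is None:
            return np.full_like(np.asarray(u, dtype=float), self.median)
        x = dist.ppf(u)
        if self.family == "lognormal_reflected":
            x = self.hi - np.clip(x, None, self.hi - 1e-9)
        return np.clip(x, np.nextafter(self.lo, self.hi), self.hi)


@dataclass(frozen=True)
class AngleDistributionSpec:
    """Per-angle marginal distributions for phi1..phi10 (independent draws).

    Independence is the deliberate default: observed AAA angles show no
    strong mutual correlation, which is what licenses mix-and-match
    construction of extreme cases.
    """

    angles: Mapping[str, AngleDist]

    def __post_init__(self):
        missing = [a for a in ANGLE_IDS if a not in self.angles]
        if missing:
            raise ValueError(f"angle spec missing entries for {missing}")

    def shifted(self, shifts: Mapping[str, float]) -> "AngleDistributionSpec":
        new = dict(self.angles)
        for name, delta in shifts.items():
            if name in new:
                new[name] = replace(new[name], median=new[name].median + delta)
        return AngleDistributionSpec(angles=new)

    def sample_matrix(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, 10) matrix of independent draws."""
        return np.column_stack([self.angles[a].sample(rng, n) for a in ANGLE_IDS])


def default_angle_spec(family: str = "truncnorm") -> AngleDistributionSpec:
    return AngleDistributionSpec(
        angles={
            a: AngleDist(median=DEFAULT_ANGLE_MEDIANS[a], iqr=DEFAULT_ANGLE_IQRS[a], family=family)
            for a in ANGLE_IDS
        }
    )


def fixed_angle_spec(medians: Mapping[str, float] | Sequence[float] | None = None) -> AngleDistributionSpec:
    """Degenerate spec returning the given (default: published-median) values."""
    if medians is None:
        medians = DEFAULT_ANGLE_MEDIANS
    elif not isinstance(medians, Mapping):
        medians = dict(zip(ANGLE_IDS, medians))
    return AngleDistributionSpec(
        angles={a: AngleDist(median=float(medians[a]), family="fixed") for a in ANGLE_IDS}
    )


@dataclass(frozen=True)
class DimensionSpec:
    """Median-matched truncated-normal marginals for the dimensional variables."""

    variables: Mapping[str, AngleDist]

    def shifted(self, shifts: Mapping[str, float]) -> "DimensionSpec":
        new = dict(self.variables)
        for name, delta in shifts.items():
            if name in new:
                new[name] = replace(new[name], median=new[name].median + delta)
        return DimensionSpec(variables=new)


def default_dimension_spec() -> DimensionSpec:
    return DimensionSpec(
        variables={
            name: AngleDist(median=m, iqr=iqr, family="truncnorm", lo=lo, hi=hi)
            for name, (m, iqr, lo, hi) in DEFAULT_DIMENSIONS.items()
        }
    )


# ---------------------------------------------------------------------------
# landmark-tree reconstruction


@dataclass(frozen=True)
class SkeletonSpec:
    """Segment lengths (mm) and per-joint torsions (deg) of the landmark tree.

    Default lengths are compatible with published cohort medians (e.g. the
    renal-to-bifurcation centreline is about 124 mm).  Torsions fix the
    rotational freedom the ten angles leave at each joint; the defaults (0,
    with the left-side branches at 180) produce a planar tree in the frontal
    XZ plane.  ``p2_p4`` is the separation of the two renal origins along
    the supra-renal axis; it must be smaller than 2 * p1_p14 so that P1 stays
    above the proximal renal origin.
    """

    p1_p14: float = 60.0
    p2_p4: float = 12.0
    p14_p6: float = 30.0
    p6_p7: float = 95.0
    p7_p8: float = 40.0
    p8_p9: float = 40.0
    p9_p10: float = 30.0
    p7_p11: float = 40.0
    p11_p12: float = 40.0
    p12_p13: float = 30.0
    p2_p3: float = 25.0
    p4_p5: float = 25.0
    #: tilt of the supra-renal axis from the body axis, within the frontal
    #: plane (deg); nonzero keeps every plane projection non-degenerate
    inlet_tilt_deg: float = 10.0
    torsions: Mapping[str, float] = field(default_factory=dict)

    _JOINTS = ("P14", "P6", "P7_right", "P8", "P9", "P7_left", "P11", "P12", "P2", "P4")
    _DEFAULT_TORSIONS = {"P7_left": 180.0, "P4": 180.0}

    def __post_init__(self):
        for name in (
            "p1_p14", "p2_p4", "p14_p6", "p6_p7", "p7_p8", "p8_p9", "p9_p10",
            "p7_p11", "p11_p12", "p12_p13", "p2_p3", "p4_p5",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"skeleton length {name} must be positive")
        if self.p2_p4 >= 2.0 * self.p1_p14:
            raise ValueError("p2_p4 must be < 2 * p1_p14 (P1 must lie above P2)")
        unknown = set(self.torsions) - set(self._JOINTS)
        if unknown:
            raise ValueError(f"unknown torsion joints: {sorted(unknown)}")

    def torsion(self, joint: str) -> float:
        return float(self.torsions.get(joint, self._DEFAULT_TORSIONS.get(joint, 0.0)))


def _step(p, t, n, length, angle_deg, torsion_deg, joint):
    """Place a new point at ``length`` from ``p`` so the vertex angle at ``p``
    between the incoming ray (back along ``t``) and the outgoing ray is
    ``angle_deg``; ``torsion_deg`` rotates the bend plane about ``t``.

    Returns (new_point, new_tangent, new_normal); the new normal is chosen in
    the bend plane so that successive zero-torsion bends curl the same way.
    """
    if not 0.0 < angle_deg <= 180.0:
        raise ValueError(f"infeasible angle {angle_deg} deg at joint {joint}: must be in (0, 180]")
    th = math.radians(angle_deg)
    ta = math.radians(torsion_deg)
    b = np.cross(t, n)
    m = math.cos(ta) * n + math.sin(ta) * b
    w = -math.cos(th) * t + math.sin(th) * m
    n_new = -(math.sin(th) * t + math.cos(th) * m)
    return p + length * w, w, n_new


def reconstruct_landmarks(
    phi: Sequence[float] | Mapping[str, float],
    skeleton: SkeletonSpec | None = None,
) -> LandmarkSet:
    """Build a landmark tree whose ten 3D triad angles equal ``phi``.

    ``phi`` is a length-10 sequence ordered phi1..phi10 (degrees, each in
    (0, 180]) or a mapping by angle id.  The tree is grown sequentially with
    the skeleton's segment lengths and torsions; recomputing the angles of
    the result reproduces ``phi`` to better than 1e-6 degrees.
    """
    skeleton = skeleton or SkeletonSpec()
    if isinstance(phi, Mapping):
        phi_arr = np.array([float(phi[a]) for a in ANGLE_IDS])
    else:
        phi_arr = np.asarray(phi, dtype=float)
    if phi_arr.shape != (10,):
        raise ValueError("phi must provide exactly 10 angles phi1..phi10")
    p = dict(zip(ANGLE_IDS, phi_arr))
    sk = skeleton

    pts: dict[str, np.ndarray] = {}
    origin = np.zeros(3)
    # descending aorta: superior -> inferior, tilted slightly within the
    # frontal plane so no segment is exactly axis-aligned
    tilt = math.radians(sk.inlet_tilt_deg)
    t0 = np.array([math.sin(tilt), 0.0, -math.cos(tilt)])
    n0 = np.array([math.cos(tilt), 0.0, math.sin(tilt)])

    pts["P1"] = origin
    p14 = origin + sk.p1_p14 * t0

    # renal origins sit on the supra-renal axis so that P14 is their midpoint
    pts["P2"] = p14 - 0.5 * sk.p2_p4 * t0
    pts["P4"] = p14 + 0.5 * sk.p2_p4 * t0

    # renal offshoots: vertex angles phi1 at P2, phi2 at P4, both against P1
    pts["P3"], _, _ = _step(pts["P2"], t0, n0, sk.p2_p3, p["phi1"], sk.torsion("P2"), "P2")
    pts["P5"], _, _ = _step(pts["P4"], t0, n0, sk.p4_p5, p["phi2"], sk.torsion("P4"), "P4")

    # main chain P14 -> P6 -> P7
    p6, t6, n6 = _step(p14, t0, n0, sk.p14_p6, p["phi3"], sk.torsion("P14"), "P14")
    p7, t7, n7 = _step(p6, t6, n6, sk.p6_p7, p["phi4"], sk.torsion("P6"), "P6")
    pts["P6"], pts["P7"] = p6, p7

    # right limb P7 -> P8 -> P9 -> P10
    p8, t8, n8 = _step(p7, t7, n7, sk.p7_p8, p["phi5"], sk.torsion("P7_right"), "P7_right")
    p9, t9, n9 = _step(p8, t8, n8, sk.p8_p9, p["phi6"], sk.torsion("P8"), "P8")
    p10, _, _ = _step(p9, t9, n9, sk.p9_p10, p["phi7"], sk.torsion("P9"), "P9")
    pts["P8"], pts["P9"], pts["P10"] = p8, p9, p10

    # left limb P7 -> P11 -> P12 -> P13
    p11, t11, n11 = _step(p7, t7, n7, sk.p7_p11, p["phi8"], sk.torsion("P7_left"), "P7_left")
    p12, t12, n12 = _step(p11, t11, n11, sk.p11_p12, p["phi9"], sk.torsion("P11"), "P11")
    p13, _, _ = _step(p12, t12, n12, sk.p12_p13, p["phi10"], sk.torsion("P12"), "P12")
    pts["P11"], pts["P12"], pts["P13"] = p11, p12, p13

    return LandmarkSet.from_mapping(pts)


def sample_phi(spec: AngleDistributionSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one 1x10 angle vector (degrees, each entry in (0, 180])."""
    return np.array([spec.angles[a].sample(rng) for a in ANGLE_IDS])


# ---------------------------------------------------------------------------
# cohort generation


def _correlation_matrix(variables: Sequence[str], pairs) -> np.ndarray:
    k = len(variables)
    corr = np.eye(k)
    idx = {v: i for i, v in enumerate(variables)}
    for va, vb, rho in pairs or []:
        if va not in idx or vb not in idx:
            raise ValueError(f"unknown variable in correlation pair ({va}, {vb})")
        corr[idx[va], idx[vb]] = corr[idx[vb], idx[va]] = float(rho)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("injected correlation matrix is not positive definite") from None
    return corr


def generate_cohort(
    n: int,
    angle_spec: AngleDistributionSpec | None = None,
    dim_spec: DimensionSpec | None = None,
    skeleton: SkeletonSpec | None = None,
    missing_tortuosity_rate: float = 9 / 258,
    male_to_female_ratio: float = 6.5,
    unspecified_rate: float = 2 / 258,
    gender_angle_shifts: Mapping[str, float] | None = None,
    gender_dimension_shifts: Mapping[str, float] | None = None,
    correlations: Sequence[tuple[str, str, float]] | None = None,
    torsion_jitter: float = 0.0,
    seed: int | None = None,
) -> Cohort:
    """Generate ``n`` synthetic patients with known statistical structure.

    Angles are drawn per patient from ``angle_spec`` and realised as landmark
    trees; dimensional variables are drawn through a Gaussian copula carrying
    any injected pairwise ``correlations`` (a non-positive-definite request
    is an error).  Gender is assigned at ``male_to_female_ratio`` (with a
    small unspecified fraction); ``gender_*_shifts`` move the male median up
    and the female median down by half the stated shift.  The average
    tortuosity index is set missing at ``missing_tortuosity_rate``, mirroring
    scan-coverage gaps in real cohorts.  Identical seeds give identical
    cohorts.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    angle_spec = angle_spec or default_angle_spec()
    dim_spec = dim_spec or default_dimension_spec()
    skeleton = skeleton or SkeletonSpec()

    p_unspec = unspecified_rate
    p_male = (1.0 - p_unspec) * male_to_female_ratio / (male_to_female_ratio + 1.0)
    p_female = 1.0 - p_unspec - p_male
    genders = rng.choice(["male", "female", "unspecified"], size=n, p=[p_male, p_female, p_unspec])
    ages = rng.integers(51, 89, size=n)

    # gender-specific marginal specs (half-shift each way keeps the pooled median)
    def specs_for(gender: str):
        a_sh = dict(gender_angle_shifts or {})
        d_sh = dict(gender_dimension_shifts or {})
        sign = {"male": 0.5, "female": -0.5}.get(gender, 0.0)
        a = angle_spec.shifted({k: sign * v for k, v in a_sh.items()}) if a_sh else angle_spec
        d = dim_spec.shifted({k: sign * v for k, v in d_sh.items()}) if d_sh else dim_spec
        return a, d

    spec_cache = {g: specs_for(g) for g in ("male", "female", "unspecified")}

    dim_vars = list(dim_spec.variables)
    corr = _correlation_matrix(dim_vars, correlations)
    z = rng.multivariate_normal(np.zeros(len(dim_vars)), corr, size=n, method="cholesky")
    u = np.clip(stats.norm.cdf(z), 1e-12, 1.0 - 1e-12)

    records: list[PatientRecord] = []
    for i in range(n):
        a_spec, d_spec = spec_cache[genders[i]]
        phi = sample_phi(a_spec, rng)
        if torsion_jitter > 0.0:
            torsions = {
                j: SkeletonSpec._DEFAULT_TORSIONS.get(j, 0.0)
                + rng.uniform(-torsion_jitter, torsion_jitter)
                for j in SkeletonSpec._JOINTS
            }
            sk = replace(skeleton, torsions=torsions)
        else:
            sk = skeleton
        landmarks = reconstruct_landmarks(phi, sk)
        dims_kw = {
            v: float(d_spec.variables[v].ppf(u[i, j])) for j, v in enumerate(dim_vars)
        }
        if rng.random() < missing_tortuosity_rate:
            dims_kw["average_tortuosity_index"] = math.nan
        records.append(
            PatientRecord(
                id=f"S{i + 1:04d}",
                landmarks=landmarks,
                age=float(ages[i]),
                gender=str(genders[i]),
                dimensions=DimensionRecord(**dims_kw),
            )
        )
    return Cohort(records=records)
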