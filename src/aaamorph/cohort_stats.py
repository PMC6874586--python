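"""Cohort-level statistical protocol for AAA morphometry.

Because most angular and dimensional variables in AAA cohorts are
non-normal, the protocol summarises every variable by median, IQR width and
range, tests normality with Shapiro-Wilk (alpha = 0.05), linear association
with the two-tailed Pearson test (alpha = 0.01), and compares medians between
two independent groups with Mood's median test (alpha = 0.05): pool the two
groups, take the grand median, build the 2x2 contingency table of counts
<= / > the grand median per group, and test it with a chi-square without
continuity correction.

Two cohort questions are wired on top of the primitives:

* symmetry — the right/left angle pairs (phi1, phi2), (phi5, phi8),
  (phi6, phi9), (phi7, phi10) compared in 3D and on each projection plane
  (16 tests);
* gender — dimensional variables divided by each patient's average neck
  diameter (a body-size surrogate) and compared male vs female; the 3D
  angles compared un-normalised.

Missing values are NaN; correlations delete missing pairwise, group
comparisons listwise per test.  No multiple-testing correction is applied by
default (the protocol reports raw p-values); Bonferroni or Benjamini-
Hochberg adjustment is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ANGLE_IDS, PLANES, compute_phi3d, compute_phi_proj
from .landmarks_io import Cohort

logger = logging.getLogger("aaamorph")

__all__ = [
    "SYMMETRY_PAIRS",
    "SummaryRow",
    "StatReport",
    "summarize",
    "summary_table",
    "shapiro_wilk",
    "pearson_corr",
    "correlation_matrix",
    "median_test",
    "cohort_angle_tables",
    "normality_tests",
    "symmetry_tests",
    "gender_comparison",
    "adjust_pvalues",
]

#: Right/left homologue angle pairs tested for symmetry.
SYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("phi1", "phi2"),
    ("phi5", "phi8"),
    ("phi6", "phi9"),
    ("phi7", "phi10"),
)


@dataclass(frozen=True)
class SummaryRow:
    """Median, IQR width (Q3 - Q1) and range of one variable."""

    variable: str
    median: float
    iqr: float
    min: float
    max: float
    n_used: int


@dataclass
class StatReport:
    """Container for the pieces of the cohort statistical report."""

    normality: pd.DataFrame | None = None
    correlations: dict | None = None
    symmetry: pd.DataFrame | None = None
    gender_dimensions: pd.Series | None = None
    gender_angles: pd.Series | None = None


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, (np.ndarray, pd.Series)) else values, dtype=float)
    return arr[~np.isnan(arr)]


def summarize(
    values: Iterable[float],
    variable: str = "",
    quartile_method: str = "linear",
) -> SummaryRow:
    """Median, IQR width and min-max of the non-missing values.

    ``quartile_method`` is any numpy percentile interpolation method; the
    default 'linear' interpolates the empirical CDF.
    """
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError(f"all values missing for variable {variable or '<unnamed>'}")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method=quartile_method)
    return SummaryRow(
        variable=variable,
        median=float(med),
        iqr=float(q3 - q1),
        min=float(arr.min()),
        max=float(arr.max()),
        n_used=int(arr.size),
    )


def summary_table(df: pd.DataFrame, quartile_method: str = "linear") -> pd.DataFrame:
    """Median/IQR/range summary of every column of a variables table."""
    rows = [summarize(df[c], c, quartile_method) for c in df.columns]
    return pd.DataFrame(
        {
            "median": [r.median for r in rows],
            "iqr": [r.iqr for r in rows],
            "min": [r.min for r in rows],
            "max": [r.max for r in rows],
            "n_used": [r.n_used for r in rows],
        },
        index=pd.Index([r.variable for r in rows], name="variable"),
    )


def shapiro_wilk(values: Iterable[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    arr = _clean(values)
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def pearson_corr(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, int]:
    """Two-tailed Pearson correlation with pairwise deletion of missing pairs.

    Returns (rho, p, n) where n is the number of complete pairs used.
    """
    xa = np.asarray(list(x) if not isinstance(x, (np.ndarray, pd.Series)) else x, dtype=float)
    ya = np.asarray(list(y) if not isinstance(y, (np.ndarray, pd.Series)) else y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = stats.pearsonr(xa, ya)
    return float(r.statistic), float(r.pvalue), int(xa.size)


def correlation_matrix(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations over the columns of ``df``.

    Returns dict with symmetric 'rho' (unit diagonal), 'p' and 'n' frames;
    missing values are deleted pairwise per cell.
    """
    cols = list(df.columns)
    k = len(cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.empty((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(df[cols[i]].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            r_ij, p_ij, n_ij = pearson_corr(df[cols[i]], df[cols[j]])
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
            n[i, j] = n[j, i] = n_ij
    idx = pd.Index(cols, name="variable")
    return {
        "rho": pd.DataFrame(rho, index=idx, columns=cols),
        "p": pd.DataFrame(p, index=idx, columns=cols),
        "n": pd.DataFrame(n, index=idx, columns=cols),
    }


def median_test(
    group_a: Iterable[float],
    group_b: Iterable[float],
    ties: str = "below",
    correction: bool = False,
) -> tuple[float, float]:
    """Mood's median test for two independent medians; returns (chi2, p).

    Values equal to the pooled grand median are counted in the "<= median"
    cell (``ties='below'``) and the chi-square carries no continuity
    correction, both switchable.
    """
    a = _clean(group_a)
    b = _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("median test needs two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        raise ValueError("median test undefined: all pooled values identical")
    res = stats.median_test(a, b, ties=ties, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level wiring


def cohort_angle_tables(cohort: Cohort, orientations=None) -> dict[str, pd.DataFrame]:
    """Per-patient angle tables keyed '3D', 'XZ', 'YZ', 'XY'.

    Each value is an (n_patients x 10) DataFrame indexed by patient id with
    columns phi1..phi10.
    """
    ids = [r.id for r in cohort]
    phi3d = np.array([compute_phi3d(r.landmarks) for r in cohort])
    proj = np.array([compute_phi_proj(r.landmarks, orientations) for r in cohort])
    idx = pd.Index(ids, name="id")
    tables = {"3D": pd.DataFrame(phi3d, index=idx, columns=list(ANGLE_IDS))}
    for r, plane in enumerate(PLANES):
        tables[plane] = pd.DataFrame(proj[:, r, :], index=idx, columns=list(ANGLE_IDS))
    return tables


def normality_tests(df: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk W and p per column; decision column at alpha = 0.05."""
    rows = {}
    for c in df.columns:
        w, p = shapiro_wilk(df[c])
        rows[c] = {"W": w, "p": p, "normal_at_0.05": p >= 0.05}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def symmetry_tests(cohort: Cohort, orientations=None) -> pd.DataFrame:
    """Right/left symmetry: Mood's median test on the four homologue pairs,
    in 3D and on each projection plane (16 tests).

    Returns a frame indexed by (space, pair) with chi2 and p columns.
    """
    if len(cohort) < 2:
        raise ValueError("symmetry tests need a cohort of at least 2 patients")
    tables = cohort_angle_tables(cohort, orientations)
    rows = []
    for space, tab in tables.items():
        for left, right in SYMMETRY_PAIRS:
            chi2, p = median_test(tab[left], tab[right])
            rows.append(
                {"space": space, "pair": f"{left}-{right}", "chi2": chi2, "p": p,
                 "significant_at_0.05": p < 0.05}
            )
    return pd.DataFrame(rows).set_index(["space", "pair"])


def gender_comparison(cohort: Cohort) -> StatReport:
    """Male vs female comparisons of normalised dimensions and raw 3D angles.

    Dimensional variables are divided by each patient's average neck diameter
    before the median test (patients with a missing neck diameter are
    excluded from the normalised comparisons and logged); the ten 3D angles
    are compared un-normalised.  Patients of unspecified gender are excluded
    from the two-group tests but remain in cohort totals.
    """
    meta = cohort.metadata_frame()
    male = meta["gender"] == "male"
    female = meta["gender"] == "female"
    if male.sum() < 2 or female.sum() < 2:
        raise ValueError("gender comparison needs >= 2 patients per gender")

    dims = cohort.dimensions_frame()
    neck = dims["average_neck_diameter"]
    n_missing_neck = int(neck.isna().sum())
    if n_missing_neck:
        logger.info(
            "%d patients lack average neck diameter; excluded from normalised comparisons",
            n_missing_neck,
        )
    normalised = dims.drop(columns=["average_neck_diameter"]).div(neck, axis=0)

    gender_dims = {}
    for var in normalised.columns:
        a = normalised.loc[male, var]
        b = normalised.loc[female, var]
        try:
            _, p = median_test(a, b)
        except ValueError:
            p = math.nan
        gender_dims[var] = p

    angles3d = cohort_angle_tables(cohort)["3D"]
    gender_angles = {}
    for var in angles3d.columns:
        _, p = median_test(angles3d.loc[male, var], angles3d.loc[female, var])
        gender_angles[var] = p

    return StatReport(
        gender_dimensions=pd.Series(gender_dims, name="p"),
        gender_angles=pd.Series(gender_angles, name="p"),
    )


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Optional multiple-testing adjustment ('bonferroni' or 'fdr_bh').

    Off by default throughout the protocol, which reports raw p-values.
    """
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")
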