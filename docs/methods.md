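# Methods

## Landmark model and coordinate conventions

An AAA centreline tree is reduced to 14 named points. Thirteen (P1–P13)
are measured on the scans; P14 is *defined* as the midpoint of the two
renal origins P2 and P4, so the package always recomputes it and warns if
an input file supplies a conflicting value. All coordinates are in
millimetres. The axes follow the usual scanner stacking: X patient-right →
patient-left, Y posterior → anterior, Z inferior → superior; the origin is
arbitrary because every quantity computed here is invariant under
translation (and the 3D angles under all rigid motion). Data exported from
systems with opposite stacking can be corrected with per-axis flips in the
YAML configuration rather than by editing files.

## Angles

Each angle φk is the vertex angle of an ordered landmark triad
(first, vertex, third): φ₁ = (P1, P2, P3), φ₂ = (P1, P4, P5),
φ₃ = (P1, P14, P6), φ₄ = (P14, P6, P7), φ₅ = (P6, P7, P8),
φ₆ = (P7, P8, P9), φ₇ = (P8, P9, P10), φ₈ = (P6, P7, P11),
φ₉ = (P7, P11, P12), φ₁₀ = (P11, P12, P13).

The 3D value is arccos of the normalised dot product, with the cosine
clamped to [−1, 1] so that numerically collinear triads return exactly
180° instead of NaN. 3D angles are unsigned and lie in (0°, 180°].

Projected angles drop the off-plane coordinate (XZ drops y, YZ drops x,
XY drops z) and measure the *signed* rotation from the ray vertex→first to
the ray vertex→third with atan2, counterclockwise positive in the plane's
ordered 2D axes, mapped to [0°, 360°). A projected angle can therefore
exceed 180°, which is what distinguishes, say, an anteriorly from a
posteriorly angulated neck in the sagittal view. Whether "counterclockwise
in (x, z)" corresponds to the clinical viewing convention for a given
plane and side is a pure sign convention, so per-plane and per-plane/angle
orientation flags (±1) are exposed in the configuration instead of being
hard-coded; the default is +1 everywhere. When a triad is coplanar with a
projection plane the projected magnitude equals the 3D angle (value θ or
360° − θ depending on winding). A triad whose outer point lands on the
vertex after projection has no defined projected angle; this is reported
as a hard error naming the plane and angle rather than silently patched,
since it only occurs for exactly axis-aligned segments.

## Dimensional variables and tortuosity

The nine dimensional variables (neck diameters/length, max and distal
diameter, renal-to-bifurcation length, sac volume, iliac landing
diameters) are measured on the scans by trained readers; the package
treats them as validated pass-through inputs and never derives them from
the landmarks, except for convenience arc-length approximations over
the straight landmark chain when no dense centreline is supplied (flagged
as approximate). Validation is advisory: sub-7-mm iliac landing diameters
(the usual delivery-system minimum), tortuosity below its definitional
bound of 1, and values outside broad plausibility ranges produce warnings,
never mutations or rejections.

The tortuosity index of a path is T = L₁/L₂ with L₁ the polyline arc
length and L₂ the straight endpoint distance; the cohort variable is the
mean of the right (P4→P9) and left (P4→P12) indexes and is treated as
missing if either femoral curve is absent — mirroring how incomplete scan
coverage is handled downstream (missing, not imputed).

## Perturbation sensitivity

Landmark picking is reproducible only to about a millimetre, so the
sensitivity analysis displaces each measured point P1–P13 independently by
a random vector drawn uniformly from the solid ball of radius 1 mm
(default), recomputes P14 from the perturbed renals, and re-evaluates the
ten 3D angles; this is repeated 100 times (default). The uniform-ball
choice interprets "up to 1 mm in space" isotropically; a per-axis cube
mode is available for comparison. P14 is *not* perturbed independently
because it is a derived midpoint, not a picked point; perturbing it
independently would double-count renal error (the alternative is a
one-line change if ever wanted). Each repetition yields a signed percent
discrepancy per angle, 100·(φ′−φ)/φ, summarised as median (IQR) with
min/max. Signed discrepancies matter: a near-straight angle can only
shrink under perturbation (180° is the attainable maximum), producing
systematically negative medians. A repetition that produces a degenerate
triad is re-drawn so exactly the configured number of valid samples is
kept; the redraw count is reported.

## Cohort statistics

Angular and dimensional variables in AAA cohorts are mostly non-normal,
so the protocol is median-based throughout: summaries are median, IQR
width (Q3 − Q1) and range; normality is checked with Shapiro–Wilk
(α = 0.05), association with the two-tailed Pearson test (α = 0.01), and
two-group median differences with Mood's median test (α = 0.05). The
quartile method is linear interpolation of the empirical CDF (any numpy
percentile method can be configured); for the median test, values equal
to the pooled grand median are counted in the "≤ median" cell and the
chi-square carries no continuity correction — both conventions are
explicit arguments because different statistical packages default
differently. These primitives are delegated to scipy behind the module's
interface; the test suite checks them against hand-built oracles (the
2×2 contingency chi-square computed from counts, the textbook covariance
formula) and against their nominal type-I error by simulation.

Missing data are NaN: correlations delete pairwise, group comparisons
listwise per test. No multiple-testing correction is applied by default —
the protocol reports raw p-values and leaves Bonferroni/Benjamini-Hochberg
as an explicit option — because the symmetry and gender screens are
exploratory comparisons whose joint calibration is the reader's judgement.

Two wired-up questions: **symmetry** compares the right/left homologue
pairs (φ₁, φ₂), (φ₅, φ₈), (φ₆, φ₉), (φ₇, φ₁₀) in 3D and on each plane (16
tests); **gender** divides every dimensional variable by the patient's
average neck diameter (a body-size surrogate when height/weight are
unavailable) before comparing males and females, and compares the ten 3D
angles un-normalised. Patients of unspecified gender are excluded from the
two-group tests but counted in totals.

## Synthetic generator

The generator has two distinct purposes and is first-class, tested code.

**Reconstruction.** `reconstruct_landmarks` grows the tree joint by
joint: main chain P1 → P14 → P6 → P7, then each iliac limb from P7 and the
renal offshoots from P2/P4. Each step places the next point at the
skeleton's segment length so the triad vertex angle equals its target;
the bend-plane orientation at each joint is the skeleton's torsion angle.
Ten angles under-determine a 3D tree, and making that residual freedom an
explicit parameter keeps both planar (torsion 0/180, the classic
single-plane parametric-study setting) and genuinely 3D anatomies
constructible. P2 and P4 are placed collinear with the supra-renal axis so
P14 is their exact midpoint by construction. Reconstruction targets Φ₃D
only; a full 3×10 projection matrix is over-constrained, so projections
are computed from the reconstructed tree, never imposed. The supra-renal
axis is tilted 10° within the frontal plane by default so that no segment
is exactly axis-aligned and every plane projection is well defined; the
tilt is a skeleton parameter. Round-trip error (rebuild then re-measure)
is below 10⁻⁶ deg for all feasible inputs — in practice ~10⁻¹³, pure
floating-point noise. Infeasible targets (angles outside (0°, 180°]) fail
with the joint named.

**Default study conditions.** Cohort defaults reproduce the published AAA
cohort: angle medians (106, 98, 159, 120, 115, 136, 134, 100, 149, 134)°
with their IQRs, the nine dimensional medians/IQRs (e.g. renal-to-
bifurcation 123.9 mm, tortuosity 1.22), n = 258, a 6.5:1 male:female ratio
with ~1% unspecified, ages 51–88, and a 9/258 missing-tortuosity rate.
Angles are drawn independently — justified by the observed weak mutual
correlations, and exactly the assumption that licenses mix-and-match
construction. The default marginal family is a truncated normal, chosen
as a testing fixture rather than a population claim (several real angles
are non-normal); a reflected-lognormal family (180 − φ lognormal) is
available for the left-skewed angles, plus triangular and fixed.

Truncation at (0°, 180°] (or at positive lower bounds for dimensions)
would bias the median and shrink the IQR of a naively parameterised
truncated normal, so both the location and scale are solved numerically
(nested Brent bisection) until the *truncated* distribution's median and
IQR equal the requested values exactly; summaries of generated cohorts
therefore recover the specification within pure Monte-Carlo error.
Dimensional variables are drawn through a Gaussian copula so pairwise
correlations can be injected (a non-positive-definite request is an
error); gender effects are additive median shifts applied +½ to males and
−½ to females, preserving the pooled median. Segment lengths default to
values compatible with the published dimensional medians (renal-to-
bifurcation ≈ 125 mm along the default chain).

What the generator does *not* emulate: the joint multivariate distribution
of real anatomies (angle–length dependence, left/right asymmetry of limb
lengths), lumen surfaces, thrombus, or measurement error in the
dimensional variables. Passing statistical tests on synthetic cohorts
therefore validates the *protocol's calibration and power*, not claims
about real AAA populations.

## Numerical choices and problem sizes

- arccos arguments clamped to [−1, 1]; projected angles wrapped to
  [0°, 360°) with the `x % 360 == 360` float edge mapped to 0.
- Uniform-ball sampling via isotropic Gaussian direction and radius
  r·U^(1/3).
- Verification sizes: 10,000 random triads and 10,000 random landmark sets
  for the geometry oracles, 1,000 seeded reconstruction round-trips, a
  100-patient × 100-repetition sensitivity cohort, and 1,000 null cohorts
  of n = 258 for the type-I calibration of the median and Pearson tests —
  sizes chosen so the whole verification completes in well under a minute
  while keeping binomial error on the calibration rates below a third of
  the nominal α.

## Known limitations

- The orientation (sign) conventions of the projected angles are
  configurable but default to +1; matching a specific clinical atlas of
  views may require per-plane flips.
- "Aneurysmal length" (used in some published correlation analyses) is not
  a defined dimensional variable here and is intentionally not guessed.
- The median test's chi-square is asymptotic; for very small groups an
  exact test would be preferable.
- Reconstruction fixes segment lengths and torsions from the skeleton;
  it makes no attempt to infer realistic torsion statistics, which are
  declared fixtures.
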