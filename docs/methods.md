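# Methods

This note documents the models implemented in `stemmorph`, the choices made
where the design was genuinely open, and what the synthetic data does and
does not establish.

## Outline representation

Outlines are ordered planar loops stored *open* (the closing segment is
implicit; a duplicated endpoint in an input file is dropped on read). This
avoids double-counting the closing segment in the Fourier integrals. All
outlines are forced counterclockwise before analysis — the signs of the
Fourier coefficients flip with traversal direction, so a consistent
orientation is a precondition for comparing specimens. Coordinates follow a
dorsal-view convention: y increases upward and anterior is toward +y, which
is what makes "forward-directed" meaningful in the visual-field model.
Units are arbitrary; per-specimen scaling (below) removes them.

## Elliptical Fourier analysis

A closed outline traversed at constant speed over its perimeter T defines
periodic signals x(t), y(t), expanded as

    x(t) = a0 + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
    y(t) = c0 + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T).

For a piecewise-linear contour the coefficient integrals have closed forms
as sums over segments; those are implemented directly and verified in the
tests against trapezoidal quadrature of the defining integrals on densely
resampled contours (relative error < 1e-4 required; observed ~1e-9 on
smooth shapes). The DC terms equal the centroid of the arc-length
parameterization, computed exactly per segment.

Note that the arc-length (constant-speed) parameterization is part of the
definition: a 3:1 ellipse traversed at constant speed is *not* a pure
first-harmonic signal (harmonic 1 carries ≈ 98.98% of its power and
a₁ ≈ 2.62 rather than the semi-axis 3). Tests assert values derived from
the quadrature oracle, not from the naive angle parameterization.

**Normalization.** Centering zeroes the DC terms. Scaling divides all
harmonics by the semi-major-axis length of the first-harmonic ellipse (the
largest singular value of the 2x2 first-harmonic matrix) — the standard
outline-analysis scale functional. Rotation/start-point alignment (phase
normalization via the first-harmonic ellipse) is implemented but **off by
default**: digitized specimens in this kind of dataset share a consistent
anterior-up orientation, and alignment would discard real orientation
signal; it is available behind a flag for datasets that need it. The
alignment phase has a π/2 ambiguity (axis swap); the implementation picks
the candidate placing the semi-major axis in the first column, which makes
alignment idempotent and rotation-invariant.

**Harmonic power and calibration.** Harmonic n has power
Pₙ = (aₙ² + bₙ² + cₙ² + dₙ²)/2. The harmonic count for a dataset is
calibrated as the smallest N whose cumulative power — as a fraction of
each outline's *total* signal power (the exact Parseval integral of the
centered traversal, not the truncated sum) — averaged across specimens
reaches the threshold (default 0.99). Normalizing by the true signal power
is what makes an unreachable threshold detectable; normalizing by the
truncated sum would always end at exactly 1. A worst-case per-specimen
mode is available. The default search bound is 20 harmonics (40 in the
acceptance script).

## Morphospace

The specimen-by-coefficient matrix (rows in manifest order, columns
a₁,b₁,c₁,d₁,…) is analyzed by covariance PCA: columns are centered but not
rescaled, because after per-specimen shape scaling all coefficients share
units and unit-variance scaling would distort the harmonic weighting.
Eigenvector signs are arbitrary, so each loading's largest-magnitude entry
is made positive for determinism. Degenerate specimens (zero first
harmonic) either raise an error naming the specimen or are excluded with a
warning, per caller choice; the pipeline excludes with a warning.

Group occupancy uses 2D convex hulls in a chosen component plane. Hull
boundaries count as inside (conservative outlier calls); groups with fewer
than three distinct non-collinear points get a degenerate zero-area hull,
reported rather than raised. A specimen is an occupancy outlier when it
falls outside every non-degenerate group hull.

`shape_at_position` renders the outline at mean + score x loading,
reinterpreted as Fourier coefficients — the standard way to visualize what
a principal component encodes.

## Allometry

Lens diameter d versus head length L is modeled as d = 10^b · L^s, fitted
by OLS of log10(d) on log10(L) with head length as predictor (matching the
axes of the scatter it summarizes). Because both variables carry
measurement error, major-axis regression (principal axis of the log-log
covariance) is available as an option; the qualitative above-the-line
calls are robust to the choice. "Above the trend line" is operationalized
as a signed log10 residual exceeding a cutoff (default 0, with a 1e-12
float-noise guard); the fit population defaults to all specimens, with an
extant-only option.

## Visual-field model

The model is two-dimensional in the dorsal plane, where the published
field-of-view reconstructions of this kind are drawn; no 3D solid angles
are computed. Each stemma is a flat lens of aperture a with a retina of
extent r at depth D behind it. The field is bounded by the limiting rays
connecting each retina edge to the *opposite* aperture edge
(wide-acceptance convention, the natural reading of a short eye with a
large opening angle); the same-side ("narrow") convention is implemented
as an option. For an untilted eye the internal half-angle is
arctan((r/2 + a/2)/D).

Refraction is applied once, at the single flat air–lens interface: an
internal ray at angle θ from the lens normal exits at
arcsin(min(1, n·sinθ)), saturating at grazing. The lens is treated as
optically continuous with the eye interior — a flat lens contributes no
focusing power, and no second interface is modeled. The default index is
n = 1.4; n = 1 reproduces the purely geometric construction exactly.

A tilt parameter rotates the retina axis away from the lens normal,
producing asymmetric boundary rays (each ray refracts at its own angle).
Fields are clipped to a window of 10 x head length centered on the head
(they are unbounded cones otherwise); circular arcs such as the stylet
capture sector use 256 segments, so sector areas are exact to ~0.5%.

The binocular (stereoscopic) region is the polygon intersection of the two
monocular fields. Its onset is the distance along the head midline from
the anterior margin to the region. Classification against the stylet
capture zone (a sector of radius = stylet length spanning the stylet span
angle in front of the head): `between_stylets` if region and zone
intersect with positive area, `beyond_stylets` if the region exists but is
disjoint from the zone, `none` if the region is empty.

### Scenario presets

Four named eye-geometry variants, in units of head length, on a head twice
as wide as long with eyes at the anterolateral corners (±0.7, 0) facing
forward and stylets of reach 1.5 spanning 90°:

| preset | aperture | depth | retina | tilt | intended outcome |
|---|---|---|---|---|---|
| `flat_short` | 0.30 | 0.30 | 0.30 | 0 | feasible; overlap between stylets |
| `tapering_long` | 0.32 | 0.70 | 0.135 | 0 | overlap beyond stylets; within reach at n = 1.4 |
| `long_clipped` | 0.30 | 1.30 | 0.30 | 0 | retina protrudes behind the capsule (infeasible) |
| `tilted` | 0.30 | 0.75 | 0.15 | −30° | toe-out; overlap far in front or absent |

These numbers were fixed analytically before testing, from the closed
forms: the inner limiting ray exits at x = 0.7 − a/2 and crosses the
midline at (0.7 − a/2)/tanθ. For `flat_short`, θ = 45° gives onset 0.55
(geometric) and 0.079 (refractive, θₑ = 81.9°), both inside the stylet
reach. For `tapering_long`, θ = arctan(0.2275/0.7) = 18.0° gives onset
1.66 > 1.5 (beyond), while refraction widens it to θₑ = 25.6°, onset
1.13 < 1.5 (between). The `tilted` preset points both limiting rays of
each eye away from the midline, so the fields never meet. Feasibility is
a containment test of the aperture-to-retina quadrilateral in the head
polygon.

## Synthetic data

`gen_head_outline` builds a single closed loop — matching the single-
contour assumption of the Fourier pipeline — as a radial function around
the head center: a p-norm superellipse capsule (p = 5, a rounded
rectangle) of the given width ratio, two anterior stylet lobes (skewed
Gaussian bumps whose tips reach `stylet_length_ratio` head lengths,
hugging the midline so head *width* is governed by the capsule and eye
bulges), optional tooth bumps on the inner stylet flanks, anterolateral
eye-protrusion bulges at ±75°, and smooth wrapped-Gaussian angular noise.
The radial function is even about the midline, so noiseless outlines are
exactly mirror-symmetric.

`gen_population` draws latent parameters from truncated Gaussians
(truncation at physical bounds keeps the construction star-shaped). The
default study conditions are: 20 "extant" specimens with parameter sd
0.04, 20 "fossil" specimens with sd 0.12 (three times as dispersed), and
one outlier with head width ratio 2.0 and eye protrusion four fossil
standard deviations above the mean — a tight extant cluster, a wider
fossil cloud, and a wide-headed large-eyed specimen outside both.
Seeding: a master seed is split per specimen with
`SeedSequence(master, spawn_key=(index,))`, so any prefix of a population
regenerates identically.

`gen_measurements` draws head lengths log-uniform over 0.5–10 (length
units) and lens diameters from the power law with slope 0.8, intercept
−1.0 and log10 noise sd 0.05 by default; implanted outliers get additive
log10 offsets (+0.2 in the default conditions).

**What the generator does not emulate:** digitization noise correlated
along the contour, non-star-shaped silhouettes (strongly recurved stylet
tips), taxon-level phylogenetic structure, allometry of shape with size,
and measurement error on head length. Passing tests therefore establish
that the pipeline recovers the structure it assumes — cluster dispersion
ordering, occupancy outliers, power-law slopes, field-of-view orderings —
not that real digitized datasets satisfy those assumptions.

## Numerical choices and limitations

- All accumulation in double precision; translation invariance of
  harmonics holds to 1e-12, scale equivariance to 1e-10 (relative).
- Nyquist guard: n_harmonics ≤ floor(point count / 2).
- PCA retains min(n − 1, p) components (full SVD); constant matrices get
  zero eigenvalues and an all-zero variance fraction.
- Polygon arithmetic uses exact-predicate planar geometry (shapely);
  field wedges are truncated at 4x the window diagonal before clipping.
- Problem sizes used in the tests and acceptance script (41-specimen
  populations, 240-point outlines, 20–200 replicates) were chosen as the
  smallest sizes at which the recovery statements are stable.
- The model reports planar angular sectors only: no acuity, photoreceptor
  sampling, 3D ray tracing, or behavioral modelling.
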