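# Methods

This note documents the models, parameter choices and numerical decisions
behind `aortiq`, and what the phantom-based validation does and does not
establish.

## Coordinate conventions

All geometry is in world millimeters. A voxel at integer index `i` has its
center at `origin + i * spacing`; masks are written as NIfTI-1 with a diagonal
affine carrying spacing and origin. Velocities are signed, forward flow
positive, in cm/s; PWV is reported in m/s; growth rates in mm/year.

## Centerline extraction

The lumen is assumed to be a single 6-connected, tube-like component
(validated: component count, an Euler-number check that rejects handles and
cavities, and an elongation check that rejects blobs).

1. **Rough path.** Dijkstra shortest path over the 26-connected foreground
   voxel graph between the two endpoints, with edge cost
   `step / mean(distance-to-wall)^4`. The strong inverse weighting pins the
   path to the medial ridge; without it a shortest path cuts the inside of
   every bend and biases the curvature fit.
2. **Smoothing.** Order-2 Savitzky–Golay over a 12 mm window on the 1 mm
   resampled polyline. A plain moving average was tried first and rejected:
   it systematically flattens circular arcs (the bias grows with the window
   and is worst at the curve ends where the window shrinks asymmetrically),
   inflating the fitted curvature radius by 2–3%. An order-2 polynomial
   filter preserves circles to second order, so the window can be wide enough
   (12 mm) to suppress boundary-jitter noise without biasing curvature.
3. **Recentering (×2).** Each point moves to the centroid of the lumen
   cross-section sampled in the plane perpendicular to the local tangent, on
   a disk of radius 2.2× the local distance-to-wall (bounded so the disk
   cannot reach an adjacent limb of the candy cane). For an ideal torus or
   cylinder this centroid is exactly the axis point.
4. **Ends.** Within about one tube radius of an opening the recentering disk
   protrudes past the cap and the centroid drifts. When the caller supplies
   endpoints — the package's emulation of manually marked valve/distal points —
   they are treated as trusted anchors and pinned through every smoothing and
   recentering pass. When endpoints are auto-detected (two-pass farthest-point
   search), the end zone is trimmed and re-grown by quadratic extrapolation of
   the interior curve until it exits the lumen (a straight tangent ray would
   flatten curved ends; the extension is capped because a long walk means the
   extrapolation is sliding along inside the lumen rather than exiting).

Accuracy on voxelized candy-cane phantoms (1 mm voxels): mean distance to the
true centerline ≈ 0.15 mm without noise, ≈ 0.3 mm at 0.3-voxel boundary
jitter.

## Cross-sections and diameters

At every 1 mm station, 90 full chords through the centerline point are cast at
2° increments in the perpendicular plane; each half-chord ends at the
sub-voxel 0.5-crossing of the trilinearly interpolated mask (ray step 0.2 mm).
The mean chord length is the station's "mean diameter"; the per-segment
maximum over stations is the segment diameter. "Mean radial spike length" is
interpreted as the mean of *full central chords* (not radii): the chords run
across the diameter through the centerline point, which for asymmetric
sections differs from twice the mean radius.

Stations whose centerline point falls outside the lumen are excluded with a
warning. Stations at the very cut face of an open tube see a partial-volume
boundary and read low by up to ~0.6 voxel; validation therefore evaluates
interior stations (≥ 2 mm from the openings). On elliptic sections the mean
chord agrees with a 10,000-angle numerical oracle to < 1%; on cylinders the
interior error is < 0.25 voxel.

## Curvature radius

The S1 (full ascending-segment) centerline is fitted by: total-least-squares
plane (SVD), projection, Kåsa algebraic circle fit, geometric least-squares
refinement. Degeneracy rule: an arc of radius R over chord c has sagitta
≈ c²/8R, so a maximum perpendicular deviation below c/80 (radius above 10×
chord) raises a "near-straight" error instead of returning an unstable radius;
this also catches exactly collinear input, where the algebraic system is
rank-deficient. Exact arcs in arbitrary 3D orientation are recovered to
float precision; voxelized phantoms over radii 30–60 mm recover within 2%
(≤ 1.5% typical) at 1 mm voxels and 0.3-voxel jitter. The residual noise
floor is set by centerline accuracy over the short S1 arc: a 0.2 mm sagitta
error on a ~60–90 mm arc is already ~1.5% of the radius.

## Regional PWV

Chords are placed at equal arc-length spacing (default 200, the protocol's
value); each chord's waveform is the per-phase maximum of its lumen samples.
Foot detection (intersecting-lines rule): the least-squares line through the
upstroke samples between 20% and 80% of peak (on the rising limb before the
global peak) is intersected with the pre-upstroke baseline level. The
baseline and its noise floor use the median/MAD of the pre-upstroke samples —
the last below-20% sample often sits on the ramp, and a mean would drag the
baseline up and the foot late. Waveforms with no credible upstroke (flat,
monotone-decreasing, or peak < 5× the baseline noise) are flagged and
excluded.

PWV per segment = 1 / slope of the OLS fit of foot time (s) on arc length
(m) — time is regressed on distance because distance is the low-noise
variable. One deterministic outlier pass removes chords whose residual
exceeds 3× the MAD. A non-positive slope is reported as invalid ("wave
appears to travel backward"), never as a negative speed.

With a piecewise-linear upstroke and zero noise the foot is sub-sample exact,
so recovery is exact despite 8.6 ms sampling; with 2 cm/s velocity noise and
200 chords, mean absolute error is ≈ 0.5–1.5% over 4–12 m/s (well inside the
5% acceptance bound).

## Flow displacement

FD = ‖velocity-weighted centroid of forward-flow (v > 0) pixels − unweighted
lumen centroid‖ / effective diameter, with effective diameter 2√(area/π).
The effective-circular definition was chosen because it is
orientation-independent and standard in the flow-displacement literature; for
flow confined to the lumen FD ≤ 0.5 by construction. Peak systole is the
phase of maximal net forward flow (sum of positive velocities × pixel area),
which is robust to single-pixel noise, unlike the raw peak velocity. Lumens
under 10 pixels or fields with no forward flow are rejected.

## Phantoms: what they emulate, and what they do not

* **Geometry.** A tube swept along a planar circular arc (ascending + arch)
  joined tangentially to a straight descending limb, optionally tilted out of
  the voxel axes, with an optional multiplicative radius profile (e.g. a
  Gaussian bulge) and flat end caps. Boundary noise is spatially correlated
  Gaussian jitter (~1 voxel correlation length) added to the signed distance
  before thresholding: correlated jitter displaces the wall without punching
  sub-voxel tunnels or cavities the way iid voxel noise does (iid jitter was
  tried and broke the tube's topology); any stray specks are removed by
  hole-filling and largest-component selection. Default 1 mm isotropic
  voxels (a choice — the original resampling resolution is not documented).
  Not emulated: patient-realistic anatomy, wall motion, intensity physics.
* **Waves.** v(s, t) = w(t − s/PWV) with a linear-upstroke/half-cosine-decay
  pulse (onset 60 ms, upstroke 80 ms, decay 200 ms, peak 100 cm/s < venc
  150 cm/s), sampled at 8.6 ms over 110 phases, plus white velocity noise
  (default SD 2 cm/s). Aliasing is simulated (wrap into (−venc, venc]) only
  on request. Not emulated: dispersion, reflections, background phase offsets.
* **Flow fields.** Circular lumen with a uniform-disk jet (truth
  |offset|/diameter is analytic) or an offset parabola clipped to the lumen
  (truth from a 10×-resolution grid oracle), optional retrograde sector and
  noise. Not emulated: realistic helical/vortical patterns.
* **Cohorts.** Covariates drawn from the published cohort's means/SDs;
  growth-rate outcomes generated by a stated linear model (defaults: −0.018
  mm/y per mm curvature radius on S1 diameter growth; +9.5 mm/y per unit FD
  on S1 length growth, intercepts and residual SDs set so the marginal growth
  means/SDs match the reported 0.40 ± 0.31 and 0.98 ± 0.83 mm/y). Follow-up
  measurements are back-computed as baseline + rate × interval, so the
  growth-rate computation is exercised end to end. Missingness is applied
  after generation, to measurement columns only. Not emulated: confounding
  structure between covariates, informative missingness, measurement error
  correlated across visits.

A green phantom test therefore establishes algorithmic correctness and
numerical stability on known geometry/kinematics — not clinical validity on
patient images.

## Statistics

Growth rates are Δ/interval per segment and measure; missing timepoints yield
missing rates, never zeros; non-positive intervals are errors. Group
comparisons use Welch's t-test by default (an `equal_var` flag restores the
pooled test), optionally age-adjusted via `outcome ~ group + age` with Marfan
coded 1. Screening fits `outcome ~ candidate` on complete cases and includes
a candidate iff p < 0.20; age and sex are always forced. Multivariable
models are OLS on complete cases with t-distribution p-values (appropriate at
the small n of such cohorts); rank deficiency is an error naming the
collinear predictors. No multiple-testing correction is applied, mirroring
the single p < 0.05 convention of the analysis being reproduced. Sex is
coded 0/1 (female/male), binary flags 0/1.

Recovery validation: 200 synthetic cohorts of n = 5000 give mean coefficient
estimates within 2 Monte-Carlo SEs of truth and 95% CI coverage of 93–95%.
At 200 replicates the binomial wobble on coverage is ±1.5%, so the 92–98%
acceptance band is attainable but not generous.

## Known limitations

* The centerline algorithm assumes an open tube with two ends; it rejects
  loops rather than handling fenestrations or dissection flaps.
* Diameter at the very cut faces of an open segmentation is not meaningful
  (partial-volume at the cap); callers should ignore the outermost station.
* The foot-detection rule is a documented, standard substitute; the original
  software's exact arrival-time algorithm is not public, so agreement with it
  cannot be claimed — only recovery of known phantom speeds.
* PWV assumes a single forward-travelling wave per segment; retrograde or
  multi-path propagation yields an "invalid" result, not a corrected one.
* The cohort generator draws covariates independently; it validates the
  estimation machinery, not robustness to real-world confounding.
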