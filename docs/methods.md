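# Methods

## Landmark model and conventions

A vertebral body is represented by its four corner landmarks AS, PS, AI,
PI (antero/postero × superior/inferior) as 2D points in the midsagittal
plane.  The internal coordinate convention is Cartesian with x increasing
anteriorly and y increasing superiorly; image-style y-down files are
negated at ingest (`read_landmarks(..., convention="y_down")`) so angle
signs are stable everywhere downstream.  Units are opaque: no mm/pixel
conversion exists anywhere because every metric is a ratio or an angle.
Vertebrae with fewer than four corner rows are dropped (and counted), not
imputed; geometric degeneracy (zero heights/widths) is detected at metric
computation and collected into a rejects report rather than aborting a
whole dataset.

## The six metrics

VBHR, EPWR, FBDR and HWR are length ratios of the corner distances; EPA
and PSA are angles computed with two-argument arctangents of cross/dot
products (never `acos`, which loses precision near 0° and 180°).
Conventions that the source measurements leave open are fixed as follows:

- **FBDR orientation.** The forward diagonal is AS↔PI and the backward
  diagonal PS↔AI, so an anterior-tall trapezoid (S1) has FBDR > 1.  The
  opposite pairing is available via `fbdr_orientation="reverse"` for
  sensitivity analyses.
- **EPA sign.** Positive when the endplates converge anteriorly
  (anterior wedging).  Consequently EPA and VBHR are near-perfectly
  *negatively* correlated on wedge-dominated variation.
- **PSA corner.** Measured at PS, between the rays PS→AS and PS→PI, as an
  unsigned interior angle in (0°, 180°).  A posterior wedge opens PSA
  above 90°, an anterior wedge closes it below 90°.
- **Orientation independence.** The EPA sign is referenced to the
  anatomy, not the coordinate frame: the anterior and superior directions
  are re-derived from the corner labels and the frame handedness term
  cancels, so a mirrored radiograph whose labels still track the anatomy
  yields bit-identical metrics.  This is asserted by tests under random
  similarity transforms (tolerance 1e−9) and label-preserving mirrors.

## Reference construction

Per (region, level) stratum:

1. **Trim** (single pass, no iteration): compute each metric's untrimmed
   mean and sample SD (n−1) and drop any vertebra with any of the six
   metrics outside mean ± k·SD, k = 2 by default.  A zero-SD metric
   imposes no exclusions.  k = ∞ is the identity.  Strata are pooled over
   sex/age/race: vertebral level dominates metric variability and
   covariates contribute little (the ANOVA module quantifies this).
2. **Tabulate** n, mean, SD, CV, skewness and kurtosis of the trimmed
   data per metric.  Skewness/kurtosis use the moment (biased)
   definitions with kurtosis non-excess (Gaussian → 3).  Degenerate
   (zero-SD) strata are flagged, with skewness/kurtosis reported as 0.
3. **Adjacent-level norms**: per subject, per adjacent pair, per metric,
   the difference caudal − cranial among trimming survivors; tabulated as
   mean, SD and the mean ± 1.96·SD normal range.  Computing these on
   trimmed rather than raw data is a deliberate choice: the norms should
   describe normal anatomy, not contaminated tails.

Z-scores use the trimmed μ and σ.  Because trimming narrows the SD,
re-scoring the reference population against its own trimmed moments flags
*more* than the 2-SD trim removed — the trimmed SDs are deliberately the
more sensitive yardstick.  Scoring a sample against its own untrimmed
moments gives per-stratum z-mean 0 and z-SD 1 to machine precision
(consistent n−1 denominators).

The level-threshold classifier picks, among midpoints of consecutive
sorted distinct metric values plus ±∞, the threshold minimizing total
misclassifications (ties broken toward the lowest threshold), and
reports the trapezoid-rule AUC of the full ROC curve.
Misclassification-minimal rather than Youden-optimal selection was
chosen; with near-balanced classes the two coincide, and the exhaustive
O(n²) search is kept in the tests as an oracle.

## Covariate analyses

ANOVA fits are ordinary least squares with vertebral level always
included as a dummy-coded factor; per-term importance uses partial
(Type II) F statistics, and the headline comparison is R² of the full
model versus a level-only refit.  PCA is an eigendecomposition of the
6×6 *correlation* matrix (the metrics mix unitless ratios and degrees,
so covariance PCA would be scale-dependent); eigenvalues sum to 6.
p-values are reported but never used for gating and no multiple-testing
correction is applied.

## Synthetic cohorts

After removing similarity (position, orientation, scale) a quadrilateral
has four shape degrees of freedom, parameterized here as (vbhr, epwr,
hwr, psa); EPA and FBDR are emergent.  `build_quadrilateral` constructs
the canonical shape — posterior wall vertical, Wi = 1, superior endplate
inclination fixed by psa — and solves the inferior endplate inclination
in (−30°, 30°) by Brent root finding (xtol 1e−14) so the anterior height
is exact; rebuild → re-measure round-trips to better than 1e−9.
Parameters with no root in that interval raise an infeasibility error;
cohort generation redraws up to 100 times.

Per-level Gaussian cores (truncated at ±4 SD) default to neutral
rectangles: vbhr 1.0 (SD 0.042), epwr 1.0 (SD 0.03), psa 90° (SD 1.0°),
hwr 0.9 lumbar / 0.75 cervical (SD 0.045), with two exceptions —
L5 vbhr 1.124 (so the caudal−cranial L4→L5 VBHR difference is 0.124 with
SD ≈ √2·0.042 ≈ 0.059) and S1 vbhr 1.15 with psa 100°.  The S1 psa
choice matters: the sacral superior endplate is inclined, which places
the anterior height surplus superiorly and pushes S1's FBDR to ≈ 1.11,
clearly above the lumbar range — with psa = 90° the builder would express
vbhr > 1 through the inferior endplate and FBDR would *fall*, which is
neither anatomic nor consistent with S1 being separable by a high-FBDR
threshold.  The psa SD of 1.0° keeps the FBDR coefficient of variation
below VBHR's, matching the qualitative CV ordering of real normative
data (PSA, FBDR, EPWR tightest).  These defaults are assumptions standing
in for population tables, exposed as configuration.

Contamination is a mixture over {none, anterior wedge, posterior wedge,
crush, endplate-width anomaly} applied geometrically: the severity factor
(default U(0.70, 0.85) for wedges/crush; U(1.15, 1.30) or its reciprocal
for width anomalies) scales the named height/width exactly by moving the
corresponding corner(s), so a wedge also perturbs EPA, PSA and HWR the
way a physical deformity does.  Ground truth (type, severity, pre-
transform metrics) is emitted alongside the landmarks.  Finally each
vertebra receives a random similarity transform (scale U(0.5, 2),
rotation U(−10°, 10°), translation U(−50, 50)², mirror with probability
0.1) under which all metrics are invariant by construction.

What the generator does **not** emulate: landmark placement noise
(corners are exact), within-subject correlation of shapes across levels
beyond the level means, osteophytes and endplate curvature, biconcave
(midpoint) deformities — which need six-point morphometry — and
realistic covariate–shape associations (covariates are drawn
independently of shape, so covariate ANOVAs on synthetic data test the
null machinery, not effect recovery).  Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and its
statistical behavior under the stated model, not the clinical validity
of any threshold.

## Projection simulation

A vertebra is modeled as a prism: the midsagittal quadrilateral swept
laterally by ±d.  A lateral radiograph is a central projection from a
point source (source–detector distance SID, object–detector distance
OID; SID = ∞ gives the parallel-beam limit), with out-of-plane pose as
an axial rotation about the superior axis followed by a tilt about the
anterior axis, both about the prism centroid.  Landmarks are then
re-derived exactly as on film: each corner is the midpoint of its left
and right projected images.  Consequences used as test anchors:

- zero pose: all eight corners of each left/right pair share one depth,
  so midshadow landmarks are a uniform magnification of the truth and
  all six metric errors are exactly zero, at any SID;
- metric errors are invariant to uniform detector rescaling
  (magnification independence);
- errors grow monotonically with |axial rotation| on the tested sweep
  (square section, SID 1000, OID 100, d 20, rotation 0–15°);
- errors are even functions of pose for the laterally symmetric prism in
  the parallel-beam limit; a point source adds a small odd component of
  order d·sinθ/SID, because ±θ sends the two lateral corners to
  different depths and hence different magnifications.

The prism ignores uncinate processes and endplate rim curvature; the
shadows of a real endplate are curves, not points, so this module bounds
pose-induced error for an idealized body rather than reproducing any
measured error table.  DXA beam geometries (pencil/fan) are out of scope.

## Numerical and testing choices

- Tolerances: geometric identities and invariances are asserted at 1e−9;
  root finding at 1e−14; Monte-Carlo assertions use 3–4 SE binomial or
  CLT bands at the stated n.
- Problem sizes: the test suite and the acceptance script use cohorts of
  up to 2,000 subjects × 6 levels and Gaussian samples of 10⁵, chosen so
  sampling bands are tight relative to the effects being checked while
  the whole suite runs in well under a minute per heavy test.
- Determinism: every stochastic path takes a single integer seed through
  `numpy.random.default_rng`; the acceptance script derives independent
  child seeds via `SeedSequence.spawn`.
- Known limitations: single-pass trimming makes reference SDs shrink by
  a truncation factor (≈4–8% at k = 2 under 5% gross contamination);
  this is inherent to the method and is why the trimmed SDs are the more
  sensitive screening yardstick.  Reference means are essentially
  unbiased because trimming is symmetric about the stratum mean.
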