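# Methods

## Thin-wall biaxial mechanics

The mechanics layer treats the artery as an incompressible thin-walled
cylinder at a fixed axial stretch. Its assumptions, in decreasing order of
importance:

* **Incompressibility.** Wall volume is conserved, so the deformed inner
  radius follows from the measured outer radius and the reference wall area:
  ri = sqrt(ro² − (Ro² − Ri²)/λz). Every processed point is checked against
  this identity (relative tolerance 1e−9 in the tests; in practice the error
  is at rounding level, ~1e−16).
* **Thin-wall (Laplace) equilibrium.** Stresses are mean values across the
  wall: σθ = P·ri/(ro − ri) and σz = (fT + P·π·ri²)/(π·(ro − ri)(ri + ro)).
  No transmural stress distribution, residual stress or opening angle is
  modeled.
* **Mid-wall stretch.** λθ = (ro + ri)/(Ro + Ri), the mean-radius ratio.
* **Units.** Lengths mm, forces mN, pressures mmHg at the interface and kPa
  internally (1 mmHg = 0.133322 kPa). With these units stresses come out in
  kPa with no further constants, which is why the readers validate units from
  column names rather than guessing.

### Stretch normalization and the exponential fit

Circumferential stretch is normalized by its value at the zero-pressure
point of the same cycle, so every curve starts at (1, 0). Real exports rarely
log exactly 0 mmHg; a point within ±0.5 mmHg (configurable) is accepted as
the anchor, and a missing anchor is an error rather than a silent
extrapolation.

The stiffening response is fitted with σ(λ) = a·(exp(b(λ−1)) − 1). This form
passes through (1, 0), matching the normalized zero-pressure anchor — an
exponential with a free offset would not. The fit is a Levenberg–Marquardt
least-squares with a fixed initial guess (a = 1 kPa, b = 1) and tolerance
1e−10, so results are bit-reproducible. Near-linear data drives the
optimizer along the a·b ≈ const ridge (a large, b → 0) without formally
converging; when that happens with a residual below 1e−5 of the data range,
the best-found parameters are returned (small b is the honest description of
linear data, not a failure). Tangent stiffness is the analytic derivative
a·b·exp(b(λ−1)) of the fitted form, never a numerical derivative of raw
data, and is reported at a pressure by linearly interpolating the recorded
pressure–stretch pairs.

Both stress components are fitted against the same normalized
circumferential stretch axis; the `direction` argument only selects the
stress series. Normalizing the longitudinal axis independently would be a
one-line change but is not the default.

### In-vivo axial stretch

"Force variation minimized during inflation" is implemented as the variance
of fT over the pressure ramp, the standard flatness measure; range or
max−min would order the same synthetic candidates identically but variance
is smooth under noise. Ties break toward the smaller stretch so the estimate
is deterministic.

## Empty-band quantification

The image layer expects a grayscale maximum-intensity projection with the
wall aligned vertically (radial axis horizontal); rotation/alignment is a
preprocessing step, not auto-detected. Binarization is Otsu by default, or a
fixed threshold; foreground means elastin signal regardless of display
polarity. The region of interest is discretized into a 30×30 grid; the grid
uses equal floor-size cells with remainder pixels attached to the last
row/column — deterministic and area-conserving. Column width in μm derives
from the ROI width, not the full field of view.

The band cutoff is media mean − 2·media SD of the column area fractions
(floored at 0). With the bundled group-level media statistics (0.318,
0.085) this is 0.148. The media is the statistics source because those
printed group numbers satisfy exactly that arithmetic; pooled media +
adventitia statistics can be supplied instead. Columns below the cutoff in
the window from media start to adventitia end are flagged; the band is the
longest contiguous flagged run (a band is contiguous by definition; the
first run wins a length tie), and its width is run length × column width.
Media/adventitia column ranges are user-declared — layer segmentation is out
of scope. Per-sample width averages the calls from four measurement
locations (fewer allowed, with a warning).

The method's resolution is one grid column (425 μm field of view → 14.17
μm); recovered widths on synthetic images are accurate to that resolution,
no better.

## Cohort and abundance statistics

Summaries report mean, sample SD (n−1) and SEM. The bundled cohort table's
printed group SDs match the n−1 convention, which fixed the choice. Ages are
summarized per donor and wall dimensions per segment, because donors
contribute multiple segments; `summarize_cohort` handles the two units
explicitly. The default two-sample test is the pooled-variance Student t
(Welch available); one-way ANOVA is the standard F test, with the degenerate
all-constant case mapped to (F = 0, p = 1) instead of NaN. Collagen
abundances are re-expressed per sample as percentages of the sample's total
collagen before testing; Bonferroni adjustment is min(1, p·m) with the
comparison family size m set by the caller — it is never inferred from the
data.

## Synthetic generators

The generators exist to give every stage a ground truth; they aim at
testability, not biophysical fidelity.

* **Inflation** uses σθ = aθ(exp(bθ(λθ−1))−1) (defaults aθ = 5 kPa,
  bθ = 12, values that put stresses and stiffness in the physiological range
  for cerebral arteries at 0–80 mmHg). For each pressure the deformed outer
  radius is the bracketed Brent root of thin-wall equilibrium (bracket: just
  above the incompressibility bound, where the law is compressive and the
  Laplace term vanishes, up to 3·Ro, doubled until the exponential stress
  dominates; tolerance 1e−13). Because the generator enforces the same
  equilibrium the analysis inverts, the noiseless round trip recovers
  (aθ, bθ) to ~1e−13 — the tests require 1e−6.
* **Axial force** is built directly on the classical observation that at the
  in-vivo stretch the wall carries the pressure thrust exactly, so the
  transducer force is constant during inflation: fT = A_w·a_z(exp(b_z(λz−1))−1)
  + κ·(λz − λz*)·P·π·ri², with A_w the deformed wall cross-section (constant
  in P by incompressibility) and κ a dimensionless gain (default 1). Force
  variance over the ramp is then exactly zero at λz* and grows
  quadratically away from it, which makes the variance criterion's ground
  truth unambiguous. An earlier sketch with a linear λθ coupling in σz was
  discarded: it does not pin the variance minimum to λz* across candidates.
* **Wall images** place vertically elongated elliptical blobs (semi-axes
  10–25 px by 1–2.5 px) in media and adventitia strips until each strip's
  binary area fraction reaches its target (defaults 0.318 / 0.478, the
  bundled group-level values), with a zero-signal gap strip of specified
  width between them, distributed over z-planes with Gaussian background
  noise. Default canvas 510×510 px at 425/510 μm/px, i.e. a 425 μm field of
  view with exact 17-px grid cells. What this does **not** emulate: fiber
  waviness and crossing, intensity falloff with depth, the internal elastic
  lamella, partial-volume edges, or any collagen channel — so passing the
  recovery tests shows the grid/threshold logic is correct at the method's
  one-column resolution, not that real images segment this cleanly.
* **Cohorts and abundances** are truncated-Gaussian and lognormal draws
  around specified group parameters (defaults: the bundled cohort's group
  means/SDs; composition defaults sum to 100). With dispersion 0 they
  reproduce their parameters exactly, which anchors the statistics tests.

All generators are bit-reproducible under a fixed seed
(`numpy.random.default_rng`).

## Problem sizes and numerical choices

Simulation studies use 100 fit replicates, 50 stretch-sweep replicates,
2000 null replicates for test calibration, 1000 random states for the
kinematics oracle, and three gap widths (15/30/45 μm) for image recovery —
sizes at which the Monte-Carlo tolerances quoted in the tests (±2 percentage
points on a 5% rate; median fit error < 15%) are comfortably stable across
seeds.

## Known limitations

* Thin-wall mean stresses only; no constitutive inverse identification
  beyond the phenomenological exponential, no viscoelasticity, no
  preconditioning simulation.
* The band quantifier needs user-declared layer ranges and pre-aligned
  images; its width resolution is one grid column.
* The bundled collagen table is group-level (means/SDs); per-sample
  proteomics, FDR machinery and enrichment analysis are out of scope.
* Whether the four band measurement locations are four images or four ROIs
  of one image is not fixed; both work.
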