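# Methods

`ecmquant` quantifies five assays used to study how dermal extracellular
matrix (ECM) remodelling conditions melanoma invasion: spheroid invasion
imaging, ECM fibre orientation, DQ-collagen degradation, AFM surface
roughness, and expression-signature survival scoring.  Each stage is paired
with a synthetic-data generator that plants known ground truth, so every
estimate the package produces can be validated quantitatively without access
to the original microscopes or cohorts.

## Spheroid invasion

**Model.** A tumour spheroid embedded in collagen is imaged in a nuclear
(Hoechst) channel as a z-stack.  The quantification pipeline is: maximal
intensity projection → flatfield correction → Gaussian blur (σ = 2 px) →
layered segmentation into *core* and *invasive area* → invasive-area
percentage and a count of individually invading cells.

**Flatfield.** Shading is modelled as a multiplicative planar ramp and
estimated by a least-squares plane through the image, normalised to mean 1;
the image is divided by it.  This preserves the image mean to <1%, is
idempotent to <1%, and in the tests reduces the coefficient of variation of
a ramp-shaded flat field by well over fivefold.  A
plane is deliberately the simplest shading model that captures the dominant
gradient; higher-order shading would require a richer basis.

**Segmentation.** Intensities are normalised so the background median is 0
and the bright plateau (99.5th percentile) is 1 — making all masks exactly
invariant under positive intensity rescaling.  The core is the largest
connected component of the half-maximum level set after morphological
closing, hole filling, and an opening with a disc of radius 10 px that
strips thin protrusions; if nothing survives the opening the field contains
no spheroid and the call fails.  Otsu's threshold is evaluated first purely
as a foreground-existence check.

The invasive area is measured at a *blur-compensated isophote*.  A nucleus
is modelled as a Gaussian spot of σ_s = r/2 (r the nucleus radius, a user
parameter like the cell-diameter settings of high-content software).  After
the pipeline blur σ_b, an isolated nucleus has peak height
p = σ_s²/(σ_s²+σ_b²) and its contour at level p·2^(−σ_s²/(σ_s²+σ_b²))
coincides with the nucleus' own full-width-half-maximum footprint, so blob
areas are not inflated by smoothing.  The peak height is calibrated per
image as the median intensity of nuclei detected outside the core.  Before
thresholding, a greyscale opening with a disc of 2r removes the smooth
pedestal that overlapping nuclear tails create under dense halos; without
it, crowded regions measure systematically wide.  Foreground components are
then chained to the core through gaps of at most 5 nucleus radii, the
chained region minus the core (and minus the 1 px band at the core's own
contour) is the invasive area, and the perimeter is the 1 px boundary of
core ∪ invasion.

**Invasive-area percentage** is 100·|invasion|/(|core|+|invasion|).  The
assay description does not state whether the "total size of the spheroid"
includes the invasive area; the denominator is configurable
(`total="core"`) and the core+invasion default is used throughout.

**Single cells.** Candidate nuclei are local maxima outside the (dilated)
spheroid region.  Candidates are split at the first *radial moat*: walking
outward from the spheroid's radial extent, the first gap of ≥ 6 nucleus
radii in candidate radii separates stragglers of a sparse invasive halo
(which belong to the invasive cloud, not the single-cell population) from
truly isolated invading cells.  The moat rule is what keeps the measured
single-cell count monotone when the planted invading population is scaled
down: at low densities a scattered halo would otherwise masquerade as
dozens of "single cells".  It presumes a roughly centred, radially coherent
spheroid — true for this assay, not for arbitrary images.

**Synthetic fields.** The generator renders a dense core disc, halo nuclei
area-uniform in an annulus, and isolated nuclei beyond an exclusion radius;
nuclei are Gaussian spots (σ = r/2, truncated at 3σ) blended by per-pixel
maximum (fluorescence saturates rather than sums in a dense core), under a
planar illumination ramp and additive Gaussian noise (snr = peak/σ).  The
ground-truth "halo coverage" is the union of FWHM discs of the planted
nuclei outside the core disc.  Reference study conditions, chosen once as
representative of the assay: 384² px fields, core radius 40–70 px, halo
outer radius 100–150 px with 100–300 halo nuclei, 10–30 single cells at
≥ 40 px beyond the halo (the moat), nucleus radius 4–6 px, snr 5–10,
illumination amplitude ≤ 0.3.  Under these conditions the pipeline recovers
the invasive-area percentage with a median absolute error of ~2–3
percentage points and matches planted single cells with median F1 = 1.0.

What the generator does *not* emulate: overlapping spheroids, anisotropic
protrusion morphology, out-of-focus haze, or camera noise statistics other
than additive Gaussian — so passing tests demonstrate correctness of the
measurement chain, not robustness to every real-microscope artefact.

## Fibre orientation

Per-pixel orientation comes from the structure tensor: the image is
pre-smoothed (σ = 1 px), gradients are taken by central differences, and
J = ⟨∇I ∇Iᵀ⟩ is averaged in a Gaussian window (σ = 2 px; the plugin this
emulates names no parameters).  The fibre axis is
θ = ½·atan2(2Jxy, Jxx−Jyy) + 90°, axial in (−90°, 90°], measured from +x
towards +y with y up.  Pixels are weighted by tensor energy (Jxx+Jyy) by
default; coherence weighting is a switch, since which weighting the
original analysis used is not recorded.  A constant image yields zero
weight everywhere and a warning rather than an error.

The orientation distribution is the weight-weighted histogram over
(−90°, 90°] (1° bins), the mode is the bin centre of maximal mass (ties →
smallest angle), and the **aligned fraction** is the mass within ±10° of
the mode, circularly with period 180°, counting bins whose centres fall in
the window inclusive — 21 bins at 1° width, so the continuous-uniform
baseline is 21/180 ≈ 0.117 rather than 20/180 ≈ 0.111; the tolerance used
in validation (±0.01) covers both conventions.  Synthetic fibre fields draw
axial angles from a von Mises distribution on the doubled angle 2θ (κ = 0
uniform) and render anti-aliased segments; stripe fields provide exact
single-orientation oracles (modal error ≤ 0.5° including wrap-around at
±90°).

## DQ-collagen degradation

Degradation of a quenched-fluorescein collagen substrate abolishes local
fluorescence.  Two quantifications:

1. **Area per cell** — pixels below half the robust background intensity
   (median of the cell-free border frame), divided by the nucleus count
   from blob detection.
2. **H-score** — each cell's peri-cytoplasmic degradation ring is classified
   low/medium/high by its ring-width/cytoplasm-diameter ratio (anchors
   <1/4, ~1/3, ~1/2; class boundaries are the anchor midpoints c12 = 0.29,
   c23 = 0.42, configurable since only the anchors are stated), and
   H = (1·n_low + 2·n_medium + 3·n_high)/n_total ∈ [1, 3].  Conditions are
   compared as ratios of H-scores.  Ring width is recovered from the
   degraded annulus area assigned to each cell by nearest-cell distance:
   w = √(R² + A/π) − R with R the equivalent cytoplasm radius.  Scoring can
   aggregate per cell (default) or per image (`per="image"`), since the
   original protocol is ambiguous about what the human assessors rated.

The generator lays cells on a jittered grid (no overlapping rings),
cytoplasm diameter 30 px, ring ratios drawn per class from
U(0.12, 0.22) / U(0.30, 0.36) / U(0.45, 0.55) — inside the anchor ranges and
clear of the class boundaries, so classification errors reflect measurement
noise, not label ambiguity.  At 300 cells the recovered H is within ~0.03
of the mixture expectation 1p₁+2p₂+3p₃ (the ±0.1 validation band mostly
absorbs the multinomial sampling noise of the draw itself, whose standard
deviation is ≈ 0.045 at n = 300).

**SHG intensity** is the mean of the z-stack *sum* projection in three
equal, non-overlapping grid ROIs.  **AFM roughness** is
Rq = √(mean((z−z̄)²)); no tilt correction by default (the protocol describes
none), with least-squares plane levelling as an option.  Closed-form
checks: constant → 0, ±A two-level → A exactly, sinusoid over integer
periods → A/√2.

## Expression and survival scoring

qPCR relative expression is 2^−ΔCt with ΔCt = Ct_target −
mean(Ct_housekeepers); the arithmetic mean of Ct values implements the
geometric mean of housekeeper expression.  The fibroblast-signature (MAF)
score of a sample is the geometric mean of its signature-gene values taken
directly on the log2(x+1)-normalised matrix (matching how the score is
defined on public cohort matrices); genes absent from the matrix are
dropped with a warning, and non-positive values are floored at ε = 0.01 —
the convention for zeros is otherwise unspecified.  Cohorts are split at
the median score with ties going to "low" (deterministic, and invariant
under strictly monotone transforms of the score).  Collagen genes
(symbols matching `^COL\d`) can be stripped from a signature, returning the
removed list for audit.  Histology binarisation: solar elastosis on the
11-point 0…3+ ladder (indices 0–10) splits noCSD (≤ "2−", index 5) from
CSD (≥ "2", index 6); invasion scores 0–4 split low (≤2) from high (≥3).
No canonical signature gene list ships with the package; any list file is
accepted, and the simulated `SIG*` genes are a synthetic stand-in.

The survival simulator plants an exact half/half high/low split with the
signature shifted by 2 within-group standard deviations, exponential event
times with a hazard ratio of 2 for the true-high half (baseline hazard 0.1,
n = 200), and 20% independent censoring.  Kaplan–Meier curves and the
log-rank test come from `lifelines`; validation checks that the median
split recovers the planted groups (≥90% agreement) and rejects the log-rank
null in ≥80 of 100 seeded cohorts.  This exercises the scoring machinery
only — it says nothing about the prognostic value of any real signature.

## Numerical and design notes

- All randomness flows from one explicit integer seed per generator call
  (`numpy.random.default_rng`); no global state, so identical specs give
  bit-identical outputs.
- Angles at exactly −90° are mapped to +90°; histogram bins are
  left-closed, right-open except the last.
- `segment_spheroid` raises `"no spheroid detected"` on blank/contrastless
  images and on fields where nothing survives the core opening.
- H-score, ring classification and Rq reject empty inputs rather than
  returning NaN.
- Problem sizes used in validation (20 spheroid fields at 384², 10⁵ angle
  draws, 300 degradation cells, 100 simulated cohorts) were chosen to give
  stable statistics at desk scale; the same code runs unchanged on larger
  fields.

## Known limitations

- The radial-moat single-cell rule assumes a single, roughly centred
  spheroid per field.
- The planar flatfield model will under-correct bowl-shaped vignetting.
- Ring measurement assumes non-overlapping degradation annuli; confluent
  cultures would need a watershed-style assignment.
- The orientation estimator reports one axis per pixel; crossing fibre
  lattices are summarised by their dominant axis.
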