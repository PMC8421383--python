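# Methods

## The measurement model

The endolymphatic-hydrops (EH) ratio of an inner-ear structure is the share
of its fluid space occupied by endolymph. The package implements the two
routes by which that share is measured in practice:

* **Negative-pixel counting on MRI.** After intravenous gadolinium the
  perilymph enhances on a heavily T2-weighted 3D-FLAIR image (PPI) while the
  endolymph stays dark; an inversion-recovery acquisition with a shorter
  inversion time (PEI) reverses the contrast. Their difference (HYDROPS)
  is therefore positive in perilymph and negative in endolymph, and
  multiplying by the cisternographic MRC image (HYDROPS-Mi2) suppresses
  non-fluid background — MRC ≈ 0 outside fluid — while preserving sign.
  The EH ratio of an ROI is the count of strictly negative HYDROPS-Mi2
  pixels over the ROI pixel count. Zero-valued pixels count as
  non-endolymph: zeros arise from background and from MRC = 0, where the
  product's sign carries no information. Counting always uses raw composed
  values; the window/level display transform (defaults 400/1000) exists only
  for figure export, because windowing destroys sign.
* **Area ratios on histology.** On a labeled section, areas are label pixel
  counts times pixel area. The cochlear ratio sums the scala-media areas of
  the basal, middle and apical turns and divides by the whole cochlear fluid
  area; vestibular ratios divide saccule and utricle areas by the entire
  vestibule area (combined = saccular + utricular exactly, because the
  labels partition the vestibule); canal ratios divide the membranous duct
  by the canal cross-section. The canal ratio is implemented as duct over
  cross-section — the orientation that keeps values inside [0, 1] and
  matches the reported range of canal ratios (≈ 0.46–0.57) — even though
  the ratio could be written either way round.

ROI slices follow reproducible rules. Cochlea: among slices showing all
three turn labels, take the one with the largest in-plane modiolus pixel
count (ties to the lower slice). "Greatest modiolus height" is
operationalized as pixel count because extent in pixels is reproducible and
monotone in size on an axial grid. Vestibule: take the lowest slice — slice
order along the configured inferior axis, default ascending last axis — on
which the lateral-canal ring is visible over **more than** 240° of arc
(strict inequality), then remove ampulla pixels from the vestibular ROI.
Arc coverage uses 1° bins around the in-plane centroid of the full 3D ring;
a bin counts as covered when any mask pixel's corner-to-corner angular
extent intersects it, which makes a geometrically complete annulus measure
exactly 360° even where a 1° bin is narrower than one pixel.

## The phantom

The synthetic ear is deliberately stylized; the validated quantities are
area *fractions*, not anatomical shapes.

* **Cochlea**: three concentric turn annuli (basal outermost) around a
  central modiolus disk whose radius peaks at the representative slice and
  tapers on neighbours. Each turn carries a scala-media sector of angular
  span 360° × fraction, so the scala-media share of the total turn area
  equals the requested fraction by construction. The whole-cochlea
  denominator is the three fluid turns, excluding the modiolus core, on
  both measurement routes; this keeps the degenerate "everything is scala
  media" case representable and gives both routes the same ground truth.
* **Vestibule**: an ellipse split by a vertical chord positioned so the
  free (perilymphatic) share is balanced between the sides; saccule and
  utricle are the two chord segments shrunk about their own centroids, so
  each organ's vestibule-area share is exact and the organs stay disjoint
  and inside the vestibule for any pair of fractions summing below one.
* **Lateral canal**: an annulus whose visible arc span grows with slice
  (defaults 140°…360° across the vestibule slices, crossing the 240°
  criterion at a known slice), an elliptical ampulla on the ring rotated
  45° off the vestibule direction, and a rectangular "canal territory"
  connecting the vestibule boundary to the ring. Herniation is rendered as
  a disk-shaped protrusion of the organ label into the territory, with
  radius 20% of the outer ring radius; detection flags an organ when its
  overlap with the territory reaches a configurable pixel minimum
  (default 1 — any protrusion counts). Only the lateral canal exists in
  the 3D volume (it is the only canal any selection rule uses); anterior
  and posterior canals appear as 2D cross-sections, modeled as a lumen
  ellipse (larger and elliptical at ampullary sites) containing a
  concentric duct scaled to the requested area fraction.

Rasterization evaluates the analytic geometry at 4× (MR volumes) or 8×
(histology sections) supersampling and assigns each pixel the majority
subsample label, keeping area bias well below one boundary-pixel row; each
region's generating polygon is attached to the section as area ground
truth. MR signals are per-tissue-class means (defaults, arbitrary units:
MRC 0/600/450, PPI 5/400/20, PEI 5/20/400 for bone/perilymph/endolymph)
plus independent Gaussian noise (default SD 20, ≈ 5% of the
perilymph–endolymph split). The signal model enforces the contrast logic
(perilymph positive and endolymph negative after subtraction, fluid bright
on MRC); Gaussian rather than Rician noise is used because the pipeline
consumes only the sign of a large subtraction and no noise model is
otherwise constrained.

## Cohort sampling

Per-ear true fractions are normal draws clipped to (0.001, 0.999).
Clipping (mass at the bounds) rather than hard truncation was chosen
because it perturbs the mean far less at the group parameters in play.
Because any bounding scheme still biases means slightly — and the
generator's contract is that cohort means converge to the requested group
parameters — the sampler is mean-compensated: the proposal mean solving
E[clip(N(m, sd))] = target is found in closed form, and the
saccule/utricle pair (whose sum must stay below 1 to fit in the vestibule)
uses a deterministic fixed-point calibration of both proposal means under
its rescaling rule: a drawn pair summing to ≥ 0.98 is rescaled
proportionally, preserving the saccule:utricle ratio. Realized marginal
means match the requested ones to ≈ 0.002 at n = 20 000. Group SDs come
out slightly compressed (≈ 0.18 realized vs 0.214 requested for the
saccule) — the cost of confining the pair to the unit simplex. The
vestibular distribution can alternatively be specified as a combined
fraction split in a fixed saccular share (default 0.513/0.755 ≈ 0.68),
which is how the MRI-population cohort is parameterized, since that
population's vestibular ratio is reported only combined.

Reference cohorts encode the two study populations: a temporal-bone series
(54 affected ears with cochlear 0.314 ± 0.118, saccular 0.513 ± 0.214,
utricular 0.242 ± 0.124, ampullary canal ratios 0.565/0.511/0.518 ± SDs,
saccular herniation probability 15/54 and utricular 9/54; 18 unaffected
ears with canal ratios 0.515/0.456/0.491; 17 control ears with cochlear
0.064 ± 0.022 and combined vestibular 0.289 ± 0.062) and an MRI series
(72 affected ears, cochlear 0.372 ± 0.164, vestibular 0.533 ± 0.250,
extension probability 29/72). Non-ampullary canal parameters reuse the
ampullary values, and control canal parameters reuse the unaffected ones,
since separate figures are not reported for them. Reported patient counts
are internally inconsistent in places (e.g. ear-versus-patient totals), so
cohort sizes are always explicit configuration, never derived.

## Statistics

Two-group comparisons run Shapiro–Wilk on each sample at α = 0.05; if both
pass, Welch's unequal-variance t-test, else Mann–Whitney U, both
two-sided, with every intermediate (normality p-values, branch, statistic)
recorded. Welch was preferred over Student's t because group SDs here
differ up to five-fold. A zero-variance sample routes to Mann–Whitney: the
Shapiro–Wilk statistic is undefined on constants (scipy returns p = 1.0
there, which would nonsensically certify normality). No multiple-testing
correction is applied; the validation report prints raw p-values, one row
per configured comparison.

A caveat the simulations make explicit: with groups simulated as
independent normals at the reported summary statistics, the
histology-vs-MRI cochlear comparison (0.372 ± 0.164, n = 72 vs
0.314 ± 0.118, n = 54) comes out *significant* in roughly 60% of seeds,
and the ampullary anterior-canal affected-vs-unaffected comparison in
roughly 80% — the non-significance of these comparisons in the source data
is a property of those particular samples that summary statistics alone do
not reproduce. The validation suite therefore asserts the robust findings
(affected-vs-control and saccule-vs-utricle at p < 0.001 in every seeded
replication) and records, rather than asserts, the fragile ones.

## Problem sizes and numerical choices

Defaults: 160 × 160 × 12 voxel grids at 0.5 × 0.5 × 1.0 mm; histology
sections 160 × 160 pixels at 8× supersampling. The reproduction script
renders full cohorts at the reported sample sizes (54/17/72 ears) and
completes in a few minutes on one CPU. Degenerate inputs raise rather than
warn: clipped geometry names the structure that does not fit, empty ROIs,
zero-area denominators and undersized groups (n < 3) are errors.
Deterministic tie-breaks throughout: majority-vote rasterization resolves
ties toward the smaller label value, cochlear slice ties toward the lower
slice index.

## What the phantom does and does not establish

Passing tests demonstrate that the measurement pipeline is exact on its
own geometry: counting is bit-faithful against brute-force oracles, area
ratios recover generating fractions to the third decimal, the slice rules
fire on the constructed slice, and group statistics recover generating
parameters within sampling error. The phantom does not emulate partial
volume beyond supersampled rasterization, intensity inhomogeneity,
registration error between contrasts, reader variability in manual
contouring, or realistic cochlear spiral anatomy — so agreement on the
phantom bounds algorithmic error only, not the full error of the clinical
measurement.
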