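# Methods

`barrelpaint` models DNA-origami barrels — cylindrical "3D pegboard"
origami presenting addressable docking sites on their surfaces — and
reimplements the quantitative analysis chain used to characterise them
by Exchange-PAINT super-resolution microscopy and negative-stain TEM.
Because no experimental data are bundled, every estimator is validated
by parameter recovery on synthetic data whose ground truth is known
exactly.

## Barrel geometry

A barrel monomer is three concentric layers of circular double helices
(outer, inner-middle, inner), described by their helix mid-point
diameters. With a duplex thickness of 2.6 nm, the external diameter is
the outer mid-point diameter plus one thickness and the cavity diameter
is the inner mid-point diameter minus one thickness; for the 90-nm
class (mid-points 84 / 81.5 / 76.5 nm) this gives 87 nm external and
74 nm cavity. Reported designed dimensions are rounded to the nearest
nanometre; the exact values remain retrievable.

Only the 90-nm class has published layer diameters. For the 30- and
60-nm presets the outer mid-point is back-computed from the designed
external diameter (31, 60 nm) minus one helix thickness, and the other
layers use the same inter-layer gaps as the 90-nm class (2.5 and
5.0 nm). Preset metadata marks these entries `back_computed`.

Pixel sites form a rhombic lattice on each cylindrical surface: rows
of equally spaced sites at fixed z, with consecutive rows offset by
half an azimuthal step and separated by `pitch * sqrt(3)/2`, so every
interior site has six nearest neighbours at roughly the 8-nm pitch.
Exact per-row site counts cannot be derived without the strand
routing, so they are preset parameters (default: circumference /
pitch, rounded). Monomer names ("90-23") carry the designed monomer
height; the per-monomer axial repeat of the polymerised class (21 nm
for the 90-nm class, 29 nm for 60, 62 nm for 30) is stored separately
as `polymer_monomer_height` because neither value is derivable from
the other. Coaxial stacks place monomer k at axial offset k times the
monomer height, so the alpha-beta repeat is twice the monomer height
(58 nm for the 60-nm class, 42 nm for the 90-nm class).

Mass and concentration arithmetic (n-mer mass = n x monomer mass;
molarity from A260 using the 50 ug/mL double-stranded-DNA convention)
is included because assembly yields are quantified that way.

## Synthetic Exchange-PAINT data

The simulator emulates the statistical structure the processing chain
relies on, not the raw camera images:

* **Labeling.** Each docking site is occupied independently with
  probability `labeling_p` (default 0.71, the typical measured staple
  availability; recovery scenarios that need full decoration set 1.0).
* **Blinking.** Binding events per occupied site arrive as a Poisson
  process (`binding_rate` per frame) with geometric bright times
  (`mean_bright_time` frames); each bright frame yields one
  localization. Defaults (0.01 /frame/site, 2 frames, 2000 frames)
  put the simulation in the event-rich regime of practical DNA-PAINT
  movies — tens of short events per site. This matters: with only a
  handful of long events per site, per-site localization counts are so
  over-dispersed that the count-weighted centre of mass of a 6-site
  ring wanders by several nanometres, which blurs and measurably
  shrinks a centre-of-mass-aligned sum image. That is a property of
  sparse movies, not of the estimators.
* **Noise.** Localization errors are isotropic Gaussians: `sigma_xy`
  (default 4 nm, inside the 3.6-6.3 nm NeNA range the analysis is
  meant for) and `sigma_z` (default 7.2 nm, i.e. a 17-nm z FWHM).
  z is generated directly rather than through astigmatic width
  fitting: the downstream analysis consumes (x, y, z) localizations,
  and direct z keeps the ground truth exact. Photon counts and fitted
  widths are decorative (log-normal / Gaussian) since no estimator
  uses them.
* **Drift and misregistration.** Stage drift is a Gaussian random walk
  per round (what redundant cross-correlation is designed to remove);
  each non-reference round additionally gets a rigid offset and small
  rotation about the field centre, emulating Exchange-PAINT round
  changes.
* **Markers.** Registration markers are compact clusters of always-on
  sites with a 10x event rate, placed at fixed world positions and
  subject to the same drift and round transforms.
* **Placement.** Particles are placed uniformly at random without
  overlap (minimum separation twice the external diameter). Upright
  particles stand with the barrel axis along optical z; sideways
  particles lie with the axis in the image plane at a random
  direction.

What the generator does *not* emulate: PSF shape and spot fitting,
photophysics beyond first-order kinetics, imager depletion,
non-specific binding, and sample tilt. Passing recovery tests
therefore demonstrate that the estimators are correct and unbiased
under the stated noise model, not that they are robust to every
artifact of real data.

## Processing

* **Rendering** is 2D histogramming; bin size is `base_pixel /
  oversampling` with a 100-nm base pixel, so the oversampling-10 and
  -20 steps of the averaging schedule use 10- and 5-nm bins.
* **Drift correction** splits the movie into temporal segments
  (default 250 frames), renders each, measures all pairwise shifts by
  FFT cross-correlation with quadratic sub-bin peak interpolation, and
  solves the over-determined shift system by least squares — the
  redundancy averages down shift-estimation noise relative to chaining
  consecutive segments. Per-frame drift is linearly interpolated
  between segment centres and linearly extrapolated at the movie ends;
  the trace is anchored to zero at frame 0.
* **Picking** renders coarsely (bin = pick radius / 2), smooths, takes
  local maxima as candidates, refines each centre to the member centre
  of mass, keeps candidates with at least `min_locs` members and
  enforces non-overlap greedily by member count. This is a
  deterministic stand-in for interactive pick curation; callers may
  apply a keep-list.
* **Round alignment** is two-stage: coarse xy alignment of whole-round
  renders by cross-correlation against the reference round, then fine
  xyz alignment from the mean displacement of matched registration
  marker centres of mass.
* **Averaging** iterates over a schedule of (plane, oversampling)
  steps; in each pass every particle is cross-correlated against the
  sum of the others (over translations, and over a grid of rotations
  about z during xy steps) and moved to the argmax. Shifts are applied
  in whole render bins, which makes each move an exact coordinate
  ascent on the total pairwise image-overlap objective; that objective
  is logged each iteration and asserted non-decreasing. Sub-bin
  precision comes from increasing oversampling along the schedule, not
  from peak interpolation. Rotation search is restricted to the
  barrel/optical axis; there is no 3D rotation search, matching the
  plane-wise procedure. Ties in correlation go to the first (smallest
  shift/angle) candidate.
* **Joint round rotation** scores every round against a target over an
  angle grid, sums the normalized correlation over rounds per angle,
  and applies the single best angle to all rounds so their relative
  alignment is preserved; ties go to the smallest angle.

No processing step creates or drops localizations; filters would be
separate, logged operations.

## Measurement estimators

* **Radial diameter.** Radial distances from the centre of mass are
  histogrammed (1-nm bins). The radial density of a ring of radius R
  blurred by isotropic Gaussian error sigma is a Rice distribution
  whose mode sits *outward* of R by about sigma^2/(2R) and whose mean
  radius is biased higher still; the default estimator therefore fits
  the Rice density and reports 2R, which is unbiased at all blur
  levels. The mode-with-quadratic-refinement ("peak", with first-order
  bias inversion) and mean-radius estimators remain available for
  comparison. Noiseless rings short-circuit to the exact sample
  radius. Comparable secondary radial peaks flag the report ambiguous.
* **Axial profiles and spacing.** Localizations are projected on the
  particle axis (for sideways polymers, the leading principal
  component of the in-plane scatter), histogrammed with 2-nm bins, and
  peaks above a relative prominence are refined quadratically.
  Consecutive-peak distances pooled over particles give the spacing
  report as a mode-centred mean and SD (window: 30% of the mode), so
  occasional missed rings (which create doubled spacings) do not drag
  the mean.
* **NeNA precision.** For every localization the nearest-neighbour xy
  distance in the following frame is collected; the histogram
  (0.25-nm bins) is fitted with the correlated-pair model
  p(d) = d/(2 sigma^2) exp(-d^2/(4 sigma^2)) plus a linear background
  term for uncorrelated neighbours. The fit range is restricted to the
  short-distance regime (8x the median short distance, capped at
  20-100 nm); without the cap the field-scale background dominates the
  fit. Recovery is within a few percent for sigma between 2 and 8 nm.
* **FWHM conversions** use 2 sqrt(2 ln 2) sigma, reported to one
  decimal (3.6 -> 8.5, 6.3 -> 14.8).
* **z resolution.** A Gaussian fit to a single ring's z histogram
  yields the axial FWHM; a two-Gaussian mixture fit yields the
  peak-to-peak distance of a ring pair, declared resolved iff the
  separation exceeds the single-ring FWHM.
* **Staple availability.** Per picked particle, localization clusters
  are found by deterministic greedy density clustering. With at least
  three clusters the designed site pattern is posed onto the data
  (circle fit through cluster centres, azimuth by template scan at 1
  degree) and a site counts as available iff at least k = 10
  localizations fall within the match radius (2 sigma_xy) of its
  expected position. Particles with fewer clusters cannot be posed;
  for them the cluster count stands in for the available count —
  excluding them would censor exactly the low-occupancy particles and
  bias the estimate upward. The match radius default is deliberately
  tighter than one might guess from the FWHM: on a 31-nm ring the
  sites are only ~15.5 nm apart, and a radius much beyond 2 sigma
  starts crediting empty sites with their neighbours' localizations.
  The pooled fraction is reported with its binomial standard error.

## Synthetic TEM and its estimators

Upright barrels are rendered as dark annuli (outer diameter = external
diameter, wall ~6 nm — the projected three-layer wall); sideways
barrels as dark rectangles of monomer height by external diameter,
optionally widened by a flattening factor emulating stain-drying
collapse of hollow particles. Diameters are estimated with a classic
gradient-edge circular Hough transform (the accumulator is re-read at
each detected centre and the outermost edge peak is reported, since a
printed TEM diameter refers to the outer wall). Heights are estimated
by zero-normalized cross-correlation against a library of binary
rectangle templates (1-px grid) after thresholding (mean minus one SD),
morphological opening and reorientation of the mask to vertical via
its principal axis; ties prefer the smaller height. Both estimators
are invariant to global intensity scaling and offset. Accuracy is
assessed against synthetic truth, not against any specific toolbox's
variant of these algorithms.

## Problem sizes and numerical choices

Recovery runs use ~110 particles for diameters (the historical 30-nm
sum image pooled 726), 50 polymers of 8 monomers for spacings, ~2000
localizations for the z ring pair, and ~124 barrels (744 expected
sites) for availability — sizes chosen so each scenario completes in
seconds while keeping estimator noise well inside the tolerance bands.
Default bin widths: radial 1 nm, axial 2 nm, NeNA 0.25 nm; every
report logs its bin widths, fit type and thresholds in its method
metadata, and every scenario summary records a config hash and seed so
runs are bit-reproducible.

## Known limitations

* The pixel-lattice site counts and the mapping of decorated rows to
  the published pixel totals are configurable approximations; strand
  routing is out of scope.
* The availability estimator assumes sites are resolvable (spacing a
  few sigma); densely decorated surfaces would require qPAINT-style
  kinetic counting, which is out of scope.
* The averaging objective is guaranteed monotone only within a
  schedule step (bin sizes change between steps) and only for
  translations in whole bins.
* Simulated TEM omits contrast transfer, stain granularity and
  partial-collapse geometries; the flattening factor is a single
  width multiplier.
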