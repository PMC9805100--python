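# Methods

This note documents the models and numerical procedures implemented in
`fecgel`, the parameter choices that matter, what the bundled simulator
does and does not emulate, and the known limitations.

## Coordinate conventions

Pixel indices are 0-based; the row index increases downward, in the
direction of electrophoretic migration. Migration distance is measured in
pixels from the stacking/resolving border (`resolving_top_row`), the row
at which size separation begins. Column bounds are half-open
(`right_col`, `bottom_row` exclusive).

## Gel-region detection

The gel cassette is located from 1-D projections of the channel-summed
raster rather than 2-D edge maps: projections are robust, parameter-light
and match how a human reads a gel scan.

* **Left/right bounds** — the strongest rising and falling
  sample-to-sample steps of the column-sum projection. Significance is
  assessed on a 5-sample-smoothed copy of the projection (so an edge
  smeared over a few columns by residual rotation still registers) and
  requires the strongest smoothed step to exceed 5× the median absolute
  smoothed step; otherwise the image is declared featureless ("no gel
  detected"). The precise edge is then the strongest raw step within
  ±4 samples of the smoothed optimum, which is exact for an ideal step.
* **Stacking/resolving border** — the strongest rising step of the
  row-sum projection (over gel columns) within the upper third of the
  image. The border is visible because the resolving gel carries a
  higher fluorescence background than the thin stacking gel.
* **Gel bottom** — the lowest row whose projection exceeds background.
  Background is the 5th percentile of the row projection and the
  threshold is background + 25 % of the (5th–95th percentile) dynamic
  range; both levels are percentile-based so bands and noise do not move
  them.

Detection is invariant under uniform intensity scaling (projections scale
linearly, argmax positions do not move).

## Rotation correction

Scanned gels are typically tilted by a degree or two. The estimate
proceeds in two stages, both deterministic:

1. **Coarse grid search** (default ±5° in 0.1° steps): each candidate
   angle rotates the (pre-smoothed, σ = 1 px) raster and scores the
   variance of the *first difference* of the column-sum projection over
   the band-bearing window. Vertical lanes concentrate intensity into
   few columns with sharp flanks, maximising the high-frequency content
   of the projection. Differencing the projection matters: broad
   intensity ramps — e.g. the wedges a tilted gel edge sweeps across a
   fixed window — contribute strongly to the variance of the raw
   projection while carrying no alignment information. For the same
   reason the scored window is inset from the gel bounds by the maximum
   edge excursion over the search range, so gel edges and the stacking
   border stay outside it at every candidate angle. Ties break toward
   the smallest |angle|, then negative before positive, so a featureless
   image returns 0.
2. **Shear refinement**: the projection score cannot resolve tilts of a
   few tenths of a degree (the per-band column smear is ≪ 1 px, and the
   interpolation blur of candidate rotations is of the same order as the
   signal). The coarse estimate is therefore refined by rectifying,
   re-detecting the geometry, and measuring the residual tilt directly:
   loaded samples are horizontally symmetric about their lane centre, so
   within each contiguous signal column-cluster (one loaded lane) the
   column centroid of the band signal in the upper vs lower half of the
   region gives a Δcolumn/Δrow slope — the tangent of the residual tilt
   — independent of which bands the lane contains and of interpolation
   blur. Cluster windows are extended into the inter-lane gaps (capped
   at the gap midpoint) because truncating the soft band shoulders at a
   fixed window biases centroids toward the window centre and attenuates
   the measured shear. The mass-weighted mean slope over clusters is
   subtracted and the loop repeats (≤ 3 times); the final angle is
   rounded to the grid resolution.

On simulated gels this recovers applied rotations of ±4° to within 0.1°
at band SNR ≈ 40 and within 0.3° at SNR ≈ 10.

`rectify` applies the correction with bilinear interpolation about the
image centre; out-of-frame pixels are filled with the scanner-margin
background (median of the outermost 5-px border ring) so no spurious
edges enter, and total intensity is conserved within 1 % for gels with
dark margins.

## Lanes, profiles and bands

Lanes are fixed equal-width partitions of the gel width given the
declared lane count, remainder pixels distributed one-per-lane from the
left — no per-lane refinement. A lane profile sums intensity across the
lane width at every migration distance; summing guarantees that the lane
profiles partition the total gel-region intensity exactly.

**Background subtraction** (for band detection): the baseline is the
rolling minimum over a window (default 51 px, several times the widest
band) smoothed by a moving average of the same window; the residual is
clipped at zero. A flat offset vanishes exactly; peaks narrower than the
window pass through with < 2 % height loss.

**Band detection**: local maxima of the background-subtracted profile
whose topographic prominence (height above the highest saddle separating
the peak from any higher peak) exceeds a threshold, by default 5 % of
the profile maximum — relative to the maximum so detection is invariant
under exposure scaling; an absolute override exists. Adjacent
equal-height plateau samples resolve to the leftmost sample. Sharp peaks
additionally receive a three-point parabolic sub-pixel apex refinement:
at the default migration slope one pixel corresponds to ≈ 1.4 % in mass,
so sub-pixel apexes are what make 2 %-level mass accuracy reachable.
Band area integrates between the two nearest flanking local minima
(parameter-free base definition). Band count is non-increasing in the
threshold.

**Quantification totals** use a different background treatment
(`lane_signal_total`): on a noisy profile the rolling-minimum baseline
sits ~2σ below truth and zero-clipping rectifies the noise, inflating a
280-row lane total by tens of percent. Instead, band-bearing rows are
masked (residual against a rolling-median baseline above 3 robust σ,
dilated by 5 px), the baseline is estimated from background rows only
and interpolated across the masked stretches, and the residual is summed
*without* clipping so zero-mean noise cancels. Noise-free this equals
the clipped total; at band SNR ≈ 10 the remaining bias is a few percent.

## Mass calibration

Detected marker-lane bands are paired with the declared ladder masses
(largest mass ↔ least migrated). With surplus detections the
highest-prominence subset of the required size is kept — because bands
are distance-sorted, every subset preserves order, so this is exactly
the maximal-prominence order-preserving assignment; fewer bands than
ladder masses is an error.

The calibration is a piecewise-linear interpolant in (distance, log₁₀
mass) through all anchors — interpolation, not regression — continued
with the end segments' slopes beyond the anchor span. Log-linear
migration is the standard SDS-PAGE approximation and is exact for the
simulator, which uses the same law. Masses assigned outside the anchor
span are flagged as extrapolated in exports. Sigmoidal/Ferguson
calibration for gradient gels is out of scope.

**Mass-axis resampling** deposits each unit pixel interval
[d, d+1) → [mass(d+1), mass(d)) into the cells of a shared strictly
decreasing mass grid in proportion to interval overlap in log₁₀-mass
coordinates (conservative rebinning; cell edges at log-midpoints, end
cells extended by half a spacing). The operation is linear in the
profile and conserves total intensity wherever the grid covers the
profile's mass span. The default grid has 500 log-spaced cells from
260 kDa down to 10 kDa, spanning typical prestained ladders at ~4× finer
resolution than the rendered band width.

**Channel bleed**: a fluorophore emission shoulder can leak sample
signal into the marker channel. The bleed coefficient k is the least
squares slope of marker on sample intensity over non-marker-lane pixels
of the resolving gel, restricted to clearly signal-bearing pixels
(sample intensity > median + 8 MAD) because the background's spatial
structure is shared by both channels and would otherwise bias the slope
toward 1; an intercept absorbs background, k is clipped to [0, 1] and
k × sample is subtracted from the marker channel. Correction is on by
default.

## Absolute quantification

The standard curve is an ordinary least-squares line through the
(moles, intensity) dilution-series points, fitted *with* an intercept:
real scanners have blank offsets, and a true zero intercept is recovered
anyway. Inverting the curve converts a lane's background-subtracted
fluorescence total into moles of fluorophore; negative inferred amounts
clip to zero with a warning rather than an error. The degree of
labelling is 100 × fluorophore moles / protein moles — above 100 % when
molecules carry several labels — and the lysine-residue fraction divides
by the protein's lysine count (98 for the antibody of the worked
examples; always a user parameter).

## Reference libraries and classification

Mass profiles on identical grids are compared by the squared Pearson
correlation of their raw rebinned intensities — no smoothing or
normalisation, since Pearson is already invariant under positive affine
transforms. That invariance is the load-bearing property: exposure and
loading differences between gels cancel, so profiles from independent
runs are directly comparable. A library is a labelled set of profiles on
one grid, serialized as a JSON manifest plus a full-precision CSV matrix
(human-inspectable, diff-able, bit-exact round trip). Classification
ranks entries by R²; ties resolve to the first entry in library order
and are flagged. Correlation of a constant (zero-variance) profile is
undefined and raised as an error, never reported as 0.

## The simulator

`fecgel.sim` renders what the pipeline assumes, plus the nuisances it
must survive: migration exactly log-linear in mass (d = a − b·log₁₀ M,
defaults a = 424 px, b = 164 px/decade placing 250–10 kDa inside a
280-px resolving gel, with an optional mild quadratic curvature for
robustness tests, default off); bands as vertical Gaussians (σ = 3 px)
spread over ~70 % of the lane pitch with soft shoulders — the well
width; real samples leave inter-lane gaps, without which lane alignment
would be unobservable; background plateaus (scanner margin 100,
stacking 110, resolving 200 counts, optional vertical gradient);
emission bleed of k × the sample band signal into the marker channel;
global rotation; exposure scaling; additive Gaussian noise (Poisson
optional, default off), all from a seeded generator recorded in the
ground truth. Band intensity is amount (pmol) × gain (default 10⁵
counts/pmol) × exposure, conserved in rendering to < 1 %.

It does **not** emulate: lane smiling/frowning or keystone distortion,
intensity saturation, spatially textured background, band tailing or
skewed band shapes, diffusion-dependent band widths, or gradient-gel
migration. Passing tests therefore demonstrate correctness of the
analysis chain under the stated model and its noise, not robustness to
these real-gel pathologies; the geometry and background stages are the
ones most exposed to them.

Class-pattern generation for library experiments uses four canonical
antibody modification classes (near-blank native; UV-stressed;
heat-stressed; deglycosylated) with disjoint band mass lists, rendered
either directly on the mass grid (Gaussians of 0.018 decades, matching a
3-px band at the default slope) or as full gels via `class_gel_config`.
Replicates receive per-band multiplicative jitter (1 + N(0, 10 %) by
default) and additive noise.

## Problem sizes and determinism

Tests and the acceptance script run on 360 × 480 px two-channel gels
with 10 lanes and a 7-mass ladder (250/150/100/75/50/37/25 kDa), the
scale at which every effect of interest is already present; rotation
recovery sweeps nine angles, classification uses two full gels with six
query lanes. The pipeline itself contains no randomness: identical
configuration and inputs give byte-identical outputs, and all simulation
randomness flows from explicit seeds.

## Known limitations

* Equal-width lane segmentation requires the declared lane count and
  assumes no lane drift; badly curved lanes will blur profiles.
* The rotation search window assumes at least a few loaded lanes with
  bands in the resolving gel; a gel with a single faint lane degrades
  gracefully but loses sub-degree accuracy.
* Bleed estimation needs signal-bearing non-marker lanes; a blank gel
  returns k = 0.
* Extrapolated masses (outside the ladder span) inherit the end-segment
  slope and should be treated as indicative; they are flagged in
  exports.
* R² classification compares full profiles; a modification visible only
  in a narrow mass window can be diluted by the rest of the lane (a
  mass-window restriction is available on the correlation utilities via
  grid choice).
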