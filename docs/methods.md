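# Methods

This note records the model as implemented: its assumptions, the parameters
that matter, the choices made where the design was genuinely open, and what
the synthetic-stimulus tests do and do not establish.

## Model structure and assumptions

The model is purely feedforward and monocular, and operates on binary (or
coverage-weighted) contour images: white 1-px contours on black, 400×400 px
canvas, closed shapes spanning ~300 px. There is no learning anywhere; every
layer is a fixed arithmetic circuit, and shape selectivity is set by a
single isolation stimulus per cell. All angles are measured from the +x axis
toward +y (y runs downward); orientation channels are defined modulo π.

### Simple cells

An oriented difference of two concentric Gaussians: the cross-section
(across the preferred orientation) is a narrow excitatory Gaussian of width
σ = size/4 minus a surround of width WR·σ with amplitude 1/WR (equal 1-D
areas), under an elongation envelope of width AR·σ along the orientation.
Kernels are forced to zero mean and unit L2 norm, so responses scale
linearly with contrast and are comparable across scales.

Two sampled-support choices matter and were fixed after a reconstruction
study against the published operating bands of the curvature cells:

- the support is *not* cut at the nominal size; it extends to the natural
  decay of the surround and length envelope (half-width
  `ceil(2·max(WR, AR)·σ)`). Cutting the largest cell (σ_len = 90 px) at
  ±60 px changes its curvature preference qualitatively and leaves it
  silent under its published flank gain.
- the nominal `size` therefore names the 4σ excitatory core, which also
  matches the σ = size/4 relation of the published parameter sets.

A consequence of AR = 0.7 at the smallest scale: that cell is wider than it
is long and carries almost no orientation tuning (an oblique bar even drives
it slightly harder than an aligned one, by the √2 length-per-pixel factor).
It acts as a compact curvature-blob detector; orientation coding rests on
the three elongated scales. The test suite checks orientation selectivity
on the AR > 1 scales only.

### Complex cells

Five simple cells displaced perpendicular to the preferred orientation,
spacing size/8, Gaussian weights (σ = one spacing) normalized to sum to 1,
sampled with bilinear interpolation at the fractional offsets. No rectified
subunit nonlinearity beyond the rectification already applied to the simple
inputs.

### Endstopped cells and the flank-drive constants

Degree-of-curvature cells subtract two same-orientation complex cells
displaced ±size/2 along the orientation from a central simple cell;
sign-of-curvature cells subtract complex cells at θ+45° and θ+135°
displaced along those directions so both flanks sit on one side of the
preferred axis (the opposite-sign variant mirrors them). The published
per-scale flank gains (1.5, 1.25, 1, 3) are defined relative to an
unpublished response normalization; under unit-L2 kernels they over-inhibit
(the largest scale is identically zero for every arc radius). We therefore
introduce one conversion constant per cell family:

- `flank_drive` = 0.165 for degree cells, calibrated once so that the
  measured 90%-of-maximum radius bands of the smallest and largest scales
  bracket their published values, then frozen;
- `sign_flank_drive` = 1.0 for sign cells, whose job is a binary
  comparison: at full drive the variant whose flanks the curve crosses is
  silenced outright, which is exactly the discrimination the layer needs.

The saturation g is a baseline-subtracted logistic, g(0) = 0, slope
α = 0.01, half-point = (population maximum for the scale)/8.5, recomputed
per stimulus batch (per image in the single-image pipeline, per sweep in
tuning experiments). At unit-normalized response magnitudes this stage is
nearly linear; it is retained as the saturation mechanism for
high-intensity inputs and its parameters are exposed.

### Curvature-radius tuning measurements

Tuning curves are measured with apex-centred arcs: the largest arc of the
given radius that fits the canvas, capped at 270° so the stimulus stays an
open arc (a closed circle adds a second, opposite-curvature apex inside
small cells' receptive fields). Arcs are rendered coverage-weighted
(anti-aliased): binary rasterization produces stair-steps at oblique
tangents that the curvature channels detect as spurious sharp-curvature
events. The response is read out at the cell centred on the apex (max over
orientations within ±6 px): arcs of radius beyond ~half the canvas must be
clipped and their terminators — loci of locally infinite curvature — would
dominate a whole-map maximum at every radius.

Under these defaults the measured 90% bands are ≈(5.5, 11.1) px for the
smallest scale and ≈(161, ≥350) px for the largest (the largest scale's
response is still rising at the canvas-limited maximum testable radius, so
its upper edge is set by the sweep limit), against published values of
(6, 11) and (140, 301). The two middle scales come out at ≈(11, 117) and
≈(100, ≥200) against published (25, 52) and (48, 77): no reconstruction of
the filter equation we tried reproduces the middle scales' bands
simultaneously with the outer ones, and their calibration tests are
expected to fail. The preferred-radius ordering across the four scales and
the unimodality of the outer scales' curves hold.

### Local curvature cells

Per (scale, orientation, location), the degree response is routed to the
positive class if the positive-sign cell strictly beats the negative one,
and vice versa; exact ties silence both. Orientation is then max-pooled,
and if the pooled signs conflict at a location only the stronger survives,
so the two signs of one scale are mutually exclusive everywhere. A
winner-take-all switch (off by default) additionally keeps only the
strongest scale per location.

The straight-contour rule flags a location as zero-curvature when the best
*full-inhibition* degree response within ±5 px is below 0.55 of the local
best simple response while that simple response is above half the scene
maximum. Three departures from the obvious per-pixel, scene-relative form
were necessary: the weakness test must use full-drive degree responses
(with the calibrated weak drive, degree cells keep responding at ~0.8 of
max on straight bars); it must be local (the untuned smallest scale fires
on straight bars through its cross-oriented channels, so the scene maximum
*is* that response); and the endstopped evidence must be pooled over a
small neighbourhood (curvature responses peak a few pixels off the
contour). Broad arcs (radius ≳ 150 px) are partially flagged straight —
locally they are straight at the cell scale — which is a known limitation.

### Shape cells

Weights are the template's curvature map max-pooled into polar bins
(radial 10 px, angular π/45, max radius 200 px; 1 800 bins, 14 400
bin × class combinations). A probe's response is the sum over pixels of its
curvature activity times the neuron's *effective* weight at that bin: the
template weights spread as a Gaussian over bin distance (σ = 1 bin radially
and angularly, wraparound angular metric) and over curvature-class rank
(σ = 1 class), with zero cross-talk between opposite signs. The max over
angles required at this stage is implemented as weight-then-max per
location via the max-combination of overlapping Gaussian contributions.
Responses are divided by the template's own response; stimuli richer than
the template can score slightly above 1 and are reported as-is.

## Synthetic stimuli

Bars, circular arcs (sampled on a periodic angular grid so complementary
arcs rasterize identically to the full circle) and closed shapes defined by
a polar radial profile: each boundary element adds a Gaussian bump (convex)
or dent (concave) to a base circle — widths 0.6 rad for "medium" and
0.32 rad for "high" curvature — while the sharp convex angle is a tent
(slope-discontinuous) profile. Shapes are scaled to a 300 px span in their
intrinsic frame and then rotated in exact 45° steps, so a rotated spec is a
pixel-exact rotation. The seeded battery generator draws 2–7 elements with
amplitudes 15–85 px (convex) / 15–55 px (concave), spanning near-circles to
strongly lobed blobs, and deduplicates rotationally redundant images.

What the generator does *not* emulate: filled silhouettes, texture,
contrast variation, retinal noise, or the exact published closed-shape
program (whose construction is not public). Passing tests establish the
model's internal consistency and its calibration on parametric contours,
not performance on recorded neural data.

## Parameter-recovery surrogate

The neuron-comparison machinery is validated end-to-end without recorded
data: a reference shape cell is isolated from the battery's most
distinctive stimulus — among one candidate per base shape, the one whose
response profile has the lowest second-highest value, the same
clear-selectivity screen electrophysiologists apply before isolating a
recorded cell — its 56-stimulus profile serves as the reference, a
new cell is isolated from the ≥70%-of-maximum superposition of that
profile, and the two profiles must agree to a mean absolute difference of
0.05. With the diverse battery roughly 40% of stimuli are distinctive
enough that the superposition contains the template alone and recovery is
exact.

## Problem sizes and numerics

The default test and acceptance runs use: per-scale radius grids of 19–25
points for the calibration tests (step 1 px for the acceptance script's
4–350 px sweeps), a 56-stimulus battery for the recovery test, and
reduced two-scale/four-orientation banks for structural unit tests.
Convolutions are FFT-based with per-configuration kernel caches;
fractional displacements use bilinear interpolation with zero (black)
padding, matching the convolution border policy. All computations are
deterministic; the only randomness is the seeded battery generator.
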