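# Methods

This note documents the models, parameter choices and numerical decisions
behind `ichnocore`, and what the synthetic validation does and does not
demonstrate about real core CT data.

## The measurement model

An archive half of a drill core is a semicylinder (6.2 cm diameter by
default) scanned into a voxel grid, here indexed `(x, y, z)` with `z` the
downcore axis.  Default voxel spacing is 0.351 × 0.351 mm in-plane and
0.5 mm between slices; spacing is always explicit configuration — image
stacks carry none, and scanner metadata can disagree between reconstruction
unit and slice increment, so nothing is guessed.

The quantity CT measures is X-ray attenuation.  Burrows are detectable only
where their fill is denser than the host sediment — pyritised fills being
the dominant case in hemipelagic muds.  The package therefore expresses
fill contrast in units of the host-noise standard deviation σ: a fill at
6σ above the host mean is comfortably segmentable, one at 0σ is invisible.
This single number is the axis along which segmentation completeness
degrades, and the contrast-sweep analysis makes that degradation explicit:
recovered fill volume falls monotonically with contrast and reaches zero
for invisible fills.  Consequently a CT-derived bioturbation estimate is a
*lower bound*: it counts only the high-contrast part of the assemblage.

## Core preparation

The core/air threshold is the midpoint of the bimodal attenuation
histogram, found by a two-means iteration; a volume whose histogram is not
bimodal (no air, or empty scan) is rejected.  The core footprint is the
largest connected component of the through-depth above-threshold map —
deliberately excluding the liner, which has near-sediment attenuation but
is separated from the sediment by the drying/shrinkage gap ubiquitous in
core CT.  Because the footprint of a half-core is a half-disc, a naive
circle fit through its whole boundary (arc + chord) biases centre and
radius; the chord is located first via the footprint's principal axes and
the circle is fitted (Kåsa least squares) to arc points only, followed by
one residual-trim refit.  On simulated scenes the fitted radius is within
one in-plane voxel of truth.

Liner and rim removal is geometric: voxels outside `radius − rim` (default
rim 2 mm, against drilling disturbance) or on the air side of the slab face
are excluded.  The default trims the rim radially only; `trim_face=True`
additionally trims perpendicular to the slab face for cores where slabbing
disturbed the cut surface (note the face plane passes through the core
axis).  Exclusion is recorded as an explicit boolean mask; attenuation
values are left untouched so intensity statistics downstream are computed
on unmodified data.  If the core sits tight in its liner (no gap), the
geometric fit returns the outer liner boundary instead; the rim margin
should then be widened by the liner thickness.

## Segmentation

Markers come from intensity quantiles of the retained voxels: fill seeds
above `q_fg = 0.995`, host seeds at or below `q_bg = 0.5`.  Quantiles make
the defaults scale-free in attenuation units, but they assume the
segmentable fill occupies *less* than `1 − q_fg` of the retained volume
while being the brightest material present; for sections with well under
~0.5 % fill the threshold dips into host noise and `q_fg` should be raised
(both quantiles are exposed in `SegmentationParams`).

The watershed floods the morphological gradient (6-neighbourhood dilation
minus erosion) seeded by the two marker classes; every retained voxel ends
up fill or host, and the fill mask always contains the fill seeds.  The
morphological gradient was chosen over smoothed derivative estimators
deliberately: smoothing correlates the noise and enlarges its catchment
basins, so stray noise seeds grow into blobs that survive the diameter
filter, whereas on the raw morphological gradient noise catchments stay at
a few voxels and die in filtering.  Inverted intensity is available as an
alternative flooding surface.

Components are 6-connected by default (26-connected optional); the stricter
connectivity avoids spurious diagonal bridges between tiny burrows.
Labelling is deterministic: components sorted by descending voxel count,
ties broken by the (z, y, x) scan position of the first voxel.  Components
with cylinder-equivalent diameter below 1 mm are removed — at this voxel
size thinner fills cannot be meaningfully isolated.

## Morphometrics

Burrows are treated as tubes.  The axis is the leading eigenvector of the
voxel-centre covariance; the length is the extent of voxel centres
projected on it; the equivalent diameter `2·sqrt(V/(πL))` is the diameter
of the cylinder with the same volume and length.  This definition is
orientation-free and robust for irregular bodies, but it *underestimates*
the true diameter of short tubes (at aspect ratio 10 it is within ~15 %)
and treats a branched network as a single tube along its global axis — one
trace, one record, no skeleton decomposition.  The z-angle
`arcsin |u_z|` is independent of the axis sign and of rotations about the
vertical, which the tests verify directly.  An endpoint-chord axis
estimator is not provided; for noisy rasterised tubes the eigen-axis is
uniformly more stable.  Single-voxel components have no defined axis: they
are flagged degenerate, given a nominal length of one voxel edge, and
excluded from orientation products.

Class boundaries: tiny means equivalent diameter strictly under 5 mm
(0.5 cm); sub-vertical means z-angle ≥ 45°.  The 45° cutoff and the 60 %
dominance threshold below are conventions, exposed as parameters.

## Downcore products

Per slice, the orientation percentages are volume-% of *segmented* fill in
that slice (per-slice normalisation; whole-section normalisation would
weight slices by their fill content and is available by combining
`fill_voxels` with the percentages).  For interval classification the
vertical-% is smoothed by a centred moving average over a 2 cm window,
weighted by fill voxels so barren slices do not dilute the signal; a depth
is V at ≥ 60 % smoothed vertical share, H at ≤ 40 %, V/H between, and
barren stretches inherit the nearest classified depth.  Runs merge into
intervals that tile the section exactly.

The bioturbated fraction per 2 cm bin — segmented fill volume over retained
volume — is mapped onto the 0–6 Bioturbation Index through a monotone band
table (0 % → 0; ≤ 4 % → 1; ≤ 30 % → 2; ≤ 60 % → 3; ≤ 90 % → 4; ≤ 99.9 % →
5; above → 6).  The band edges follow the standard visual grading scale
(none / sparse / low / moderate / high / intense / complete); they are
configurable, and since CT sees only high-contrast fills the CT log should
be read as a lower bound on the true grade.

Combining the CT log with a 2D-image log takes, per bin on the union of
bin edges over the common depth range, the maximum of the two grades, +1
(capped at 6) when both record bioturbation and the 2D log flags its
structures as disjoint from what CT resolves.  The combined grade is never
below either input.  The exact increment is a design decision: the two
methods sample partially disjoint assemblages, so their combination can
only add information, but no published formula exists for the increment.

## The simulator and what passing tests mean

`synthetic_core` renders: air at `host_mean − 10σ`; a half-core of
Gaussian-noise sediment; a liner shell at near-sediment attenuation
separated from the core by a 0.5 mm shrinkage gap; and burrows as analytic
tubes — a voxel belongs to a burrow iff its centre lies inside the tube,
which keeps rasterised volumes checkable by brute-force counting.
Straight tubes have fixed diameter; branched networks are a random-walk
trunk with side branches and sinusoidal radius modulation (pinch-and-swell).
Overlaps resolve to the earlier-listed burrow; tubes leaving the core are
clipped with a warning.  Everything is a deterministic function of the
scene seed.

Default study conditions for recovery scoring: sections of 256 × 128 × 400
voxels, 10–30 disjoint straight tubes of 1.5–4 mm diameter and 15–50 mm
length at uniform-random orientation, with one fill contrast per scene
drawn from 6–10σ (mineralised fills within a section are similarly dense,
and a single scene-wide contrast is what the quantile marker rule assumes).
Tubes are placed by rejection sampling with ≥ 2.5 mm clearance so that
ground-truth component counts are unambiguous.  The `mixed` preset builds
four 5 cm depth bands alternating vertical-dominated and
horizontal-dominated populations, with 5 mm guard zones at band boundaries
so the constructed truth is well defined at the scale of the smoothing
window.

The simulator does **not** model CT physics: no beam hardening, streaks,
partial-volume blur or reconstruction kernels, and its noise is i.i.d.
Gaussian rather than spatially correlated.  Passing recovery tests
therefore demonstrates that the *algorithm chain* is correct and
internally consistent under the stated contrast model — not that any
particular real core will segment as cleanly.  On real scans the marker
quantiles, rim width and minimum diameter are the knobs to revisit, and
low-contrast parts of the assemblage will be missing by construction.

## Problem sizes

The test suite runs 20 full-size simulated sections for the recovery
statistics (about 3–4 minutes on one CPU) plus fast unit and property
tests; the acceptance script repeats the 20-scene suite with seed-derived
scenes, a 5-point contrast sweep on a shorter section, one mixed-preset
classification and 10,000 random BI combinations.
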