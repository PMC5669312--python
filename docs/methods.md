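# Methods

`voxelgram` reduces laser-ablation ICP-MS (LA-ICP-MS) line-scan data from
serial tissue sections to a calibrated, registered, multichannel 3D voxel
volume, and provides the analysis operations that make such volumes
useful: multi-criteria voxel selection and fuzzy c-means segmentation.
This note records the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Data model and geometry

A run is a set of ablation lines; each line contributes one pixel row per
channel image, with one image per measured m/z (e.g. ³¹P, ⁵⁶Fe, ⁶³Cu,
⁶⁶Zn, ¹⁹⁷Au). Pixel geometry is fixed by the acquisition:

* `dx = scan_speed x acquisition_period` along the scan direction,
* `dy = line_spacing` between ablation lines,
* `dz = section_interval` between serial sections.

The defaults throughout mirror a murine whole-brain series: an 80 um spot
traversed at 320 um/s with a 0.25 s acquisition period (dx = 80 um),
80 um line spacing, and 30 um sections cut at 90 um intervals, so 23-24
sections span ~2 mm of tissue. Ragged line lengths are reconciled to the
modal length — short lines padded with 0, long lines truncated, every
event logged — because interpolating raw counts would silently fabricate
data.

## Signal correction

**Background.** Slow instrument drift over multi-hour runs adds a smooth
offset to every channel. Operator-designated tissue-free regions
constrain a 2D polynomial surface (total degree <= `order`, default 2)
fitted by least squares on coordinates rescaled to [-1, 1] for
conditioning, then evaluated over the full grid and subtracted. A global
polynomial rather than patchwise interpolation keeps the model fully
specified and reproducible; degree 2 is enough for the slowly varying
drift this corrects, and the residual over the designated regions has
zero mean by construction of the least-squares fit.

**Despiking.** Spikes are isolated single-pixel transients (aberrant
particles, electron-multiplier events). A pixel is replaced by the median
of its surrounding window (default 9x9, excluding the pixel itself,
truncated at image edges) when it exceeds `factor x median + floor`
(default factor 5, floor 0). The pipeline sets the floor automatically to
10% of the image's 99th percentile: a purely multiplicative rule fires on
*any* positive pixel whose neighbourhood median is ~0, which is exactly
the situation just outside tissue, so the floor restricts despiking to
pixels that are also non-trivial on the image's own intensity scale.
Despiking runs on raw counts before background subtraction because spikes
are artefacts of the raw detector stream. A corollary of any
local-median rule: genuine structures smaller than about half the window
and more than `factor` above their surroundings are indistinguishable
from spikes; real elemental images are band-limited by the spot size,
which keeps anatomical features below that contrast.

**Calibration.** Matrix-matched reference standards of known
concentration are ablated before and after each scan. The per-line
sensitivity (CPS per ug/g) is interpolated linearly between the two
brackets — in scan-line index by default, in acquisition time when
timestamps are present (the two coincide for constant line pacing) — and
each pixel row is multiplied by the reciprocal factor, converting CPS to
ug/g. The stored factor is ug/g-per-CPS so that "multiply by the row's
factor" yields concentration directly. Channels without a tissue-matched
standard (commonly Mn; here also P and the Au/Yb immunolabels) pass
through in CPS with an `unquantified` flag rather than receiving a
fabricated scale. Calibration is exactly invertible, and a noise-free
linear drift is removed to machine precision because a piecewise-linear
interpolant reproduces a linear truth exactly.

## Sections and masking

Section extents are declarative bounding boxes ordered anterior to
posterior (overlaps allowed — neighbouring sections can overlap on the
slide); tissue boundaries are polygons rasterised with the even-odd rule
at pixel centres, boundary pixels included. The masked exterior is stored
as value 0 *plus* an explicit boolean mask, because 0 is also a
legitimate background-subtracted intensity; every downstream statistic
consults the mask. Sections are centre-padded to a common frame before
registration.

## Registration

Consecutive sections are aligned by minimising the squared intensity
difference `eps^2 = ||f_R(x) - Q_P{f_T(x)}||^2` between 3rd-order spline
models of a reference image (the preceding, already-aligned section) and
a rigidly transformed test image. The transform family is rotation +
translation only — pixel size is fixed by the instrument, and the
concentrations themselves must survive the transform, so scale, shear and
grey-level changes are excluded. The rotation centre is the geometric
centre of the common frame, which minimises rotation-translation
coupling.

The search is pyramidal: 4 block-mean halvings (mask-aware, with Gaussian
anti-aliasing before decimation) put the coarsest stage at 1/16 scale;
each stage's optimum, translations scaled, seeds the next, ending at full
resolution. The coarsest stage has no prior estimate and is seeded by an
exhaustive grid (theta +/-15 deg in 2 deg steps, shifts in 2 px steps
scaled to the level); every stage refines with a Nelder-Mead simplex
(parameter tolerance 1e-3, <=400 evaluations). Pyramid levels stop
halving below 8 px. The identity transform always remains a candidate, so
the returned residual never exceeds the unregistered residual. For small
images the effective number of levels is reduced so the coarsest stage
stays at least 8 px.

Alignment runs on a composite channel: each alignment channel is
normalised to greyscale 0-255 and combined by non-negative weights
summing to 1 (default equal — 0.5/0.5 for the canonical
tissue-structure + immunolabel pair), and the recovered parameters are
applied retrospectively to every channel of the section. Grey
normalisation uses **stack-wide** per-channel anchors (in-mask min/max
over all sections): per-section anchors would give each section its own
gain, and since grey-level change is excluded from the transform family,
a gain mismatch between sections masquerades as misalignment and biases
the optimum — an effect we observed directly on synthetic stacks.

The reported alignment residual is the mean absolute difference of
unit-normalised ([0, 1]) images over the union of the two masks: 0 for
identical sections, values around 0.5 for morphologically distinct but
correctly aligned tissue.

**Known limitation.** Chained pairwise registration inherits the
displacement of each pair's SSD optimum. When consecutive sections
genuinely differ (changing anatomy), the optimum sits slightly off the
true mounting, and these offsets accumulate along the stack as a slow
rotational drift. At the phantom's default morphology variation (~2%
radius change across the stack plus evolving internal regions) the
accumulated drift stays within 0.5 deg; at ~5x stronger per-slice
variation we measured ~1 deg of accumulated rotation. Applications with
strongly varying anatomy need external anchors, which rigid pairwise
SSD cannot provide by itself.

## Voxel volume, selection, smoothing, export

Aligned sections stack into a (channel, nz, ny, nx) volume with the
spacing above. Histograms are computed over in-mask voxels only.
Multi-criteria selection is a conjunction of per-channel intervals
(closed by default, each bound optionally open or absent): a voxel is
selected iff it is in the tissue mask and inside every interval; channels
not named are unconstrained. Selection is monotone — tightening an
interval never adds voxels.

Smoothing is mask-aware Gaussian convolution per channel, normalised by
the smoothed mask so the zero-valued exterior does not bleed inward;
sigma 0 is the identity and constant in-mask fields are preserved.

Volumes export as VTK XML ImageData (`.vti`, ASCII, spacing in mm, origin
0, x-fastest ordering) with one Float32 array per channel and a UInt8
mask or selection array; a legacy STRUCTURED_POINTS writer is available
behind a flag. Surface reconstruction (e.g. Delaunay in ParaView) is
deliberately left to the viewer.

## Fuzzy c-means

In-mask elements become rows of a feature matrix, one column per channel,
min-max normalised to [0, 1] so channels of very different dynamic range
contribute comparably (z-scoring is available; constant channels are
dropped). The clustering is standard Bezdek fuzzy c-means: memberships
`u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))` with Euclidean distance, centres
as `u^m`-weighted means, iterated until the maximum relative centre
change falls below `tol` (default 1e-5) or `max_iter` (default 100).
Defaults: fuzzifier m = 2 (the common neutral choice; m -> 1 approaches
hard k-means), initial centres drawn uniformly from the data points with
a fixed seed. A plain normalised inverse-distance membership is available
behind a flag for sensitivity checks. Points coincident with a centre get
full membership there; empty clusters retain their previous centre.
Results are made deterministic and comparable by sorting clusters on
their first-feature centre value; hard labels are argmax memberships with
ties to the lowest index. The objective `J = sum u^m d^2` is recorded
per iteration and is non-increasing.

Reports give, per cluster and channel, the membership-weighted mean
de-normalised to original units, the min/max over hard members, the
member count and the percentage of the dataset.

## The synthetic phantom

No public serial-section LA-ICP-MS dataset with recorded per-slice
mounting errors exists, so validation rests on a phantom whose every
corruption is recorded. The clean volume is "brain-like" in the features
that matter to the pipeline, not anatomically accurate: an outer tissue
ellipsoid with a strong, regionally varying P signal; an inner high-Zn
shell; two off-axis Fe + Au hotspot spheres (the Au standing in for a
nanoparticle immunolabel); a thin high-Cu streak; two fibre-tract-like
low-P cylinders running the full z-range; and a smooth z-continuous
texture field (8% of the tissue level, ~2.5 px correlation length)
standing in for the cell-density structure that anchors rotation in real
images. Region interiors sit exactly at their configured level; region
means are preserved exactly under the texture by per-region
mean-correction. Tissue edges carry a ~2 px decaying skirt outside the
boundary, emulating the band-limiting of a finite laser spot (an ideal
step edge would make boundary pixels indistinguishable from spikes under
any local-median rule).

Default study conditions: 24 sections of 128x128 px at 80/80/90 um
spacing; per-slice mounting theta ~ U(-10, 10) deg and shifts
~ U(-6, 6) px (slice 0 keeps the identity so the chained registration is
anchored to the absolute frame); linear sensitivity drift on the
quantified channels (Fe x0.85, Cu x1.10, Zn x0.92 over the series) with
noise-free bracketing standards synthesised from the true sensitivities;
a positive order-2 polynomial background at 5% of each channel's peak
CPS; additive Gaussian noise at 1% of peak CPS (within the Poisson
shot-noise band for these count rates and dwell times); and isolated
spikes at 0.5 per kilopixel, 10x the channel's peak, with a minimum
separation of 5 px. Tissue radii vary ~2% across the stack and internal
regions appear/disappear along z, so consecutive sections genuinely
differ. Corruptions draw from named substreams of one seed, so disabling
one corruption does not shift the others.

With all corruptions disabled (and the phantom configured z-uniform so
that the "nothing to correct" condition genuinely holds for registration
too), the full pipeline returns the source volume to better than 1e-6
relative — every stage passes clean data through unchanged. At default
corruption levels, >=95% of slices are recovered within 0.5 deg / 1 px
and the pooled per-voxel relative RMS against truth is about 4-5%
depending on the noise realisation (4.3% at the fixed seed the suite
runs; per-channel ~2% for P and ~5% for the trace channels, dominated
by the noise floor since reconstruction involves no averaging).

**What this does and does not show.** The phantom exercises the full
chain — parsing, despiking, background removal, calibration, masking,
registration, assembly — against recorded truth, including realistic
coupling (spikes on top of background, drift under mounting error). It
does not emulate plasma/transport physics, isobaric interference,
washout tails between lines, section tearing or folding, or anatomy with
landmark-free rotational symmetry; passing it shows the data reduction
is correct and stable under the stated corruption model, not that any
particular real tissue series will align within tolerance.

## Problem sizes in the test suite

The suite and the acceptance script run the full 24 x 128 x 128 phantom
once (about a minute on one CPU) and use 64 x 96 px fixtures for
pairwise registration properties; the exhaustive grid-search baseline
uses a 1 deg / 1 px grid over +/-10 deg and +/-6 px on 64 px instances.
These sizes keep the whole suite to a few minutes while leaving every
stage's behaviour measurable.
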