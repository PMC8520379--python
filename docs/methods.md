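# Methods

## Scope and model

`endostitch` registers and blends pairs of 2-D endoscopic frames assumed
to view a locally near-planar mucosal surface, so that a 3×3 projective
transform (homography) relates the two views. The pipeline is: Gaussian
scale-space keypoint detection, gradient-histogram description,
ratio-test matching, two geometric mismatch filters (slope-consistency
pre-check and disparity-gradient constraint), seeded RANSAC homography
estimation, and feathered compositing. The package additionally ships a
descriptive tabulation of a 111-patient gastric-polyp cohort as a worked
example of the clinical context in which mosaicking is used.

## Scale space and detection

The pyramid follows the canonical design: σ₀ = 1.6 base smoothing, s = 3
intervals per octave (scale ratio k = 2^(1/3)), s + 3 Gaussian levels and
s + 2 DoG levels per octave, 4 octaves by default, each octave seeded
from the previous octave's level at 2σ₀ downsampled by taking every
second pixel. Convolution is separable with a kernel truncated at radius
⌈4σ⌉ and renormalised to unit sum (error < 1e-10); boundaries are
handled by reflection, which avoids the dark-rim artefacts zero padding
creates on vignetted endoscopic frames. No initial 2× upsampling by
default (`upsample=True` enables it; coordinates and scales are always
reported in the full-resolution frame, x = column, y = row, 0-based,
pixel centres at integers).

Candidate keypoints are strict extrema over the 26 space-and-scale
neighbours, refined by up to 5 iterations of the 3-D quadratic (Taylor)
step with re-localisation whenever an offset exceeds 0.5; points that
fail to converge, drift out of the valid interior, or (after moving) are
no longer strict extrema are dropped — stability is preferred over
recall. Survivors must pass |D̂| ≥ 0.03 on the interpolated response and
the edge test tr²/det < (r+1)²/r with r = 10 on the 2×2 spatial Hessian.
Keypoints within 5 px of the border at their octave are discarded so the
descriptor window is valid. Orientation uses a 36-bin histogram of
gradient angles in a Gaussian window of σ = 1.5·σ_kp (radius 3σ),
smoothed twice with a circular binomial kernel; every peak at ≥ 0.8 of
the maximum spawns a keypoint, with parabolic peak interpolation. The
descriptor is the standard 4×4 × 8-bin layout with trilinear vote
interpolation and Gaussian spatial weighting, normalised, clamped at 0.2
and renormalised; flat or out-of-frame windows yield the flagged all-zero
descriptor. All constants are exposed through `RunConfig`.

## Matching and the two mismatch filters

Coarse matching keeps a source descriptor's nearest target neighbour iff
d₁/d₂ < 0.8 (Euclidean), then enforces one-to-one assignment by letting
the smallest distance win each contested target.

**Slope pre-check.** With the target frame shifted right by a composite
offset equal to the source width (guaranteeing a strictly positive run
and hence finite slopes), each match's line slope is
(y′ − y)/((x′ + offset) − x). Every observed slope serves as a candidate
neighbourhood centre; the centre whose t-neighbourhood (t = 0.02,
half-width, boundary inclusive) contains the most slopes wins, and
matches outside the winning neighbourhood are rejected. Candidate centres
are drawn from the match slopes themselves rather than a continuous grid
— with a census objective that is piecewise constant between observed
slopes, an off-sample centre can never beat the best on-sample one by
more than a boundary tie. Ties between equal-census centres are broken by
smaller |k|, then by positive before negative sign. This key is a
function of the slope multiset only, which makes the filter invariant to
the order matches arrive in (a property the test suite asserts); an
index-based tie-break would not be. With fewer than 3 matches the census
is meaningless and the filter passes matches through with a warning.

**Disparity-gradient filter.** For matches m, n the disparity gradient is
‖d(m) − d(n)‖ / ‖c(m) − c(n)‖, with disparity vectors d = dst − src in
the raw frames and cyclopean midpoints c = (src + dst)/2; coincident
midpoints give +∞. "Adjacent" is operationalised as the K = 4 nearest
preselected neighbours by source-point distance (deterministic tie-break
on distance, then coordinates); a match is retained iff the median of its
neighbour gradients is **strictly** below 2 — the boundary value 2 itself
is rejected, matching the stated inequality. K shrinks to n − 1 when
fewer matches are available; with fewer than 2 the filter passes through
with a warning. The median-of-neighbours rule keeps the test local (a
wrong match cannot hide behind far-away consistent ones) while a single
bad neighbour cannot veto a good match.

## Homography estimation and blending

Estimation is normalised (Hartley) DLT on minimal 4-point samples inside
RANSAC with a fixed seed (default 17), skipping samples with any 3
collinear points; inliers are classified by symmetric transfer error
(mean of forward and backward distances) below 3 px, the best consensus
is refit by least squares and inliers are re-classified once. The RMS
error is reported over the final inliers. Exactly 4 matches bypass the
loop (exact solve). The projective family is the default model; frames
with negligible parallax are equally served by it, so no separate affine
path is used in the pipeline.

Stitching warps the target frame into the source frame by H⁻¹ with
bilinear sampling on the union bounding-box canvas; samples outside the
target frame are transparent (excluded from blending), not black. The
blend is linear feathering: each frame's weight is its
distance-to-border + 1, and the target weight is normalised as the exact
complement of the source weight so the two sum to 1 bitwise at every
covered pixel. A canvas exceeding 20× the larger input area raises a
divergent-model error. The seam mask records per-pixel provenance
(source / target / blended).

## Synthetic fixtures

The generator emulates what the detector and filters need from
endoscopic video, not its appearance: band-limited Gaussian noise texture
(σ = 3 px — no public dataset exists for this task, and gradient-based
detection only needs realistic texture statistics), 8 polyp-like Gaussian
blobs (σ 5–15 px, amplitude ±0.1–0.25), a radial vignette, a smooth
multiplicative illumination field on the second frame, and additive
sensor noise. The second frame is the first resampled under a known
homography built from rotation/scale/translation/perspective about the
image centre, so exact correspondences (12 px grid restricted to the
mutually visible region) come for free, and injected false matches are
guaranteed ≥ 10 px of reprojection error. Everything is a pure function
of the seed; fixture PNGs are written 16-bit to keep quantisation below
test tolerances. It does not model specular highlights, deformation of
the mucosa, motion blur, or fluid/debris — passing tests therefore show
correctness of the geometry and filtering, not robustness to every
artefact of real endoscopy.

Benchmark conditions (chosen once): the filter benchmark draws
consecutive-frame-like motion — rotation ≤ 3°, scale 0.97–1.03,
translation ≤ 25 px, noise σ = 0.01 — over 20 seeded 256×256 pairs with
30% injected false matches; the end-to-end benchmark stresses the
pipeline harder with rotation ≤ 10°, scale 0.9–1.1, noise σ = 0.01 over
10 seeded 256×256 pairs, scoring the mean corner displacement of the
estimated vs the true homography (median across pairs). 256×256 frames
keep a full pipeline run under a second while leaving ~200+ keypoints
per frame, ample for all statistics. Note that under rotations of
several degrees the slope band of correct matches is wider than t, so
the pre-check intentionally trims correct matches down to the densest
band; enough well-spread matches survive for RANSAC, which is why
true-match retention is benchmarked under the small-rotation regime the
filter is designed for.

## Cohort tabulation

The bundled CSVs transcribe the cohort's three contingency tables
(histology × age band, × maximum polyp diameter, × location; 111
patients, 165 polyps). Loading validates label vocabularies, integer
non-negative cells and the grand total. Percentages always use patients
(111) as denominator and round half-up to one decimal — the convention
that reproduces every published percentage; the one internally
inconsistent figure in the source (stomach-body share, variously printed
52.2% and 53.2% where the table sum gives 58/111 = 52.25%) is simply
recomputed from the table, yielding 52.3%. Where the source text and its
tables disagree on a count (metaplastic polyps: text "one case", table
total 2, with 2/111 matching the printed 1.8%), the table is treated as
authoritative.

## Numerical choices and limitations

Tolerances: kernel normalisation 1e-10; semigroup blur composition holds
to ~1e-7 mean absolute difference on interior pixels (tested at 1e-4);
descriptor norms exact to machine precision; DLT on exact minimal data
recovers H to ~1e-14 relative Frobenius error. Degenerate inputs are
handled explicitly: all-zero descriptor sets warn and match nothing;
collinear 4-point samples are skipped; identical matches raise on the
pairwise disparity-gradient but are skipped as neighbours inside the
filter. Known limitations: two frames only (no bundle adjustment or
multi-frame drift control), no exposure compensation beyond feathering,
no denoising stage, and no claim about diagnostic utility of the mosaics.
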