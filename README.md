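# endostitch

Endoscopic image mosaicking with geometric mismatch filtering, plus a
worked gastric-polyp cohort tabulation.

Consecutive endoscopic frames show overlapping views of the mucosa under
changing illumination and viewpoint. Stitching them into a single mosaic
gives the endoscopist a wider, steadier view of a lesion — but naive
feature matching between such frames produces many wrong correspondences,
and a single surviving mismatch can visibly warp the mosaic. `endostitch`
implements the full pipeline with two dedicated mismatch filters between
coarse matching and model estimation.

## Method

1. **Scale-space keypoints.** The scale space of a frame is
   `L(x, y, σ) = G(σ) * I`, the image convolved with Gaussians of growing
   standard deviation σ; keypoints are strict local extrema of the
   difference of Gaussians `D(x, y, σ) = L(x, y, kσ) − L(x, y, σ)` over
   their 26 space-and-scale neighbours (k = 2^(1/s) with s = 3 intervals
   per octave, σ₀ = 1.6, 4 octaves), refined to sub-pixel position,
   filtered by contrast (|D̂| ≥ 0.03) and edge-curvature ratio
   (tr²/det < (r+1)²/r, r = 10), oriented by a 36-bin gradient histogram
   and described by the 128-D gradient-histogram descriptor (4×4 cells ×
   8 orientation bins, normalise → clamp 0.2 → renormalise).

2. **Coarse matching.** Nearest-neighbour descriptor pairing with the
   ratio test d₁/d₂ < 0.8 and one-to-one assignment.

3. **Slope-consistency pre-check.** Both frames are placed in one
   side-by-side composite coordinate system (target shifted right by the
   source width W). Each match i then defines a line of slope
   `kᵢ = (yᵢ′ − yᵢ) / (xᵢ′ + W − xᵢ)`. Correct matches concentrate in a
   narrow slope band; the filter censuses, for every candidate slope, the
   number of matches within the neighbourhood threshold t = 0.02
   (empirical value), keeps the densest neighbourhood and deletes the
   rest.

4. **Disparity-gradient filter.** For matches m, n with disparity
   vectors d(m), d(n) and cyclopean midpoints c(m), c(n), the disparity
   gradient is `‖d(m) − d(n)‖ / ‖c(m) − c(n)‖`; mutually consistent
   matches satisfy a gradient **strictly below 2**. Each match is tested
   against its K = 4 nearest spatial neighbours (median rule).

5. **Model building and blending.** A homography is fitted to the
   retained matches by normalised DLT inside seeded RANSAC (symmetric
   transfer error, 3 px threshold), refit on the consensus set; the
   frames are unified into one canvas and feather-blended (weights
   proportional to distance-to-frame-border, summing to 1).

A synthetic fixture generator produces endoscopic-like frame pairs
(band-limited texture, polyp-like blobs, vignette, illumination drift,
sensor noise) under a known homography, with exact correspondences and
controllable injected false matches, so every stage is benchmarked
against ground truth.

The package also bundles a 111-patient gastric-polyp cohort
(histology × age band / polyp diameter / location contingency tables) and
reproduces its marginal counts and percentage distributions — the worked
example the stitching pipeline was motivated by.

## Worked example

```bash
python examples/stitch_synthetic_pair.py
```

prints (machine-exact values may differ in the last digits):

```
keypoints:    224 / 222
filters:      {'retained': 159}
RANSAC:       159 inliers, rms 0.111 px
corner error: 0.052 px vs the generating homography
mosaic:       (266, 281) canvas, origin shift (-25, -9)
```

i.e. both frames yield ~220 keypoints, 159 matches survive the two
filters, RANSAC keeps all of them at 0.11 px residual, and the recovered
homography displaces the frame corners by 0.05 px relative to the
transform the pair was generated with — sub-pixel registration.
`examples/match_filtering_demo.py` shows the filters removing 98% of
injected false matches while retaining every true one, and
`examples/cohort_tables.py` prints the cohort marginals (e.g. elderly
≥ 60 y: 63 patients, 56.8%; hyperplastic polyps: 45, 40.5%).

The same pipeline is exposed as a CLI:

```bash
endostitch make-fixtures --out /tmp/fix --seed 4 --preset easy
endostitch stitch /tmp/fix/frame_a.png /tmp/fix/frame_b.png -o mosaic.png --report report.json
endostitch evaluate --fixture /tmp/fix
endostitch cohort --table age
```

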