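# Methods

## The model

`mammotrace` extracts the breast (skin-line) boundary of an MLO-view
mammogram as an ordered open pixel curve P¹…Pᵏ, grown one point at a
time.  Given the current point Pᵏ and its predecessor Pᵏ⁻¹, every pixel
P_cⁱ within Euclidean radius r of Pᵏ that the texture classifier accepts
as boundary is scored by the product

    P(Tⁱ) · P(P_cⁱ | Pᵏ, Pᵏ⁻¹) · P(P_cⁱ)

and the maximizer is appended.  The three factors:

1. **Texture probability P(Tⁱ).**  Each pixel's surroundings are
   described by local binary patterns: the 8-bit code of a pixel sets bit
   i−1 when its i-th neighbor (clockwise from top-left) is *strictly
   brighter* (δ(u)=1 iff u ≥ 1; the common u ≥ 0 convention is available
   behind the `convention="standard"` flag).  A w×w window (default
   w = 50) of codes is split into four equal quadrants whose 256-bin
   histograms concatenate into a 1024-vector, reduced by PCA to the
   smallest basis whose cumulative eigenvalue fraction exceeds 0.99.  A
   binary RBF-kernel SVM (cost and kernel width from a logarithmic grid
   search under stratified 5-fold cross-validation) separates boundary
   from non-boundary windows, and a logistic sigmoid fitted to its
   decision values converts the margin into P(boundary | window) — the
   two-class case of pairwise-coupling probability estimation, where the
   coupling problem is trivially a single sigmoid.

2. **Smoothness P(P_cⁱ | Pᵏ, Pᵏ⁻¹).**  For consecutive training-boundary
   points, the pair of segment directions (atan2(Δx, Δy) of the newest
   and previous segment, x = column, y = row) clusters tightly; a
   bivariate Gaussian (ML mean, covariance divided by N, + 10⁻⁶·I) fitted
   to that cloud is evaluated at the slope pair the candidate would
   create.  Angle residuals are wrapped into (−π, π] before the quadratic
   form, and the standard bivariate normalizer 1/(2π√|Σ|) is used.
   Because the conditioning variables are fixed across candidates at a
   given step, evaluating the joint density ranks candidates identically
   to the conditional.

3. **Laplace prior P(P_cⁱ).**  The sigmoid at the core of SVM probability
   estimation has no sharp transition near high probabilities, so
   near-best candidates look alike.  Evaluating the lower Laplace branch
   exp(−(μ−x)/β)/(2β) at x = P(Tⁱ) (defaults μ = 1, β = 0.05) multiplies
   the score by e for every β of extra texture probability, restoring a
   strong preference for the highest-probability candidates.

**Initialization** scans rows top to bottom; the first row containing any
boundary-classified pixel is fully evaluated and its maximum-probability
pixel starts the trace (with no history the smoothness term marginalizes
out and the prior is monotone in texture probability, so ranking by
texture probability is exact).  The second point is chosen without the
smoothness factor.  **Termination**: no candidate classifies as boundary,
a step cap (default 4000) is reached, or an accepted point touches an
image border side that the start point does not itself lie on — the start
sits on the border whenever the boundary meets the image edge, so only
contact with a *new* side marks the far end of the curve.  A Chebyshev
revisit-exclusion zone (default r/2) around previously accepted points
supplies the forward bias without assuming an orientation and guarantees
termination.

Ablation modes: `T` scores by texture alone, `TS` adds smoothness, `TSP`
(default) adds the prior.

The pectoral-muscle boundary is extracted by the identical pipeline
trained on pectoral-line ground truth; no separate code path exists.

## Training-set construction

Positives: every ground-truth boundary pixel plus its immediate left and
right neighbors (deduplicated).  Negatives: uniform random pixels,
re-drawn until exactly `n_negatives_per_image` (default 900) fall farther
than `exclusion_distance` (Chebyshev) from the boundary.

The exclusion default is 10 px, just beyond the phantom's ±7.5 px
textured transition band.  An exclusion of half the window (25 px) was
evaluated and rejected: it leaves no labeled example centered 2–25 px
from the skin line, so the classifier's "boundary" corridor widens to
±13 px and mean tracer deviation grows from ≈4.7 to ≈7.2 px at 512².
Negatives whose windows partially overlap the band are exactly the hard
examples that teach the model to localize.

For large training sets, `max_per_class` draws a seeded per-class
subsample before PCA and the grid search (SVM training is superlinear in
n); the pipeline runs here use 1200 per class with the factor-16
`COARSE_GRID`, which reaches the same CV accuracy as the full factor-4
grid on the phantom task at a fraction of the cost.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window` | 50 px | texture window side; must match between training and tracing (enforced by the model archive) |
| `radius` | 20 px | candidate search radius per step |
| `revisit_exclusion` | radius/2 | Chebyshev no-return zone around accepted points |
| prior `mu`, `beta` | 1, 0.05 | Laplace location and scale; `beta` sets the sharpening strength (ratio e per β of probability) |
| `exclusion_distance` | 10 px | Chebyshev distance within which random negatives are rejected |
| SVM grid | 2⁻⁵…2¹⁵ / 2⁻¹⁵…2³, ×4 steps | logarithmic cost/width search space |
| PCA rule | 0.99 | cumulative eigenvalue fraction retained |

## The phantom generator

`synthetic.generate_phantom` renders, deterministically per seed, a
mammogram-like 8-bit image (default 512×512): a near-black background
(mean 5, σ 2) right of a smooth open skin line; a breast interior left of
it ramping from 40 at the line to 180 deep inside, multiplied by
correlated speckle (Gaussian-filtered noise, correlation length 4 px,
relative σ 0.06 — tissue-like texture at mini-MIAS-like sampling); and a
15 px transition band with finer, stronger speckle (σ 10) bridging the
two, emulating the thin compressed boundary tissue.  The skin line is a
PCHIP spline through jittered control points, anchored `curve_margin`
(default 0.12) of the width from the left edge and bulging right by
0.26 of the width; amplitudes keep |dcol/drow| ≲ 1 so that per-row
integer sampling yields segment angles in a single tight cluster, the
regime the smoothness Gaussian assumes.  Options add a bright
pectoral-muscle wedge (top-left triangle to 0.65 of the height, with its
own ground-truth line) and a bright label rectangle in the background.
Ground truth is sampled at one-pixel row spacing, as manually annotated
boundaries would be.

What the phantom does *not* emulate: real parenchymal structure,
vessels/ducts, skin folds, scanner vignetting, or the label/breast
overlap failure cases.  Its texture classes are almost perfectly
separable, with two visible consequences measured in the acceptance
suite: calibrated probabilities saturate (so the Laplace prior has less
contrast to amplify than on real data), and texture-only tracing is
cleanly localized.  Passing end-to-end tests therefore demonstrates the
machinery — not performance on real mammograms.

## Numerical and design choices

- Coordinates are 0-based (row, col), origin top-left; slope vectors use
  x = col, y = row with the x-difference as atan2's first argument,
  consistently at training and tracing (any fixed convention is
  equivalent).
- LBP maps replicate-pad the image by one pixel; descriptor windows clamp
  to the image by edge replication, so every pixel — including the border
  rows the initialization scans — has a descriptor.
- Ties: the start row takes the leftmost maximum; candidate argmax breaks
  ties in row-major order; the greedy snake keeps a vertex in place
  unless a strictly lower energy exists.  All runs are bitwise
  reproducible given seeds; the trace loop itself uses no randomness.
- `acc_mean` uses the slope-free point-line distance
  |Δx(y_e−y₁) − Δy(x_e−x₁)|/√(Δx²+Δy²), defined also for vertical
  ground-truth segments where the slope-intercept form divides by zero.
  When the two nearest ground-truth points tie in distance, a gt-order
  neighbor of the nearest is preferred so the local line joins adjacent
  points.  The measure is deliberately asymmetric (extracted → gt).
- The curve measure sums squared first and second differences over
  interior points only (both neighbors required); it is translation- and
  rotation-invariant but *not* normalized by point count, so comparisons
  are meaningful only between boundaries of similar extent — a caveat
  that matters for truncated traces (see limitations).
- The greedy snake moves each vertex within an odd search window to the
  minimum of α·E_ext + β·‖vᵢ−vᵢ₋₁‖² + γ·‖vᵢ₊₁−2vᵢ+vᵢ₋₁‖², visiting
  vertices in index order with previous-iteration neighbors.  The β/γ
  naming follows the formulation reproduced here, which attaches
  "curvature" to the first difference and "continuity" to the second —
  the standard snake names are swapped; weights bind to the formulas, not
  the names.
- The threshold baseline replaces an under-specified iterative method
  with Otsu thresholding, largest connected component, 3×3 closing, and
  an ordered outer-edge trace clipped to pixels that actually abut
  background inside the image.

## Problem sizes in the test and acceptance runs

The shipped end-to-end runs use 5 training + 5 test phantoms at 512×512
for clean-recovery figures and 5 + 20 at 256×256 (boundary-band noise
doubled to σ 20) for the mode ablation, with 1200 training samples per
class and the coarse grid.  These sizes reproduce the qualitative
behavior of interest — full-span recovery, the mode ordering, and the
stability contrast between modes — at desk-scale cost.

## Known limitations

- On the cleanly separable phantom task the calibrated probabilities of
  near-boundary windows all approach 1, so the prior's sharpening — whose
  design assumes visible probability contrast among good candidates —
  contributes less than on real, noisier data.  The measured consequence:
  texture-only tracing is the most accurate mode (≈2.9–4.7 px mean
  deviation of traced points), full TSP tracing runs ≈4.2–4.7 px (the
  smoothness factor trades a few pixels of localization for robustness),
  and TSP is by far the most *stable* (every trace spans ≥98% of the
  boundary, while texture-only traces occasionally die early, spanning as
  little as 15%).
- The curve-measure comparison between modes is confounded by trace
  length: a truncated trace loses curve mass.  Per-point jitter between
  texture-only and TSP traces is equal on phantoms.
- The pectoral wedge's boundary is a long-range intensity edge, so
  texture windows localize it only coarsely (≈10 px).
- Boundaries are open curves; closed contours, sub-pixel refinement, and
  multi-boundary extraction are out of scope.
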