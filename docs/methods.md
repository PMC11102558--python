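# Methods

## The measurement

The ratio of cadherin-5 discontinuity quantifies fragmentation of the
adherens-junction signal along a single cell's perimeter. Two processing
tracks share the raw 8-bit channel and the rolling-ball background
subtraction, then diverge:

1. **Geometry track** (where is the cell outline?). Background-subtracted
   image → Gaussian blur σ = 2.0 px applied twice → 3×3 sharpen (center 12,
   neighbors −1, divisor 4, clipped to 0–255) → Huang fuzzy-entropy
   auto-threshold → foreground = strictly above threshold → 3×3 binary
   dilation twice → automated bridging of broken junctions → skeletonization
   with spur pruning → each enclosed face of the skeleton traced as one
   closed pixel loop → uniform random sample of 25 complete outlines per
   image.
2. **Scoring track** (is there junction signal under the outline?). The same
   background-subtracted image binarized at the fixed window 21–255
   (inclusive), with no smoothing — the geometry track deliberately fills
   gaps so outlines stay closed; the discontinuity must be read from a mask
   that still shows them.

Each selected outline is profiled pixel-by-pixel on the scoring mask and the
ratio is 100 × (zero-valued profile pixels) / (profile length). The heavy
filtering exists only to close the outline; the fixed 21–255 window, applied
to the almost-raw signal, decides presence or absence of junction staining.

Rationale for reading "intensity 0" on the binary mask rather than the raw
image: the procedure binarizes immediately before profiling, so profile
values can only be 0 or 255, which makes "pixels with an intensity 0" a
stable count rather than a quantity that depends on camera offset.

## Statistics

Per-cell ratios are pooled across the images of a condition (the cell is the
unit of analysis, matching the classic 100-cells-over-4-images design) and
compared with the Kruskal–Wallis rank test: tie-corrected H, p from the
chi-squared approximation with (groups − 1) degrees of freedom. Box-plot
summaries use linear-interpolation quartiles. A per-image aggregation is
also exported, with the caveat (written into the output) that cells within
one image are not independent; no mixed-effects modeling of the image or
experiment level is attempted, and no post-hoc pairwise tests are run.

TEER: `(R_exp − R_blank) × 0.32 Ω·cm²` (0.32 cm² is the membrane area of the
standard 24-well 0.4 µm insert), optionally divided by the pre-stimulation
baseline. Negative blank-corrected resistance is rejected as a labeling
error rather than silently clipped.

## The synthetic monolayer generator

The generator emulates what the assay actually sees: a confluent monolayer
whose junctional signal is a bright, ridge-like band along shared borders,
fragmented to a controlled degree.

* **Tessellation.** Seed points sampled uniformly with a minimum-separation
  rejection rule, then regularized by 4 Lloyd (centroidal Voronoi) steps.
  The relaxation matters: raw random Voronoi contains near-degenerate
  vertices with thin wedge corners that no real monolayer shows (junctions
  meet near 120° in confluent endothelium), and borders closer together than
  the rendered junction width cannot be resolved by any downstream method.
* **Junction rendering.** Shared borders are rasterized as the two facing
  1-px chains of pixels whose 4-neighbor carries a different cell label. The
  surviving junction is rendered as `peak · exp(−d²/2σ²)` of the distance to
  the nearest junction pixel (default σ = 1.5 px, peak 200), plus a smooth
  low-frequency illumination field (bicubic upsampling of a 6×6 random grid,
  amplitude 30) and Gaussian pixel noise (σ = 5). Peak + illumination ≤ 255
  by construction, so the render never saturates.
* **Gaps (the ground truth).** Contiguous spatial intervals of border —
  covering both facing chains — are deleted until the requested global gap
  fraction is met; interval lengths are drawn around `gap_length_pixels`
  (default 12 px, a few µm at typical 20× sampling) and the final interval
  is trimmed so the realized fraction lands on the request. Gap placement is
  uniform along total junction length.
* **Defaults as study conditions.** 512×512 px, 60 cells per field (so that
  ≥ 25 complete interior cells are available per image, matching the
  25-cells-per-image design), one image per derived seed;
  `generate_condition_panel` derives independent per-replicate seeds from a
  base seed, so a whole panel is reproducible from one integer.

What the generator does **not** emulate: nuclei or any second channel,
optics (PSF, depth of field), photobleaching, intensity variation along a
junction, cell-size heterogeneity beyond Voronoi variation, and cytoplasmic
background texture. Passing tests on synthetic panels therefore demonstrate
that the operator chain and statistic behave as specified under controlled
geometry and noise — not that segmentation will survive every real staining
artifact. Physical pixel size is deliberately absent: all lengths are in
pixels, and calibration is the user's concern.

## Numerical and design choices

* **Rolling ball** is the classic ball-of-radius-r grayscale opening
  (scikit-image's exact implementation), radius 20 px, reproducible from the
  printed radius alone — not the sliding-paraboloid variant.
* **Huang threshold**: for each candidate t the below/above classes get
  means μ₀, μ₁; membership u(g) = 1/(1 + |g − μ_class|/C) with C the dynamic
  range; fuzziness is the histogram-weighted Shannon entropy of u; the
  minimizing t wins, ties broken toward the smaller t. On a pure two-level
  image every candidate has zero fuzziness and the tie rule returns the
  lowest candidate — still a correct split under the strictly-greater
  binarization convention. A constant image has no threshold and is an
  error.
* **Blur passes** are composed in float and quantized once, so two passes at
  σ equal one pass at σ√2 to within one intensity unit.
* **Bridging (`close_gaps`)** replaces the interactive line-tool touch-up.
  Loose ends of the thinned network are joined to the nearest network pixel
  (another loose end, or the flank of a continuing border at three-way
  corners) by a straight stroke. The budget `max_bridge` (default 10 px)
  bounds the *uncovered* span the stroke crosses, because thinning retracts
  blunt stub tips well inside the inked area; a target already reachable by
  a short path along the network is skipped, and bridging is iterated until
  stable.
* **Skeletonization** fills holes below 32 px² first (far below any
  plausible cell face; they would thin into tiny loops at junction corners),
  then iterates thinning and spur pruning (< 5 px) to a joint fixed point,
  which makes the operation idempotent by construction and preserves
  connected components.
* **Outline tracing**: faces are 4-connected background regions of the
  skeleton; each face's surrounding ring is traced by Moore-neighbor
  boundary following and snapped back onto skeleton pixels where the trace
  steps one pixel inside at diagonal staircases. Loops under 20 px are
  discarded as noise. The path is an ordered, closed, repeat-free 8-connected
  loop, so the ratio is invariant to starting pixel and traversal direction.
* **Border policy**: an outline whose face touches the frame, or whose path
  comes within a 20 px guard band of it, is never scored — within that band
  the filter chain's support extends beyond the image and junction geometry
  is unreliable. On the truth side, `MonolayerTruth.scorable_cells()`
  mirrors the same policy on the *observable* geometry (junction mask
  dilated by the 8 px rendered half-width), because a frame-clipped cell
  whose borders converge just outside the field can be sealed shut by the
  blur and appear complete; territory membership alone cannot predict what
  extraction sees.
* **Selection** of the 25 scored cells is a seeded uniform draw without
  replacement; an undersupplied image returns all eligible outlines with a
  recorded warning.
* **Determinism**: every stage is deterministic; the two random stages
  (simulation, cell selection) are fully determined by recorded seeds, and
  the result CSV is byte-identical across reruns of the same configuration.
  All outputs embed a hash of the analysis parameters.

## Known limitations

* **Vertex sealing bounds outline fidelity.** After the mandated σ = 2 blur
  (twice) and double dilation, the rendered junction band is ~12–16 px wide;
  wherever two borders approach more closely — sharp wedge corners, borders
  converging near the frame — they merge, and the traced outline must cut
  across the sealed wedge (a simple closed pixel loop cannot descend a
  merged single line and return without repeating pixels). Outlines
  therefore track the true boundary to within ~1–3 px along open borders
  but can deviate 4–6 px at such corners, even at an ideal 120° vertex
  (merge height ≈ 3.5 px). This is a property of the published operator
  chain, not of the tracer.
* **The statistic under-reports the true gap fraction.** Ridge tails extend
  ~3 px into each gap end above the fixed 21 threshold, so short gaps are
  partially masked; on the standard recovery panel the measured means for
  true fractions 0/0.1/0.2/0.4 are ≈ 0/2.5/6.4/16 %. Ranking and
  correlation (Spearman ρ ≈ 0.95 per image) are preserved — the statistic
  is a sensitive *relative* measure, not an unbiased gap estimator, which
  matches how it is used for group comparisons.
* **Cells within an image are treated as independent** by the omnibus test,
  as in the original design; the per-image export exists for users who want
  to aggregate first.
* **Problem sizes.** The test suite and the acceptance script use 256×256
  fields (9–25 cells) for geometry checks and 512×512 fields (60 cells,
  8 images per condition, 4 conditions) for end-to-end recovery; these sizes
  give stable statistics while keeping a full run to minutes on one CPU.
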