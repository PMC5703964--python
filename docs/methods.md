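# Methods

`isletmorph` quantifies pancreatic endocrine-cell mass and islet number
from whole-organ section series. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Stereological model

The core estimator is classical area-fraction stereology. For block $b$
with tissue section area $A_b$ and summed islet-structure area $E_b$,
the percent fractional area is $p_b = 100\,E_b/A_b$. The donor-level
fraction is the tissue-area-weighted mean

$$\bar p_w = 100\,\frac{\sum_b E_b}{\sum_b A_b},$$

which is the unbiased whole-organ estimator when every block is
sectioned; the unweighted mean ± SEM over blocks is also reported as the
conventional regional summary. Taking area fraction as volume fraction
(Delesse principle) and tissue density $\rho \approx 1$ g/mL, absolute
mass is

$$m_x\,[\mathrm{mg}] = \frac{\bar p_{w,x}}{100}\, W\,[\mathrm{g}] \times 10^3,$$

with $W$ the measured pancreas weight. A measured weight is required:
substituting population-based organ volume is a documented source of
bias and is deliberately not offered. Analyzed blocks are treated as
representative of the whole organ (alternating-block sampling), with no
correction factor.

Two endocrine percentages exist and are kept distinct throughout:
`pct_endocrine` is the total islet-structure area ratio (including
unstained intra-islet fractions such as capillaries), while
`pct_beta/alpha/delta` are hormone-positive area ratios. When no
explicit endocrine profile is supplied, the endocrine percent falls back
to the sum of the three hormone percents and masses are exactly
additive.

## Segmentation and shape metrics

Islet structures are connected components of the union of thresholded
hormone channels after morphological closing and hole filling.

- Thresholding: Otsu per channel by default (constant channels map to
  all-background if zero, all-foreground otherwise); a fixed threshold
  is available for calibrated data.
- Closing radius: 7.5 µm (half a 15 µm cell diameter), so touching
  cells merge and intra-islet capillaries are spanned. Structures
  closer than twice this radius merge — a declared grouping rule, since
  no standard exists. Implemented as a Euclidean closing via two
  distance transforms, executed per padded bounding box of coarse
  foreground clusters; clusters are grouped beyond the interaction
  range, so the tiled result equals the full-image closing.
- Minimum structure: 178 µm² (one cell-equivalent), making single
  hormone-positive cells the smallest recorded cluster.
- Perimeter: from the marching-squares sub-pixel contour, smoothed with
  a 5-point circular moving average. The raw contour staircases along
  the pixel grid and reads a digitized disk ~6% long, biasing
  circularity ($4\pi A/P^2$) low; after smoothing, disks of radius
  ≥ 5 px measure within ±2% of circularity 1 while true corners are
  barely rounded (a rasterized square reads ≈ 0.80 vs the exact π/4 ≈
  0.785). Mask circularity is clipped at 1.0; analytic polygon metrics
  are unclipped.
- Feret diameter: rotating calipers on the convex hull of the raw
  (unsmoothed) contour, verified in tests against the exhaustive
  pairwise maximum.
- Coordinates are pixel centers, origin top-left, x right / y down; all
  reported geometry is in µm.

## Size scale and binning

Islet area divided by the single-cell reference area 178 µm² gives a
dimensionless cell-equivalent count $n$; bin $k \ge 1$ spans
$[2^{k-1}, 2^k)$ (lower edge inclusive). Effective diameter is
$d(n) = 2\sqrt{n\cdot 178/\pi}$; bin edges reported as integers are
truncated toward zero, reproducing the conventional printed ranges
30–42, 60–85 and 120–170 µm for bins 3, 5 and 7. Structures below one
cell-equivalent would be labeled "sub-cell" and excluded from summaries
(the generator never produces them; measured data might). Per-islet
composition is area-based — hormone area over summed hormone area — and
per-bin composition is the unweighted mean ± SEM across islets of one
donor; pooling across donors is a reporting option, not the default.

## Islet number and IEQ

The islet number estimate divides the endocrine volume budget
(mass/density) by a representative islet volume per size bin:

$$N_k = \frac{m\,s_k \times 10^{-3} / \rho \times 10^{12}}
             {\overline{V}_k\,[\mu m^3]},$$

where $s_k$ is bin $k$'s share of total observed islet area (2D shares
read as volume shares) and $\overline V_k$ the arithmetic mean of
per-islet sphere volumes $V = (\pi/6)\,d_\mathrm{eff}^3$. The sphere on
the effective diameter is this package's declared 2D→3D volume model —
the choice is genuinely open, and a bin-midpoint volume mode exists in
spirit via custom inputs but the per-islet mean is the default because
it uses all measured data. Σ$N_k \overline V_k$ equals the volume
budget identically, so total IEQ (= budget / $V_{150\,\mu m}$) is
conserved under any re-binning. The >40 µm count applies the same
formula restricted per islet (sub-bin resolution at the cut inside bin
3). The clinical yield criterion is strict: IEQ > 400,000. Counts are
real-valued internally and rounded only for reporting.

Because the pipeline observes 2D sections only, the generator's "true"
islet number used in recovery tests is defined as the same volume
bookkeeping applied to ground-truth areas and ground-truth mass. Those
tests therefore measure segmentation and binning error, not the truth
of the stereological 2D→3D model itself.

## Synthetic donor generator

The generator emulates the statistical structure the analysis assumes:

- Sizes: log-normal cell-equivalent counts conditioned on ≥ 1 cell
  (log-mean ln 5, log-SD 1.0 by default), i.e. a heavily right-skewed
  distribution whose median structure is a ~34 µm cluster. The family
  is a generator choice, not a biological claim.
- Composition: beta fraction 0.60 for every bin up to bin 6 (the first
  bin reaching 100 µm), then −0.03 per doubling bin, clamped to
  [0, 1 − delta]; delta constant at 0.10; alpha the remainder. This
  makes small-islet (<100 µm) beta composition exactly the configured
  60% and beta decline in larger islets.
- Shape: aspect ratio 1 + 0.08·(k−1) with small Gaussian jitter, so
  large islets elongate; orientation uniform.
- Regional profile: per-block endocrine fraction interpolates
  head 0.4% → tail 1.0% with multiplicative log-normal noise of CV
  0.35, then is renormalized so the tissue-weighted mean equals the
  configured donor mean — the noise redistributes endocrine tissue
  across blocks without moving the whole-organ truth, which keeps
  targeted configurations (`config_for_target_beta_pct`) on their
  nominal value.
- Within a block, islets are drawn until the cumulative area is closest
  to the block's target endocrine area (the last draw is kept only if
  it reduces the gap), so realized block fractions track the profile to
  ~2% per block.
- Defaults: 24 blocks of 5 × 5 mm sections at 1 µm/px, tissue
  rectangles covering 85–100% of the frame edge, pancreas weight 100 g,
  density 1 g/mL — mimicking the scale (not the identity) of adult
  human organs with mean endocrine fraction ~0.7% and a few thousand
  islet sections per donor.
- Rendering partitions each ellipse's pixels among the three hormone
  channels in exact proportions, grouped into ~178 µm² cell-like
  patches; islets are placed with ≥ 20 µm clearance (beyond twice the
  default closing radius) so distinct islets do not merge during
  segmentation. Table mode skips rasterization and emits analytic
  ellipse measurements (Ramanujan perimeter), which is exact and fast.

What the generator does **not** model: 3D tissue (sections are
independent planes), nuclei, imaging noise or point-spread, staining
variability, overlapping or concave islets, acinar texture, or
non-parenchymal holes in the tissue mask. Passing recovery tests
therefore shows the measurement chain is faithful on clean geometry at
realistic scales and abundances; it does not certify performance on
real immunofluorescence images, where thresholds and the grouping
radius need tuning.

## Sampling-bias simulator

"Islet-containing area" selection is operationalized as ranking
candidate units (blocks, or square fields tiled from section masks) by
endocrine density and averaging the top fraction q; random selection
uses a seeded generator. Fold-overestimation is the biased estimate
over the tissue-weighted whole estimate. Point counting lays a regular
grid (spacing and offset in µm) and reports hormone-positive hits over
tissue hits; at 1-px spacing it equals the pixel fraction exactly, and
its offset-average is exactly unbiased. Fold values are data-dependent
descriptions, not constants: on default synthetic donors, aggressive
field-level selection (top 2% of 500 µm fields) yields severalfold
overestimates.

## Numerical and interface choices

- All randomness flows from `numpy.random.default_rng` seeded via the
  config; per-islet render streams derive from (seed, block, islet), so
  donors are bit-reproducible for a fixed seed.
- Degenerate inputs: empty sections segment to an empty list; zero
  tissue area, empty block lists, zero selection and zero-volume
  density inputs raise `ValueError`; a single-pixel component gets a
  pixel-boundary perimeter so circularity stays defined; islets with
  zero hormone-positive area are excluded from composition summaries
  with a logged warning.
- Problem sizes in the shipped tests and the acceptance script are
  chosen for a laptop-class single-core run: recovery suites use 20
  donors of 6 blocks at 1536² px, and the end-to-end rendered run uses
  20 blocks at 5000² px (~1 minute); the statistical conclusions are
  insensitive to these sizes.
- The packaged `cohort_reference_synthetic.csv` is a hand-built,
  synthetic 10-donor display table used by report/plot smoke tests; it
  is not pipeline output.

## Known limitations

- The 2D→3D volume model (sphere on effective diameter) is the largest
  unverifiable assumption in the islet-number estimate; sectioning
  stereology (e.g. Wicksell-type corrections) is intentionally out of
  scope.
- Otsu thresholds are only sensible on images with clear bimodal
  channels; real data generally needs the fixed-threshold path.
- Circularity clipping at 1.0 discards the (small) discretization
  overshoot rather than propagating it.
- Cohort correlations are descriptive Pearson r with n; no inferential
  testing is provided by design.
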