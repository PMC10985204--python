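# Methods and conventions

This note records the algorithmic conventions used throughout
`micsflow`, the default parameters, and why each convention was chosen.
Everything here is testable against the synthetic ground truth or an
independent brute-force oracle; the test suite does exactly that.

## Synthetic tissue model

The generator (`micsflow.synth`) is the ground-truth source for every
downstream stage.

- **Placement.** Nucleus centers are rejection-sampled so that every
  placement circle (radius = nucleus radius) lies fully inside the
  image and circles are pairwise separated by at least 2 px. Nuclei are
  rendered as rotated ellipses *inscribed* in their placement circle
  (major semi-axis = r, minor = r·eccentricity), so rendered nuclei can
  never touch each other or the border.
- **Intensity.** Each cell type specifies per-marker lognormal rate
  mixtures: positive ln-mean ln 20, ln-sd 0.35; negative ln-mean
  ln 0.8, ln-sd 0.5 — medians separated ~25-fold. Pixel values are
  rate × exposure + background × exposure + Gaussian read noise,
  quantized to 12 bits (saturation 4095). SNR is defined as
  nuclear DAPI rate / read-noise sd; the defaults 30/3 give SNR 10.
- **Determinism.** One `numpy` Generator seeded from the spec drives
  every draw, so identical specs give bit-identical scenes.
- **Pixel pitch.** The package default is 0.106 µm/px (so a 25 µm
  radius spans ~236 px). The synthetic demos use 0.5 µm/px so that
  whole scenes with hundreds of cells stay small; all geometric
  parameters are specified in µm and converted per scene, so the pitch
  is a free parameter, not an assumption.

## Image preprocessing

- **Exposure fusion.** For each pixel the fused value is intensity ÷
  exposure time from the *longest unsaturated* exposure (saturation
  4095). Pixels saturated at every exposure are flagged and fall back
  to the shortest exposure.
- **Bleach subtraction.** Fused stain minus fused bleach, clipped at 0.
- **Stitching.** Integer shifts between overlapping tiles are estimated
  by maximizing normalized cross-correlation over a ±15 px window on
  the DAPI channel (windows smaller than 8 px of overlap are rejected).
  Tile origins follow a spanning tree from the first tile; shifts with
  confidence below 0.3 fall back to nominal origins. Overlapping mosaic
  pixels are averaged.
- **Cropping.** A fixed border of 200 px top/bottom and 100 px
  left/right is removed from stitched mosaics, matching the region with
  reliable DAPI after stage-motion artifacts.

## Segmentation

- **Detection.** DAPI is Gaussian-smoothed (σ = 1.5 px) and thresholded
  at a quantile mapped from the `sensitivity` parameter: sensitivity 0
  → quantile 0.999 (nearly nothing), 0.5 → the Otsu threshold's
  quantile, 1 → half the Otsu quantile; the mapping is piecewise-linear
  and monotone, so higher sensitivity never shrinks the foreground.
- **Splitting.** Touching nuclei are split by watershed on the negated
  distance transform. Markers are plateau maxima of the morphological
  reconstruction of (distance − h) under distance, intersected with the
  foreground: this merges peaks whose separating saddle is within h of
  the peak height, so `separation_force` interpolates smoothly from
  "never split" (h ≈ min nucleus radius) to "always split" (h = 0.1 px).
  The intersection with the foreground guarantees at least one marker
  per connected component even when h exceeds every peak.
- **Size filter.** Components outside the equivalent-diameter range
  (default 4–20 µm) are removed and labels are re-compacted.
- **Constrained donut.** The cytoplasmic ring is a fixed-width (default
  3 µm) expansion where every pixel joins its *nearest* nucleus
  (Euclidean distance transform; scikit-image `expand_labels`). Rings
  therefore never overlap; equidistant pixels resolve by scan order,
  which the tests treat as a legitimate tie.

## Expression normalization

- **Compartment means.** Each marker yields nucleus, cytoplasm
  (donut minus nucleus), and whole-cell mean intensities per cell;
  empty compartments give NaN.
- **Winsorization (fixed convention).** Percentile caps use *inward
  closest-rank order statistics*: on the sorted finite sample of size
  n, the lower cap is element `ceil(p_lo/100·(n−1))` and the upper cap
  is element `floor(p_hi/100·(n−1))`. If the ranks cross, no capping is
  applied. This convention — rather than linearly interpolated
  percentiles — is required for winsorization to be **idempotent**:
  caps are actual sample values, so re-winsorizing clipped data
  recovers the same caps. Linearly interpolated percentiles re-estimate
  strictly inside the clipped range and provably fail idempotence.
  Defaults: 1st/99th percentile per marker and compartment.
- **arcsinh.** Capped values are transformed by arcsinh(x / cofactor),
  cofactor 1 by default: zero maps to zero, the map is strictly
  monotone, and for x ≫ cofactor it approaches ln(2x/cofactor).

## Phenotyping

- **Gates.** Populations are JSON gate trees over marker positivity
  atoms, explicit comparison atoms, boolean combinators (`all`, `any`,
  `not`), and references to previously defined populations. Schemas are
  priority-ordered; a cell receives the highest-priority satisfied
  label, else the schema's unassigned label.
- **Automatic thresholds.** Per marker, the threshold is the midpoint
  of the largest gap between consecutive unique normalized values
  (degenerate distributions threshold above the maximum, i.e. all
  negative). The largest gap is robust for the strongly bimodal
  arcsinh-transformed synthetic data and for rare-positive markers
  where variance-based criteria misplace the cut.
- **T-cell states.** Differentiation uses a first-match table of six
  states (TN, TSCM, TCM, TEM, TEMRA, TTE) over
  CD45RA/CD45RO/CD27/CD95/CD11a; the activation ladder resolves
  co-positivity to the latest tier (CD69 early < CD25 late < HLA-DR
  very late); exhaustion is anchored on PD1 (single = PD1 only,
  double/triple add TIM3/LAG3).
- **PD1 tiers.** Percentile ranks use the average-rank tie convention
  pr = 100·(avg_rank − 1)/n over the reference sample; quartile cuts
  (25, 75) give low/intermediate/high and a rank exactly at a cut
  belongs to the upper tier.

## Neighborhood analysis

- **Radius query.** Anchor cells of a chosen population collect all
  cells within radius r (boundary inclusive, d ≤ r) via a k-d tree;
  the contract is identical to brute-force pairwise distances, which
  the tests verify. Anchors themselves are excluded from neighbor sets
  unless requested.
- **Enrichment null.** The permutation test shuffles cell labels over
  positions (fixing the anchor geometry), recomputes the pooled
  within-radius fraction of the target population, and reports the
  add-one p-value (b+1)/(n+1).

## Workflow

The staged pipeline (synth → process → segment → express → phenotype →
neighborhood → report) writes a manifest with a SHA-256 digest per
output file. CSVs are written with 9 significant digits, which is
enough to round-trip float64 through text for the value ranges
produced here; two runs with the same seed produce byte-identical
CSVs.

## Limitations

- The synthetic model draws one rate per cell and marker (no
  subcellular texture), so segmentation and normalization recover
  parameters more cleanly than on real tissue.
- Stitching estimates integer shifts only; subpixel registration and
  rotation are out of scope.
- Automatic thresholds assume bimodality; on unimodal real-data
  distributions, explicit threshold overrides should be supplied to
  `apply_schema`.
- The cycle planner is greedy first-fit; it is validated for
  correctness (no rule violations, full coverage) but not minimality
  of cycle count.
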