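# Methods

## What the package measures

At pachytene, each pair of synapsed homologous chromosomes (a bivalent)
appears in an immunostained spermatocyte spread as an elongated ribbon of
SYCP3 (red). Mature, interfering crossovers are marked by MLH1 foci (green)
and the centromere by CREST (blue). For each bivalent the package measures:

* **SC length** — the length of the straightened midline of the ribbon, in
  pixels and micrometres;
* **centromere position** and **MLH1 focus positions** — projected onto the
  arc-length coordinate of that midline, then oriented so that arc 0 is the
  centromere-proximal end and normalized by SC length.

Per-cell MLH1 totals estimate the genome-wide recombination rate (one focus
≈ one crossover ≈ 50 cM). Chromosome 1 — the metacentric with the longest
SC — is isolated per cell by rule, and its focus counts and positions feed
the crossover-patterning statistics.

## Measurement pipeline

1. **Preprocessing.** Per channel, a least-squares plane is subtracted
   (removing constant background and linear illumination gradients exactly)
   and intensities are min–max rescaled to [0, 1]. The operation is exactly
   idempotent, which makes reprocessing safe.
2. **Segmentation.** The red channel is smoothed (Gaussian, σ = 1 px) and
   thresholded at the larger of Otsu's value and a robust background bound
   (median + 6·1.4826·MAD), so a signal-free image produces no objects.
   The mask is closed with a radius-1 disk and hole-filled; connected
   components are enumerated row-major by bounding-box origin.
3. **Heuristic bivalent classification.** A candidate passes if all criteria
   hold, checked in a fixed order (the first violation is reported): area
   150–6000 px², pruned-skeleton length 30–400 px, eccentricity ≥ 0.85,
   solidity ≥ 0.25, zero branch points after pruning spurs < 5 px, and a
   3-px border margin. The thresholds make the qualitative "elongated
   ribbon" notion explicit and are calibrated on synthetic spreads only;
   all are configurable.
4. **Midline.** The mask is skeletonized; spurs shorter than 5 px are
   pruned; the midline is the longest geodesic path between skeleton
   endpoints (ties broken lexicographically on the endpoint pair). A cubic
   smoothing spline is fitted, with stiffness halved until the curve
   deviates from the skeleton by at most 1 px. Because skeletons recede
   from ribbon tips, both ends are extended along the end tangents until
   they leave the mask (0.25-px steps, capped at 12 px). The curve is
   resampled at 0.5-px arc steps; SC length is the integrated length of
   this smoothed, extended curve (integrating the raw skeleton instead
   would under-measure by the receded tips and over-measure pixel
   staircasing).
5. **Foci and centromere.** Background mean and SD are computed outside all
   (dilated) object masks. Green local maxima above background mean + 4 SD
   and within 6 px of the midline are projected to the nearest arc
   position; maxima closer than 5 px along the arc are merged to their
   intensity-weighted centroid (one physical focus, double-detected). The
   centromere is the brightest in-ribbon blue maximum; an exact brightness
   tie picks the candidate nearer an end and flags
   `ambiguous_centromere`; several strong candidates flag
   `multiple_centromeres`; no candidate flags `no_centromere` (the
   bivalent keeps its focus count but is excluded from position analyses).
6. **Orientation.** If the centromere falls in the distal half, all
   positions are reflected (x → L − x); foci are then sorted ascending,
   i.e. by proximity to the centromere end. The reflection is an
   involution.

## Curation rules

The two dominant automated error classes are diagnosed from the output
tables alone, without re-measurement:

* **Merged bivalents** (two ribbons traced as one): residual skeleton
  branch points, more than one strong centromere candidate, or an SC
  length above a per-cell robust bound (median + 3.5·1.4826·MAD).
* **Extra foci**: more than 4 foci on one bivalent (flagged, never silently
  truncated), or any focus whose perpendicular offset from the midline
  exceeds 2.5 px (the centrality re-check: genuine foci sit centred within
  the SC width).

Chromosome-1 isolation: the longest measured bivalent of each cell, if it
is unflagged, has SC length within 10–17 µm and normalized centromere
position within 0.15–0.40 (a window bracketing per-mouse chromosome-1 means
of roughly 11–14 µm and the ~0.25 mean centromere position); at most one
candidate per cell. The longest-in-cell requirement together with an
optional reject list replaces interactive manual verification, keeping the
step reproducible. Accuracy against a reference table is summarized per
metric (SC length, centromere position, focus position) by Pearson's r and
mean signed percent bias, after greedy one-to-one centroid matching of
measurements to reference rows.

## Statistics

* **Count summaries.** Sample SD uses n − 1; SE = SD/√n; CV = 100·SD/mean.
  Group rows pool per-mouse rows: the weighted mean uses cell counts as
  weights (equal to the raw pooled mean); the unweighted across-mice mean
  is reported alongside; the pooled SD combines within- and between-mouse
  sums of squares on an n − 1 denominator. Machine files keep full
  precision; report files round to 3 decimals.
* **Map length.** 50 cM per MLH1 focus times mean foci per cell.
* **Positions.** Normalized positions are binned at 5% for display only;
  the two-sample Kolmogorov–Smirnov test runs on the raw unbinned
  positions (a KS test on binned data is ill-defined).
* **Interference.** For two-focus bivalents the inter-focus distance
  (absolute µm, or normalized by SC length) is fitted to a gamma
  distribution; the shape ν measures interference strength (ν = 1 is no
  interference). The fit is plain maximum likelihood: the digamma equation
  log a − ψ(a) = log(mean) − mean(log x) is solved by safeguarded Newton
  iteration (bisection-bracketed, tolerance 1e-8); no small-sample bias
  correction is applied. Distances below 1 µm are excluded and reported —
  implausibly short gaps are double detections of one focus, not genuine
  double crossovers; the threshold generalizes a single-outlier removal to
  a rule.
* **Intra-chromosomal r̄.** For sorted normalized crossover positions
  partitioning the bivalent into proportions a₀…a_m,
  r̄ = ½(1 − Σ aᵢ²) ∈ [0, 0.5]. This closed form equals the probability
  that a uniformly drawn locus pair recombines in a random gamete when
  each crossover involves a random chromatid with probability ½ (no
  chromatid interference); the test suite checks it against an independent
  Monte-Carlo gamete simulation.
* **Permutation tests.** Mouse-level label permutation with two statistics:
  difference in the mean of within-mouse count variances, and difference in
  the variance of mouse mean counts. Two-sided p with the add-one
  correction p = (1 + #{|T*| ≥ |T|})/(n_perm + 1); default 10,000
  permutations; sidedness is a conservative choice, as the scientific
  question is whether the groups *differ*.
* **Logistic model.** P(2 foci vs 1) as a logit in SC length, optionally
  with a covariate; single-class samples and perfect separation raise
  rather than returning unstable estimates. Bivalents with 0 or 3 foci are
  excluded from position and logistic analyses (configurable).

## Synthetic spreads

The generator emulates what the measurement code must cope with, not
photorealism: cubic-spline ribbons (resampled at 0.25 px for sub-pixel
length accuracy) of width 5 px and arc length 80–160 px, ~24 per 900² px
cell (a full karyotype of 23 autosomes plus one XY body with attenuated
green/blue signal); foci as isotropic Gaussians (σ = 2 px, clipped at 3σ)
on the midline — longer bivalents more likely to carry two well-separated
foci, mimicking interference; centromeres at 0.18–0.32 of arc length
(metacentric-like, matching the ~0.25 convention); additive Gaussian noise
(SD 1% of range), optional salt speckle, and a 10% corner-to-corner
multiplicative illumination gradient; 16-bit channels. Flat ribbon end caps
make the rendered tip coincide with the nominal arc endpoints, so manifest
arc lengths are exact oracles.

Two error-injection controls drive the curation tests: overlap-designated
bivalents are placed end-to-end continuing an existing ribbon (a merge that
*passes* the shape heuristics and must be caught by curation), and
`n_stray_foci` adds bright green spots inside the detection ribbon but
offset from the midline centre (caught by the centrality re-check).

Not emulated: chromatin texture, asynapsis morphology, synaptic forks,
3-D stacks, focus-intensity variation between true foci, and the
microscope PSF (the pixel depth and PSF of the original instrument are
unknown; the 16-bit/Gaussian choices are package defaults, not claims).
Passing tests therefore demonstrate correctness of the geometry,
projection, curation and statistics under realistic noise — not
performance on any particular microscope's data.

## Numerical and design choices

* px-per-µm conversion defaults to 9.8152 (an instrument-specific factor)
  and is configurable; lengths convert by exact division.
* Object indices are 1-based, row-major by bounding-box origin;
  coordinates are 0-based (row, col).
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reruns the full simulate → measure → curate → stats pipeline
  byte-identically (CSV headers carry the tool version and config hash).
* Degenerate inputs raise: cyclic skeletons ("degenerate skeleton"),
  zero-variance gamma samples ("degenerate sample (shape unbounded)"),
  single-class logistic fits, unsorted or out-of-range r̄ positions.
* Problem sizes in the test suite (6 × 9-bivalent cells for accuracy
  properties, 20 × 8-bivalent cells for the end-to-end reproducibility
  check, 10⁴ distances for gamma recovery, 10⁶ gametes per r̄ oracle
  configuration, 200 replicates for permutation calibration) were chosen
  as the smallest sizes at which the checked statistics are stable.

## Known limitations

* Crossing (X-shaped) merges are excluded by the branch-point criterion and
  simply remain unmeasured; the package does not attempt watershed
  splitting.
* The heuristic thresholds are calibrated on synthetic ribbons; real
  spreads will need per-dataset tuning through the config file.
* Type II (non-interfering, MLH1-negative) crossovers are invisible to the
  assay; counts are therefore lower bounds on total crossovers.
* The centromere-at-0.25 window convention treats chromosome 1 as
  submetacentric-like; the filter windows are configurable where that
  convention does not apply.
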