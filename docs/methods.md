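# Methods

`carfind` counts CAR T-cells captured on a CD19-functionalized
microfluidic sensor surface from label-free brightfield images. This
note documents the models, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the known
limits of each component.

## Imaging model and conventions

Images are single-plane 16-bit monochrome tiles, nominally 2048 × 2048
pixels from a 6.5 µm-pitch camera behind a 40×/0.75 NA objective, so
the sample-plane pixel is 6.5/40 = **0.1625 µm** (the default
`pixel_size_um`; always taken from configuration, never from file
metadata). Coordinates are `(row, col)`, 0-based, origin top-left;
object centers are real-valued pixel positions. A sample is scanned as
30 tiles covering a linear flow channel of 203 µm × 1.0 mm × 35 mm
(7.1 µL); tiles are treated as disjoint fields of view — no cross-tile
deduplication is attempted because the tile overlap of the scan is not
known in general and is zero by construction for the bundled generator.

## Candidate detection: the five-stage prefilter

1. **Local standard-deviation filter** (`std_window_px = 9`). Assigns
   each pixel the population SD of its window. Cells carry granular
   internal contrast under defocus, so the whole cell lights up
   regardless of whether it appears bright- or dark-centered; this
   rectifies contrast polarity. Computed via shifted moment sums —
   intensities are first reduced by their global mean because the raw
   E[x²] − E[x]² difference loses ~10 digits at 16-bit scales.
2. **Match filter** (`template_radius_px = 35`, disc template by
   default, annulus available). Zero-mean normalized cross-correlation
   (ZNCC) of the SD response with a rotationally symmetric template:
   both template and each sliding window are mean-subtracted, so flat
   background scores exactly 0 and output lies in [−1, 1]. Implemented
   by FFT with edge-including reflective padding; windows of zero
   variance score 0. The 35 px radius (≈11 µm diameter) balances the
   7–15 µm lymphocyte range: the correlation peak of the smallest and
   largest cells stays above the blank-noise ceiling (see threshold).
3. **Thresholding** (`threshold = 0.45`). Values below
   max(0, threshold) are zeroed. Pure negative-value thresholding
   (threshold 0) is insufficient on its own: the ZNCC of a pure-noise
   tile reaches per-tile maxima of ≈0.35–0.49 because normalization
   amplifies near-flat windows, while true cell peaks measure ≈0.47–0.75
   at the study's contrast. 0.45 sits at the measured crossover; it is
   a config value and should be re-derived (from blank tiles) when the
   optics change.
4. **Local-maxima identification** (`min_peak_distance_px = 35`,
   following the template radius). A pixel qualifies if strictly
   positive and maximal in its (2d+1)² neighborhood; qualifying pixels
   are accepted greedily by descending score (ties by (row, col)) with
   Euclidean minimum separation.
5. **Radial segmentation** (32 rays, boundary fraction 0.2,
   `segment_radius_px = 80`, area bounds 80–15000 px²). From each peak,
   rays are cast on the original tile; the local background is the
   median intensity on the circle at `segment_radius_px` (80 px clears
   the defocus ring of the largest cells); each ray stops at the first
   radius whose |intensity − background| falls below 0.2× the center
   deviation, and the boundary is the last radius still at/above the
   cutoff. Per-ray boundaries pass a circular 3-tap median so a single
   noise dip cannot dent the polygon; the footprint is the filled
   polygon. The peak is then re-seeded at the footprint centroid and
   rays recast (≤3 passes): the match peak sits off-center when object
   and template sizes disagree, and the centroid converges to within a
   few pixels of the true center across the whole size range. Reported
   candidate centers are footprint centroids. Footprints of overlapping
   candidates are deliberately not merged — separating crowded
   neighbors is the stage's purpose.

Measured on the bundled generator at default conditions (512² tiles,
20 non-overlapping cells, ring amplitude 15% of background, read noise
1%): recall ≈ 0.94–0.99 at a 5 px matching radius, and 0 false
candidates on pure-noise tiles (the property suite requires ≤1 per
tile).

## Object classification

Candidates are sorted into CART / PLATELET / RBC / OTHER by a
**100-tree random forest** (unlimited depth, √p features per split,
bootstrap on, explicit seed) over a frozen 16-feature vector: area,
equivalent radius, perimeter, circularity (4πA/P²), eccentricity,
mean/median/SD/min/max intensity over the mask, the three intensity
quartiles, ring contrast (outer-annulus mean − inner-disc mean, split
at 0.6× the equivalent radius), the mean stage-1 SD response over the
mask, and the match-filter peak score. The feature order is embedded in
serialized models and checked on reuse.

Training uses a labeled library of 150 crops per category in a 100/50
train/test split (400 train / 200 test). The bundled synthetic library
segments every crop with the *same* radial-segmentation operator used
at detection time, so the training feature distribution matches
deployment; on it, CART sensitivity and specificity (one-vs-rest,
TP/(TP+FN) and TN/(TN+FP)) are ≥0.85/≥0.90 across seeds — in practice
≈0.99/≈0.99, noticeably better than on real blood objects, because the
synthetic classes are cleaner than real debris.

## Quantification and calibration

Per-sample counts are the sum of CART-labeled candidates over all
tiles. Two calibration forms relate counts y to spiked concentration x:

* **power** (buffer): y = a·x^b, fitted as ln y = ln a + b·ln x by
  ordinary least squares; R² and residual SD are reported on that
  log-log scale;
* **logarithmic** (whole blood): y = a·ln x + b by OLS of raw counts on
  ln x; blood blanks carry a high background (>100 counts of captured
  white cells) which enters only through the blank statistics, not by
  subtraction from the curve.

**LOD/LOQ** use blank-based decision thresholds at 95% certainty:
y_D = blank_mean + 2·z₀.₉₅·blank_sd with z₀.₉₅ = 1.645 (α = β = 0.05,
the familiar 3.29σ detection rule) and y_Q = blank_mean + 10·blank_sd;
both are inverted through the fitted curve in closed form
(power: x = (y/a)^(1/b); log: x = exp((y − b)/a)). If the blank SD is
zero the fit's residual SD substitutes; if both vanish LOD = LOQ at the
blank mean. LOD ≤ LOQ always, since 3.29 < 10 and both forms are
monotone. Alternative "95% certainty" constructions exist; this one is
closed-form and reproducible, and every report records the blank
statistics needed to recompute others.

`ratio_stat` covers the two paired-count ratios used in validation:
filtration efficiency (WBC after / before) and washing retention
(cells bound after / before flushing), with per-replicate ratios and
their SD/SE.

## Fluorescence validation

Each brightfield detection defines a disc ROI reused on the paired
fluorescence image. The per-cell statistic is **population SD / median**
of the ROI intensities: clustered punctate CAR staining raises the SD
at fixed median, and the ratio is invariant under multiplicative gain,
normalizing across experiments. Across cells the statistic is bimodal;
a two-component Gaussian mixture is fitted by EM (hand-rolled 1-D
implementation: k-means initialization plus quantile/random restarts
with the best final likelihood kept, SD floor 1e-4 with an explicit
degeneracy error, non-decreasing log-likelihood by construction).
Restarts matter: when the negative population is much narrower than the
positive one, the variance-minimizing 2-means split can seed EM inside
the broad mode. The positivity threshold is the root of
w₁·N(x|μ₁,σ₁) = w₂·N(x|μ₂,σ₂) strictly between the ordered means,
solved from the quadratic in closed form; the positivity fraction is
the fraction of cells strictly above it.

## Synthetic data generator

The generator is the package's test harness and defines its study
conditions; it emulates geometry and SNR, not optics.

* **Brightfield tiles**: background 30 000 counts, Gaussian read noise
  SD 300 (1%), default test tile 512² (full 2048² by config). Object
  classes: CART cells as bright-center/dark-rim radial profiles with
  granular intracellular texture (smoothed-noise field under a radial
  envelope, amplitude 0.35× ring amplitude), diameters uniform in
  7–15 µm and ring amplitude 15% of background; platelets as 2–4 µm
  low-contrast Gaussian blobs; RBCs as 6–8.5 µm dark discs with a
  central dimple and light texture; OTHER as irregular multi-lobe
  blobs. Counts are Poisson at configured per-tile densities (or exact
  with `exact_counts`); placement is dart-throwing with restarts and a
  shuffled-grid fallback near the packing limit, raising a placement
  error when the requested spacing is infeasible. Contrast polarity can
  be inverted. Everything is deterministic under the seed.
* **Fluorescence tiles**: shared coordinates; CART objects are
  CAR-positive with a configurable probability (default operating point
  0.88); positives receive 3–8 bright punctate dots inside 0.7× their
  radius, negatives only uniform dim autofluorescence over the
  footprint.
* **Calibration tables**: observed counts are Poisson around
  expected = captured + background. Buffer uses a linear capture model
  (efficiency × effective volume × concentration; defaults 0.85 and
  7.1 µL). Whole blood uses a saturating response,
  captured = A·ln(1 + x/x₀) (defaults A = 300, x₀ = 1 cells/µL), on a
  background of mean 120 counts: competitive adsorption on limited
  capture sites yields a logarithmic isotherm, which is also the form
  the whole-blood data take empirically; a purely linear model cannot
  produce a good logarithmic fit over 1–1000 cells/µL.

What passing tests on this generator do **not** show: robustness to
illumination gradients, focus drift, real debris morphology, RBC
agglutinates, or overlapping cell clusters thicker than the crowding
model — the classifier metrics in particular should be read as an
upper bound relative to real blood.

## Numerical choices and degenerate inputs

FFT-based correlation and moment-sum SD filters operate on mean-shifted
intensities for conditioning; zero-variance windows score 0 in the
match filter; flat tiles yield no candidates (zero center deviation
aborts segmentation); mixture EM errors out (rather than returning
nonsense) on identical data, vanishing components or sub-floor SDs;
power fits reject non-positive concentrations or counts with guidance
to handle blanks separately; LOD inversion raises when the detection
threshold lies below the curve's range. Greedy peak suppression breaks
score ties lexicographically by (row, col) so results are
order-independent.

## Problem sizes in the bundled checks

The property/acceptance suites run at 512² tiles (20 tiles × 20 cells
for detection; 10 blank tiles), 150 crops per category × 5 seeds for
the classifier, 200 Monte-Carlo replicates of the 4-concentration ×
3-replicate calibration design, and ≈800 cells for the fluorescence
gate. These sizes give stable statistics (binomial/Poisson SEs well
inside the asserted bands) at desk-scale runtime; all are configurable.

## Known limitations

* The brightfield appearance model is parametric, not physical; no PSF
  or partial-coherence simulation.
* Single-scale template: very large (>15 µm) or very small objects
  score lower; multi-scale matching is out of scope.
* No cross-tile deduplication; overlapping scans would double-count.
* CD19⁺ B-cells in real blood would be captured and counted; the
  classifier cannot distinguish them from CAR T-cells.
* The whole-blood background model is stationary; donor-to-donor WBC
  variation is not modeled beyond the blank statistics.
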