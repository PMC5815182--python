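# Methods

## Scope

`gliamorph` quantifies glial cells (microglia, astrocytes) in brightfield
images of DAB-stained, hematoxylin-counterstained brain sections: it
counts somata, splits each cell's process arbor into proximal and distal
compartments, and reduces them to morphometric readouts of activation
state. It also computes magnetization-transfer-ratio (MTR) maps from
paired MR acquisitions, and carries two small tabular utilities
(2^−ΔΔCt fold changes for qPCR, control-group normalization). A seeded
synthetic generator provides ground-truthed inputs for every stage.

## Image model and conventions

All images are (row, col), row 0 at top. Pixel calibration (µm/pixel) is
mandatory; there is no default because scan files rarely carry a
trustworthy pixel size, and every reported length/area is in µm/µm².
ROI polygons rasterize by pixel-center containment — pixel (r, c) is in
the region iff (r + 0.5, c + 0.5) lies strictly inside — which makes
integer axis-aligned polygons half-open (a 10×10 square covers exactly
100 pixels) and is orientation-independent. Object labeling is
8-connected throughout.

## Stain separation

Brightfield absorption is modeled by Beer–Lambert: per-channel optical
density OD = −log10((I + 1)/256), so white (255) has OD 0 and the +1
offset keeps OD finite at 0. Each stain contributes its amount times a
unit absorption vector; unmixing inverts the 3×3 system per pixel
(two-stain matrices are completed with the normalized cross product of
the two vectors; the residual channel is discarded). Defaults are the
Ruifrok–Johnston hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778) vectors, normalized and overridable in config.
Negative solutions are clipped to zero. The chromogen gray rendering
g = 255·10^(−c) puts stained structures dark on a bright background and
is strictly decreasing in stain amount; all downstream thresholds
operate on this image.

## Segmentation sequence

The order is fixed: tissue → adaptive soma threshold → soma labeling →
top-hat processes → soma subtraction → thinning.

* **Tissue** is masked on the raw-image mean gray (counterstained tissue
  vs white slide): threshold (default 235), closing (disk, 5 µm), hole
  filling by border-connected background flood fill, opening (5 µm),
  and removal of fragments under 10,000 µm². An empty mask is a valid,
  logged outcome.
* **Adaptive soma threshold**: the mean chromogen gray of the darkest
  `dark_seed_fraction` of in-tissue pixels (default 0.005) times
  `soma_threshold_factor` (default 1.4), clamped to [0, 255]. Somata
  are the densest chromogen accumulations, so the seed must stay
  within the soma pixel population; 0.5% suits fields of tens of cells
  per 500 µm field. Note the seed mean is a truncated mean and sits
  below the soma gray level — the factor supplies the headroom.
* **Soma**: in-tissue pixels at or below the threshold, 8-connected,
  kept when their area lies in [20, 400] µm² (Iba1 default; the
  GFAP/astrocyte variant widens the upper bound to 800 µm²), labels
  renumbered consecutively.
* **Processes**: black top-hat with a 1.5 µm disk responds to dark
  structures thinner than the disk (processes) and not to wide blobs
  (somata). The response is binarized at
  `process_threshold_factor × (255 − seed mean)` (default factor 0.15,
  reusing the soma seed gray as the image's contrast scale), speckles
  under 5 px are dropped, and soma pixels are subtracted — no dilated
  halo, so the soma/process boundary is exact.
* **Skeleton**: homotopic thinning (`skimage.morphology.thin`) to one
  pixel width; it preserves the 8-connected component count and is a
  subset of the process mask.

None of these defaults is a measurement; all are config-exposed and were
chosen by contrast arithmetic on the generator's reference conditions.

## Arbor decomposition

Per soma with centroid c (unweighted pixel centroid): the proximal
marker is the soma dilated `soma_dilations` times (3×3, default 2); the
influence zone is the Euclidean disk of `influence_radius_um` (default
12 µm, a typical proximal-arbor scale) around c. Skeleton pixels inside
the disk reachable from the marker seed the proximal thinned set; whole
8-connected process components touching that set are reconstructed
(morphological reconstruction = component selection), giving final
proximal processes inside the disk and distal processes outside it.
Soma ∪ proximal is the cell's "visible" extent, the reference object for
densitometry. Components touching no marker (staining from another
focal plane) stay unassigned. Pixels claimable by two cells go to the
nearer centroid, ties to the lower label, so compartment maps are a
strict partition — stored as two owner-label images.

## Morphometry

* Soma area = pixel count × calibration²; perimeter uses the Crofton
  4-direction estimator. A raw chain-code boundary walk overestimates
  smooth outlines by ~5–6% and would deflate the form factor
  4πA/P² of round somata to ~0.89; Crofton keeps rasterized disks at
  0.97–0.99 for radii 20–80 px, converging to 1.
* Skeleton lengths count each adjacent pixel pair once: 1 per
  orthogonal step, √2 per diagonal, × calibration. On a thinned
  skeleton no redundant corner adjacencies remain, so the pair count is
  the path length; straight bars are exact by construction.
* Optical density of an object set is log10(mean_gray(background) /
  mean_gray(objects)), with the background being in-tissue pixels
  outside all visible-cell sets (local background, log base 10 as in
  standard chromogen densitometry).
* Region summaries: the **activation index**
  (Σ soma + Σ proximal area)/(Σ distal area) rises as cells retract
  distal arbors; a zero distal sum yields NaN (flagged undefined, never
  infinity). The **size index** is (Σ soma + Σ proximal area)/cell
  count in µm²/cell. Cells belong to a region when their soma centroid
  lies inside it; counts are normalized per mm² of the region's
  *tissue* area (not total region area). Bulk stains are summarized as
  stained-area fraction (gray ≤ threshold within region tissue) and
  integrated density Σ(255 − gray)×calibration² over those pixels.

## MTR

MTR = (S0 − S_MT)/S0 per pixel, a dimensionless fraction (×100 for
percentage points). Pixels with S0 at or below a noise floor are NaN
and excluded from ROI statistics; the floor defaults to 0, can be set
absolutely, or estimated from a named background (air) region as
median + 5 × 1.4826 × MAD. Masking of the map is this package's
addition; ROI means additionally accept control-group means for
normalization (control ↦ 1.0).

For a constant-signal phantom S with independent Gaussian noise σ on
both acquisitions, the ROI mean of the ratio is a ratio estimator: its
first-order standard error is σ√(1+(1−m)²)/(S√n) and its analytic
expectation carries a second-order term m − (1−m)(σ/S)². Tests compare
ROI means against that expectation at 3 SE; at σ/S = 0.02 the bias is
about one SE for n ≈ 6000 and ignoring it would make a correct
implementation fail sporadically.

## Synthetic ground truth

The histology generator renders n cells in a square field (default
conditions: 30 cells, 500 µm field, 0.5 µm/px, 15 µm minimum soma
separation, 10 µm white slide margin, pixel noise σ = 4). Somata are
rotated ellipses; processes are 1-px-step random walks (heading noise
0.15 rad/step) launched radially from the soma boundary, with optional
branching, terminated at the tissue edge. Two morphotypes:

| parameter | ramified | ameboid |
| --- | --- | --- |
| soma radii (µm) | 2.5–4.0 | 4.0–6.0 |
| primary processes | 4–6 | 2–4 |
| process length (µm) | N(25, 5) | N(10, 3) |
| branch prob./step | 0.03 | 0.01 |
| thickness (px) | 1 | 3 |
| process OD | 0.30 | 0.45 |

Soma chromogen OD is 0.80 ± 0.01 (gray ≈ 40): DAB accumulates densely
and uniformly in somata, and the tight spread keeps the adaptive
threshold's truncated seed mean within ~3σ of every soma's gray even
when the dark seed lies entirely inside the soma population. The
chromogen field gets a 0.5 px Gaussian blur (soft optical edges), the
hematoxylin counterstain is a smooth low-amplitude texture
(OD 0.12 ± 0.04), and rendering inverts the exact OD transform before
adding noise, so unmixing is consistent by construction. Ground truth
records per-cell specs, polylines, total/proximal/distal lengths at a
stated influence radius, soma label map and the stained-area fraction
counted from the generator's own masks. Identical seeds give bitwise
identical outputs (a single explicit `numpy` Generator per call, no
global state).

What the generator does *not* emulate: out-of-focus staining planes,
uneven illumination, stain colocalization gradients, touching somata,
and scanner artifacts. Passing tests therefore demonstrate the
pipeline's correctness on well-separated cells with known optics, not
robustness to every real-slide pathology.

The MR generator draws S0 = S + N(0, σ²) and S_MT = S(1−m) + N(0, σ²)
per pixel with piecewise-constant regional m, returning the noiseless
truth field.

## Problem sizes and verification

Tests run the full pipeline on 1000×1000 px reference fields (five
seeds per morphotype) and on a 12-cell 250 µm field for invariants;
`scripts/acceptance.py` regenerates everything from scratch per run.
Observed behavior at these conditions: exact 30/30 soma recovery on all
probed seeds, total skeleton length within 3–4% of ground truth,
activation index ≈ 0.9–1.0 (ramified) vs ≈ 5–7 (ameboid), and
byte-identical CSVs on re-runs.

## Known limitations

* Thin-process areas are resolution-limited: segmentation resolves the
  blur shoulders of 1-px rendered lines, so ramified proximal *area*
  exceeds the rasterized truth by ~20–25% (lengths are unaffected;
  size-index recovery is validated on ameboid fields where area sits in
  wide structures).
* Thinning is not exactly 90°-rotation-equivariant; region indices move
  by up to a few percent under rotation (translation is exact).
* The adaptive threshold assumes somata are the darkest structures; a
  stain whose processes are as dark as somata needs a different
  `dark_seed_fraction`/factor pairing.
* Overlapping arbors are resolved by nearest-centroid assignment, a
  deterministic heuristic, not a biological claim.
* No whole-slide formats, registration, stitching, or 3-D stacks.
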