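# Methods

## Pipeline model and assumptions

The package estimates per-plot seedling stand counts from high-resolution
(≈0.19 cm/px) RGB orthomosaics of small-plot field trials at early, mixed
growth stages (2–4 leaves). It assumes:

* vegetation is separable from soil by green chromaticity alone — weeds
  are sparse enough that a colour rule plus template matching suffices;
* seedlings are approximately rosette-shaped and fit within a 20 × 20 px
  window at the working resolution (≈3.8 × 3.8 cm);
* the orthomosaic is radiometrically reasonable (white-balanced) but may
  vary in illumination — the matching score is invariant to positive
  affine intensity changes, which absorbs that variation;
* plants may touch but mostly do not stack; heavily overlapped canopies
  are a known failure mode (see Limitations).

### Part I — vegetation classification

Green ratio `G/(R+G+B)` is computed per pixel in float64 from the raw
band values (the ratio is scale-invariant, so 8-bit vs float input is
immaterial). Pixels with ratio **strictly greater than 0.36** classify as
plant; pixels whose bands sum to zero get ratio 0 (black is never
vegetation). Plant pixels merge into connected components at
8-connectivity (configurable; 8 is the conservative choice that joins
diagonal leaf pixels) and components **smaller than 30 px are removed**
(strict: a 30 px component survives). The classification operates
directly per pixel; an object grid at unit cell size would be
mathematically identical. The selected band (green by default) is copied
where the mask is true and zeroed elsewhere; those zeros are part of the
matching signal, not missing data.

### Part II — grouped template matching

Sample patches (20 × 20 px, default 1000) centred on marked seedlings are
cut from the classified layer, normalized per patch to zero mean and unit
L2 norm, and clustered into k = 10 subgroups with k-means (10 restarts,
fixed seed; deterministic). Normalizing *before* clustering makes
Euclidean clustering distance equivalent to correlation distance — the
same geometry the detector uses, since for unit-norm zero-mean vectors
`||p − q||² = 2(1 − corr(p, q))`. Each subgroup template is the pixel
mean of its members, re-normalized.

**Template quality R** is the mean zero-normalized correlation between
training patches and their subgroup templates (assigned subgroup when
reported by the builder; best-matching subgroup in `template_quality`,
which is what rises monotonically with k). Whether an eCognition-style
quality score averages over patches or pixels is not documented anywhere
we could verify; the patch-mean definition is used because it reproduces
the expected qualitative orderings (grouped > single template, masked >
raw source layer, green ≥ red channel).

Matching computes, at every candidate centre whose full footprint lies in
the image **and** overlaps at least one plant-mask pixel, the Pearson
correlation between the 20 × 20 window and each subgroup template; the
pointwise maximum over subgroups is the combined score (ties to the
lowest subgroup index). Windows with (near-)zero variance score 0 — a
flat window is never a seedling. Restricting scoring to mask-valid
centres is both the semantic contract (matching runs on the classified
layer) and the main speed lever: plant cover is sparse, so correlation is
evaluated over padded bounding boxes of mask components only. The FFT
evaluation is exact (float64) and is checked against the direct
double-loop formula at 1e-6 in the test suite.

Detections are score-thresholded (default **0.5**, strict; the
pre-optimization value 0.36 remains available through configuration) and
thinned by greedy non-maximum suppression in descending score order
(ties: lower row, then lower column) with radius **10 px** — half the
template, ≈1.9 cm, the natural minimum centre spacing of distinct
seedlings. The combined (max-over-subgroups) score is thresholded rather
than per-subgroup scores; with a shared threshold the two are equivalent
for detection, and the combined form also fixes the winning subgroup.

### Aggregation and accuracy

Detections map to world coordinates through the raster affine at the
pixel-centre convention (+0.5 px; prevents half-pixel drift in
plot-boundary assignment) and are assigned to plot polygons by
point-in-polygon. A detection exactly on a shared boundary belongs to the
plot whose id sorts first — deterministic, never double-counted. Density
is count divided by polygon area (m²).

R² is the **squared Pearson correlation** between digital and manual
counts — the spreadsheet scatter-trendline convention — not
`1 − SSE/SST` about the 1:1 line; a constant offset therefore gives
R² = 1 with nonzero MAE, which is why MAE and RMSE are always reported
alongside (the 1:1 variant is available in verbose reports). Evaluation
requires n ≥ 2 plots and nonzero variance in both series.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| green_ratio_threshold | 0.36 | – | strict >; plant-vs-soil chromaticity cut |
| min_component_px | 30 | px | strict <; soil-speckle size cut |
| connectivity | 8 | – | component merging neighbourhood |
| patch_size | 20 | px | template side; ≈3.8 cm at 0.19 cm/px |
| n_subgroups (k) | 10 | – | quality gain beyond 10 is marginal |
| match_threshold | 0.5 | – | lower over-counts, higher under-counts |
| nms_radius | 10 | px | half template; min seedling separation |
| channel | green | – | strongest plant/soil contrast channel |

## The synthetic-field generator

No imagery ships with the package, so `synthetic_field` renders the
study conditions directly: 5 m × 1 m plots at 0.19 cm/px, per-plot true
counts uniform in [40, 200] (target densities 8–40 plants/m²), a
30/40/30 mix of 2-/3-/4-leaf plants, 15% of plants placed in tight
pairs/triples at 0.5–1.0 canopy-width spacing, and ~0.5 grass-like weeds
per m². Soil is a brown base with smooth multiplicative luminance texture
plus fine noise, hard-capped so its green ratio stays below 0.33
everywhere (soil can never classify as plant at the 0.36 cut — asserted
per build on the quantized 8-bit values). Seedlings are rosettes of
elliptical leaves around a small apical disc: cotyledon pairs for 2-leaf
plants plus longer, narrower true leaves; leaf lengths default to
7–12 px (plants ≈2.5–5 cm across, cotyledon-stage plants rendered
smaller), radial luminance falloff from the bright apex to the darker
leaf rim, leaf-to-leaf brightness differences, and per-pixel speckle
(σ = 0.32 of local luminance) emulating leaf texture and sensor noise.
Every opaque sprite pixel keeps green ratio > 0.40 and every sprite
covers ≥ 32 px, so real plants always survive Part I. Weed sprites are
thin radiating blades — green enough to classify as vegetation, shaped
unlike any rosette template.

Sample patch centres for template building come from the ground truth of
the first plots with 1 px isotropic Gaussian "click error", emulating
hand-digitized patch selection; positional error is one of the factors
that keeps template quality in the realistic 0.4–0.7 band (the defaults
land near R ≈ 0.65–0.70 for k = 10).

Randomness: one `SeedSequence` per (experiment seed, plot index, stream),
so every artifact is a pure function of (config, seed) and earlier plots
do not change when `n_plots` grows. Tiles are re-rendered lazily rather
than held in memory; a 300-plot experiment streams at a small constant
footprint.

**What passing tests do and do not show.** The generator reproduces the
geometry and chromaticity of the counting problem (mixed stages,
heterogeneous density, clustered overlap, weeds) but not radiometric
field effects — shadows, specular highlights, wind blur, mosaic seams, or
real weed flora. Accuracy figures on synthetic fields therefore validate
the pipeline's mechanics and its qualitative behaviours (threshold
stringency trade-off, masked-layer gains, overlap degradation), not
field-ready accuracy on any particular crop.

## Numerical choices

* ZNCC by FFT with a shared forward transform per image; float64
  throughout; scores clipped to [−1, 1] against rounding overshoot;
  window variance below 1e-12 ⇒ score 0.
* Component-box evaluation is exact: every valid centre's footprint lies
  inside its padded box, and overlapping boxes recompute identical
  values.
* k-means uses 10 restarts with a fixed seed; empty clusters are handled
  by the library's relocation strategy (never observed at k=10, n=1000).
* Greedy NMS uses grid hashing (cell = radius) so only 3×3 neighbouring
  cells are scanned; output is provably identical to the quadratic
  reference and independent of candidate enumeration order.
* Plot polygons and point-in-polygon queries go through shapely
  (`covered_by`, boundary inclusive) with the sorted-id tie rule applied
  on top.
* Degenerate inputs: empty masks, soil-only plots, and empty detection
  lists flow through every stage; evaluation raises on n < 2 or
  zero-variance count series.

## Design choices where the design was open

* **Coordinate convention:** 0-based (col, row) pixels, world mapping at
  pixel centres (+0.5). One stated example for point export that omits
  the half-pixel offset was judged inconsistent with the convention and
  the centre convention was applied uniformly.
* **Shapefile support** was dropped: no shapefile library is available in
  the supported environment, GeoJSON is the default interchange format,
  and CSV carries pixel plus world coordinates; both round-trip exactly.
* **Detection threshold 1.0** is accepted (maximal stringency, zero
  detections) even though scores are compared strictly; values above 1
  are rejected.
* **CRS handling:** the coordinate reference system identifier is an
  opaque pass-through (read from GeoTIFF keys when present, echoed into
  GeoJSON output); no reprojection is attempted.
* **Problem sizes in the test-bench:** headline accuracy analogues run
  at the full 300-plot scale; behavioural checks (threshold sweep,
  channel orderings, clean-field recovery) use 1–20 plot experiments,
  which already contain hundreds to thousands of plants — ample for sign
  and ordering assertions.

## Known limitations

* Counts degrade in tight clusters: members closer than the NMS radius
  merge into one detection, and partially occluded rosettes score lower.
  The default conditions show a small net over-count (weeds plus
  double-hits on elongated plants) of a few plants per 120-plant plot.
* No rotation- or scale-augmented matching; plants far larger than the
  template window (later growth stages) will multi-trigger.
* The green-ratio rule cannot separate green weeds from crop; weed
  rejection relies on templates not matching weed morphology.
* R² as squared correlation rewards linear association, not agreement;
  calibration offsets are visible only in MAE/RMSE.
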