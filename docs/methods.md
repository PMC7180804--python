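# Methods

This note documents the models, parameters, numerical choices and
limitations behind `foascope`. Coordinates are row-major and 0-based
throughout, with pixel centers at integer coordinates; `x` indexes
columns, `y` rows. Intensities live on a [0, 1] working scale and
rendered images are 8-bit.

## The synthetic scene model

A fiber-optic-array (FOA) micrograph of stained yeast is modeled as

```
image = clip( background_with_cells × lattice_gain × illumination_gain
              + N(0, σ²) ) quantized to 8 bits
```

**Fiber lattice.** Fiber cores form a hexagonal lattice (rows spaced
`pitch·√3/2`, odd rows offset by `pitch/2`; a square arrangement is also
available). A pixel inside a core disk transmits `core_gain` (default
1.0), the lighttight gaps between cores transmit `gap_gain` (default
0.5). Defaults — core radius 3 px, pitch 7 px — put the core image at
about 6 px across, the size a 9 µm large-end core projects onto a
1.4 µm sensor pixel. With these defaults cores cover `2π/√3·(r/p)² ≈
67 %` of the field.

**Illumination.** A radial field rising from `center_level` (default
0.6) at the image center to `edge_level` (default 1.0) at the farthest
corner, as `t²` (or `t⁴`) of the normalized center distance — the
center-dark vignetting-like profile a cropped taper plus a simple LED
produces.

**Cells.** Live cells are disks with a bright interior
(`live_interior_level` 0.85) surrounded by a 2 px rim at
`live_rim_level` 0.25; dead (stain-absorbing) cells are uniform disks
at `dead_level` 0.20 on a `background_level` of 0.55. Radii are uniform
in 6.5–10.5 px (13–21 px diameters: 3–5 µm yeast under 6× taper
magnification on a 1.4 µm pixel). Placement is rejection sampling with
a 10 000-attempt cap per cell and fails loudly rather than
under-placing; non-cluster cells keep ≥ `min_separation_px` (26 px)
between centers, and an optional `cluster_fraction` of cells is instead
planted within that separation of a partner and flagged, emulating the
cell clusters that viability protocols exclude from counting. Additive
Gaussian noise (default σ = 0.02) is applied after the gains; a Poisson
noise model was considered and deferred as unnecessary for stressing
the detector.

**What the generator does not emulate:** optical blur (edges are
razor-sharp), chromatic staining color (scenes are grayscale; RGB input
is exercised by channel replication), fiber-to-fiber transmission
variation, focus drift, and debris. Passing the benchmark therefore
shows that the pipeline recovers cells under the lattice/illumination
artifacts and mild noise — not that it handles the full variability of
real micrographs.

## Preprocessing

The pipeline converts RGB to L\*a\*b\* (sRGB, D65, via scikit-image),
rescales L\* to [0, 1], applies CLAHE, converts back to RGB and reduces
to gray with fixed BT.601 weights (0.299, 0.587, 0.114) for detection.
8-bit input is rounded back to 8 bits after the luma sum, mirroring
what a camera pipeline would store. Both the re-grayscaled output and
the equalized L channel are available; the re-grayscaled image is the
default detection input.

**CLAHE semantics.** The image is partitioned into `num_tiles` regions
by rounded even splits. Per tile, a 256-bin histogram is clipped at
`clip_limit × tile_pixel_count` per bin (`clip_limit` ∈ [0.01, 1];
1 disables clipping) and the clipped excess is redistributed uniformly
over all bins in a single pass (no iterative re-clipping). The tile
mapping is the CDF of the clipped histogram. Each pixel interpolates
bilinearly between the two bracketing tile centers per axis; pixels
beyond the outermost centers clamp to the nearest tile. This mapping is
monotone in the input value for any fixed blend of tiles, maps constant
images to constant images, and with one unclipped tile reduces exactly
to global histogram equalization.

**Moving-template AHE.** The reference equalizer recomputes, for every
pixel, the histogram of its odd-sized surrounding window
(edge-replicated at the borders) and assigns the window CDF value of
the center pixel. It is quadratic in the window area and used as the
exact oracle that tiled CLAHE approximates; on a slow ramp with the
window matched to about two tile pitches the two agree to ≈ 0.1 max /
0.03 mean away from the borders, where their boundary conventions
differ (replication vs clamping).

**Tile-grid scaling.** The effective grid on full-resolution device
micrographs is 25×25 with clip limit 0.1, and those are the package
defaults. The tile *count* does not transfer to images of other sizes;
the geometric constraints behind it do: a tile must span several cell
diameters (a cell that dominates its tile histogram is equalized away,
and lattice texture is amplified to cell-like contrast) while staying
well below the illumination scale (too few tile centers cannot track
the radial field). `tile_grid_for_shape` encodes this as a tile edge of
≈ 4.5 mean cell diameters, giving 5×5 tiles of 77 px on the 384 px
benchmark scenes; the synthetic benchmark uses that grid.

**Neutral-axis collapse.** For replicated-gray input the Lab route
collapses to CLAHE on the gray channel in rank terms, but not bin by
bin: L\*(gray) is nonlinear, so values that share a gray-space bin may
split across L\*-space bins and vice versa, changing the clipped
histograms. Measured agreement is ≈ 0.04 max deviation; the tests
assert 0.06 max / 0.02 mean.

**Known limitation — lattice contrast.** Tile-wise equalization
*stretches* any background mode pair that carries substantial mass: the
equalized separation of the core and gap modes approaches their CDF
quantile distance, which is at least their input separation (clipping
at 0.1 per bin cannot compress modes ~50 bins apart). The core/gap
gray difference therefore *rises* (typically 0.20 → 0.37 on noise-free
scenes) rather than falling. What preprocessing actually buys the
detector — and what the tests assert — is that the live-cell
interior-vs-rim contrast does not decrease and its **margin over the
lattice contrast widens** (typically 0.14 → 0.20), together with the
flattened illumination that makes one global threshold usable.

## Detection

**Window.** A flat-topped regular hexagon of circumradius `R` (default
9 px, matched to the 13–21 px cell diameters) rasterized as the pixels
whose centers satisfy the inner-distance test
`√3·R/2 − max(|y|, |√3x+y|/2, |√3x−y|/2) ≥ 0`; the edge ring is the
band within `ring_thickness` (default 2 px) of the boundary, the
interior the rest. The mask is 180°-rotation symmetric and requires
`R ≥ 2` with a nonempty interior.

**Scores.** Region *sums* are normalized to *means* so thresholds do
not rescale with window size. The live score (interior mean minus ring
mean) is invariant under global additive shifts; the dead score (mean
over the whole hexagon) shifts by exactly the added constant. Border
positions where the window does not fit are invalid (NaN) and can
never detect.

**Peak retention.** Local extrema (3×3 neighborhood, non-strict so
plateaus survive) that strictly exceed (live) or fall below (dead) the
threshold are visited from most extreme to least, ties broken by lower
row then lower column; a candidate within `nms_radius` (default 13 px,
about three quarters of a mean cell diameter) of a retained one is
suppressed. Retained same-class detections are therefore pairwise
≥ `nms_radius` apart, and the procedure is fully deterministic. When a
live and a dead detection collide within `nms_radius`, the one with the
larger margin beyond its own threshold wins; both margins are in
mean-gray units, which makes them directly comparable without extra
normalization.

**Counting.** Retained detections are painted as 5-pixel dots into
binary masks and counted as connected components with area ≥ 2 px
(no upper bound), 8-connectivity by default — the particle-analysis
convention. Centroids are reported per component.

## Evaluation protocol

Detections are matched one-to-one to same-class ground-truth cells by
increasing distance within `match_max_dist` (10 px, about one cell
radius); greedy rather than optimal assignment, which coincides with
the optimum in the unambiguous well-separated regime the tests cover.
Ground-truth cells with any neighbor closer than `cluster_separation`
(25.5 px = 1.5 mean diameters) are excluded from both numerator and
denominator, and a detection landing on an excluded cell is ignored
rather than counted as false — the cluster-exclusion convention of
manual viability counts. Identification percentage is
`100·matched/counted ground truth`, reported to one decimal; the
false-detection percentage divides unmatched detections by the same
denominator.

**Cross-validation.** Scenes are shuffled by seed into k folds
(default 5). The only free parameters of the detector — the live and
dead score thresholds — are chosen per fold on the other k−1 folds by
maximizing mean identification rate minus mean false-detection rate
over a fixed grid (live 0.05–0.50, dead 0.10–0.60, step 0.05), then
the held-out fold is scored. The two classes are selected and scored
independently (cross-class arbitration is a detection-time feature,
not part of threshold selection). Score maps are computed once per
scene; because greedy NMS at a stricter threshold retains exactly the
surviving detections that still pass it, peaks are extracted once at
the loosest grid value and filtered per candidate threshold.

**Benchmark scale.** The standard benchmark is 20 scenes of 384×384 px
with 15 live + 15 dead cells each, no deliberate clusters, σ = 0.02 —
small enough to render and evaluate in seconds while leaving ~150
cells per class per fold split. Fold-mean identification rates are
≈ 91–95 % (live) and ≈ 99–100 % (dead) with false detections ≤ 5 % of
ground truth across seeds. Live cells are the harder class because the
fixed window cannot place its ring on the rim of both the smallest and
largest cells; the weakest live responses come from small cells whose
rim falls inside the window interior.

## Optics formulas

All formulas are evaluated exactly as stated, in radians and
micrometres. Two printed design figures are internally inconsistent
with their own formulas and are deliberately **not** reproduced:

* the taper V number at r = 0.6 µm, λ = 550 nm, indices 1.52/1.50
  evaluates to ≈ 1.685, not the published 0.41 (still single-mode
  either way);
* √3 × 0.61 µm = 1.056 µm, not the published 0.95 µm resolvable
  period.

The package returns the computed values; the tests pin them and this
note records the discrepancy. Two further conventions: the
penetration-depth formula takes `nco` as the *core* index (required
for a positive radicand under total internal reflection, though the
surrounding naming is ambiguous), and `arcsin(θₛ)` is kept as printed
with its argument validated to [−1, 1] rather than silently replaced
by `sin`. The two taper cone angles δ (incidence recursion) and α
(mode-angle recursion) are stored as distinct parameters since nothing
relates them.

## Determinism and I/O

Every stochastic step (cell placement, noise, fold shuffling) derives
from an explicit integer seed through `numpy.random.default_rng`;
renders are bit-identical across runs and platforms at fixed seed.
Images are 8/16-bit PNG or TIFF (1 or 3 channels; 8-bit data
round-trips losslessly), ground truth is CSV with header
`x,y,radius_px,label,cluster_member`, configuration is a flat
`key = value` file with unknown keys rejected, and each pipeline run
writes a log with the package version and full configuration so it can
be replayed exactly.
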