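# Methods

## Scope and data model

`satquant` quantifies three co-registered single-channel fluorescence
images per muscle section: DAPI (all nuclei), Pax-7 (satellite-cell
marker) and BrdU (proliferation marker). Images are 2-D 8-bit grayscale
arrays; masks are boolean arrays of the same shape with 8-connected
foreground and 4-connected background (the convention that reproduces
interactive image-analysis component counts on diagonal contacts).
Channels must share dimensions; a mismatch is an error, never a
resample, because the chains assume pixel-level co-registration of one
acquisition frame. All intensity arithmetic rounds half-up and every
operator is deterministic, so identical inputs and configuration yield
bit-identical outputs on any platform.

## Channel chains

Stage order is fixed (and asserted in tests via an execution trace):

| channel | chain |
|---|---|
| DAPI | rolling ball → 8-bit rescale → sharpen → mean threshold → erode ×1 → dilate ×1 |
| Pax-7 | edge magnitude → 8-bit → luminance stretch → watershed lines → rolling ball → Rényi entropy threshold → close → outline → fill holes → (line exclusion) → erode ×1 → remove objects < 20 px |
| BrdU | 8-bit → sharpen → rolling ball → 3×3 mean convolution → watershed lines → Intermodes threshold → remove objects < 20 px |

The erode/dilate pair in the DAPI chain is an opening: it removes the
halo of stray pixels around each nucleus and restores the surviving
objects to their pre-shrinkage size. Nuclei below 30 px are treated as
debris at the counting stage (the DAPI chain itself has no
small-object-removal step).

### Rolling-ball background subtraction

The background estimate is the grayscale opening of the image by a
spherical-cap structuring function of radius *r* (erosion then dilation
with heights √(r² − d²)): a ball of radius *r* rolled beneath the
intensity surface. The subtraction `clamp(image − background, 0, 255)`
never increases a pixel. This is the exact cap opening, not the
historical shrink/process/enlarge approximation. Defaults: r = 25 px for
DAPI and BrdU, 15 px for the (smaller) Pax-7 structures — at least
twice the diameter of the largest object of interest in the emulated
sections, which is the standard sizing rule for the method; larger radii
change the result negligibly on these images while the cost of the exact
opening grows quadratically.

### Filters

* `sharpen`: 3×3 kernel (center 12, −1 elsewhere) / 4; coefficients sum
  to one so flat regions are fixed points.
* `edge_magnitude`: Sobel √(Gx²+Gy²) clamped to [0, 255].
* `normalize_range`: Py = (Px − a)(d − c)/(b − a) + c with a, b the image
  min/max and (c, d) = (0, 255) by default; a constant image returns
  constant c with a warning (degenerate stretch).
* `median_filter` / `convolve_kernel`: standard, with odd kernels only.
* Border policy everywhere: edge replication, which avoids the spurious
  dark frame a zero pad would introduce ahead of thresholding and
  watershed.

### Auto-thresholds

All three methods consume only the 256-bin histogram and return the last
background level *t*; foreground is `pixel > t`.

* **Mean**: t = ⌊Σ k·n_k / N⌋.
* **Rényi entropy**: for α ∈ {½, 1, 2}, t_α maximizes
  H_A^α(t) + H_B^α(t) (Shannon limit at α = 1; smallest maximizer on
  ties; candidates with an empty class are skipped). The three
  candidates are fused by the classical weighted rule: sort them, weight
  by whether consecutive candidates lie within 5 gray levels, and
  combine with the cumulative masses. Per-α candidates, weights and ω
  are kept in the result's diagnostics so either the single-α or the
  fused variant can be reproduced.
* **Intermodes**: smooth the histogram with a 3-point running mean
  (edge-replicated) until exactly two modes remain; t = ⌊(m₁+m₂)/2⌋;
  give up (not-bimodal error) after 10 000 iterations. Mode detection
  includes the end bins: after rolling-ball subtraction the background
  lobe of a fluorescence histogram sits at (and, under smoothing, drifts
  onto) bin 0, and a detector restricted to interior bins loses it —
  the bimodality test then terminates on meaningless residual wiggles in
  the foreground tail. With endpoint modes included, such histograms
  stop at the intended background/foreground pair. Degenerate single-bin
  histograms still fail as not-bimodal.

Numerical note: class validity in the Rényi scorer is decided with an
epsilon (10⁻¹²) on the cumulative masses, because float cumsum can leave
a residue of ~10⁻¹⁶ where the above-threshold class is actually empty,
which would otherwise send the α ≠ 1 objective to +∞ at t = 255. Genuine
classes are ≥ 1/N ≈ 3·10⁻⁶ for any realistic image, far above the
epsilon.

### Watershed splitting

Touching nuclei are separated before binarization by zero-valued
dividing lines drawn on the grayscale image. The intensity landscape is
inverted (bright nuclei become basins), basins shallower than *h* gray
levels are filled by the h-minima transform (erosion-reconstruction of
landscape + h over the landscape), the regional minima of the transform
seed a flood, and the one-sided 1-px boundary between basins (pixels
whose 3×3 label minimum differs from their own label) is set to 0 — of
every cross-basin 8-adjacent pixel pair the higher-labeled pixel is
removed, so no two basins remain 8-connected after thresholding. Images
with one surviving basin are returned unchanged.

Two implementation choices matter here:

* Markers must come from the regional minima *of the transform*, one
  connected plateau per surviving basin. Marking every pixel deep enough
  below its spill level instead (a common shortcut) produces several
  disconnected markers on a rough basin floor and therefore spurious
  dividing lines inside single nuclei.
* **h default = 20 gray levels.** The suppression depth must exceed the
  relief of noise pits in saturated nucleus cores (≈ 4–5 σ of the
  noise after the chain's sharpening ×3 and 3×3-mean smoothing ≈ 20
  levels at the emulated noise σ = 5) while staying below the relief of
  the genuine valley between two overlapping nuclei (≥ 50 levels for
  center separations around 0.75 of the summed radii). Within the
  working band h ∈ [15, 25], results are insensitive to the exact
  value; h is configurable per channel.

The Pax-7 chain computes its dividing lines from the *original*
intensity image, not from the edge-magnitude image the chain otherwise
transforms, and excludes the line pixels from the mask once more after
hole filling. Both choices are forced by the topology of edge images:
each object interior is walled in by its own outline, so edge-landscape
basins cannot separate two touching spots whose outlines have merged;
and the outer edge contour of a touching pair is a single closed curve,
so cavity filling would otherwise re-connect any separation made before
binarization. A binary distance-transform watershed
(`watershed_split_binary`) is provided as an alternative mode for
sensitivity checks.

## Counting and ratios

* n_nuclei: components of the DAPI mask ≥ 30 px.
* n_pax7 = components of dilate(Pax-7 ∩ DAPI), n_brdu = components of
  dilate(median(BrdU ∩ DAPI)), n_copositive = components of
  dilate(BrdU ∩ Pax-7). The dilation (2 iterations by default) merges
  fragments of marker signal within one nucleus so a fragmented
  detection is still counted once; the median filter (radius 1) on the
  BrdU/DAPI overlay drops single-pixel background coincidences.
* Ratios divide each positive count by the DAPI nucleus count of the
  same section. With zero nuclei the ratios are NaN with
  `ratios_defined = False` — a flag, not a division failure. A blank
  BrdU channel (Intermodes undefined) contributes zero counts at the
  section level and the error message is preserved in
  `channel_errors`; calling `process_brdu` directly still raises.
* `validate_against_manual` fits auto = β₀ + β₁·manual by OLS and
  reports slope, intercept and R² = 1 − SS_res/SS_tot. It accepts raw
  counts or ratios; report which was used alongside R². Manual values
  with zero variance are an error (undefined slope).

## Synthetic sections

The generator emulates 40× fluorescence fields at 640 × 480 px
(≈ 1 µm/px): nuclei are cosine-tapered disks (flat core, smooth rim,
default rim 2 px) with radius 6 ± 0.75 px (clipped at ±2 σ, i.e.
9–15 µm diameters), peak 200; markers render inside the nucleus
footprint (Pax-7 and BrdU are nuclear antigens), so true positives
always co-locate with DAPI. Each channel adds an independent smooth
background (sum of 2–4 random-phase sinusoids, amplitude 20 by default —
the slow variation from nonspecific staining and tissue-thickness
changes that the rolling ball must remove) and Gaussian pixel noise
(σ = 5 by default; an optional intensity-scaled "poisson-like" mode
exists). Channels accumulate by per-pixel maximum, which keeps each
nucleus's peak calibrated and preserves the intensity valley between
overlapping nuclei. One master seed spawns independent sub-streams for
placement, marker labels, background and noise, so changing the noise
level never reshuffles the geometry, and identical (parameters, seed)
give byte-identical images.

Default study conditions: 100 nuclei, 20 % Pax-7⁺, 10 % BrdU⁺, 5 forced
co-positive. Minimum center spacing is 4 × mean radius, chosen so that
rendered nucleus masks (effective radius ≈ r + rim + threshold spill)
can never touch: the DAPI chain contains no watershed and cannot split
merged nuclei, so exact count recovery is only a meaningful benchmark
when the scene respects that assumption. The nucleus radius range is
likewise chosen consistently with the pipeline's documented 30 px
minimum nucleus area. `generate_touching_pair` deliberately violates
the spacing (two radius-12 disks 18 px apart, rim 5 px so a clear
valley exists between the peaks) as the fixture for the watershed tests.

What the synthetic model does *not* emulate: point-spread blur,
out-of-focus haze, autofluorescent fiber texture, staining heterogeneity
within a nucleus, anisotropic nucleus shapes, and section-to-section
intensity drift. Passing the synthetic benchmarks therefore shows the
chains are correct and self-consistent implementations with sensible
defaults — not that the defaults are optimal for any particular
microscope; on real data the thresholds are data-driven but the radii,
minimum sizes, h and dilation counts should be reviewed against object
scales, which is why every one of them lives in the config file and is
logged with each run.

## Reported problem sizes

The acceptance script simulates 12 noisy and 5 noiseless sections at
full 640 × 480 scale, 10 touching-pair fixtures per chain variant, 200
random lobe-mixture histograms for the threshold-oracle check, and two
repeat runs for the determinism check; the test suite additionally runs
50 noisy sections, 25 fixtures and 1000 histograms. These sizes keep a
complete run in the minutes range on one CPU while the binomial bounds
asserted (e.g. ≥ 90 % of sections within ±5 % per count) remain
meaningful.

## Known limitations

* The exact cap opening costs O(r²) per pixel; radii ≫ 25 px get slow
  (≈ 19 s per 640 × 480 channel at r = 50).
* Intermodes is undefined on blank or extremely skewed channels by
  construction; the section-level API reports zero counts with a
  recorded error rather than inventing a threshold.
* Counting assumes markers of one nucleus stay within dilation reach of
  each other and that distinct nuclei are farther apart than twice the
  co-positivity dilation; extremely dense fields would need a smaller
  dilation count.
* The manual-vs-automatic regression is a plain OLS on paired values;
  it does not model counting error in the manual reference.
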