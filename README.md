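# satquant

Semi-automated counting of Pax-7- and BrdU-positive nuclei in
multi-channel immunofluorescence micrographs of skeletal muscle.

## The problem

Muscle regeneration studies quantify satellite cells (nuclear **Pax-7**
immunofluorescence) and newly generated cells (nuclear **BrdU**
incorporation) on frozen sections counterstained with **DAPI**. Counting
these by eye across dozens of sections is slow and subjective. `satquant`
implements a reproducible processing chain for each channel — background
correction, filtering, histogram auto-thresholding, binary morphology and
watershed splitting of touching nuclei — followed by mask-overlap counting
of Pax-7⁺, BrdU⁺ and BrdU/Pax-7 co-positive cells, each gated on the DAPI
nucleus mask of the same frame.

## Method summary

Each channel is an 8-bit grayscale image (nominally 640 × 480 px). The
chains are, in order:

* **DAPI** — rolling-ball background subtraction → 8-bit rescale → sharpen
  → *mean* threshold → erode → dilate. Remaining objects ≥ 30 px are nuclei.
* **Pax-7** — Sobel edge magnitude → 8-bit → min–max luminance stretch
  `Py = (Px − a)(d − c)/(b − a) + c` → watershed dividing lines → rolling
  ball → *Rényi entropy* threshold → close → outline → fill holes → erode →
  small-object removal.
* **BrdU** — 8-bit → sharpen → rolling ball → 3×3 kernel convolution →
  watershed dividing lines → *Intermodes* threshold → small-object removal.

The Rényi entropy threshold maximizes, over candidate levels *t*, the sum
of order-α entropies of the below-*t* and above-*t* distributions,

H<sub>A</sub><sup>α</sup>(t) = (1−α)⁻¹ ln Σ<sub>i≤t</sub> (P<sub>i</sub>/P<sub>A</sub>)<sup>α</sup>,  H<sub>B</sub><sup>α</sup>(t) = (1−α)⁻¹ ln Σ<sub>i>t</sub> (P<sub>i</sub>/P<sub>B</sub>)<sup>α</sup>,

for α ∈ {½, 1, 2} (α = 1 is the Shannon limit), fusing the three candidate
thresholds with the classical weighted rule. Intermodes smooths the
histogram with a 3-point running mean until exactly two modes m₁ < m₂
remain and takes t = ⌊(m₁+m₂)/2⌋.

Co-positivity counts intersect two masks, optionally median-filter the
overlay (BrdU/DAPI), then dilate so fragments of signal within one nucleus
merge into a single object. Agreement with manual counts is summarized by
ordinary least squares (slope, intercept, R²) over paired per-section
values.

A seeded synthetic-section generator (`satquant.synthetic`) renders
three-channel fields with known ground truth — soft-edged nuclei on a
low-frequency background with pixel noise — so the whole pipeline is
testable without real micrographs.

## Worked example

Simulate a section with 100 nuclei (20 % Pax-7⁺, 10 % BrdU⁺, 5 forced
co-positives) and quantify it:

```sh
$ satquant simulate --n-nuclei 100 --copos 5 --seed 42 --out demo
wrote dapi.tif pax7.tif brdu.tif truth.json to demo
$ satquant quantify --dapi demo/dapi.tif --pax7 demo/pax7.tif --brdu demo/brdu.tif --section-id demo
section_id,n_nuclei,n_pax7,n_brdu,n_copositive,ratio_pax7,ratio_brdu,ratio_copositive,error,config_hash,package_version
demo,100,20,10,5,0.2,0.1,0.05,,2fa864bdfc47ee00,0.1.0
```

The row reports the DAPI nucleus count, the three gated positive counts,
and each count divided by the nucleus count (here: exactly the simulated
ground truth). The stderr log records the per-channel thresholds chosen
(e.g. `dapi threshold = 18`, `pax7 threshold = 48`, `brdu threshold =
127`), and the JSON sidecar written with `--out` carries the full
configuration and its hash so any run can be reproduced byte-for-byte.

Other subcommands: `satquant batch --manifest sections.csv` (per-section
failure isolation, exit code 2 on partial failure), `satquant validate
--auto a.csv --manual m.csv` (OLS agreement), `satquant dump-config`
(editable JSON template of every pipeline parameter), and
`satquant quantify --save-stages DIR` to write every intermediate image
for visual audit.

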