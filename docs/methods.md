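# Methods

## The assay

Neutrophils (PMN) entering NETosis decondense their chromatin before any
extracellular trap is released; in a 2D fluorescence image of a DNA stain
(e.g. Sytox Orange) this appears as an expansion of the projected nuclear
area. `netquant` implements the tissue-cytometry readout of that process,
**nuclear area expansion (NAE)**: segment every stained nucleus in a
calibrated single-channel image, remove everything that is not a PMN
nucleus, and report either the percentage of nuclei whose area exceeds a
NETotic threshold (bovine workflow) or the mean nuclear area (canine
workflow). The method quantifies *early* NETosis; it does not measure NET
release itself.

## Pipeline model and conventions

1. **ROI sampling.** Either one square region of a requested total area
   (default 5 mm², placement exposed to the user so preparation artefacts
   such as air bubbles can be avoided) or five randomly placed,
   non-overlapping 4 mm² square quadrants (seeded rejection sampling with a
   10 000-attempt cap; the upstream assay does not document its
   randomisation, so reproducible uniform placement is our choice). Pixel
   coordinates are 0-based and row-major; rectangles are half-open in pixel
   space; physical x/y map to columns/rows with the origin at the image's
   top-left corner.
2. **FI threshold.** A global fluorescence-intensity threshold separates
   background noise from stained material — Otsu's criterion by default,
   or a manual value, mirroring an operator-placed threshold. Foreground is
   *strictly above* the threshold (a fixed, testable convention).
3. **Segmentation.** Connected components (8-connectivity by default)
   labelled in raster-scan order of each object's first pixel, so labels
   are deterministic. No hole-filling by default: nuclei adjacent to NETs
   can legitimately be annular.
4. **Clump splitting.** Marker-controlled watershed on the Euclidean
   distance transform, markers being distance maxima at least
   `min_peak_separation_um` apart (default 4 µm, about one nucleus radius)
   found independently inside each object. The distance map is smoothed by
   one pixel before peak finding, otherwise the rasterised boundary of an
   elongated nucleus produces spurious secondary maxima and oversplitting.
   Only objects yielding ≥ 2 markers are re-partitioned, each inside its
   own bounding box, so single-marker objects pass through bit-identically
   and the object count never decreases. The upstream software resolves
   touching nuclei by an undocumented mechanism; this stage is our
   replacement and is fully config-exposed.
5. **Measurement.** Per-object pixel count, physical area
   (`area_px · pixel_size_um²`), arithmetic mean of raw intensities (no
   background subtraction — whether the original software subtracts
   background is unknown, so the simpler convention is used and stated),
   centroid, and a flag for contact with the ROI border.
6. **Filtering.** A fixed-order chain: drop the ⌊f·N⌋ smallest objects,
   then the ⌊f·N′⌋ dimmest (count-based floor semantics, ties broken by
   ascending label — deterministic, no interpolation ambiguity), then an
   absolute area floor, then border-touching objects ("measuring inside
   ROI": partially captured cells are never measured). The percentile drops
   model the assay's manually compensated "10 % smallest size / 10 % lowest
   FI" thresholds; they are applied per ROI (the original's per-ROI vs
   per-slide behaviour is unstated). Species presets:
   * **bovine** — 10 % size drop + 10 % FI drop, no floor. Bovine sperm
     heads are comparable in size to PMN nuclei but dimmer, so exclusion is
     by fluorescence; small debris is taken by the size drop.
   * **canine** — 14 µm² floor only. Canine sperm heads are bright but
     small, so exclusion is by size.
7. **Classification and summary.** A nucleus is NETotic when its area is
   *strictly greater* than the threshold (default 80 µm², the reported
   resting bovine PMN area); 80.0 µm² exactly is not NETotic, and the
   14 µm² floor keeps an area of exactly 14 µm². Summaries report n,
   % NETotic, mean area and the n−1 sample SD, overall and per ROI, and
   warn below 2×10⁴ counted nuclei (the assay's validity floor). Both
   headline metrics are always computed; the species profile only selects
   which one leads. Scattergram tables (area vs mean FI per nucleus) use
   the mean object intensity; whether the original plots mean or integrated
   intensity is unstated.

## Statistics

Group comparisons follow the classical parametric workflow: normality is
screened with the D'Agostino–Pearson K² (n ≥ 8) and Shapiro–Wilk (n ≥ 3)
tests — below those floors the respective test is skipped and flagged;
if either group fails (any computed p < 0.05) and the metric is a
percentage, both groups are passed through the arcsine transform before a
pooled-variance Student's t-test (df = n₁+n₂−2) at α = 0.05. "Arcsine
value" is implemented as the variance-stabilising arcsin(√(p/100)) in
radians, the standard usage for proportions; the literal arcsin(p/100) is
available behind a flag, as is Welch's t. Confidence intervals are
two-sided t-based, mean ± t₍₀.₉₇₅,n₋₁₎·SD/√n: with n = 4 this exactly
reproduces the published bovine group intervals from their printed
mean/SD pairs, which is the workflow's only externally checkable
arithmetic. The published canine intervals are *not* reproducible as
t-intervals at any plausible n (the 15-min lower bound is ~1.0 off at
n = 3); the suite carries that as a negative control and no canine CI is
used as an anchor. Published p-values are likewise unrecoverable from the
printed summaries (raw per-animal values and the transform actually
applied are unavailable) and are not asserted anywhere.

## Synthetic scenes

Real slides for this assay are not publicly deposited, so correctness is
established on rendered scenes with exact ground truth. The generator
places non-overlapping objects (seeded rejection sampling on a cell grid,
largest objects first, a ≥ 1.5 µm gap and a 4 µm border margin) and renders
them as constant-intensity shapes plus Gaussian pixel noise on a constant
background — no point-spread blur by default, which keeps each ellipse's
analytic area the ground truth up to pixelation (a Gaussian blur is
config-exposed for robustness experiments).

Object model and defaults (chosen once, as field-realistic values):

* **PMN nuclei**: ellipses, axis ratio 1–1.4; resting areas lognormal with
  median 37 µm² and log-SD 0.25 (around the reported resting canine mean);
  an expanded subpopulation (default 4 %) lognormal with median 120 µm²
  and log-SD 0.3, representing early NETotic decondensation. Per-object
  brightness N(3000, 300) on a 16-bit scale over background 100 with noise
  SD 10.
* **Sperm heads**: narrow ellipses (axis ratio 2.5–3.5). Canine mode:
  5–12 µm², 2× PMN brightness. Bovine mode: 20–35 µm² (PMN-sized) at 0.6×
  PMN brightness — dim but clearly above background, as the assay's FI
  threshold must detect all stained material for the FI drop to act on it.
* **Debris**: small dim fragments (3–8 µm², 0.6× brightness).
* **NETs**: unions of 4–8 dim discs (radius up to 8 µm); their ground-truth
  area is the rendered pixel count since the union has no closed form.

The standard **bovine co-culture field** (1.2×1.2 mm at 0.5 µm/px) holds
5000 PMN at 4 % expanded plus contaminants at the prevalence the
compensated percentile drops are calibrated to remove — the in-silico
analogue of the operator compensating the two 10 % thresholds until sperm
and debris are eliminated. The capacity arithmetic fixes the counts: with
N ≈ 6172 objects the size drop removes ⌊0.1·N⌋ = 617 (the debris), and the
FI drop removes ⌊0.1·(N−617)⌋ ≈ 555 of the survivors (the 550 dim sperm
plus the NET blobs and their watershed fragments). The standard **canine
field** (0.8×0.8 mm) holds 1000 PMN and 3000 small bright sperm heads,
removed by the 14 µm² floor.

What the scenes deliberately do **not** model: optical blur and halos,
uneven illumination, true chromatin texture, overlapping or touching
nuclei at density, out-of-focus debris, and NET morphological diversity.
Passing recovery tests therefore demonstrates that the measurement chain
and exclusion rules are implemented correctly, not that the assay is
robust to real acquisition artefacts.

## Problem sizes and numerical choices

Recovery runs use the standard fields above (≈ 6700 rendered objects over
two scenes); null calibration of the t-test uses 10 000 replicates of two
n = 4 groups; the segmentation oracle sweep covers all 512 binary 3×3
grids plus 200 random 16×16 grids for both connectivities. Degenerate
inputs are first-class: a constant image under Otsu, a constant sample
under normality testing, and zero pooled variance with unequal means raise
typed errors; zero pooled variance with equal means returns t = 0, p = 1;
an empty record list summarises to n = 0 with undefined-metric flags
rather than raising.

## Known limitations

* The upstream segmentation engine is proprietary and undocumented; Otsu +
  connected components + optional watershed is the simplest faithful
  reading, and all three stages are config-exposed rather than claimed
  equivalent.
* The percentile drops are deterministic idealisations of a manual
  compensation step; on a slide whose contamination differs from the drop
  fractions they will remove either too few contaminants or some true PMN.
* No µm/px default is shipped: the original acquisition's pixel size is
  unrecorded, so calibration is mandatory user input and explicit
  configuration overrides any file metadata.
* Scene realism is limited as described above; absolute biological values
  (mean areas, % NETotic of real samples) are outside what this package
  can validate.
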