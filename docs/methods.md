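# Methods

## The measurement problem

Prox1 is a homeodomain transcription factor whose immunofluorescence in
Müller glia (MG) changes with retinal injury. Quantifying it on a confocal
section is harder than it sounds: MG nuclei sit in the middle of the inner
nuclear layer (INL), wedged between bipolar-cell (BC) and amacrine-cell (AC)
nuclei that themselves express Prox1 strongly, often within one or two
pixels. Optical blur spreads a bright neighbour's fluorescence into the rim
of the nucleus being measured, and the nucleus segmentations of the Prox1
channel and of the target-marker channel (e.g. Sox2 for MG) never agree
perfectly. `retquant` implements the per-nucleus scoring chain that deals
with this, together with a synthetic-section generator that makes every
stage testable against known ground truth.

## The scoring chain

For one single-focal image with a target-channel label map, a Prox1-channel
label map, the Prox1 channel and compartment masks:

1. **Region extraction.** One region per positive label; a pixel set is a
   set of 0-based (row, col) pairs; areas are pixel counts.
2. **Area filter.** Target nuclei with area > 200 px are scored; the bound
   is strict (a 200-px nucleus is dropped).
3. **Compartment assignment.** A nucleus belongs to the compartment (MG, BC
   or AC band mask) covering more than half of its pixels; anything else is
   `other`. Masks must be disjoint.
4. **Normalization.** The Prox1 channel is divided by the pooled mean
   intensity over the union of all Prox1-channel nucleus pixels (each pixel
   counted once). This makes scores comparable across images and makes every
   downstream quantity invariant to detector gain: scaling the raw channel
   by any c > 0 changes nothing.
5. **Spill-over correction.** For a target nucleus B, every Prox1-channel
   region A_i with A_i ∩ B ≠ ∅ is examined. If A_i ⊆ B the target is treated
   as containing its own Prox1-positive nucleus and nothing is removed.
   Otherwise the Sørensen–Dice coefficient is computed and, when it is below
   0.5, the overlap A_i ∩ B is classed as spill-over and excluded. All
   exclusions are taken against the *original* B, so the result does not
   depend on the order in which neighbours are processed, and
   corrected ⊆ original with (deduplicated spill area) + corrected area =
   original area. A nucleus emptied by the correction is excluded from
   aggregation rather than scored zero, which would bias ratios.
6. **Median and aggregation.** The nucleus score is the median normalized
   intensity over its corrected pixels (even counts: mean of the two central
   values). The image score per compartment is the mean of these medians,
   and MG is reported relative to BC within the same image
   (ratio = mean-of-medians(MG) / mean-of-medians(BC)). Per-retina values
   collapse per-image scores with a mean by default (a median aggregator is
   available).

### Two Dice variants

The standard Sørensen–Dice coefficient is 2|A∩B|/(|A|+|B|) and lies in
(0, 1]; a frequently printed variant divides by |A∪B| instead and can reach
2. Both are exposed (`sdc_variant` = `sum_denominator`, the default, or
`union_denominator`) with the same 0.5 threshold, and reports record which
was used. The two differ materially in one regime: a target engulfed by a
larger Prox1 region has sum-variant SDC 2|B|/(|A|+|B|) < 0.5 (excluded,
nucleus emptied) but union-variant SDC 2|B|/|A| which may reach the
threshold and keep it.

## GFP and puncta scoring

**GFP positivity.** GFP images are histogram-equalized with the plain
cumulative-histogram mapping v → round(255·cdf(v)) — monotone, spreading
occupied levels over 0–255 — then binarized by Otsu's threshold on the 8-bit
histogram. Nuclei whose area is covered strictly more than 50 % by binary
GFP are selected; their median intensities are aggregated exactly like the
Prox1 chain but with spill-over correction bypassed, and image values are
reported relative to a reference group's mean.

**RNAscope puncta.** The puncta channel is reduced to 8 bits (16-bit input:
linear min–max rescale), binarized with the fixed threshold [1, 255]
(dark-background convention: signal is high), and particles are 8-connected
components of the foreground restricted to qualifying nuclei (> 200 px),
with each particle's holes filled before measuring its size. Counts and
areas are divided by the number of qualifying nuclei; the mean particle size
(area / count) is reported alongside. Per-image averaging was chosen over
pooling across a retina before division.

## Statistics

Two groups are compared with the unpaired pooled-variance (Student's)
t-test; the one-sided direction is an explicit analyst input, never inferred
from the data. Zero pooled variance with equal means yields p = 0.5 by
convention. Three or more groups use one-way ANOVA with Tukey's HSD
post-test (no further multiple-testing correction is applied). Dispersion is
reported as mean ± SEM with the sample SD (n − 1). Stars follow
*, p < 0.05; **, p < 0.01; ***, p < 0.005; ****, p < 0.001; n.s., p > 0.05,
with strict inequalities; p exactly 0.05 is conservatively labelled n.s.

## The synthetic section generator

`synthetic_retina` emulates the features of a sectioned retina that the
scoring chain is sensitive to, and nothing else:

* **Geometry.** Horizontal bands ONL / BC / MG / AC / GCL on a 256 × 260 px
  field; BC is the outermost two nucleus rows of the INL, MG the middle row,
  AC the innermost row. Nuclei are near-circular ellipses (semi-axes
  8.5–9.5 px, areas ≈ 230–280 px — just above the 200-px filter, as real
  somata are at this magnification) packed in rows with 1–3 px gaps, the way
  INL somata actually abut; facing edges across the BC/MG and MG/AC
  boundaries end up a few pixels apart. Nuclei within one label map never
  overlap. A band that cannot hold its requested count raises an error
  naming it.
* **Intensities.** Per-nucleus true intensities are drawn per band
  (positive-nucleus Prox1 means: BC = AC = 100, MG = 250, i.e. an
  injured-retina MG/BC ratio of 2.5; 5 % coefficient of variation, rounded
  to integers so 16-bit rendering is lossless). 80 % of BC/MG/AC nuclei are
  Prox1-positive; ONL and GCL are negative. Positives always exceed the
  background level.
* **Corruption.** The Prox1 channel is the sum of flat disks at true
  intensity, Gaussian-blurred (σ = 2 px by default — the optical spill-over),
  plus a background of 5 and additive Gaussian noise (SD 3, clipped at 0),
  quantized to 16 bits.
* **Discordant segmentations.** The target map is exact. The Prox1-channel
  map emulates an instance segmenter run on the *blurred* image: each
  positive nucleus is detected as the footprint where its own blurred signal
  exceeds an absolute detection level (25 units), so bright nuclei come out
  oversized and reach into their dimmer neighbours; `segmentation_jitter`
  dilates the footprint further (2 px by default). One pixel holds one
  label; contested pixels go to the nucleus with the larger blurred
  contribution, which means a Prox1-positive nucleus keeps its own interior
  while Prox1-negative nuclei absorb their bright neighbours' overhang —
  precisely the contamination the Dice correction is meant to remove. With
  blur = 0 and jitter = 0 both maps coincide with the truth exactly.
* **Determinism.** One master seed; per-image seeds are master + index. The
  same config yields byte-identical pixels, ground-truth CSVs and
  quantification CSVs.

### What the generator does *not* model

Three-dimensional stacks, point-spread-function physics, photobleaching,
tissue texture, autofluorescence, and segmentation errors other than
blur-driven oversizing and dilation. Passing the recovery tests therefore
shows that the scoring chain is correct and beneficial under this corruption
model, not that it removes every artefact of real confocal data. Real
sections also vary in staining efficiency between batches, which is why the
within-image BC reference ratio — not an absolute intensity — is the
reported quantity.

### The clean limit and the corrupted regime

With blur, jitter, noise, background and intensity variation all zero, the
pipeline recovers every per-nucleus median exactly (up to float division)
and the MG/BC ratio equals the configured 2.5 to float precision — the
background is part of the corruption set here, since an additive offset
shifts every median. Under the default corruption (jitter 2 px, blur σ = 2,
noise 3, background 5) the recovered ratio sits a few percent below 2.5,
dominated by the additive background (255/105 ≈ 2.43); switching the
correction off makes the absolute bias strictly larger on the same fixtures.
The correction's benefit is concentrated where it should be: Prox1-negative
nuclei flanked by bright neighbours, whose contaminated rims the oversized
Prox1-channel regions mark for exclusion. The per-nucleus median is itself
highly robust to thin-rim contamination, so the net effect on the image
ratio is small but systematic — an honest reflection of how the correction
and the median back each other up.

## Numerical choices

* Pixel sets are stored as sorted flat raster indices; set algebra uses
  numpy's sorted-array routines and is exactly equivalent to explicit set
  operations (tested against a brute-force oracle on random label maps).
* Median of an even-sized set: mean of the two central values.
* RGB exports are collapsed with ITU-R 601 luminance weights normalized to
  sum to one, so a pure-gray RGB image maps to its gray value.
* Area filter (> 200 px), GFP coverage (> 50 %) and the star bins are all
  strict inequalities; the spill-over threshold is `SDC < 0.5`.
* `segment_classic` (Otsu → opening → distance transform → peak-seeded
  watershed) is a deterministic classic segmenter for well-separated nuclei;
  externally produced label maps are the first-class input path and no
  trained model is bundled.
* Greedy label matching pairs labels by descending IoU, one-to-one, with
  ties broken by id; pairs below `iou_min` stay unmatched.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on generated data:
single 256 × 260 px images (73 nuclei) for exactness checks, 20-image
batches for ratio recovery, 300–1000 random ≤ 64 × 64 label-map pairs for
the set-algebra oracle, and 100 random sample pairs for the t-test oracle.
These sizes give stable means while keeping a full run in a few minutes on
one core.

## Known limitations

* The per-retina aggregation hierarchy (images → retina → group) is a
  configuration choice (`mean` default, `median` available); with few images
  per retina the two differ noticeably.
* The union-denominator Dice variant is provided for fidelity to the printed
  formula; its values are not comparable to standard Dice coefficients.
* The normalizer is a pooled-pixel mean over Prox1-positive nuclei; a mean
  of per-nucleus means would weight small nuclei more. The pooled form was
  chosen and is the one the scale-invariance guarantees refer to.
* `gfp_intensity` scores the equalized image when `equalize=True`; absolute
  values are then rank-based and only relative comparisons are meaningful.
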