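# retquant

Nucleus-wise immunofluorescence quantification for retinal sections, built
around the measurement that matters when a dim cell population sits between
bright ones: **how much Prox1 is in a Müller glia (MG) nucleus, relative to
the bipolar cells (BC) in the same image, after removing spill-over from
neighbouring Prox1-bright nuclei**.

## Who this is for

Labs quantifying confocal immunostaining (Prox1, GFP reporters, RNAscope
puncta) on sectioned retina — or any tissue where nuclei of interest abut
brighter neighbours — who already have nucleus segmentations (e.g. from a
StarDist-style model) and need the downstream scoring to be reproducible and
testable. Segmentations are plain integer label-map TIFFs; no model is
bundled or required.

## The method

For each single-focal image, with a target-channel label map, a
Prox1-channel label map (two independent segmentations of the same field),
and MG/BC/AC compartment masks:

1. keep target nuclei with area > 200 px;
2. normalize the Prox1 channel by the mean intensity pooled over all
   Prox1⁺ nucleus pixels;
3. for each target nucleus *B* and each overlapping Prox1⁺ region *Aᵢ* with
   *Aᵢ* ⊄ *B*, compute the Sørensen–Dice coefficient

   SDCᵢ = 2|Aᵢ ∩ B| / (|Aᵢ| + |B|)

   (a union-denominator variant, 2|Aᵢ ∩ B| / |Aᵢ ∪ B|, is selectable) and
   exclude overlaps with SDCᵢ < 0.5 as spill-over, all against the original
   *B* so neighbour order cannot matter;
4. score each nucleus by the **median** normalized intensity of its
   corrected pixels, each compartment by the **mean of medians**, and report
   MG relative to BC within the same image.

The package also implements GFP-positivity scoring (histogram equalization →
Otsu binarization → nuclei covered > 50 % selected → same median/mean chain
without spill-over correction, relative to a reference group), RNAscope
puncta counting (fixed 1–255 threshold, 8-connected particles with holes
filled, totals divided by nucleus count), and the reporting conventions
(one-sided unpaired Student's t-test with explicit direction, ANOVA +
Tukey's HSD, mean ± SEM, star bins from p < 0.05 to p < 0.001).

A first-class synthetic-retina generator (`retquant.synthetic_retina`)
renders banded sections with known per-nucleus ground truth — tightly packed
elliptical nuclei, optical blur, noise, and two deliberately discordant
segmentations — so the entire chain is validated against truth without any
micrographs. See `docs/methods.md` for the model and its limits.

## Worked example

```sh
python examples/simulate_and_quantify.py
```

```
nuclei placed: 73; scored (area > 200 px, non-empty after correction): 73
  AC: mean of per-nucleus medians = 0.848 (n = 10)
  BC: mean of per-nucleus medians = 0.855 (n = 20)
  MG: mean of per-nucleus medians = 2.085 (n = 10)
MG/BC ratio: 2.438  (configured truth 2.5; the gap comes from the additive background and residual blur)
spill-over regions excluded: 18 (overlapping Prox1+ neighbours with Dice coefficient < 0.5)
```

One synthetic image is generated with MG nuclei configured 2.5× brighter in
Prox1 than BC nuclei, corrupted with σ = 2 blur, noise and 2-px segmentation
jitter; the pipeline recovers the ratio to within a few percent (the
residual gap is the additive background, which a within-image ratio cannot
remove). Compartment values are in normalized units — BC sits near its
attenuated flat-disk value, MG about 2.4× higher.

Other examples, one per capability: `spillover_correction.py` (the Dice rule
on a hand-built overlap), `puncta_counting.py`, `gfp_scoring.py`,
`group_statistics.py`.

A thin CLI mirrors the library:

```sh
retquant simulate --n-images 5 --out data/ --seed 1
retquant quantify --manifest data/manifest.json --out scores/
retquant puncta   --manifest data/manifest.json --channel prox1 --out puncta.csv
retquant stats    --scores per_retina.csv --design design.yaml --out report/
```

## Layout

```
src/retquant/
  synthetic_retina.py   ground-truth section generator
  image_io.py           TIFF/label/manifest I/O, classic fallback segmenter,
                        label matching
  nucleus_quant.py      normalization, area filter, Dice spill-over
                        correction, median/mean scoring, compartment ratios
  puncta_positivity.py  RNAscope puncta counts, GFP positivity and intensity
  stats_report.py       t-test / ANOVA+Tukey, SEM, stars, report writer
  cli.py                thin command-line wrapper
examples/               one narrative script per capability
tests/                  unit, property and end-to-end suites (+ oracles)
```
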