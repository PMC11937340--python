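"""Nucleus-wise Prox1 intensity scoring with Dice-based spill-over correction.

The scoring chain, per image:

1. extract nucleus regions from the target-channel and Prox1-channel label
   maps (two independent segmentations of the same field);
2. keep target nuclei with area > 200 px;
3. tag each target nucleus with the compartment (MG / BC / AC) whose mask
   covers more than half of it;
4. normalize the Prox1 channel by the mean Prox1 intensity pooled over all
   Prox1-positive nucleus pixels, so images are comparable;
5. spill-over correction: for every Prox1-positive region A_i overlapping a
   target nucleus B (and not a subset of it), compute the Sørensen–Dice
   coefficient; overlaps with SDC below 0.5 are classed as spill-over from a
   neighbouring bright nucleus, and their pixels are removed from B. All
   exclusions are taken against the original B, so the result does not depend
   on neighbour order;
6. the median normalized intensity over the corrected pixel set is the
   nucleus's score; the mean of these medians per compartment is the image
   score; MG is reported relative to BC within the same image.

Two Dice variants are exposed: ``sum_denominator`` is the standard
Sørensen–Dice 2|A∩B|/(|A|+|B|); ``union_denominator`` is 2|A∩B|/|A∪B|
(which can exceed 1). Both use the same < 0.5 spill-over threshold.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _pixels as px
from .image_io import ChannelImage, ImageBundle

SDC_VARIANTS = ("sum_denominator", "union_denominator")


@dataclass
class NucleusRegion:
    """One segmented nucleus: id, pixel set (flat indices), provenance."""

    id: int
    pixels: np.ndarray  # sorted unique flat raster indices
    shape: tuple[int, int]
    source: str = "target_map"
    compartment: str = "other"

    def __post_init__(self) -> None:
        self.pixels = np.unique(np.asarray(self.pixels, dtype=np.int64))
        if self.pixels.size == 0:
            raise ValueError(f"region {self.id} has no pixels")
        if self.pixels[0] < 0 or self.pixels[-1] >= self.shape[0] * self.shape[1]:
            raise ValueError(f"region {self.id} has pixels outside the image")

    @property
    def area(self) -> int:
        return int(self.pixels.size)

    @property
    def coords(self) -> np.ndarray:
        return px.flat_to_coords(self.pixels, self.shape)


@dataclass
class OverlapRecord:
    """One (neighbour A_i, target B) overlap and its spill-over call."""

    target_id: int
    neighbor_id: int
    overlap_area: int
    union_area: int
    sum_area: int
    is_subset: bool
    sdc: float  # NaN when is_subset (coefficient not evaluated)
    is_spillover: bool


@dataclass
class NucleusMeasurement:
    """Corrected pixel set and median score of one target nucleus."""

    id: int
    compartment: str
    area: int
    corrected_pixels: np.ndarray
    median_intensity: float = math.nan
    excluded_reason: str = "none"  # none | too_small | empty_after_correction

    @property
    def corrected_area(self) -> int:
        return int(np.asarray(self.corrected_pixels).size)


@dataclass
class ImageScore:
    """Per-image aggregate: compartment mean-of-medians and relative ratios."""

    image_id: str
    compartment_means: dict[str, float]
    ratios: dict[str, float]
    n_nuclei: dict[str, int]
    reference_compartment: str
    reference_defined: bool


@dataclass
class ImageQuantification:
    score: ImageScore
    nuclei: pd.DataFrame
    overlaps: pd.DataFrame


@dataclass
class QuantConfig:
    """Tunables of the scoring chain (defaults follow the published method)."""

    sdc_variant: str = "sum_denominator"
    sdc_threshold: float = 0.5
    min_area: int = 200
    membership_fraction: float = 0.5
    reference_compartment: str = "BC"
    correct_spillover: bool = True

    def __post_init__(self) -> None:
        if self.sdc_variant not in SDC_VARIANTS:
            raise ValueError(f"sdc_variant must be one of {SDC_VARIANTS}")

    def fingerprint(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "QuantConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def extract_regions(labels: np.ndarray, source: str = "target_map") -> list[NucleusRegion]:
    """One region per positive label; pixel sets partition the foreground."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    first_fg = np.searchsorted(sorted_vals, 1)
    regions = []
    ids, starts = np.unique(sorted_vals[first_fg:], return_index=True)
    bounds = np.append(starts, sorted_vals.size - first_fg)
    for k, lab in enumerate(ids):
        idx = order[first_fg + starts[k]: first_fg + bounds[k + 1]]
        regions.append(NucleusRegion(id=int(lab), pixels=np.sort(idx),
                                     shape=labels.shape, source=source))
    return regions


def normalize_by_positive_nuclei(
    prox1: ChannelImage | np.ndarray,
    prox1_regions: list[NucleusRegion],
) -> tuple[np.ndarray, float]:
    """Divide the Prox1 channel by the pooled mean over Prox1+ nucleus pixels.

    Returns (normalized float image, normalizer m). The mean of the output
    over the union of Prox1-positive pixels is 1 up to float rounding.
    """
    pixels = prox1.pixels if isinstance(prox1, ChannelImage) else np.asarray(prox1)
    if not prox1_regions:
        raise ValueError("cannot normalize: no Prox1-positive regions")
    union = np.unique(np.concatenate([r.pixels for r in prox1_regions]))
    m = float(pixels.ravel()[union].mean())
    if m == 0:
        raise ValueError("cannot normalize: mean Prox1 intensity is zero")
    return pixels.astype(np.float64) / m, m


def filter_by_area(regions: list[NucleusRegion], min_pixels: int = 200) -> list[NucleusRegion]:
    """Keep nuclei with area strictly greater than ``min_pixels``."""
    return [r for r in regions if r.area > min_pixels]


def compute_sdc(a_pixels, b_pixels, variant: str = "sum_denominator",
                shape: tuple[int, int] | None = None) -> float:
    """Sørensen–Dice coefficient between two overlapping pixel sets.

    ``a_pixels``/``b_pixels`` may be sets of (row, col) pairs, (N, 2)
    coordinate arrays (pass ``shape``), or flat index arrays. Raises on
    disjoint sets and on A ⊆ B, which the spill-over rule excludes upstream.
    """
    if shape is None:
        shape = (1, 1 << 20)  # only set identity matters for the coefficient
    a = px.as_flat(a_pixels, shape)
    b = px.as_flat(b_pixels, shape)
    n_overlap = px.intersect(a, b).size
    if n_overlap == 0:
        raise ValueError("compute_sdc requires overlapping pixel sets")
    if n_overlap == a.size:
        raise ValueError("compute_sdc undefined when A is a subset of B")
    return _sdc_from_sizes(a.size, b.size, n_overlap, variant)


def _sdc_from_sizes(n_a: int, n_b: int, n_overlap: int, variant: str) -> float:
    if variant == "sum_denominator":
        return 2.0 * n_overlap / (n_a + n_b)
    if variant == "union_denominator":
        return 2.0 * n_overlap / (n_a + n_b - n_overlap)
    raise ValueError(f"unknown SDC variant {variant!r}")


def spillover_correct(
    target: NucleusRegion,
    prox1_regions: list[NucleusRegion],
    threshold: float = 0.5,
    variant: str = "sum_denominator",
) -> tuple[NucleusMeasurement, list[OverlapRecord]]:
    """Remove spill-over overlaps from a target nucleus.

    For each Prox1-positive region A_i overlapping the target B: if A_i ⊆ B
    the target is treated as itself Prox1-positive and nothing is removed;
    otherwise the Dice coefficient is computed and overlaps with
    SDC < ``threshold`` are excluded. Exclusions are collected against the
    original B, so the outcome is independent of neighbour order.
    """
    b = target.pixels
    records: list[OverlapRecord] = []
    spill_chunks: list[np.ndarray] = []
    for neigh in prox1_regions:
        ov = px.intersect(neigh.pixels, b)
        if ov.size == 0:
            continue
        subset = ov.size == neigh.pixels.size
        if subset:
            records.append(OverlapRecord(
                target_id=target.id, neighbor_id=neigh.id,
                overlap_area=int(ov.size),
                union_area=px.union_size(neigh.pixels, b, ov.size),
                sum_area=neigh.area + target.area,
                is_subset=True, sdc=math.nan, is_spillover=False))
            continue
        sdc = _sdc_from_sizes(neigh.area, target.area, ov.size, variant)
        spill = sdc < threshold
        if spill:
            spill_chunks.append(ov)
        records.append(OverlapRecord(
            target_id=target.id, neighbor_id=neigh.id,
            overlap_area=int(ov.size),
            union_area=px.union_size(neigh.pixels, b, ov.size),
            sum_area=neigh.area + target.area,
            is_subset=False, sdc=float(sdc), is_spillover=spill))
    if spill_chunks:
        corrected = px.setdiff(b, np.unique(np.concatenate(spill_chunks)))
    else:
        corrected = b
    meas = NucleusMeasurement(
        id=target.id, compartment=target.compartment, area=target.area,
        corrected_pixels=corrected,
        excluded_reason="none" if corrected.size else "empty_after_correction",
    )
    return meas, records


def nucleus_median(normalized: np.ndarray, measurement: NucleusMeasurement) -> float:
    """Median normalized intensity over the corrected pixel set."""
    pixels = np.asarray(measurement.corrected_pixels)
    if pixels.size == 0:
        raise ValueError(f"nucleus {measurement.id}: empty region has no median")
    return float(np.median(np.asarray(normalized).ravel()[pixels]))


def assign_compartments(
    regions: list[NucleusRegion],
    masks: dict[str, np.ndarray],
    membership_fraction: float = 0.5,
) -> list[NucleusRegion]:
    """Tag each region with the compartment covering > ``membership_fraction``
    of its pixels; none (or a tie at the threshold) leaves it as ``other``."""
    flat_masks = {name: np.asarray(m, dtype=bool).ravel() for name, m in masks.items()}
    for region in regions:
        hits = []
        for name, m in flat_masks.items():
            frac = float(m[region.pixels].sum()) / region.area
            if frac > membership_fraction:
                hits.append(name)
        if len(hits) > 1:
            raise ValueError(
                f"region {region.id}: masks {hits} overlap beyond the membership "
                "fraction; compartment masks must be disjoint")
        region.compartment = hits[0] if hits else "other"
    return regions


def quantify_image(bundle: ImageBundle, config: QuantConfig | None = None,
                   channel: str = "prox1") -> ImageQuantification:
    """Run the full per-image scoring chain; see the module docstring."""
    config = config or QuantConfig()
    for required in ("target", "prox1"):
        if required not in bundle.label_maps:
            raise ValueError(f"bundle lacks required label map {required!r}")
    image_id = str(bundle.metadata.get("image_id") or bundle.metadata.get("id") or "")

    target_regions = extract_regions(bundle.label_maps["target"], "target_map")
    prox1_regions = extract_regions(bundle.label_maps["prox1"], "prox1_map")
    kept = filter_by_area(target_regions, config.min_area)
    assign_compartments(kept, bundle.masks, config.membership_fraction)
    normalized, scale = normalize_by_positive_nuclei(bundle.channels[channel],
                                                     prox1_regions)

    kept_ids = {r.id for r in kept}
    rows, overlap_rows = [], []
    measurements: list[NucleusMeasurement] = []
    for region in target_regions:
        if region.id not in kept_ids:
            rows.append(dict(image_id=image_id, nucleus_id=region.id,
                             compartment="other", area=region.area,
                             corrected_area=region.area,
                             median_intensity=math.nan,
                             excluded_reason="too_small"))
            continue
    for region in kept:
        if config.correct_spillover:
            meas, records = spillover_correct(
                region, prox1_regions, config.sdc_threshold, config.sdc_variant)
        else:
            meas, records = NucleusMeasurement(
                id=region.id, compartment=region.compartment, area=region.area,
                corrected_pixels=region.pixels), []
        if meas.excluded_reason == "none":
            meas.median_intensity = nucleus_median(normalized, meas)
        measurements.append(meas)
        rows.append(dict(image_id=image_id, nucleus_id=meas.id,
                         compartment=meas.compartment, area=meas.area,
                         corrected_area=meas.corrected_area,
                         median_intensity=meas.median_intensity,
                         excluded_reason=meas.excluded_reason))
        for rec in records:
            overlap_rows.append(dict(image_id=image_id, **dataclasses.asdict(rec)))

    compartments = sorted(bundle.masks.keys())
    comp_means, n_nuclei = {}, {}
    for comp in compartments:
        vals = [m.median_intensity for m in measurements
                if m.compartment == comp and m.excluded_reason == "none"]
        n_nuclei[comp] = len(vals)
        comp_means[comp] = float(np.mean(vals)) if vals else math.nan

    ref = config.reference_compartment
    ref_value = comp_means.get(ref, math.nan)
    ref_ok = math.isfinite(ref_value) and ref_value > 0
    ratios = {}
    for comp in compartments:
        if comp == ref:
            continue
        ratios[f"{comp}/{ref}"] = (comp_means[comp] / ref_value
                                   if ref_ok and math.isfinite(comp_means[comp])
                                   else math.nan)

    score = ImageScore(image_id=image_id, compartment_means=comp_means,
                       ratios=ratios, n_nuclei=n_nuclei,
                       reference_compartment=ref, reference_defined=ref_ok)
    nuclei_df = pd.DataFrame(rows, columns=[
        "image_id", "nucleus_id", "compartment", "area", "corrected_area",
        "median_intensity", "excluded_reason"])
    overlaps_df = pd.DataFrame(overlap_rows, columns=[
        "image_id", "target_id", "neighbor_id", "overlap_area", "union_area",
        "sum_area", "is_subset", "sdc", "is_spillover"])
    return ImageQuantification(score=score, nuclei=nuclei_df, overlaps=overlaps_df)


def scores_to_frame(scores: list[ImageScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"image_id": s.image_id, "reference_compartment": s.reference_compartment,
               "reference_defined": s.reference_defined}
        for comp, v in s.compartment_means.items():
            row[f"mean_of_medians_{comp}"] = v
            row[f"n_nuclei_{comp}"] = s.n_nuclei[comp]
        for name, v in s.ratios.items():
            row[f"ratio_{name.replace('/', '_over_')}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_dataset(manifest: dict, root, config: QuantConfig | None = None,
                     out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Quantify every image in a manifest; optionally write the three CSVs
    (image_scores.csv, nuclei.csv, overlaps.csv) plus the config fingerprint."""
    from .image_io import read_bundle

    config = config or QuantConfig()
    scores, nuclei, overlaps = [], [], []
    for entry in manifest.get("images", []):
        bundle = read_bundle(entry, root)
        bundle.metadata.setdefault("image_id", entry.get("id"))
        q = quantify_image(bundle, config)
        scores.append(q.score)
        nuclei.append(q.nuclei)
        overlaps.append(q.overlaps)
    scores_df = scores_to_frame(scores)
    nuclei_df = (pd.concat(nuclei, ignore_index=True)
                 if nuclei else pd.DataFrame())
    overlaps_df = (pd.concat(overlaps, ignore_index=True)
                   if overlaps else pd.DataFrame())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores_df.to_csv(out / "image_scores.csv", index=False)
        nuclei_df.to_csv(out / "nuclei.csv", index=False)
        overlaps_df.to_csv(out / "overlaps.csv", index=False)
        with open(out / "quant_config.yaml", "w") as fh:
            yaml.safe_dump(config.fingerprint(), fh, sort_keys=True)
    return scores_df, nuclei_df, overlaps_df


def aggregate_scores(scores_df: pd.DataFrame, column: str,
                     by: str = "image_id", aggregator: str = "mean") -> pd.Series:
    """Collapse per-image scores to one value per retina/animal.

    ``aggregator`` is ``mean`` (default) or ``median``; figure dots in this
    kind of analysis are one value per retina.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    grouped = scores_df.groupby(by)[column]
    return grouped.mean() if aggregator == "mean" else grouped.median()
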