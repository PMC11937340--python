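"""RNAscope puncta counting and GFP-positivity scoring.

RNAscope in-situ hybridization renders single transcripts as bright puncta;
the readout here is particle count and size per segmented nucleus: the
channel is binarized with a fixed threshold (min 1, max 255 on the 8-bit
scale, dark-background convention), particles are 8-connected components
restricted to qualifying nuclei (area > 200 px) with holes filled, and totals
are divided by the number of qualifying nuclei.

GFP scoring: the GFP channel is histogram-equalized, binarized by Otsu's
method, nuclei whose area is covered > 50% by binary GFP are called positive,
and their median intensities are aggregated exactly like the Prox1 chain but
without spill-over correction; image values are reported relative to a
reference group's mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image_io import ChannelImage
from .nucleus_quant import (NucleusMeasurement, NucleusRegion, filter_by_area,
                            nucleus_median)


@dataclass
class PunctaResult:
    """Particle statistics over one image's qualifying nuclei."""

    n_nuclei: int
    total_particle_count: int
    total_particle_area: int
    mean_count_per_nucleus: float
    mean_area_per_nucleus: float
    mean_particle_size: float  # total area / particle count


@dataclass
class PositivityCall:
    nucleus_id: int
    gfp_covered_fraction: float
    selected: bool


def to_uint8(channel: ChannelImage | np.ndarray) -> np.ndarray:
    """8-bit view of a channel; wider/float data is min-max rescaled to 0-255."""
    pixels = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    if pixels.dtype == np.uint8:
        return pixels
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    return np.round((pixels.astype(np.float64) - lo) / (hi - lo) * 255).astype(np.uint8)


def binarize_fixed(channel: ChannelImage | np.ndarray, min_t: int = 1,
                   max_t: int = 255) -> np.ndarray:
    """Fixed-threshold binarization on the 8-bit scale (dark background)."""
    img = to_uint8(channel)
    return (img >= min_t) & (img <= max_t)


def count_puncta(binary: np.ndarray, regions: list[NucleusRegion],
                 fill_holes: bool = True, min_area: int = 200) -> PunctaResult:
    """Count 8-connected particles inside qualifying nuclei.

    Foreground is restricted to the union of nuclei with area > ``min_area``;
    each particle's holes are filled before its size is measured.
    """
    binary = np.asarray(binary, dtype=bool)
    qualifying = filter_by_area(regions, min_area)
    if not qualifying:
        raise ValueError("no nuclei: every region fails the area filter")
    for r in qualifying:
        if r.shape != binary.shape:
            raise ValueError("binary image and regions must share dimensions")
    nucleus_mask = np.zeros(binary.shape, dtype=bool)
    for r in qualifying:
        nucleus_mask.ravel()[r.pixels] = True
    restricted = binary & nucleus_mask
    labels, n_particles = ndi.label(restricted, structure=np.ones((3, 3), dtype=int))
    total_area = 0
    if n_particles:
        slices = ndi.find_objects(labels)
        for lab, sl in enumerate(slices, start=1):
            comp = labels[sl] == lab
            if fill_holes:
                comp = ndi.binary_fill_holes(comp)
            total_area += int(comp.sum())
    n_nuclei = len(qualifying)
    return PunctaResult(
        n_nuclei=n_nuclei,
        total_particle_count=int(n_particles),
        total_particle_area=int(total_area),
        mean_count_per_nucleus=n_particles / n_nuclei,
        mean_area_per_nucleus=total_area / n_nuclei,
        mean_particle_size=total_area / n_particles if n_particles else 0.0,
    )


def otsu_binarize(channel: ChannelImage | np.ndarray) -> np.ndarray:
    """Otsu threshold on the 8-bit histogram; foreground = values above it."""
    img = to_uint8(channel)
    if img.min() == img.max():
        raise ValueError("degenerate histogram: constant image has no Otsu threshold")
    t = threshold_otsu(img, nbins=256)
    return img > t


def select_gfp_positive(regions: list[NucleusRegion],
                        gfp_binary: np.ndarray) -> list[PositivityCall]:
    """Call a nucleus GFP-positive when binary GFP covers > 50% of its area."""
    fg = np.asarray(gfp_binary, dtype=bool).ravel()
    calls = []
    for r in regions:
        frac = float(fg[r.pixels].sum()) / r.area
        calls.append(PositivityCall(nucleus_id=r.id, gfp_covered_fraction=frac,
                                    selected=frac > 0.5))
    return calls


def equalize_histogram(channel: ChannelImage | np.ndarray) -> np.ndarray:
    """Cumulative-histogram equalization of an 8-bit image.

    Gray level v maps to round(255 · cdf(v)); the mapping is monotone
    non-decreasing and spreads the occupied levels over the full 0–255 range.
    """
    img = to_uint8(channel) if not (
        isinstance(channel, np.ndarray) and channel.dtype == np.uint8) else channel
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    lut = np.round(255.0 * cdf).astype(np.uint8)
    return lut[img]


def gfp_intensity(
    channel: ChannelImage | np.ndarray,
    nucleus_regions: list[NucleusRegion],
    gfp_binary: np.ndarray | None = None,
    min_area: int = 200,
    equalize: bool = True,
) -> tuple[float, list[PositivityCall], dict[int, float]]:
    """Image-level GFP score: mean of per-nucleus medians over selected nuclei.

    Reuses the nucleus median machinery with spill-over correction bypassed.
    Returns (image value, positivity calls, per-nucleus medians). The image
    value is NaN when no nucleus is selected.
    """
    img = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    work = equalize_histogram(to_uint8(img)) if equalize else img
    if gfp_binary is None:
        gfp_binary = otsu_binarize(work)
    qualifying = filter_by_area(nucleus_regions, min_area)
    calls = select_gfp_positive(qualifying, gfp_binary)
    selected = {c.nucleus_id for c in calls if c.selected}
    medians: dict[int, float] = {}
    for r in qualifying:
        if r.id not in selected:
            continue
        meas = NucleusMeasurement(id=r.id, compartment=r.compartment,
                                  area=r.area, corrected_pixels=r.pixels)
        medians[r.id] = nucleus_median(np.asarray(work, dtype=np.float64), meas)
    value = float(np.mean(list(medians.values()))) if medians else math.nan
    return value, calls, medians


def relative_to_reference(values, reference_group_mean: float) -> np.ndarray:
    """Express image values relative to a reference group's mean."""
    if not np.isfinite(reference_group_mean) or reference_group_mean <= 0:
        raise ValueError("reference group mean must be positive and finite")
    return np.asarray(values, dtype=np.float64) / reference_group_mean
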