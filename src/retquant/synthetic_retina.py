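"""Synthetic retinal-section fixtures with known per-nucleus ground truth.

Real quantification runs on confocal sections of the retina, where nuclei sit
in horizontal bands: the outer nuclear layer (ONL), the inner nuclear layer
(INL) — whose outer sublayer holds bipolar cells (BC), middle holds Müller
glia (MG) and innermost single layer holds amacrine cells (AC) — and the
ganglion cell layer (GCL). This module emulates that geometry: elliptical,
non-overlapping nuclei per band, a configurable subset of them Prox1-positive,
a Prox1 channel rendered as flat disks at each nucleus's true intensity,
optionally Gaussian-blurred (optical spill-over), with background and
additive noise; plus two deliberately discordant segmentations — an exact
"target" label map holding every nucleus, and a "Prox1-channel" label map
holding only Prox1-positive nuclei, jittered so that its regions overlap
neighbouring target nuclei the way two independent segmentations of the same
field do.

Every stochastic choice is driven by a single seed, so identical configs give
identical pixels and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk

from .image_io import ChannelImage, ImageBundle, write_bundle

BANDS = ("ONL", "BC", "MG", "AC", "GCL")
CHANNELS = ("dapi", "prox1", "marker")

_GT_COLUMNS = [
    "id", "band", "prox1_positive",
    "center_row", "center_col", "axis_row", "axis_col", "angle",
    "intensity_dapi", "intensity_prox1", "intensity_marker",
]


def _default_bands() -> dict[str, tuple[int, int]]:
    # sized for rows of ~10 px-radius nuclei: ONL 3 rows, BC the outermost
    # 2 rows of the INL, MG a single middle row, AC the innermost row
    return {"ONL": (15, 85), "BC": (85, 125), "MG": (125, 146),
            "AC": (146, 167), "GCL": (180, 230)}


def _default_counts() -> dict[str, int]:
    return {"ONL": 27, "BC": 20, "MG": 10, "AC": 10, "GCL": 6}


def _default_positive_fraction() -> dict[str, float]:
    # Prox1 is expressed by most (not all) BCs, ACs and, after injury, MG;
    # photoreceptors and ganglion cells are negative in this model.
    return {"ONL": 0.0, "BC": 0.8, "MG": 0.8, "AC": 0.8, "GCL": 0.0}


def _default_intensity_means() -> dict[str, dict[str, float]]:
    return {
        "prox1": {"ONL": 0.0, "BC": 100.0, "MG": 250.0, "AC": 100.0, "GCL": 0.0},
        "marker": {"ONL": 60.0, "BC": 80.0, "MG": 200.0, "AC": 80.0, "GCL": 60.0},
        "dapi": {"ONL": 150.0, "BC": 150.0, "MG": 150.0, "AC": 150.0, "GCL": 150.0},
    }


@dataclass
class SimulationConfig:
    """Geometry, intensity and corruption parameters of one synthetic image.

    Units: lengths in pixels, intensities in arbitrary fluorescence units
    (rendered into a 16-bit range), ``noise_sd`` and ``background_level`` on
    the same intensity scale.
    """

    image_height: int = 260
    image_width: int = 256
    band_boundaries: dict[str, tuple[int, int]] = field(default_factory=_default_bands)
    nuclei_per_band: dict[str, int] = field(default_factory=_default_counts)
    radius_range: tuple[float, float] = (8.5, 9.5)
    prox1_positive_fraction: dict[str, float] = field(default_factory=_default_positive_fraction)
    intensity_means: dict[str, dict[str, float]] = field(default_factory=_default_intensity_means)
    intensity_cv: float = 0.05
    spillover_blur_sigma: float = 2.0
    segmentation_jitter: int = 2
    detection_level: float = 25.0
    noise_sd: float = 3.0
    background_level: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_stop = -1
        for band in BANDS:
            if band not in self.band_boundaries:
                raise ValueError(f"band_boundaries missing band {band!r}")
            start, stop = self.band_boundaries[band]
            if not (0 <= start < stop <= self.image_height):
                raise ValueError(f"band {band!r} interval ({start}, {stop}) out of range")
            if start < prev_stop:
                raise ValueError(f"band {band!r} overlaps or precedes the previous band")
            prev_stop = stop
        for band, frac in self.prox1_positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"prox1_positive_fraction[{band!r}] = {frac} not in [0, 1]")
        if self.radius_range[0] < 2:
            raise ValueError("radius_range minimum must be >= 2 px")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        for name in ("spillover_blur_sigma", "noise_sd", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.segmentation_jitter < 0:
            raise ValueError("segmentation_jitter must be non-negative")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("band_boundaries",):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        if "radius_range" in raw:
            raw["radius_range"] = tuple(raw["radius_range"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-nucleus truth table for one synthetic image.

    ``nuclei`` has one row per nucleus with its label id, band/compartment,
    Prox1-positivity, ellipse parameters (centre, semi-axes, rotation) and the
    true per-channel intensity painted into the rendered image (before
    background, blur and noise).
    """

    nuclei: pd.DataFrame
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        ids = self.nuclei["id"]
        if ids.duplicated().any():
            raise ValueError("ground-truth nucleus ids must be unique")

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def to_csv(self, path) -> None:
        self.nuclei.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape: tuple[int, int]) -> "GroundTruth":
        return cls(pd.read_csv(path), shape)


def _rasterize(row, shape) -> tuple[np.ndarray, np.ndarray]:
    return draw_ellipse(
        row.center_row, row.center_col, row.axis_row, row.axis_col,
        shape=shape, rotation=row.angle,
    )


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Place non-overlapping elliptical nuclei in tight rows, band by band.

    Somata in the nuclear layers of a real section sit in densely packed
    rows, so nuclei are laid out row-wise with 1-3 px lateral gaps and a row
    pitch of twice the maximum radius plus one; facing edges of neighbours
    (including across the BC/MG/AC boundaries) end up a few pixels apart,
    which is what makes optical spill-over between compartments possible.
    A band that cannot hold its requested count raises ``RuntimeError``
    naming it. Deterministic for a given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    shape = (config.image_height, config.image_width)
    occupancy = np.zeros(shape, dtype=bool)
    margin = int(np.ceil(config.radius_range[1]))
    pitch = 2 * margin
    rows: list[dict] = []
    next_id = 1
    for band in BANDS:
        count = int(config.nuclei_per_band.get(band, 0))
        if count == 0:
            continue
        start, stop = config.band_boundaries[band]
        row_centers = list(range(start + margin, stop - margin + 1, pitch))
        if not row_centers:
            raise RuntimeError(
                f"infeasible packing: band {band!r} is too thin for radius "
                f"range {config.radius_range}")
        placed = 0
        for cr in row_centers:
            if placed >= count:
                break
            cc_edge = float(margin + rng.integers(0, 5))  # stagger rows
            while placed < count:
                ry, rx = rng.uniform(*config.radius_range, size=2)
                angle = float(rng.uniform(0, np.pi))
                # horizontal semi-extent of the rotated ellipse
                ext = float(np.hypot(ry * np.sin(angle), rx * np.cos(angle)))
                cc = int(round(cc_edge + ext)) + 1
                if cc + margin > config.image_width:
                    break  # row full, move to the next row
                rr, cols = draw_ellipse(cr, cc, ry, rx, shape=shape,
                                        rotation=angle)
                if occupancy[rr, cols].any():  # cannot happen with this pitch
                    raise RuntimeError(
                        f"packing collision in band {band!r}; check geometry")
                occupancy[rr, cols] = True
                rows.append(dict(id=next_id, band=band, center_row=cr,
                                 center_col=cc, axis_row=ry,
                                 axis_col=rx, angle=angle))
                next_id += 1
                placed += 1
                cc_edge = cc + ext + float(rng.integers(0, 3))  # 1-3 px gap
        if placed < count:
            raise RuntimeError(
                f"infeasible packing: could not place {count} nuclei in band "
                f"{band!r} (placed {placed}; add rows or widen the image)")
        # exact positive count per band (round(fraction * n))
        frac = float(config.prox1_positive_fraction.get(band, 0.0))
        band_rows = rows[-count:]
        n_pos = int(round(frac * count))
        pos_idx = rng.choice(count, size=n_pos, replace=False)
        for j, r in enumerate(band_rows):
            r["prox1_positive"] = bool(j in set(pos_idx.tolist()))

    floor = int(np.floor(config.background_level)) + 1
    for r in rows:
        for channel in CHANNELS:
            mean = float(config.intensity_means[channel][r["band"]])
            if channel == "prox1" and not r["prox1_positive"]:
                r["intensity_prox1"] = 0.0
                continue
            value = mean if config.intensity_cv == 0 else float(
                rng.normal(mean, config.intensity_cv * mean))
            value = float(np.round(value))  # integers survive 16-bit rendering
            if channel == "prox1":
                value = max(value, float(floor))  # positives stay above background
            r[f"intensity_{channel}"] = max(value, 0.0)

    nuclei = pd.DataFrame(rows, columns=_GT_COLUMNS) if rows else pd.DataFrame(
        columns=_GT_COLUMNS)
    return GroundTruth(nuclei=nuclei, shape=shape)


def _paint_channel(gt: GroundTruth, channel: str, shape) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    for row in gt.nuclei.itertuples():
        value = getattr(row, f"intensity_{channel}")
        if value <= 0:
            continue
        rr, cc = _rasterize(row, shape)
        img[rr, cc] = value
    return img


def _jittered_prox1_labels(gt: GroundTruth, config: SimulationConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Prox1-channel segmentation of the blurred image, emulated.

    A segmenter run on the blurred Prox1 channel detects each positive
    nucleus as the footprint where its own blurred signal exceeds
    ``detection_level``, so bright nuclei come out systematically oversized —
    their footprint reaches a few pixels into adjacent (dimmer or negative)
    nuclei, exactly the discordance the Dice-based correction targets.
    ``segmentation_jitter`` adds further boundary error as a dilation of the
    detected footprint by ``jitter`` px. A pixel holds one label: contested
    pixels go to the nucleus with the larger blurred contribution there
    (ties to the lower id). With blur σ = 0 and jitter = 0 the map equals
    the true positive regions exactly.
    """
    shape = gt.shape
    jitter = int(config.segmentation_jitter)
    sigma = float(config.spillover_blur_sigma)
    labels = np.zeros(shape, dtype=np.int32)
    best_score = np.zeros(shape, dtype=np.float64)
    selem = disk(jitter) if jitter > 0 else None
    for row in gt.nuclei.itertuples():
        if not row.prox1_positive:
            continue
        mask = np.zeros(shape, dtype=bool)
        rr, cc = _rasterize(row, shape)
        mask[rr, cc] = True
        blurred = (ndi.gaussian_filter(mask * float(row.intensity_prox1), sigma)
                   if sigma > 0 else mask * float(row.intensity_prox1))
        footprint = blurred >= config.detection_level
        if not footprint.any():
            footprint = mask  # dim nucleus: detected at its true extent
        if jitter > 0:
            footprint = dilation(footprint, selem)
        # conflict score: blurred contribution; when the optical blur is
        # narrower than the jitter the boundary uncertainty is set by the
        # jitter itself
        sigma_score = max(sigma, jitter / 2.0)
        if sigma_score > sigma:
            score_img = ndi.gaussian_filter(
                mask * float(row.intensity_prox1), sigma_score)
        else:
            score_img = blurred
        pr, pc = np.nonzero(footprint)
        score = score_img[pr, pc]
        take = score > best_score[pr, pc]
        labels[pr[take], pc[take]] = row.id
        best_score[pr[take], pc[take]] = score[take]
    return labels


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    src = mask[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
    out[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)] = src
    return out


def _quantize16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def render_bundle(gt: GroundTruth, config: SimulationConfig,
                  image_id: str = "img000") -> ImageBundle:
    """Render channels, label maps and compartment masks from ground truth."""
    config.validate()
    shape = gt.shape
    rng = np.random.default_rng([config.seed, 1])

    target_labels = np.zeros(shape, dtype=np.int32)
    for row in gt.nuclei.itertuples():
        rr, cc = _rasterize(row, shape)
        target_labels[rr, cc] = row.id

    channels: dict[str, ChannelImage] = {}
    for channel in CHANNELS:
        img = _paint_channel(gt, channel, shape)
        if channel == "prox1" and config.spillover_blur_sigma > 0:
            img = ndi.gaussian_filter(img, config.spillover_blur_sigma)
        img = img + config.background_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        channels[channel] = ChannelImage(_quantize16(img), name=channel)

    prox1_labels = _jittered_prox1_labels(gt, config, rng)

    masks = {}
    for band in ("BC", "MG", "AC"):
        start, stop = config.band_boundaries[band]
        m = np.zeros(shape, dtype=bool)
        m[start:stop, :] = True
        masks[band] = m

    return ImageBundle(
        channels=channels,
        label_maps={"target": target_labels, "prox1": prox1_labels},
        masks=masks,
        metadata={"image_id": image_id, "seed": config.seed},
    )


def make_dataset(config: SimulationConfig, n_images: int, out_dir) -> dict:
    """Write ``n_images`` rendered bundles plus ground truth and a manifest.

    Per-image seeds are ``config.seed + index``, so images are independent yet
    the whole dataset is reproducible from the master seed. Returns the
    manifest dict (also written to ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(int(n_images)):
        cfg_i = config.replace(seed=config.seed + i)
        image_id = f"img{i:03d}"
        gt = generate_ground_truth(cfg_i)
        bundle = render_bundle(gt, cfg_i, image_id=image_id)
        paths = write_bundle(bundle, out, stem=image_id)
        gt_path = f"{image_id}_ground_truth.csv"
        gt.to_csv(out / gt_path)
        entries.append({
            "id": image_id,
            "retina_id": f"retina{i:03d}",
            "group": "simulated",
            "seed": cfg_i.seed,
            "ground_truth_path": gt_path,
            **paths,
        })
    manifest = {"master_seed": config.seed, "n_images": int(n_images),
                "images": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
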