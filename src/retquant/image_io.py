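"""Image, label-map and manifest I/O plus a classic fallback segmenter.

Quantification consumes an :class:`ImageBundle`: named fluorescence channels,
integer nucleus label maps (at least a ``target`` and a ``prox1`` map) and
binary compartment masks, all sharing one 2-D shape. Label maps are expected
to come from an external instance segmenter (e.g. a pretrained deep-learning
model run elsewhere) and are read purely as integer TIFFs;
:func:`segment_classic` provides a deterministic threshold/watershed stand-in
so the pipeline runs end to end without any model, and :func:`match_labels`
scores one label map against another for validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.segmentation import relabel_sequential, watershed

logger = logging.getLogger(__name__)

# ITU-R 601 luminance weights for RGB exports, normalized so a pure-gray
# RGB image maps exactly to its gray value
_LUMINANCE = np.array([0.2989, 0.5870, 0.1140])
_LUMINANCE = _LUMINANCE / _LUMINANCE.sum()


@dataclass
class ChannelImage:
    """One fluorescence channel: a 2-D non-negative intensity grid."""

    pixels: np.ndarray
    name: str = ""
    bit_depth: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"channel {self.name!r} must be 2-D")
        if np.issubdtype(self.pixels.dtype, np.signedinteger) and (self.pixels < 0).any():
            raise ValueError(f"channel {self.name!r} has negative intensities")
        if np.issubdtype(self.pixels.dtype, np.floating) and (self.pixels < 0).any():
            raise ValueError(f"channel {self.name!r} has negative intensities")
        if not self.bit_depth:
            self.bit_depth = _bit_depth_of(self.pixels.dtype, self.name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _bit_depth_of(dtype, name) -> str:
    if dtype == np.uint8:
        return "8"
    if dtype == np.uint16:
        return "16"
    if np.issubdtype(dtype, np.floating):
        return "float"
    if np.issubdtype(dtype, np.integer):
        return "16"
    raise ValueError(f"unknown bit depth for channel {name!r}: dtype {dtype}")


@dataclass
class ImageBundle:
    """All rasters of one field of view, plus identifying metadata."""

    channels: dict[str, ChannelImage]
    label_maps: dict[str, np.ndarray] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("bundle needs at least one channel")
        shape = self.shape
        for name, ch in self.channels.items():
            if ch.shape != shape:
                raise ValueError(f"channel {name!r} shape {ch.shape} != {shape}")
        for name, lab in self.label_maps.items():
            lab = np.asarray(lab)
            if lab.shape != shape:
                raise ValueError(f"label map {name!r} shape {lab.shape} != {shape}")
            if not np.issubdtype(lab.dtype, np.integer):
                raise ValueError(f"label map {name!r} must be integer-valued")
            if lab.min() < 0:
                raise ValueError(f"label map {name!r} contains negative labels")
            self.label_maps[name] = lab
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != {shape}")
            self.masks[name] = m.astype(bool)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to grayscale with fixed luminance weights."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        return pixels[..., :3].astype(np.float64) @ _LUMINANCE
    raise ValueError(f"cannot interpret array of shape {pixels.shape} as an image")


def read_channel(path, name: str = "") -> ChannelImage:
    arr = tifffile.imread(str(path))
    arr = to_grayscale(arr)
    return ChannelImage(arr, name=name or Path(path).stem)


def read_label_map(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label map {path} must be a 2-D integer TIFF")
    if arr.min() < 0:
        raise ValueError(f"label map {path} contains negative labels")
    return arr.astype(np.int32)


def write_bundle(bundle: ImageBundle, out_dir, stem: str) -> dict:
    """Write one TIFF per channel/label map/mask; returns manifest path groups.

    Integer data round-trips exactly: channels keep their dtype, label maps are
    written as 16-bit (ids must fit), masks as 8-bit 0/1.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_paths, label_paths, mask_paths = {}, {}, {}
    for name, ch in bundle.channels.items():
        p = f"{stem}_{name}.tif"
        tifffile.imwrite(out / p, ch.pixels)
        channel_paths[name] = p
    for name, lab in bundle.label_maps.items():
        if lab.max(initial=0) > 65535:
            raise ValueError(f"label map {name!r} exceeds 16-bit range")
        p = f"{stem}_labels_{name}.tif"
        tifffile.imwrite(out / p, lab.astype(np.uint16))
        label_paths[name] = p
    for name, m in bundle.masks.items():
        p = f"{stem}_mask_{name}.tif"
        tifffile.imwrite(out / p, m.astype(np.uint8))
        mask_paths[name] = p
    return {"channel_paths": channel_paths, "label_paths": label_paths,
            "mask_paths": mask_paths}


def read_bundle(entry: dict, root) -> ImageBundle:
    """Load one manifest entry; every raster must share one shape."""
    root = Path(root)
    channels = {name: read_channel(root / p, name)
                for name, p in entry.get("channel_paths", {}).items()}
    label_maps = {name: read_label_map(root / p)
                  for name, p in entry.get("label_paths", {}).items()}
    masks = {name: tifffile.imread(str(root / p)).astype(bool)
             for name, p in entry.get("mask_paths", {}).items()}
    if channels:
        try:
            bundle = ImageBundle(
                channels=channels, label_maps=label_maps, masks=masks,
                metadata={k: entry.get(k) for k in ("id", "retina_id", "group", "seed")},
            )
        except ValueError as exc:
            raise ValueError(f"inconsistent bundle for image {entry.get('id')!r}: {exc}")
        return bundle
    raise ValueError(f"manifest entry {entry.get('id')!r} lists no channels")


def read_manifest(path) -> tuple[dict, Path]:
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    return manifest, path.parent


def segment_classic(channel: ChannelImage, smoothing_sigma: float = 1.0,
                    min_distance: int = 7,
                    threshold_method: str = "otsu") -> np.ndarray:
    """Deterministic classic nucleus segmentation.

    Global Otsu threshold on the smoothed image, morphological opening,
    Euclidean distance transform, peak-seeded watershed. A stand-in for
    externally produced (deep-learning) label maps, adequate for
    well-separated synthetic nuclei.
    """
    img = np.asarray(channel.pixels, dtype=np.float64)
    if img.max() == img.min():
        logger.warning("segment_classic: blank image, returning empty label map")
        return np.zeros(img.shape, dtype=np.int32)
    if smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, smoothing_sigma)
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    fg = img > threshold_otsu(img)
    fg = opening(fg, disk(2))
    if not fg.any():
        logger.warning("segment_classic: no foreground after opening")
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def match_labels(pred: np.ndarray, truth: np.ndarray,
                 iou_min: float = 0.0) -> list[tuple[int, int, float]]:
    """Greedy one-to-one label matching by descending IoU.

    Returns (pred_id, truth_id, iou) triples with iou >= ``iou_min``; each id
    appears at most once. Ties broken by (pred_id, truth_id).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth label maps must share dimensions")
    both = (pred > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], truth[both]]), axis=1, return_counts=True)
    pred_areas = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    truth_areas = dict(zip(*np.unique(truth[truth > 0], return_counts=True)))
    candidates = []
    for (p, t), inter in zip(pairs.T, counts):
        union = pred_areas[p] + truth_areas[t] - inter
        candidates.append((inter / union, int(p), int(t)))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p, used_t, matches = set(), set(), []
    for iou, p, t in candidates:
        if iou < iou_min or p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        matches.append((p, t, float(iou)))
    return matches
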