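import numpy as np
import pytest

from retquant.nucleus_quant import NucleusRegion
from retquant.synthetic_retina import SimulationConfig


@pytest.fixture
def clean_config():
    """Corruption-free simulation: no blur, no jitter, no noise, no
    background, deterministic per-nucleus intensities."""
    return SimulationConfig(seed=11, spillover_blur_sigma=0.0,
                            segmentation_jitter=0, noise_sd=0.0,
                            background_level=0.0, intensity_cv=0.0)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def sparse_config():
    """One nucleus per band: every pair of nuclei is far apart."""
    return SimulationConfig(seed=11, nuclei_per_band={b: 1 for b in
                            ("ONL", "BC", "MG", "AC", "GCL")})


def region_from_coords(coords, shape, rid=1, **kw):
    """Build a NucleusRegion from (row, col) pairs."""
    coords = np.asarray(sorted(coords), dtype=np.int64).reshape(-1, 2)
    flat = coords[:, 0] * shape[1] + coords[:, 1]
    return NucleusRegion(id=rid, pixels=flat, shape=shape, **kw)


def square_region(shape, top, left, size, rid=1, **kw):
    coords = [(r, c) for r in range(top, top + size)
              for c in range(left, left + size)]
    return region_from_coords(coords, shape, rid=rid, **kw)


def random_label_maps(rng, max_size=64, n_target=3, n_prox=4):
    """A pair of discordant label maps built from random rectangles.

    Returns (target_labels, prox1_labels); rectangles within one map never
    overlap (later rectangles are clipped against earlier ones), while the
    two maps overlap freely.
    """
    h = int(rng.integers(16, max_size + 1))
    w = int(rng.integers(16, max_size + 1))

    def one_map(n):
        labels = np.zeros((h, w), dtype=np.int32)
        next_id = 1
        for _ in range(n):
            rh = int(rng.integers(2, max(3, h // 3)))
            rw = int(rng.integers(2, max(3, w // 3)))
            r0 = int(rng.integers(0, h - rh + 1))
            c0 = int(rng.integers(0, w - rw + 1))
            block = labels[r0:r0 + rh, c0:c0 + rw]
            free = block == 0
            if not free.any():
                continue
            block[free] = next_id
            next_id += 1
        return labels

    return one_map(n_target), one_map(n_prox)
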