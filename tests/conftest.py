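"""Shared fixtures.

Images are generated once per session at two scales: a coarse profiling
scale (8 µm/px, full 2 mm pattern) where radial statistics are cheap, and a
cell scale (2 µm/px, 0.8 mm pattern) where nuclei are resolved for
segmentation, redox and YAP/TAZ scoring.
"""

import numpy as np
import pytest

import mitopattern as mp
from mitopattern import simulate as sim


NOISELESS = dict(noise_gain=float("inf"), read_noise_sd=0.0)


@pytest.fixture(scope="session")
def cell_scale_params() -> mp.GeneratorParams:
    return mp.GeneratorParams(island_radius_um=400.0, pixel_size_um=2.0, seed=7)


@pytest.fixture(scope="session")
def cell_scale(cell_scale_params):
    """Default-noise cell-resolved image with ground truth."""
    return mp.generate_micropattern(cell_scale_params)


@pytest.fixture(scope="session")
def cell_scale_segmented(cell_scale):
    """Segmented, region-annotated, classified cell table for the image."""
    img, truth = cell_scale
    geom = mp.detect_island(img)
    spec = mp.RegionSpec()
    cells = mp.segment_nuclei(img)
    cells = mp.annotate_regions(cells, geom, spec)
    cells = mp.classify_cell_types(cells, img)
    return img, truth, geom, spec, cells


@pytest.fixture(scope="session")
def profile_scale_noiseless():
    """Coarse noiseless image of the full pattern for radial-profile oracles."""
    p = mp.GeneratorParams(pixel_size_um=8.0, seed=2, **NOISELESS)
    return mp.generate_micropattern(p)


@pytest.fixture(scope="session")
def coculture_50k_image():
    p = sim.preset("coculture_50k", seed=3, pixel_size_um=8.0)
    return mp.generate_micropattern(p)
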