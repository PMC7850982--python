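"""Shared phantom fixtures (generated at test time; nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

import uvcollagen as uv
from uvcollagen.core import StructureLabel


@pytest.fixture(scope="session")
def small_phantom():
    """A small noisy phantom with all structure classes present."""
    spec = uv.PhantomSpec(
        image_size_px=(256, 256),
        pixel_size_um=0.5,
        n_fibers=8,
        n_nuclei=10,
        n_vacuoles=2,
        rng_seed=1,
    )
    return uv.generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: classification should be exact."""
    spec = uv.PhantomSpec(
        image_size_px=(256, 256),
        pixel_size_um=0.5,
        n_fibers=8,
        n_nuclei=10,
        n_vacuoles=2,
        noise_sd=0.0,
        rng_seed=1,
    )
    return uv.generate_phantom(spec)


@pytest.fixture(scope="session")
def slender_phantom():
    """>= 20 well-separated slender fibers for recovery checks.

    Fibers are long relative to their thickness so that the inevitable
    skeleton end-retraction (about one fiber half-width per end) stays
    well under the recovery tolerance.
    """
    spec = uv.PhantomSpec(
        image_size_px=(640, 640),
        pixel_size_um=1.0,
        n_fibers=22,
        crosslink_probability=0.0,
        fiber_length_um=uv.DistributionSpec(120.0, 30.0),
        fiber_thickness_um=uv.DistributionSpec(6.0, 1.5),
        n_nuclei=0,
        n_vacuoles=0,
        noise_sd=0.0,
        rng_seed=3,
    )
    return uv.generate_phantom(spec)


def match_strands(truth_table, measured_table):
    """Greedy nearest-centroid matching of truth fibers to measured strands."""
    from scipy.spatial import cKDTree

    tree = cKDTree(measured_table[["centroid_row", "centroid_col"]].values)
    _, idx = tree.query(truth_table[["centroid_row", "centroid_col"]].values)
    return measured_table.iloc[idx].reset_index(drop=True)


def collagen_mask_of(truth) -> np.ndarray:
    return truth.label_map.mask(StructureLabel.COLLAGEN)
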