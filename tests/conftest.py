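"""Shared fixtures: tiny rendered tiles and hand-constructed H&E-like images.

All fixtures are generated programmatically at test time; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw as skdraw

import gliograde as gg
from gliograde.synthetic import EOSIN_OD, HEMATOXYLIN_OD, _BACKGROUND_EOSIN


def paint_nuclei(size: int, centers, radii, darkness: float = 0.6,
                 background_eosin: float = _BACKGROUND_EOSIN,
                 axes=None, rotations=None) -> np.ndarray:
    """Noise-free H&E-like image with disks/ellipses at known positions.

    Uses the same Beer-Lambert composition as the cohort generator, but with
    no texture or pixel noise, so segmentation results are fully predictable.
    """
    h_map = np.zeros((size, size), dtype=np.float64)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(centers),))
    for i, (r, c) in enumerate(centers):
        if axes is not None:
            a, b = axes[i]
            rot = rotations[i] if rotations is not None else 0.0
            rr, cc = skdraw.ellipse(r, c, b, a, shape=h_map.shape, rotation=rot)
        else:
            rr, cc = skdraw.disk((r, c), radii[i], shape=h_map.shape)
        h_map[rr, cc] = darkness * 2.0
    e_map = np.full((size, size), background_eosin)
    od = h_map[..., None] * HEMATOXYLIN_OD + e_map[..., None] * EOSIN_OD
    return np.clip(255.0 * np.power(10.0, -od), 0, 255).astype(np.uint8)


def blank_tile(size: int = 128) -> np.ndarray:
    return paint_nuclei(size, [], [])


@pytest.fixture(scope="session")
def small_cohort():
    """Six cases per grade, in memory; enough to exercise every stage."""
    cfg = gg.CohortConfig(counts_by_grade={"II": 6, "III": 6, "IV": 6})
    return gg.generate_cohort(cfg, master_seed=42)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table = gg.build_feature_table(small_cohort)
    assert table.attrs["skipped"] == []
    return table


def planted_table(n_per_class=60, n_informative=5, n_noise=45, effect=2.0, seed=0):
    """Two-class table with known informative columns, for selection tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat(["II", "IV"], n_per_class)
    X = rng.standard_normal((n, n_informative + n_noise))
    X[n_per_class:, :n_informative] += effect
    cols = [f"inf_{i}" for i in range(n_informative)] + [f"noise_{i}" for i in range(n_noise)]
    df = pd.DataFrame(X, columns=cols)
    df["grade"] = y
    return df, cols[:n_informative]
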