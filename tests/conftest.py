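"""Shared fixtures: small phantom specs and deterministic test masks."""

from __future__ import annotations

import numpy as np
import pytest

from vasomet import phantom


@pytest.fixture
def flat_spec() -> phantom.PhantomSpec:
    """Single-layer 200x200 spec for purely geometric (2D) checks."""
    return phantom.PhantomSpec(frame_shape=(200, 200), n_layers=1, seed=1)


@pytest.fixture
def small_spec() -> phantom.PhantomSpec:
    """Small 5-layer acquisition with both tracer channels, noise off."""
    return phantom.PhantomSpec(frame_shape=(128, 128), n_layers=5, seed=7,
                               noise_model=(0.0, 0.0))


@pytest.fixture
def tube_mask(flat_spec) -> np.ndarray:
    """Horizontal straight tube of radius 8 px."""
    g = phantom.straight_tube_graph(flat_spec, radius_um=8.0)
    return phantom.rasterize(g, flat_spec)[0]


def random_blob_mask(seed: int, shape=(64, 64), threshold: float = 0.1):
    """Smooth random field thresholded into blobs (may contain holes)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    mask = field > np.quantile(field, 1 - max(threshold, 0.02))
    if not mask.any() or mask.all():
        mask[shape[0] // 2, shape[1] // 2] = True
        mask[0, 0] = False
    return mask
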