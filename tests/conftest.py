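"""Shared fixtures: phantom sequences are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

import hemidia as h


@pytest.fixture(scope="session")
def clean_phantom():
    """Default 30-frame breathing phantom, no obscured frames."""
    cfg = h.PhantomConfig()
    frames, gt = h.generate_sequence(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def clean_results(clean_phantom):
    _, frames, _ = clean_phantom
    return h.detect_sequence(frames)


@pytest.fixture(scope="session")
def case3_phantom():
    """Default phantom with the left notch obscured at frames 2-26."""
    cfg = h.PhantomConfig(obscured_frames=h.case3_obscured_frames())
    frames, gt = h.generate_sequence(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def case3_results(case3_phantom):
    _, frames, _ = case3_phantom
    return h.detect_sequence(frames)


@pytest.fixture(scope="session")
def case3_optimized(case3_results):
    return h.optimize_sequence(case3_results)


def two_disc_mask(shape=(200, 400), c_right=(100, 120), c_left=(100, 300),
                  radius=50) -> np.ndarray:
    """Two disjoint filled discs standing in for the two lung fields."""
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for (r0, c0) in (c_right, c_left):
        mask[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = 1
    return mask
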