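"""Shared phantoms for the test suite.

Simulations are the slow part, so the commonly reused movies are built once
per session.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from furrowquant.cortexprofile import subtract_camera_background, trace_contour
from furrowquant.synthmovie import SimulationParams, simulate_division


@pytest.fixture(scope="session")
def clean_params() -> SimulationParams:
    """Noise-free default phantom parameters."""
    return SimulationParams(seed=1, shot_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_division(clean_params):
    """Noise-free phantom movie with ground truth."""
    return simulate_division(clean_params)


@pytest.fixture(scope="session")
def clean_movie_bg(clean_params, clean_division):
    """Background-subtracted noise-free movie."""
    movie, _ = clean_division
    return subtract_camera_background(movie, clean_params.camera_offset)


@pytest.fixture(scope="session")
def clean_contours(clean_movie_bg):
    """Traced contours of every frame of the noise-free movie."""
    out = []
    for frame in clean_movie_bg.frames:
        try:
            out.append(trace_contour(frame))
        except ValueError:
            out.append(None)
    return out


@pytest.fixture(scope="session")
def noisy_division():
    """Default-noise phantom movie with ground truth."""
    return simulate_division(SimulationParams(seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
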