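"""Shared fixtures: small rendered dose pairs and smooth random fields."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from doseqa.errors import ErrorSpec, ErrorType, apply_error
from doseqa.plans import DoseImage, SimConfig, generate_plan, render_dose


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A compact VMAT-like configuration for fast rendering in tests."""
    return SimConfig.vmat_like(
        rng_seed=42,
        target_field_size_mm=(40.0, 38.0),
        grid_shape=(80, 80),
        n_segments_per_arc=6,
        n_arcs=1,
    )


@pytest.fixture(scope="session")
def rendered_pair(small_sim_config):
    """(reference, evaluated) doses for a collimator-rotation error."""
    plan = generate_plan(small_sim_config)
    ref = render_dose(plan, small_sim_config, arc_index=0)
    applied = apply_error(
        plan, ErrorSpec(ErrorType.COLLIMATOR, 2.0), np.random.default_rng(5)
    )
    ev = render_dose(applied.plan, small_sim_config, arc_index=0)
    return ref, ev


def smooth_field(rng: np.random.Generator, shape=(24, 24), low=5.0, high=100.0) -> DoseImage:
    """A strictly positive smooth random dose field."""
    raw = rng.uniform(low, high, shape)
    return DoseImage(ndimage.uniform_filter(raw, 3, mode="reflect"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
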