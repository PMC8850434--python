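"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nanomap.synthetic import (
    SimulationConfig,
    make_cell_mask,
    render_channel_pair,
    sample_truth_spots,
)


@pytest.fixture(scope="session")
def small_mask():
    return make_cell_mask((256, 256), coverage_fraction=0.8, irregularity=0.1, seed=11)


def make_channel_pair(
    coloc_fraction: float,
    amp_corr: float,
    seed: int,
    n_spots: int = 120,
    shape=(256, 256),
    noise: bool = True,
    mask=None,
):
    """Render a channel pair on a fresh or supplied mask; returns (A, B, truth, mask)."""
    config = SimulationConfig(
        image_shape_px=shape,
        n_spots=n_spots,
        coloc_fraction=coloc_fraction,
        amp_corr=amp_corr,
        shot_noise=noise,
        read_noise_sd=2.0 if noise else 0.0,
        seed=seed,
    )
    if mask is None:
        mask = make_cell_mask(shape, coverage_fraction=0.85, irregularity=0.1, seed=seed + 1000)
    spots = sample_truth_spots(
        mask, n_spots, config.min_sep_um, config.edge_margin_um, config.pixel_size_um,
        seed=seed + 2000,
    )
    chan_a, chan_b, truth = render_channel_pair(spots, config)
    return chan_a, chan_b, truth, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simulate_pair():
    """The channel-pair factory as a fixture, shared across test modules."""
    return make_channel_pair
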