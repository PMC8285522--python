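"""Shared fixtures: small, seeded synthetic inputs for every stage."""

import numpy as np
import pytest

from gatekit.movie import MovieConfig, simulate_afm_movie
from gatekit.synthetic import TelegraphConfig, simulate_telegraph
from gatekit.trace import TimeTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_trace(rng):
    """Pure Gaussian noise, sigma=1.0, 100 kHz."""
    return TimeTrace(rng.normal(0.0, 1.0, 100_000), 100_000.0)


@pytest.fixture
def telegraph_snr5():
    """Unfiltered two-level telegraph at SNR 5 (0.5 nm step, 0.1 nm noise)."""
    cfg = TelegraphConfig(tau_low=2e-3, tau_high=2e-3, level_low=0.0,
                          level_high=0.5, noise_sigma=0.1,
                          sample_rate=50_000.0, duration=0.4, seed=7)
    return simulate_telegraph(cfg)


@pytest.fixture
def static_movie():
    """Noiseless lattice movie, every molecule pinned open."""
    cfg = MovieConfig(n_frames=5, noise_sigma=0.0, tau_open=1e6,
                      tau_closed=1e-9, seed=3)
    movie, truth = simulate_afm_movie(cfg)
    return cfg, movie, truth


def interior_dimer(truth, shape, margin_px=25):
    """Ground-truth dimer center farthest from the frame border."""
    from gatekit.movie import dimer_centers
    dc = dimer_centers(truth)
    d0 = dc[dc.frame == 0].copy()
    d0["edge"] = np.minimum.reduce([
        d0.row_px, d0.col_px,
        shape[0] - 1 - d0.row_px, shape[1] - 1 - d0.col_px])
    return d0.sort_values("edge", ascending=False).iloc[0]
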