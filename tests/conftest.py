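import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from sptquant import SptSimConfig, render_movie, simulate_trajectories


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def bright_spot_movie():
    """One static bright emitter imaged for 100 frames (no blinking)."""
    mask = np.ones((64, 64), dtype=bool)
    cfg = SptSimConfig(n_frames=100, image_size=64, n_molecules=1, f_bound=1.0,
                       d_bound=0.0, d_mobile=0.5, photons_per_spot=5000.0,
                       background=2.0, k_off_frame=0.0, k_on_frame=0.0,
                       nucleus_mask=mask, seed=404)
    trajectories = simulate_trajectories(cfg)
    return cfg, trajectories, render_movie(trajectories, cfg)


def random_scene(seed: int, n_frames: int = 10, max_spots: int = 6,
                 box: float = 40.0) -> pd.DataFrame:
    """Small random localization table for tracker-oracle comparisons."""
    r = np.random.default_rng(seed)
    rows = []
    for f in range(n_frames):
        for _ in range(int(r.integers(0, max_spots + 1))):
            rows.append({"frame": f, "x_px": float(r.uniform(0, box)),
                         "y_px": float(r.uniform(0, box))})
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
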