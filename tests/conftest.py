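import numpy as np
import pandas as pd
import pytest

from nanospt.simulate import SptSimConfig, simulate_tracks


def make_locs(frames, xs, ys, intensity=1.0, sigma=0.0, mol=-1):
    """Convenience builder for small localization tables."""
    frames = np.asarray(frames)
    n = len(frames)
    return pd.DataFrame({
        "frame": frames.astype(np.int64),
        "x_um": np.broadcast_to(np.asarray(xs, dtype=float), (n,)).copy(),
        "y_um": np.broadcast_to(np.asarray(ys, dtype=float), (n,)).copy(),
        "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), (n,)).copy(),
        "sigma_um": np.broadcast_to(np.asarray(sigma, dtype=float), (n,)).copy(),
        "molecule_id": np.broadcast_to(np.asarray(mol), (n,)).astype(np.int64).copy(),
    })


@pytest.fixture(scope="session")
def small_spt_run():
    """A modest blinking acquisition shared across linking tests."""
    cfg = SptSimConfig(n_frames=400, n_molecules=100, fov_um=8.0,
                       p_activate=0.01, seed=11)
    locs, truth = simulate_tracks(cfg)
    return cfg, locs, truth
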