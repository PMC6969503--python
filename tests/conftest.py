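"""Shared fixtures: small simulated movies reused across test modules."""

import numpy as np
import pytest

from pclsrhythm.fitting import rhythm_maps
from pclsrhythm.tissue import SimulationConfig, build_tissue, simulate_movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wt_small():
    """One wild-type bleomycin slice movie at reduced field size."""
    cfg = SimulationConfig(preset="wt_bleomycin", seed=1, shape=(128, 128))
    tissue = build_tissue(cfg)
    stack, mask, truth = simulate_movie(tissue, cfg)
    return {"config": cfg, "tissue": tissue, "stack": stack,
            "mask": mask, "truth": truth}


@pytest.fixture(scope="session")
def wt_small_maps(wt_small):
    """Rhythm maps of the shared wild-type movie (bin 4)."""
    return rhythm_maps(
        wt_small["stack"], bin_factor=4, mask=wt_small["mask"],
        n_permutations=300, seed=0,
    )
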