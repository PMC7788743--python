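import numpy as np
import pytest

from rohscan.simulate import BreedConfig, Hotspot, SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_noisy_panel():
    """A 2-chromosome, 2-breed panel with planted segments, errors and
    missingness — shared read-only input for module-level tests."""
    cfg = SimConfig(
        breeds=[
            BreedConfig("BreedA", 12, 0.20, "mutton",
                        hotspots=(Hotspot(chrom=1, center_bp=25_000_000, p_member=0.9),)),
            BreedConfig("BreedB", 12, 0.05, "wool"),
        ],
        seed=20240,
        n_chroms=2,
        chrom_length_bp=60_000_000,
        error_rate=0.002,
        missing_rate=0.01,
    )
    panel, meta, truth = simulate_panel(cfg)
    return panel, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(11)
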