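import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from gad.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """The parameter-recovery study: 10 families x 3 genera x 4 species,
    length 250, no read noise, fixed seed."""
    config = SimulationConfig(seed=11, noise_rate=0.0)
    return config, simulate_study(config)


@pytest.fixture(scope="session")
def small_refdb_with_variants():
    """Reference set with two records per species, for calibration tests."""
    from gad.synthetic_data import simulate_reference_taxonomy

    config = SimulationConfig(
        seed=5, n_families=4, genera_per_family=3, species_per_genus=3,
        variants_per_species=2,
    )
    db, truth = simulate_reference_taxonomy(config)
    return config, db, truth
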