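import numpy as np
import pytest

from vocalmap import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def two_region_cohort():
    """Small deterministic cohort: one strongly coupled region, one null region."""
    config = syn.CohortConfig(
        n_exposed=6,
        n_control=4,
        regions=(
            syn.RegionSpec("COUP", (0.0, 1.2), 20.0, 1.6, 0.9, reactivation_prob=0.4),
            syn.RegionSpec("NULL", (0.0, 1.2), 20.0, 1.0, 0.0, reactivation_prob=0.4),
        ),
        master_seed=11,
    )
    return syn.generate_cohort(config)


@pytest.fixture(scope="session")
def striatal_section():
    r = np.random.default_rng(5)
    spec = syn.StriatalSectionSpec(base_density_per_mm2=40.0)
    return syn.generate_striatal_section(spec, r)
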