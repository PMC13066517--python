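import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aptaprofile import PlantedEffect, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mutated, well-separated cohort shared across tests."""
    cfg = SimulationConfig(
        n_ancestors=60,
        n_participants=8,
        depth_mean=5000,
        mutation_rate=0.05,
        well_separated=True,
        seed=101,
    )
    counts, meta, truth = generate_cohort(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Balanced cohort with a known elevated-BMI effect on 10 sequences."""
    planted = (
        PlantedEffect("bmi_group", "elevated", tuple(range(10)), 1.8),
    )
    cfg = SimulationConfig(
        n_ancestors=300,
        n_participants=20,
        depth_mean=30000,
        mutation_rate=0.0,
        planted=planted,
        balanced_groups=True,
        seed=202,
    )
    counts, meta, truth = generate_cohort(cfg)
    return cfg, counts, meta, truth
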