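"""Shared fixtures: genomes of several sizes and a tiny scenario config."""

import dataclasses

import numpy as np
import pytest

from bridgesim.engine import ScenarioConfig
from bridgesim.genome import MapConfig, sample_genome
from bridgesim.ocs import DEParams


@pytest.fixture(scope="session")
def small_genome():
    """Reduced-scale genome: 133 QTLs + 267 markers on 10 x 100 cM."""
    return sample_genome(MapConfig(10, 100.0, 0.1, 133, 267), rng_seed=7)


@pytest.fixture(scope="session")
def micro_genome():
    """A few loci on 2 chromosomes, for exact enumeration oracles."""
    return sample_genome(MapConfig(2, 50.0, 0.5, 8, 4), rng_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def tiny_config(**overrides) -> ScenarioConfig:
    """A seconds-scale scenario configuration for engine plumbing tests."""
    base = ScenarioConfig(
        years=3, burnin_years=8, n_replicates=1,
        map_config=MapConfig(4, 80.0, 0.2, 40, 60),
        panel_groups=(12, 10, 20), panel_he_targets=(0.36, 0.30),
        n_commercial_founders=6, n_external_founders=12,
        com_n_families=6, com_family_size=10, com_init_families=4,
        com_selected_fraction=0.2,
        ext_n_families=6, ext_family_size=10, ext_selected_fraction=0.2,
        mating_pool_size=12,
        n_bridging_families=2, n_breeding_families=4,
        donor_window_20y=(3, 5), donor_window_5y=(1, 2),
        de_params=DEParams(pop_size=20, max_gen=60, stagnation=20),
    )
    return dataclasses.replace(base, **overrides)
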