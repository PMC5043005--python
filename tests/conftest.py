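import pytest

from cultx import (
    DiseaseSpec,
    SimulationConfig,
    build_ortholog_map,
    simulate_disease_conditions,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=300,
        motif_sizes={
            "metabolism_down_unrescued": 50,
            "inflammation_persistent": 50,
        },
        n_replicates=3,
        timepoints=(0, 1, 2, 3),
        conditions=("M_C", "S"),
        disease_conditions=(DiseaseSpec("dz", 0.6),),
        noise_sd=0.3,
        effect_size_log2=2.5,
        ortholog_discordant_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds = simulate_timecourse(small_config)
    ds = simulate_disease_conditions(ds, small_config)
    return build_ortholog_map(ds, small_config)
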