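import pytest

from neomer_mrd.catalog import build_catalog
from neomer_mrd.config import SimulationConfig
from neomer_mrd.simulate import generate_cohort


def tiny_config(**overrides) -> SimulationConfig:
    """A cohort small enough for exhaustive oracles but with every moving
    part present (three time points, overlap with the population list)."""
    defaults = dict(
        genome_length=8000,
        n_recurrent_snvs=20,
        n_population_variants=10,
        k=8,
        n_patients=12,
        samples_per_timepoint=(10, 8, 6),
        read_length=60,
        reads_per_sample=200,
        tumor_fraction_positive=0.2,
        overlap_fraction=0.2,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tiny_cohort")
    return generate_cohort(tiny_config(), outdir)


@pytest.fixture(scope="session")
def tiny_catalog(tiny_cohort):
    return build_catalog(
        tiny_cohort.recurrent_snvs,
        tiny_cohort.population_variants,
        tiny_cohort.reference,
        k=8,
    )
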