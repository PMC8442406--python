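import pytest

from phagelink.hmm_hits import HmmHit, build_occurrence_index
from phagelink.pipeline import prepare_datasets
from phagelink.sequence_io import NtInterval
from phagelink.synthetic_data import SyntheticScenario, generate_training_scenario


def make_hit(
    pvog: str,
    genome: str,
    start: int,
    end: int,
    strand: str = "+",
    bitscore: float = 100.0,
    evalue: float = 1e-10,
    frame: int = 1,
) -> HmmHit:
    """Terse constructor for hit records in tests."""
    return HmmHit(
        pvog_id=pvog,
        genome_id=genome,
        interval=NtInterval(start, end, strand),
        bitscore=bitscore,
        evalue=evalue,
        frame=frame,
    )


SMALL_PARAMS = SyntheticScenario(
    n_genomes=12,
    genome_length=40_000,
    n_interacting_pairs=20,
    n_background_pvogs=30,
)


@pytest.fixture(scope="session")
def small_training_scenario():
    """A scaled planted-signal scenario shared across the suite."""
    return generate_training_scenario(SMALL_PARAMS, seed=7)


@pytest.fixture(scope="session")
def small_prepared(small_training_scenario):
    return prepare_datasets(small_training_scenario, seed=7)


@pytest.fixture(scope="session")
def small_index(small_training_scenario):
    return build_occurrence_index(
        small_training_scenario.scenario.hits,
        {
            g.genome_id: g.length
            for g in small_training_scenario.scenario.genomes
        },
    )
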