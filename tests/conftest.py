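import pytest

from panhog.align import ScoringScheme, matrix_from_dict
from panhog.pipeline import analyze_pangenome
from panhog.synthetic_data import SimulationConfig, simulate_pangenome


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


TOY_ALPHABET = "ACDE"


def toy_matrix_dict(match=3.0, mismatch=-1.0):
    return {(x, y): (match if x == y else mismatch)
            for x in TOY_ALPHABET for y in TOY_ALPHABET}


@pytest.fixture(scope="session")
def toy_scheme():
    scores = {(x, y): v for (x, y), v in toy_matrix_dict().items()}
    return ScoringScheme(matrix=matrix_from_dict(scores, TOY_ALPHABET),
                         gap_open=2.0, gap_extend=1.0)


SMALL_CONFIG = dict(
    n_base_genomes=3, n_added_genomes=1, n_core_families=6,
    n_accessory_families=4, n_unique_true=2, n_unique_decoy=1,
    n_singletons_per_genome=3, n_outgroup_random=20,
    length_range=(60, 120), seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_pangenome(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_result(small_sim):
    return analyze_pangenome(
        small_sim.base, small_sim.added, small_sim.outgroup,
        small_sim.associations,
        reference_genome_id=small_sim.reference_genome_id, seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """The standard desk-scale study conditions (5 base + 2 added genomes)."""
    return simulate_pangenome(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_result(default_sim):
    return analyze_pangenome(
        default_sim.base, default_sim.added, default_sim.outgroup,
        default_sim.associations,
        reference_genome_id=default_sim.reference_genome_id, seed=42)
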