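import numpy as np
import pytest

from shmprof.mutations import MutationRecord
from shmprof.simulate import SimulationConfig, simulate_repertoire

BASES = "ACGT"


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_substitution(position, from_base, to_base, clone_id="c", effect="replacement",
                      region=""):
    from shmprof._util import is_transition

    return MutationRecord(
        clone_id=clone_id, position=position, from_base=from_base, to_base=to_base,
        event_class="substitution",
        titv="transition" if is_transition(from_base, to_base) else "transversion",
        effect=effect, region=region)


def make_frameshift(position, clone_id="c"):
    return MutationRecord(
        clone_id=clone_id, position=position, from_base="A", to_base="",
        event_class="deletion", titv="n/a", effect="frameshift")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180522)


@pytest.fixture(scope="session")
def basic_sim():
    """Homozygous, indel-free, fixed-junction repertoire: 30 clones sharing
    one pre-mutation sequence."""
    config = SimulationConfig(seed=7, n_clones=30, junction_indel_range=0,
                              indel_rate=0.0, mutation_rate=5e-3,
                              j_library_size=1)
    return simulate_repertoire(config)


@pytest.fixture(scope="session")
def het_sim():
    """Heterozygous repertoire with two constant-region allotypes at ~50/50."""
    config = SimulationConfig(seed=11, n_clones=40, junction_indel_range=0,
                              indel_rate=0.0, mutation_rate=2e-3,
                              j_library_size=1, heterozygous=True,
                              diagnostic_positions=(30, 120, 210))
    return simulate_repertoire(config)
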