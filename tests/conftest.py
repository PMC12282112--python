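import numpy as np
import pytest

from vivipart.core_io import SequenceRecord, reverse_complement
from vivipart.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim1():
    """Default simulation at seed 1: (records, truth)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim1_plus(sim1):
    """Seed-1 contigs restored to the planted plus strand, keyed by id."""
    records, truth = sim1
    return {
        r.id: (
            reverse_complement(r.residues)
            if truth.orientation[r.id] == "-"
            else r.residues
        )
        for r in records
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(seq: str, rid: str = "x", moltype: str = "nucleotide") -> SequenceRecord:
    return SequenceRecord(id=rid, residues=seq, moltype=moltype)
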