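import numpy as np
import pytest

from barcode_librarian.distances import DistanceMatrix
from barcode_librarian.library_io import ReferenceLibrary, SpecimenRecord
from barcode_librarian.synthetic import SimulationConfig, simulate_library


def make_record(voucher, species, genus, subfamily, sequence, source=None):
    return SpecimenRecord(
        voucher_id=voucher,
        nominal_species=species,
        genus=genus,
        subfamily=subfamily,
        sequence=sequence,
        source=source,
    )


def make_matrix(vouchers, dvals):
    """DistanceMatrix from an explicit symmetric array of distances."""
    d = np.asarray(dvals, dtype=float)
    n = len(vouchers)
    assert d.shape == (n, n)
    zeros = np.zeros_like(d)
    return DistanceMatrix(list(vouchers), d, zeros, zeros, np.full((n, n), 100))


@pytest.fixture
def tiny_library():
    """Two genera, three species, five specimens; 12-column alignment."""
    records = [
        make_record("Q1", "Alpha one", "Alpha", "Eristalinae", "AAAACCCCGGGG"),
        make_record("Q2", "Alpha one", "Alpha", "Eristalinae", "AAAACCCCGGGG"),
        make_record("Q3", "Alpha two", "Alpha", "Eristalinae", "AAAACCCCGGGA"),
        make_record("Q4", "Beta one", "Beta", "Syrphinae", "AAAACCTTGGGG"),
        make_record("Q5", "Beta one", "Beta", "Syrphinae", "AAAACCTTGGGT"),
    ]
    return ReferenceLibrary(records)


@pytest.fixture(scope="session")
def small_sim():
    """Well-separated simulated library: 6 genera x 3 species, with outgroup."""
    cfg = SimulationConfig(
        n_genera=6,
        species_per_genus=3,
        mean_extra_individuals=2.0,
        scenarios=frozenset(),
        seed=11,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def twin_sim():
    """Simulated library containing a near-zero-divergence species pair."""
    cfg = SimulationConfig(
        n_genera=4,
        species_per_genus=3,
        mean_extra_individuals=2.0,
        scenarios=frozenset({"twin_pair"}),
        seed=7,
    )
    return simulate_library(cfg)
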