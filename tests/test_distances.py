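import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcode_librarian.distances import (
    distance_matrix,
    k2p,
    k2p_from_counts,
    low_divergence_pairs,
    pair_summary,
    partition,
    species_summaries,
    specimens_vs_haplotypes_correlation,
)
from barcode_librarian.library_io import ReferenceLibrary, collapse_haplotypes

from conftest import make_record

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def count_sites(a, b):
    """Independent site-by-site oracle: (transitions, transversions, n)."""
    ts = tv = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    return ts, tv, n


def k2p_oracle(a, b):
    ts, tv, n = count_sites(a, b)
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p("ACGT" * 10, "ACGT" * 10)
        assert r.P == r.Q == 0.0
        assert r.d == 0.0 and r.defined

    def test_closed_form_ten_transitions_five_transversions(self):
        # 100 sites, 10 A->G transitions, 5 A->C transversions; expected
        # value frozen from direct evaluation of the closed form at
        # P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p(a, b)
        assert (r.P, r.Q, r.n_sites) == (0.10, 0.05, 100)
        assert r.d == pytest.approx(0.17018116514034703, abs=1e-12)
        assert r.d == pytest.approx(k2p_oracle(a, b), abs=1e-12)

    def test_saturation_is_masked_not_clamped(self):
        # P = Q = 0.5: both log arguments non-positive
        r = k2p_from_counts(50, 50, 100)
        assert not r.defined and math.isnan(r.d)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p("ACGT", "ACGTA")

    def test_ambiguity_codes_excluded_pairwise(self):
        r = k2p("ACGTN-", "ACGAYA")
        assert r.n_sites == 4  # N, -, and Y columns dropped
        assert r.P == 0.0 and r.Q == pytest.approx(0.25)  # T/A is a transversion

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, ts, tv):
        rng = np.random.default_rng(ts * 37 + tv)
        base = rng.integers(0, 4, 200)
        lookup = np.array(list("AGCT"))
        a = "".join(lookup[base])
        mutated = base.copy()
        pos = rng.permutation(200)
        mutated[pos[:ts]] ^= 1
        mutated[pos[ts:ts + tv]] ^= 2
        b = "".join(lookup[mutated])
        ra, rb = k2p(a, b), k2p(b, a)
        assert (ra.P, ra.Q, ra.d) == (rb.P, rb.Q, rb.d)

    def test_transition_strictly_increases_distance(self):
        for ts in range(0, 20):
            d0 = k2p_from_counts(ts, 5, 200).d
            d1 = k2p_from_counts(ts + 1, 5, 200).d
            assert d1 > d0

    def test_small_divergence_approximates_p_distance(self):
        # for P + Q <= 0.01 the correction is below 1%
        for ts, tv in [(1, 0), (0, 1), (5, 5), (10, 0)]:
            r = k2p_from_counts(ts, tv, 2000)
            p_dist = (ts + tv) / 2000
            assert r.d == pytest.approx(p_dist, rel=0.01)


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        recs = [
            make_record(f"V{i}", "Alpha one", "Alpha", "Eristalinae", "ACGT" * 5)
            for i in range(3)
        ]
        m = distance_matrix(ReferenceLibrary(recs))
        assert np.all(m.d == 0.0)

    def test_matches_per_pair_oracle_on_random_fixture(self):
        rng = np.random.default_rng(42)
        lookup = np.array(list("ACGTN"))
        seqs = ["".join(lookup[rng.integers(0, 5, 120)]) for _ in range(10)]
        recs = [
            make_record(f"V{i}", "Alpha one", "Alpha", "Eristalinae", s)
            for i, s in enumerate(seqs)
        ]
        m = distance_matrix(ReferenceLibrary(recs))
        for i in range(10):
            for j in range(i + 1, 10):
                expect = k2p(seqs[i], seqs[j])
                got = m.d[i, j]
                if expect.defined:
                    assert got == pytest.approx(expect.d, abs=1e-12)
                else:
                    assert math.isnan(got)

    def test_symmetric_with_zero_diagonal(self, small_sim):
        lib, _ = small_sim
        m = distance_matrix(lib)
        assert np.allclose(m.d, m.d.T, equal_nan=True)
        assert np.all(np.diag(m.d) == 0.0)

    def test_too_small_library_rejected(self):
        rec = make_record("V1", "Alpha one", "Alpha", "Eristalinae", "ACGT")
        with pytest.raises(ValueError):
            distance_matrix(ReferenceLibrary([rec]))


def two_species_one_genus_library():
    seqs = ["AAAAAAAAAA", "AAAAAAAAAG", "AATTAAAAAA", "AATTAAAAAC"]
    species = ["Alpha one", "Alpha one", "Alpha two", "Alpha two"]
    return ReferenceLibrary(
        [
            make_record(f"V{i}", sp, "Alpha", "Eristalinae", s)
            for i, (sp, s) in enumerate(zip(species, seqs))
        ]
    )


class TestPartition:
    def test_two_by_two_pair_counts(self):
        # 4 specimens -> 6 pairs: 2 intraspecific, 4 congeneric (by hand)
        lib = two_species_one_genus_library()
        m = distance_matrix(lib)
        [part] = partition(m, lib, "dataset")
        assert part.intraspecific.size == 2
        assert part.congeneric_interspecific.size == 4
        assert part.n_cross_genus_pairs == 0

    def test_single_species_has_empty_congeneric_pool(self):
        recs = [
            make_record(f"V{i}", "Alpha one", "Alpha", "Eristalinae", "ACGT" * 3)
            for i in range(3)
        ]
        lib = ReferenceLibrary(recs)
        [part] = partition(distance_matrix(lib), lib, "dataset")
        assert part.congeneric_interspecific.size == 0
        assert part.intraspecific.size == 3

    def test_conservation_within_subfamilies(self, small_sim):
        lib, _ = small_sim
        m = distance_matrix(lib)
        for part in partition(m, lib, "subfamily"):
            n = sum(
                1 for r in lib.ingroup() if r.subfamily == part.label
            )
            total = (
                part.intraspecific.size
                + part.congeneric_interspecific.size
                + part.n_cross_genus_pairs
            )
            assert total == n * (n - 1) // 2

    def test_outgroup_excluded(self, small_sim):
        lib, _ = small_sim
        m = distance_matrix(lib)
        n_in = len(lib.ingroup())
        [part] = partition(m, lib, "dataset")
        total = (
            part.intraspecific.size
            + part.congeneric_interspecific.size
            + part.n_cross_genus_pairs
        )
        assert total == n_in * (n_in - 1) // 2

    def test_unknown_group_label_rejected(self, tiny_library):
        m = distance_matrix(tiny_library)
        with pytest.raises(ValueError):
            partition(m, tiny_library, "tribe")


class TestSummaries:
    def test_two_specimen_species_mean_equals_max(self):
        recs = [
            make_record("V0", "Alpha one", "Alpha", "Eristalinae", "A" * 100),
            make_record("V1", "Alpha one", "Alpha", "Eristalinae", "G" * 4 + "A" * 96),
            make_record("V2", "Alpha two", "Alpha", "Eristalinae", "C" * 50 + "A" * 50),
        ]
        lib = ReferenceLibrary(recs)
        m = distance_matrix(lib)
        summaries = {s.species: s for s in species_summaries(m, lib)}
        s = summaries["Alpha one"]
        assert s.mean_intra == s.max_intra > 0.03
        assert summaries["Alpha two"].n_specimens == 1
        assert math.isnan(summaries["Alpha two"].mean_intra)

    def test_nearest_neighbour_matches_brute_force(self, small_sim):
        lib, _ = small_sim
        sub = lib.subset(lib.voucher_ids[:15])
        m = distance_matrix(sub)
        species_of = {r.voucher_id: r.nominal_species for r in sub}
        for s in species_summaries(m, sub):
            best = (None, float("inf"))
            for va in sub.voucher_ids:
                if species_of[va] != s.species:
                    continue
                for vb in sub.voucher_ids:
                    if species_of[vb] == s.species:
                        continue
                    d = m.get(va, vb)
                    if d < best[1]:
                        best = (species_of[vb], d)
            assert s.nn_species == best[0]
            assert s.nn_distance == pytest.approx(best[1], abs=1e-12)

    def test_pair_summary_matches_enumeration(self):
        lib = two_species_one_genus_library()
        m = distance_matrix(lib)
        ps = pair_summary(m, lib, "Alpha one", "Alpha two")
        cross = [m.get(a, b) for a in ["V0", "V1"] for b in ["V2", "V3"]]
        assert ps.n_pairs == 4
        assert ps.mean == pytest.approx(np.mean(cross))
        assert ps.min == pytest.approx(np.min(cross))
        assert ps.max == pytest.approx(np.max(cross))
        assert ps.min <= ps.mean <= ps.max

    def test_pair_summary_missing_species_rejected(self, tiny_library):
        m = distance_matrix(tiny_library)
        with pytest.raises(KeyError):
            pair_summary(m, tiny_library, "Alpha one", "Gamma one")

    def test_low_divergence_pairs_flags_twins(self, twin_sim):
        lib, truth = twin_sim
        m = distance_matrix(lib)
        pairs = low_divergence_pairs(m, lib, cutoff=0.03)
        flagged = {frozenset((p.species_a, p.species_b)) for p in pairs}
        assert frozenset(truth.scenario_labels["twin_pair"]) in flagged


class TestSpearman:
    def test_perfectly_monotone_counts(self):
        recs = []
        for i, n in enumerate([2, 3, 4, 5]):
            for k in range(n):
                # one substitution per specimen index -> distinct haplotypes
                seq = list("A" * 20)
                seq[k] = "G"
                recs.append(
                    make_record(
                        f"V{i}_{k}", f"Sp{i} a", f"Sp{i}", "Eristalinae", "".join(seq)
                    )
                )
        table = collapse_haplotypes(ReferenceLibrary(recs))
        rs, t, n = specimens_vs_haplotypes_correlation(table)
        assert rs == pytest.approx(1.0)
        assert n == 4

    def test_tied_example_matches_hand_ranking(self):
        # oracle: average-rank both vectors explicitly, then Pearson on ranks
        from scipy import stats as sps

        x = [2, 2, 3, 5, 8]
        y = [1, 2, 2, 4, 7]

        def avg_ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                r = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = r
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])

        table = type("T", (), {})()  # minimal stand-in with per_species
        per_species = {f"s{i}": (x[i], y[i]) for i in range(5)}
        from barcode_librarian.library_io import HaplotypeTable

        table = HaplotypeTable(haplotypes=[], scope="per-species", per_species=per_species)
        rs, t, n = specimens_vs_haplotypes_correlation(table, exclude_singletons=False)
        assert rs == pytest.approx(expected, abs=1e-12)
        assert t == pytest.approx(rs * math.sqrt((n - 2) / (1 - rs**2)), abs=1e-12)

    def test_constant_vector_rejected(self):
        from barcode_librarian.library_io import HaplotypeTable

        table = HaplotypeTable(
            haplotypes=[], scope="per-species",
            per_species={"a": (2, 1), "b": (2, 1), "c": (2, 1)},
        )
        with pytest.raises(ValueError):
            specimens_vs_haplotypes_correlation(table, exclude_singletons=False)
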