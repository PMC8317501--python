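"""Minimum Entropy Decomposition: entropy formula, splitting, noise filter."""

import numpy as np
import pandas as pd
import pytest

from oligogeo.oligotyping import (
    AlignedReadSet,
    build_count_matrix,
    column_entropy,
    med_decompose,
)


def readset(seq_counts, site="A"):
    """Build a read set from {sequence: count} (single site by default)."""
    seqs, sites = [], []
    for seq, spec in seq_counts.items():
        if isinstance(spec, int):
            spec = {site: spec}
        for s, c in spec.items():
            seqs.extend([seq] * c)
            sites.extend([s] * c)
    return AlignedReadSet(seqs, sites)


class TestColumnEntropy:
    def test_uniform_column_zero_bits(self):
        prof = column_entropy(readset({"AAAA": 5}))
        assert np.allclose(prof.entropy, 0.0)

    def test_even_split_is_one_bit(self):
        prof = column_entropy(readset({"A": 5, "C": 5}))
        assert prof.entropy[0] == pytest.approx(1.0)

    def test_three_one_split(self):
        prof = column_entropy(readset({"A": 3, "C": 1}))
        expect = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert prof.entropy[0] == pytest.approx(expect, abs=1e-10)
        assert prof.entropy[0] == pytest.approx(0.8113, abs=5e-5)

    def test_gap_is_a_fifth_state(self):
        prof = column_entropy(readset({"A-": 5, "AA": 5}))
        assert prof.entropy[1] == pytest.approx(1.0)

    def test_all_n_column_zero_with_warning(self):
        with pytest.warns(UserWarning, match="entirely of N"):
            prof = column_entropy(readset({"NA": 4}))
        assert prof.entropy[0] == 0.0

    def test_n_excluded_from_denominator(self):
        # A:2 C:2 with two N -> still a 50/50 column
        prof = column_entropy(readset({"A": 2, "C": 2, "N": 2}))
        assert prof.entropy[0] == pytest.approx(1.0)


class TestMedDecompose:
    def test_forced_two_way_partition(self):
        reads = readset({"AAAA": 60, "AATA": 40})
        cat = med_decompose(reads, min_substantive_abundance=1)
        assert len(cat) == 2
        assert sorted(o.total for o in cat.oligotypes) == [40, 60]
        assert {o.sequence for o in cat.oligotypes} == {"AAAA", "AATA"}

    def test_identical_reads_one_oligotype(self):
        cat = med_decompose(readset({"ACGT": 30}))
        assert len(cat) == 1
        assert cat.oligotypes[0].positions == ()

    def test_noise_reassigned_to_min_hamming_sibling(self):
        # h3 (3 reads) is below threshold and at Hamming 1 from h2, 2 from h1
        reads = readset({"AAAA": 15, "AATA": 12, "AATT": 3})
        cat = med_decompose(reads, min_substantive_abundance=5)
        assert len(cat) == 2
        by_seq = {o.sequence: o.total for o in cat.oligotypes}
        assert by_seq == {"AAAA": 15, "AATA": 15}

    def test_noise_reassignment_matches_exhaustive_oracle(self):
        """The reassignment minimises per-read Hamming cost to survivors."""
        from itertools import product

        from oracles import hamming_bf

        reads = readset({"AAAA": 10, "CCAA": 9, "CCCT": 2, "AACA": 1})
        cat = med_decompose(reads, min_substantive_abundance=4)
        survivors = sorted(o.sequence for o in cat.oligotypes)
        assert survivors == ["AAAA", "CCAA"]
        # brute force: each noise read joins its closest survivor
        expect = {"AAAA": 10, "CCAA": 9}
        for noise_seq, n in (("CCCT", 2), ("AACA", 1)):
            dists = {s: hamming_bf(noise_seq, s) for s in survivors}
            best = min(sorted(dists), key=lambda s: dists[s])
            expect[best] += n
        got = {o.sequence: o.total for o in cat.oligotypes}
        assert got == expect

    def test_discard_policy_accounts_filtered_reads(self):
        reads = readset({"AAAA": 15, "AATA": 12, "AATT": 3})
        cat = med_decompose(reads, min_substantive_abundance=5, noise_policy="discard")
        assert cat.total_counts == 27
        assert cat.n_filtered_reads == 3
        assert cat.total_counts + cat.n_filtered_reads == reads.n_reads

    def test_noise_free_identifiability(self, rng):
        """With no error and M_min=1 the oligotypes are exactly the distinct
        input sequences with exact counts (deduplication oracle)."""
        for _ in range(10):
            k = int(rng.integers(2, 7))
            seqs = set()
            while len(seqs) < k:
                seqs.add("".join(rng.choice(list("ACGT"), size=15)))
            seqs = sorted(seqs)
            counts = rng.integers(1, 20, size=k)
            reads = readset(dict(zip(seqs, map(int, counts))))
            cat = med_decompose(reads, min_substantive_abundance=1)
            got = {o.sequence: o.total for o in cat.oligotypes}
            assert got == dict(zip(seqs, map(int, counts)))

    def test_monotone_in_m(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(5)]
        counts = {s: int(c) for s, c in zip(seqs, rng.integers(5, 30, size=5))}
        reads = readset(counts)
        sizes = [
            len(med_decompose(reads, m=m, min_substantive_abundance=1))
            for m in (0.0, 0.1, 0.5, 1.0, 2.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_n_follows_majority_child(self):
        reads = readset({"AAAA": 10, "CAAA": 4, "NAAA": 2})
        cat = med_decompose(reads, min_substantive_abundance=1)
        by_seq = {o.sequence: o.total for o in cat.oligotypes}
        assert by_seq == {"AAAA": 12, "CAAA": 4}

    def test_node_explosion_guard(self, rng):
        seqs = ["".join(p) for p in __import__("itertools").product("AC", repeat=4)]
        reads = readset({s: 1 for s in seqs})
        with pytest.raises(RuntimeError, match="increase m"):
            med_decompose(reads, m=0.0, min_substantive_abundance=1, max_oligotypes=4)

    def test_count_conservation_under_reassignment(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(8)]
        counts = {s: int(c) for s, c in zip(seqs, rng.integers(1, 25, size=8))}
        reads = readset(counts)
        cat = med_decompose(reads, min_substantive_abundance=0.1)
        assert cat.total_counts == reads.n_reads


class TestCountMatrix:
    def test_single_oligotype_two_sites(self):
        reads = readset({"AAAA": {"X": 5, "Y": 7}})
        cat = med_decompose(reads, min_substantive_abundance=1)
        mat = build_count_matrix(cat, ["X", "Y"])
        assert mat.shape == (1, 2)
        assert list(mat.iloc[0]) == [5, 7]

    def test_column_permutation_preserves_values(self):
        reads = readset({"AAAA": {"X": 5, "Y": 7}, "AATA": {"X": 2, "Y": 1}})
        cat = med_decompose(reads, min_substantive_abundance=1)
        m1 = build_count_matrix(cat, ["X", "Y"])
        m2 = build_count_matrix(cat, ["Y", "X"])
        assert (m1[["X", "Y"]].to_numpy() == m2[["X", "Y"]].to_numpy()).all()

    def test_unknown_site_rejected(self):
        cat = med_decompose(readset({"AAAA": 5}), min_substantive_abundance=1)
        with pytest.raises(ValueError, match="unknown site"):
            build_count_matrix(cat, ["A", "Z"])

    def test_single_site_reads_leave_other_column_zero(self):
        reads = readset({"AAAA": {"X": 60}, "AATA": {"X": 40, "Y": 3}})
        cat = med_decompose(reads, min_substantive_abundance=1)
        mat = build_count_matrix(cat, ["X", "Y"])
        row = mat.loc[[o.id for o in cat.oligotypes if o.sequence == "AAAA"][0]]
        assert row["Y"] == 0 and row["X"] == 60


class TestAlignedReadSet:
    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="homologous"):
            AlignedReadSet(["AAA", "AAAA"], ["X", "X"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            AlignedReadSet([], [])
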