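import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoforge import kmerqc, synthio
from chromoforge.assembly import Assembly, reverse_complement


class TestCounting:
    def test_window_enumeration_with_canonicalization(self):
        # windows ACG and CGT; canonical(CGT) = ACG
        assert kmerqc.count_kmers("ACGT", 3).as_dict() == {"ACG": 2}

    def test_windows_overlapping_n_are_skipped(self):
        assert kmerqc.count_kmers("AANAA", 2).as_dict() == {"AA": 2}

    def test_sequence_of_length_k_gives_single_key(self):
        tab = kmerqc.count_kmers("ACGTACG", 7)
        assert len(tab) == 1 and tab.total_occurrences == 1

    def test_oversized_k_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            tab = kmerqc.count_kmers("ACGT", 10)
        assert len(tab) == 0

    @pytest.mark.filterwarnings("ignore:no windows")
    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=120), st.integers(1, 9))
    def test_strand_symmetry(self, seq, k):
        fwd = kmerqc.count_kmers(seq, k).as_dict()
        rev = kmerqc.count_kmers(reverse_complement(seq), k).as_dict()
        assert fwd == rev

    def test_batching_matches_per_sequence_counting(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(300)]
        merged = kmerqc.count_kmers(seqs, 5).as_dict()
        manual = {}
        for s in seqs:
            for kmer, n in kmerqc.count_kmers(s, 5).as_dict().items():
                manual[kmer] = manual.get(kmer, 0) + n
        assert merged == manual


class TestSpectra:
    def test_self_comparison_has_empty_missing_column(self):
        asm = ["ACGTACGTTTGCAGGT" * 10]
        tab = kmerqc.count_kmers(asm, 7)
        sp = kmerqc.spectra_cn(tab, tab)
        assert sp.matrix[:, 0].sum() == 0
        assert kmerqc.missing_content(sp, 1) == 0.0

    def test_read_kmer_absent_from_assembly_lands_in_column_zero(self):
        reads = kmerqc.count_kmers(["AAAAAA"] * 15, 6)  # multiplicity 15
        asm = kmerqc.count_kmers("CCCCCC", 6)
        sp = kmerqc.spectra_cn(reads, asm, m_max=200)
        assert sp.matrix[15][0] == 1
        assert kmerqc.missing_content(sp, 1) == 1.0

    def test_conservation_total_equals_distinct_read_kmers(self):
        rng = np.random.default_rng(2)
        reads = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(100)]
        asm = ["".join(rng.choice(list("ACGT"), size=500))]
        rt, at = kmerqc.count_kmers(reads, 11), kmerqc.count_kmers(asm, 11)
        sp = kmerqc.spectra_cn(rt, at)
        assert sp.distinct_read_kmers() == len(rt)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            kmerqc.spectra_cn(kmerqc.count_kmers("ACGTACGT", 3),
                              kmerqc.count_kmers("ACGTACGT", 5))


class TestErrorCutoff:
    @pytest.mark.parametrize(
        "hist, expected",
        [
            ([1000, 400, 50, 80, 300, 500, 300], 3),  # valley between peaks
            ([1000, 500, 250, 100, 50], 1),  # strictly decreasing
            ([100, 100, 100, 100], 1),  # flat
        ],
    )
    def test_examples(self, hist, expected):
        assert kmerqc.error_cutoff(hist) == expected

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            kmerqc.error_cutoff([])


class TestMissingContent:
    def test_error_free_reads_from_assembly_have_zero_missing(self, truth):
        r1, r2 = synthio.generate_reads(truth, 8, 100, 0.0, seed=21)
        rt = kmerqc.count_kmers((s for _, s in r1 + r2), 27)
        at = kmerqc.count_kmers((s for _, s in truth.chromosomes), 27)
        assert kmerqc.missing_content(kmerqc.spectra_cn(rt, at), 1) == 0.0

    def test_deletion_recovered_as_missing_fraction(self, truth):
        # delete ~5% of the genome from the assembly copy; error-free reads
        # from the full genome should report that share as missing
        genome = truth.chromosomes.total_size
        cut = int(0.05 * genome)
        records = []
        for i, (name, seq) in enumerate(truth.chromosomes):
            records.append((name, seq[cut:] if i == 0 else seq))
        damaged = Assembly(records)
        r1, r2 = synthio.generate_reads(truth, 15, 100, 0.0, seed=22)
        rt = kmerqc.count_kmers((s for _, s in r1 + r2), 27)
        at = kmerqc.count_kmers((s for _, s in damaged), 27)
        missing = kmerqc.missing_content(kmerqc.spectra_cn(rt, at), 1)
        assert abs(missing - cut / genome) <= 0.01

    def test_monotone_in_deleted_fraction(self, truth):
        r1, r2 = synthio.generate_reads(truth, 10, 100, 0.0, seed=23)
        rt = kmerqc.count_kmers((s for _, s in r1 + r2), 27)
        missing = []
        for frac in (0.10, 0.05, 0.0):
            cut = int(frac * truth.chromosomes.total_size)
            records = [
                (n, s[cut:] if i == 0 else s)
                for i, (n, s) in enumerate(truth.chromosomes)
            ]
            at = kmerqc.count_kmers((s for _, s in Assembly(records)), 27)
            missing.append(kmerqc.missing_content(kmerqc.spectra_cn(rt, at), 1))
        assert missing[0] >= missing[1] >= missing[2]
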