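import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoforge.assembly import Assembly
from chromoforge.asmstats import (
    compare_stats,
    compute_stats,
    cumulative_curve,
    nx_lx,
    round_half_up,
    sequencing_coverage,
    split_into_contigs,
)


def nx_lx_oracle(lengths, fraction):
    """Independent cumulative-sum reading of the Nx/Lx definition."""
    arr = np.sort(np.asarray(lengths))[::-1]
    cum = np.cumsum(arr)
    idx = int(np.argmax(cum >= fraction * cum[-1]))
    return int(arr[idx]), idx + 1


class TestContigSplitting:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACGT", ["ACGT"]),
            ("AAAA" + "N" * 25 + "CCCC", ["AAAA", "CCCC"]),  # run at threshold splits
            ("AAAA" + "N" * 24 + "CCCC", ["AAAA" + "N" * 24 + "CCCC"]),  # below: kept
            ("NNNNN" * 10 + "ACGT" + "N" * 30, ["ACGT"]),  # flanking runs dropped
            ("acgtnnnnnnnnnnnnnnnnnnnnnnnnnACGT", ["acgt", "ACGT"]),  # case-blind
        ],
    )
    def test_examples(self, seq, expected):
        assert split_into_contigs(seq, 25) == expected

    def test_all_n_sequence_yields_no_contigs(self):
        assert split_into_contigs("N" * 100, 25) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            split_into_contigs("", 25)

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300), st.integers(1, 30))
    def test_conservation_and_monotonicity(self, seq, min_gap):
        contigs = split_into_contigs(seq, min_gap)
        # every non-split N run is inside a contig: contig bases + split-run
        # bases add back to the scaffold length
        split_bases = len(seq) - sum(len(c) for c in contigs)
        assert split_bases >= 0
        assert "".join(contigs).count("A") == seq.count("A")
        # raising the threshold never increases the contig count
        more = split_into_contigs(seq, min_gap + 5)
        assert len(more) <= len(contigs)


class TestNxLx:
    @pytest.mark.parametrize(
        "lengths, fraction, expected",
        [
            ([10, 8, 6, 4, 2], 0.5, (8, 2)),
            ([7], 0.3, (7, 1)),
            ([5, 5, 5, 5], 0.9, (5, 4)),
        ],
    )
    def test_worked_examples(self, lengths, fraction, expected):
        assert nx_lx(lengths, fraction) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nx_lx([], 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(1, 10_000), min_size=1, max_size=200),
        st.sampled_from([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]),
    )
    def test_matches_cumulative_sum_oracle(self, lengths, fraction):
        assert nx_lx(lengths, fraction) == nx_lx_oracle(lengths, fraction)

    def test_n90_never_exceeds_n50(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lengths = rng.integers(1, 1000, size=rng.integers(1, 50)).tolist()
            n50, l50 = nx_lx(lengths, 0.5)
            n90, l90 = nx_lx(lengths, 0.9)
            assert n90 <= n50 and l50 <= l90


class TestComputeStats:
    def test_hand_computed_single_scaffold(self):
        asm = Assembly([("s", "AAAA" + "N" * 25 + "CCCC")])
        st_ = compute_stats(asm)
        assert st_.total_size == 33
        assert st_.gap_length == 25
        assert st_.scaffold_n50 == 33
        assert st_.contig_n50 == 4
        assert st_.contig_count == 2
        assert st_.contig_count >= st_.scaffold_count

    def test_gapless_assembly_has_equal_contig_and_scaffold_stats(self):
        asm = Assembly([("a", "ACGT" * 100), ("b", "GGCC" * 30)])
        st_ = compute_stats(asm)
        assert st_.gap_length == 0
        assert st_.contig_n50 == st_.scaffold_n50
        assert st_.contig_count == st_.scaffold_count

    def test_gap_accounting_on_scaffolded_synthetic(
        self, draft_and_map, scaffolded_and_map
    ):
        # joins with 1000-N gaps and no fills: gap growth is exactly
        # (#joins x 1000) over the draft's own gap content
        draft, _ = draft_and_map
        scaf, tmap = scaffolded_and_map
        n_joins = len(tmap.join_ledger)
        d, s = compute_stats(draft), compute_stats(scaf)
        assert s.gap_length - d.gap_length == n_joins * 1000
        assert s.total_size - d.total_size == n_joins * 1000


class TestCompare:
    def test_identical_stats_give_zero_deltas_and_unit_folds(self):
        asm = Assembly([("a", "ACGT" * 100)])
        st_ = compute_stats(asm)
        rep = compare_stats(st_, st_)
        assert rep.bases_added == 0
        assert all(v == 1.0 for v in rep.fold_changes.values())

    def test_mismatched_min_gap_len_is_incomparable(self):
        asm = Assembly([("a", "ACGT" * 100)])
        with pytest.raises(ValueError):
            compare_stats(compute_stats(asm, 25), compute_stats(asm, 10))


class TestCurvesAndCoverage:
    def test_cumulative_curve_ends_at_total_and_is_monotone(self):
        pts = cumulative_curve([10, 8, 6, 4, 2])
        assert pts[-1] == (5, 30)
        assert all(b[1] >= a[1] for a, b in zip(pts, pts[1:]))
        assert cumulative_curve([7]) == [(1, 7)]

    def test_coverage_quotient(self):
        assert round_half_up(sequencing_coverage(3 * 10**9, 10**9), 2) == 3.00
        with pytest.raises(ValueError):
            sequencing_coverage(10, 0)

    def test_round_half_up_ties(self):
        assert round_half_up(2.675, 2) == 2.68
        assert round_half_up(0.5, 0) == 1.0
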