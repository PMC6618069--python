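import numpy as np
import pytest

from chromoforge import synthio
from chromoforge.assembly import reverse_complement


class TestTruthGenome:
    def test_single_chromosome_no_repeats(self):
        t = synthio.generate_truth_genome(1, (1000, 1000), 0.0, seed=1)
        assert len(t.chromosomes) == 1
        assert len(t.chromosomes["chr1"]) == 1000
        assert t.repeats == ()

    def test_repeat_fraction_realized_within_tolerance(self):
        t = synthio.generate_truth_genome(5, (50_000, 100_000), 0.1, seed=7)
        assert 0.08 <= t.repeat_fraction() <= 0.12

    def test_deterministic_per_seed(self):
        a = synthio.generate_truth_genome(3, (5_000, 8_000), 0.1, seed=7)
        b = synthio.generate_truth_genome(3, (5_000, 8_000), 0.1, seed=7)
        assert a.chromosomes == b.chromosomes and a.repeats == b.repeats
        c = synthio.generate_truth_genome(3, (5_000, 8_000), 0.1, seed=8)
        assert a.chromosomes != c.chromosomes

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            synthio.generate_truth_genome(0, (1000, 1000), 0.0, seed=1)
        with pytest.raises(ValueError):
            synthio.generate_truth_genome(1, (1000, 500), 0.0, seed=1)
        with pytest.raises(ValueError):
            synthio.generate_truth_genome(1, (1000, 1000), 0.6, seed=1)


class TestFragmentation:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_round_trip_reconstruction_exact(self, seed):
        t = synthio.generate_truth_genome(3, (8_000, 15_000), 0.05, seed=seed)
        draft, tmap = synthio.fragment_genome(t, 2_000, (50, 200), seed=seed)
        rebuilt = tmap.reconstruct(draft)
        for chrom, seq in t.chromosomes:
            assert rebuilt[chrom] == seq

    def test_zero_gap_range_gives_gapless_scaffolds(self):
        t = synthio.generate_truth_genome(2, (5_000, 8_000), 0.0, seed=3)
        draft, tmap = synthio.fragment_genome(t, 1_500, (0, 0), seed=3)
        assert all("N" not in seq for _, seq in draft)
        assert tmap.reconstruct(draft) == t.chromosomes

    def test_fragment_count_tracks_mean_length(self):
        t = synthio.generate_truth_genome(1, (100_000, 100_000), 0.0, seed=5)
        _, tmap = synthio.fragment_genome(t, 10_000, (0, 0), seed=5)
        n_frag = len(tmap.placements)
        assert 5 <= n_frag <= 20  # ~10 with Poisson-ish spread

    def test_non_gap_bases_conserved(self, truth, draft_and_map):
        draft, _ = draft_and_map
        non_gap = sum(
            len(s) - s.count("N") - s.count("n") for _, s in draft
        )
        withheld = truth.chromosomes.total_size - non_gap
        assert 0 <= withheld < truth.chromosomes.total_size * 0.2


class TestScaffolding:
    def test_error_free_join_yields_one_scaffold_per_chromosome(
        self, truth, scaffolded_and_map
    ):
        scaf, tmap = scaffolded_and_map
        assert len(scaf) == len(truth.chromosomes)
        assert all(rec.correct for rec in tmap.join_ledger)

    def test_join_gap_arithmetic(self, draft_and_map):
        draft, tmap = draft_and_map
        scaf, smap = synthio.scaffold_draft(draft, tmap, join_gap=500, seed=9)
        assert scaf.total_size == draft.total_size + 500 * len(smap.join_ledger)

    def test_all_joins_wrong_at_rate_one(self, draft_and_map):
        draft, tmap = draft_and_map
        _, smap = synthio.scaffold_draft(draft, tmap, join_error_rate=1.0, seed=9)
        assert smap.join_ledger and all(not r.correct for r in smap.join_ledger)

    def test_error_rate_validation(self, draft_and_map):
        draft, tmap = draft_and_map
        with pytest.raises(ValueError):
            synthio.scaffold_draft(draft, tmap, join_error_rate=1.5, seed=0)


class TestGapFilling:
    def test_fill_rate_zero_is_identity(self, truth, scaffolded_and_map):
        scaf, tmap = scaffolded_and_map
        out, fmap = synthio.fill_gaps_synthetic(scaf, truth, tmap, 0.0, seed=1)
        assert out == scaf
        assert not any(f.filled for f in fmap.fill_ledger)

    def test_fill_rate_one_closes_all_gaps_error_free(self, truth):
        draft, m1 = synthio.fragment_genome(truth, 4_000, (50, 300), seed=50)
        scaf, m2 = synthio.scaffold_draft(draft, m1, seed=51)
        out, m3 = synthio.fill_gaps_synthetic(scaf, truth, m2, 1.0, seed=52)
        assert m3.gap_count() == 0
        assert all("N" not in s for _, s in out)
        # with nothing withheld, filling everything recovers the genome size
        assert out.total_size == truth.chromosomes.total_size

    def test_over_filled_gap_grows_assembly_by_ledger_delta(self, truth):
        # withheld spans can exceed the 1000-N join placeholder: those gaps
        # over-fill, and the size change equals the summed ledger deltas
        draft, m1 = synthio.fragment_genome(
            truth, 4_000, (50, 300), seed=60, missing_span_range=(0, 1_500)
        )
        scaf, m2 = synthio.scaffold_draft(draft, m1, seed=61)
        out, m3 = synthio.fill_gaps_synthetic(scaf, truth, m2, 1.0, seed=62)
        fills = [f for f in m3.fill_ledger if f.filled]
        assert any(f.true_len > f.placeholder_len for f in fills)  # over-filled
        assert any(f.true_len < f.placeholder_len for f in fills)  # under-filled
        delta = sum(f.true_len - f.placeholder_len for f in fills)
        assert out.total_size - scaf.total_size == delta

    def test_gap_count_non_increasing(self, truth, scaffolded_and_map):
        scaf, tmap = scaffolded_and_map
        _, fmap = synthio.fill_gaps_synthetic(scaf, truth, tmap, 0.5, seed=2)
        assert fmap.gap_count() <= tmap.gap_count()


class TestProbes:
    def test_clean_probes_are_exact_substrings(self, truth):
        probes, labels, origin = synthio.generate_probes(truth, 5, 120, 0.0, 0.0, seed=8)
        for pid, seq in probes:
            assert len(seq) == 120
            assert seq in truth.chromosomes[labels[pid]]
            assert labels[pid] == origin[pid]

    def test_mislabel_rate_realized(self, truth):
        probes, labels, origin = synthio.generate_probes(
            truth, 100, 120, 0.0, 0.04, seed=9
        )
        swapped = sum(labels[p] != origin[p] for p in labels)
        n = len(labels)
        # binomial 99% band around 4%
        sd = np.sqrt(0.04 * 0.96 * n)
        assert abs(swapped - 0.04 * n) <= 3 * sd


class TestReads:
    def test_pair_count_formula(self):
        t = synthio.generate_truth_genome(1, (100_000, 100_000), 0.0, seed=2)
        r1, r2 = synthio.generate_reads(t, 30, 100, 0.0, seed=2)
        assert len(r1) == len(r2) == round(30 * 100_000 / 200)

    def test_error_free_reads_are_genome_substrings(self):
        t = synthio.generate_truth_genome(2, (5_000, 6_000), 0.0, seed=3)
        r1, r2 = synthio.generate_reads(t, 2, 100, 0.0, seed=3)
        genome = {seq for _, seq in t.chromosomes}
        for _, read in (r1 + r2)[:50]:
            assert any(
                read in chrom or reverse_complement(read) in chrom
                for chrom in genome
            )

    def test_zero_coverage_gives_no_reads(self, truth):
        assert synthio.generate_reads(truth, 0, 100, 0.0, seed=1) == ([], [])


class TestAnnotation:
    def test_zero_genes_gives_header_only(self, truth):
        gff, table = synthio.generate_annotation(truth, 0, seed=1)
        assert gff.strip() == "##gff-version 3"
        assert table.empty

    def test_feature_nesting_invariant(self, truth):
        gff, _ = synthio.generate_annotation(truth, 50, seed=4)
        genes, mrnas = {}, {}
        for line in gff.splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(kv.split("=") for kv in f[8].split(";"))
            span = (int(f[3]), int(f[4]))
            if f[2] == "gene":
                genes[attrs["ID"]] = span
            elif f[2] == "mRNA":
                mrnas[attrs["ID"]] = span
                g = genes[attrs["Parent"]]
                assert g[0] <= span[0] and span[1] <= g[1]
            else:
                m = mrnas[attrs["Parent"]]
                assert m[0] <= span[0] and span[1] <= m[1]

    def test_truncated_fraction_within_binomial_band(self, truth):
        _, table = synthio.generate_annotation(
            truth, 400, seed=5, truncated_fraction=0.3
        )
        ratios = table.query_len / table.subject_len
        frac = float((ratios < 0.85).mean())
        n = len(table)
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) <= 3 * sd
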