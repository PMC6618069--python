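import shutil
import subprocess

import numpy as np
import pytest

from chromoforge import asmstats, probemap, synthio
from chromoforge.assembly import Assembly
from chromoforge.probemap import (
    ProbeHit,
    assignment_report,
    best_hit_per_probe,
    vote_assignments,
)


def hit(probe="p", scaffold="s", e=1e-40, bits=200.0, ident=100.0, length=100):
    return ProbeHit(
        probe=probe, scaffold=scaffold, identity_pct=ident, length=length,
        mismatches=0, q_start=1, q_end=length, s_start=1, s_end=length,
        e_value=e, bit_score=bits,
    )


class TestBuiltInAligner:
    def test_exact_substring_hits_full_length_at_full_identity(self):
        asm = Assembly([("s1", "A" * 50 + "ACGTTGCAGGCTTACGGATCA" * 6 + "C" * 50)])
        probe = asm["s1"][60:180]
        hits = probemap.align_probes(Assembly([("p1", probe)]), asm)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity_pct == 100.0 and h.length == len(probe)
        assert h.s_start == 61 and h.s_end == 180  # 1-based inclusive

    def test_reverse_complement_probe_found_on_minus_strand(self):
        from chromoforge.assembly import reverse_complement

        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        asm = Assembly([("s1", seq)])
        probe = reverse_complement(seq[100:220])
        (h,) = probemap.align_probes(Assembly([("p1", probe)]), asm)
        assert h.strand == "-" and h.s_start > h.s_end
        assert (h.s_end, h.s_start) == (101, 220)

    def test_unmatchable_probe_yields_no_hits(self):
        asm = Assembly([("s1", "AC" * 200)])
        hits = probemap.align_probes(Assembly([("p1", "G" * 60)]), asm)
        assert hits == []

    def test_noisy_probes_recover_true_scaffold(self, truth):
        probes, labels, origin = synthio.generate_probes(
            truth, 10, 120, mutation_rate=0.02, mislabel_rate=0.0, seed=31
        )
        hits = probemap.align_probes(probes, truth.chromosomes)
        best = best_hit_per_probe(hits)
        recovered = sum(
            best[p].scaffold == origin[p] for p in best
        )
        assert len(best) >= 0.99 * len(probes)
        assert recovered >= 0.99 * len(best)

    @pytest.mark.skipif(shutil.which("blastn") is None, reason="blastn not on PATH")
    def test_agrees_with_blastn_on_best_scaffold(self, truth, tmp_path):
        # independent oracle: NCBI blastn on the same probes and scaffolds
        probes, _, origin = synthio.generate_probes(
            truth, 6, 120, mutation_rate=0.01, mislabel_rate=0.0, seed=32
        )
        asm_fa, probe_fa = tmp_path / "asm.fa", tmp_path / "probes.fa"
        truth.chromosomes.to_fasta(asm_fa)
        probes.to_fasta(probe_fa)
        subprocess.run(
            ["makeblastdb", "-in", str(asm_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        out = tmp_path / "hits.tsv"
        subprocess.run(
            ["blastn", "-query", str(probe_fa), "-db", str(asm_fa),
             "-outfmt", "6", "-max_hsps", "1", "-dust", "no", "-out", str(out)],
            check=True, capture_output=True,
        )
        blast_best = best_hit_per_probe(probemap.read_blast_tab(out), e_max=1e-30)
        ours_best = best_hit_per_probe(
            probemap.align_probes(probes, truth.chromosomes), e_max=1e-30
        )
        shared = set(blast_best) & set(ours_best)
        assert len(shared) >= 0.9 * len(probes)
        agree = sum(blast_best[p].scaffold == ours_best[p].scaffold for p in shared)
        assert agree == len(shared)


class TestBestHit:
    def test_lowest_e_value_wins(self):
        hits = [hit(e=1e-35, bits=150), hit(e=1e-40, bits=140)]
        assert best_hit_per_probe(hits)["p"].e_value == 1e-40

    def test_threshold_excludes_weak_probes(self):
        assert best_hit_per_probe([hit(e=1e-20)]) == {}

    def test_tie_breaks_by_bit_score_then_name(self):
        hits = [
            hit(scaffold="b", e=1e-40, bits=180),
            hit(scaffold="a", e=1e-40, bits=200),
        ]
        assert best_hit_per_probe(hits)["p"].scaffold == "a"
        tie = [
            hit(scaffold="b", e=1e-40, bits=200),
            hit(scaffold="a", e=1e-40, bits=200),
        ]
        assert best_hit_per_probe(tie)["p"].scaffold == "a"

    def test_stricter_ceiling_never_grows_output(self):
        hits = [hit(probe=f"p{i}", e=10.0 ** -(25 + i)) for i in range(10)]
        loose = best_hit_per_probe(hits, e_max=1e-25)
        tight = best_hit_per_probe(hits, e_max=1e-30)
        assert set(tight) <= set(loose)


class TestVoting:
    def test_simple_tally_and_concordance(self):
        best = {f"p{i}": hit(probe=f"p{i}", scaffold="scaffold_5") for i in range(9)}
        best["p9"] = hit(probe="p9", scaffold="scaffold_7")
        labels = {f"p{i}": "chr1" for i in range(10)}
        asg = vote_assignments(best, labels)
        assert asg.primary["chr1"] == ("scaffold_5", 9)
        assert asg.concordance["chr1"] == pytest.approx(0.9)

    def test_conflict_resolved_by_concordance(self):
        best = {}
        labels = {}
        # chrA: 9/10 vote s3 ; chrB: 6/10 vote s3, runner-up s9
        for i in range(10):
            labels[f"a{i}"] = "chrA"
            best[f"a{i}"] = hit(probe=f"a{i}", scaffold="s3" if i < 9 else "s1")
        for i in range(10):
            labels[f"b{i}"] = "chrB"
            best[f"b{i}"] = hit(probe=f"b{i}", scaffold="s3" if i < 6 else "s9")
        asg = vote_assignments(best, labels)
        assert asg.primary["chrA"][0] == "s3"
        assert asg.primary["chrB"][0] == "s9"
        assert asg.concordance["chrB"] == pytest.approx(0.4)

    def test_unlabeled_probe_rejected(self):
        with pytest.raises(ValueError):
            vote_assignments({"p": hit()}, {})

    def test_noiseless_synthetic_recovers_every_chromosome(
        self, truth, filled_and_map
    ):
        filled, tmap = filled_and_map
        probes, labels, origin = synthio.generate_probes(
            truth, 10, 120, 0.0, 0.0, seed=33
        )
        best = best_hit_per_probe(probemap.align_probes(probes, filled))
        asg = vote_assignments(best, labels)
        assert len(asg.primary) == len(truth.chromosomes)
        assert asg.unassigned_chromosomes == []
        assert all(c == 1.0 for c in asg.concordance.values())
        # each chromosome's scaffold is the one that carries it
        for chrom, (scaffold, _) in asg.primary.items():
            assert scaffold == f"scf_{chrom}"


class TestReport:
    def test_hand_computed_summary(self):
        asm = Assembly([("s1", "A" * 600), ("s2", "C" * 300), ("s3", "G" * 100)])
        stats = asmstats.compute_stats(asm)
        asg = probemap.ChromosomeAssignment(
            primary={"chr1": ("s1", 10), "chr2": ("s2", 9), "chr3": ("s3", 8)},
            concordance={"chr1": 1.0, "chr2": 0.9, "chr3": 0.8},
        )
        rep = assignment_report(asg, stats, asm, population_sd=True)
        assert rep.mean_concordance == pytest.approx(0.9)
        assert rep.sd_concordance == pytest.approx(0.0816, abs=1e-4)
        assert rep.unassigned_bases == 0
        assert rep.unassigned_percent == 0.0

    def test_unassigned_percent_rounding(self):
        asm = Assembly([("s1", "A" * 9_528), ("junk", "C" * 472)])
        stats = asmstats.compute_stats(asm)
        asg = probemap.ChromosomeAssignment(
            primary={"chr1": ("s1", 5)}, concordance={"chr1": 1.0}
        )
        rep = assignment_report(asg, stats, asm)
        assert rep.unassigned_bases == 472
        assert rep.unassigned_percent == 4.72
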