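"""Assembly statistics and version comparison on a synthetic upgrade.

Builds a small truth genome, fragments it into a draft, scaffolds the draft
with 1,000-N joins and fills the gaps, then prints the contiguity table for
each version and the deltas between them — the same accounting a genome
upgrade report prints (total size, gap bases, N50/L50, fold changes).
"""

from chromoforge import asmstats, synthio

truth = synthio.generate_truth_genome(6, (40_000, 80_000), 0.05, seed=1)
draft, tmap = synthio.fragment_genome(
    truth, 5_000, (50, 400), seed=2, missing_span_range=(0, 1_500)
)
scaffolded, tmap2 = synthio.scaffold_draft(draft, tmap, join_gap=1000, seed=3)
filled, tmap3 = synthio.fill_gaps_synthetic(scaffolded, truth, tmap2, 0.9, seed=4)

print(f"{'statistic':<20}{'draft':>12}{'scaffolded':>12}{'filled':>12}")
stats = {name: asmstats.compute_stats(asm) for name, asm in
         [("draft", draft), ("scaffolded", scaffolded), ("filled", filled)]}
for key in ("total_size", "gap_length", "scaffold_count", "scaffold_n50",
            "scaffold_l50", "contig_count", "contig_n50"):
    row = "".join(f"{getattr(s, key):>12,}" for s in stats.values())
    print(f"{key:<20}{row}")

rep = asmstats.compare_stats(stats["draft"], stats["filled"])
fills = [f for f in tmap3.fill_ledger if f.filled]
over = sum(1 for f in fills if f.true_len > f.placeholder_len)
print(f"\ndraft -> filled: {rep.bases_added:+,} bases ({rep.bases_added_mbp} Mbp), "
      f"scaffold N50 x{rep.fold_changes['scaffold_n50']:.1f}")
print(f"gap filling closed {len(fills)} gaps, {over} of them over-filled "
      f"(true span longer than the 1,000-N placeholder)")
print("\nThe N50 fold change is the headline contiguity gain; over-filled gaps")
print("explain why gap filling can grow an assembly beyond its placeholder size.")
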