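"""Chromosome assignment of scaffolds by marker-probe best-hit voting.

Draws chromosome-labelled probes (4% deliberately mislabelled, 1% per-base
mutation), maps them to the assembled scaffolds with the built-in ungapped
aligner, keeps each probe's most significant hit below E = 1e-30, and lets
each chromosome's probe set vote for its scaffold.
"""

import numpy as np

from chromoforge import asmstats, probemap, synthio

truth = synthio.generate_truth_genome(6, (25_000, 45_000), 0.05, seed=13)
draft, m1 = synthio.fragment_genome(truth, 5_000, (50, 300), seed=14)
scaffolded, m2 = synthio.scaffold_draft(draft, m1, seed=15)
filled, m3 = synthio.fill_gaps_synthetic(scaffolded, truth, m2, 1.0, seed=16)

probes, labels, origin = synthio.generate_probes(
    truth, n_per_chrom=30, probe_len=120,
    mutation_rate=0.01, mislabel_rate=0.04, seed=17,
)
hits = probemap.align_probes(probes, filled)
best = probemap.best_hit_per_probe(hits, e_max=1e-30)
assignment = probemap.vote_assignments(best, labels)
report = probemap.assignment_report(
    assignment, asmstats.compute_stats(filled), filled
)

print(f"{len(best)}/{len(probes)} probes had a hit passing E <= 1e-30")
print(f"{'chromosome':<12}{'scaffold':<14}{'votes':>6}{'concordance':>12}")
for chrom in sorted(assignment.primary):
    scaffold, votes = assignment.primary[chrom]
    print(f"{chrom:<12}{scaffold:<14}{votes:>6}{assignment.concordance[chrom]:>12.3f}")
print(f"\nmean concordance {report.mean_concordance:.1%} "
      f"± {report.sd_concordance:.1%} (sample SD)")
print(f"unassigned: {report.unassigned_bases:,} bases "
      f"({report.unassigned_percent}% of the assembly)")
print("\nConcordance is the majority share of each chromosome's probe votes; it")
print("sits near 1 minus the mislabelling rate when scaffolds are chromosome-scale.")
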