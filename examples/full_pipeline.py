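"""End-to-end synthetic run of every QC stage with one consolidated report.

Equivalent to `chromoforge demo --seed 1 --outdir chromoforge_demo`: builds
the genome and all derived inputs, then runs stats/comparison, k-mer
completeness, alignment ordering/orientation, probe-vote chromosome
assignment and annotation QC, writing artifacts and report.json/report.md.
"""

from chromoforge import pipeline

report = pipeline.demo(seed=1, outdir="chromoforge_demo")

print("stages run:", ", ".join(s for s in pipeline.ALL_STAGES if s in report))
syn = report["synthesize"]
print(f"genome: {syn['genome_size']:,} bp over {syn['n_chromosomes']} chromosomes; "
      f"{syn['read_pairs']:,} read pairs, {syn['probes']} probes")
print(f"gap filling: {report['stats']['gap_filling']['gaps_closed']} gaps closed, "
      f"{report['stats']['gap_filling']['gaps_over_filled']} over-filled")
print(f"k-mer missing content: {report['kmerqc']['missing_content']:.3%}")
print(f"chromosomes assigned: {report['probemap']['chromosomes_assigned']}"
      f"/{syn['n_chromosomes']}, mean concordance "
      f"{report['probemap']['mean_concordance']:.1%}")
print(f"annotation: {report['annosum']['summary']['genes']} genes, "
      f"{report['annosum']['truncation_percent_in_window']}% full-length proteins")
print("\nArtifacts (FASTA/FASTQ/GFF3/PAF/TSV/PNG) and the consolidated report")
print("are under chromoforge_demo/.")
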