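# chromoforge

QC toolkit for genome assembly upgrades: the bespoke computations a genome
project performs when a fragmented short-read draft is scaffolded to
chromosome scale (proximity-ligation joins), gap-filled with long reads, and
anchored to chromosomes with marker probes — packaged as a tested, reusable
library with a synthetic-data generator so the whole pipeline runs end to
end without any downloads.

Written for assembly bioinformaticians who need the *evaluation* side of
such a project: contiguity tables, gap accounting, k-mer completeness,
alignment dot plots, chromosome assignment and annotation QC — not the
scaffolders and polishers themselves.

## What it computes

**Assembly statistics** (`chromoforge.asmstats`). For scaffold lengths
$\ell_1 \ge \ell_2 \ge \dots$, N50 is the smallest $\ell_i$ with
$\sum_{j \le i} \ell_j \ge 0.5 \sum_j \ell_j$ and L50 is that $i$ (N90/L90
at 90%). Contigs are obtained by splitting scaffolds at N-runs of at least
`min_gap_len` (default 25 bp). Version comparison reports signed bases
added, gap-base deltas, scaffolds merged and fold changes, with Mbp
renderings rounded half-up to 2 decimals.

**K-mer completeness** (`chromoforge.kmerqc`). Canonical 27-mers (the
lexicographic minimum of a k-mer and its reverse complement) are counted in
reads and assembly; each distinct read k-mer is binned by read multiplicity
$m$ and assembly copy number $c$ (the spectra-cn matrix). After discarding
the sequencing-error peak ($m < m_{err}$, found at the valley below the
main peak), the missing-content estimate is the $c=0$ share:
$\sum_{m \ge m_{err}} M[m][0] \,/\, \sum_{m \ge m_{err}, c} M[m][c]$.

**Alignment dot plots and orientation** (`chromoforge.alnmap`). PAF
matches are filtered the way dot-plot viewers do — a match is dropped when
its block length is ≤ `width_fraction` (default 0.001%) of the total target
length or its identity (matching bases / block length) is ≤ `min_identity`
(default 0.75). Queries are ordered along the reference by their dominant
target and base-weighted median position; orientation per query is the
strand carrying the majority of matching bases, and '−' calls are applied
by reverse complement.

**Probe-vote chromosome assignment** (`chromoforge.probemap`). Marker
probes with known chromosome labels (a radiation-hybrid panel in the
motivating use case) are aligned to scaffolds — BLAST outfmt 6 input or the
built-in ungapped seed-and-extend aligner with Karlin–Altschul E-values.
Per probe only the most significant hit with E ≤ 1e−30 is kept; each
chromosome is assigned the scaffold with the most best hits from its probe
set, with per-chromosome concordance (majority vote share), mean ± SD, and
the unassigned residue of the assembly.

**Annotation QC** (`chromoforge.annosum`). GFF3 feature summaries (introns
derived from exon gaps), filtering on annotation edit distance
(AED ≤ 0.50 kept), cumulative AED curves, predicted/subject protein length
ratio profiles (ratios in [0.85, 1.15] count as full length), and
complete-ortholog proportions from benchmark (BUSCO-style) counts.

**Synthetic data with ground truth** (`chromoforge.synthio`). A truth
genome with interspersed repeats; a fragmented draft with N-gaps; a
scaffolded version with 1,000-N joins and optional join errors; gap filling
that over- or under-fills placeholders; labelled probes with mutation and
mislabelling rates; paired reads; GFF3 annotations with AED values — every
output tied to a `TruthMap` for parameter-recovery tests.

`chromoforge.pipeline` chains the stages and writes one consolidated
report; the `chromoforge` CLI wraps the library
(`stats`, `compare`, `dotplot`, `assign`, `annosum`, `run`, `demo`).

## Worked example

```bash
python examples/chromosome_assignment.py
```

```
180/180 probes had a hit passing E <= 1e-30
chromosome  scaffold       votes concordance
chr1        scf_chr1          30       0.938
chr2        scf_chr2          26       0.867
chr3        scf_chr3          27       0.964
chr4        scf_chr4          29       0.906
chr5        scf_chr5          28       0.966
chr6        scf_chr6          28       0.966

mean concordance 93.4% ± 4.1% (sample SD)
unassigned: 0 bases (0.0% of the assembly)
```

Six chromosomes were simulated with 30 probes each, 4% of labels
deliberately swapped and 1% per-base probe mutation. Every chromosome
recovers the scaffold that actually carries it, and the mean concordance
sits near 1 minus the mislabelling rate — the signature that best-hit
voting is robust to realistic label noise. The other scripts under
`examples/` demonstrate the statistics table, k-mer completeness,
dot-plot ordering, annotation QC and the full pipeline the same way.

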