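# Methods

## Scope and model

chromoforge evaluates a genome-assembly upgrade: a short-read draft is
scaffolded into chromosome-scale super-scaffolds by proximity-ligation
evidence, gaps are filled with long reads, scaffolds are anchored to
chromosomes by marker probes, and the result is annotated. The package
implements the measurements around that process, not the assembly tools:
contiguity statistics, gap accounting, k-mer completeness, alignment
filtering/ordering/orientation, probe-vote chromosome assignment and
annotation QC. A synthetic-data generator supplies every input together
with its ground truth, so each measurement can be validated as a
parameter-recovery problem.

## Assembly statistics

* Nx/Lx follow the universal convention: lengths sorted descending, Nx is
  the length at which the running sum first reaches x% of the total, Lx its
  1-based rank. (Definitions phrased as the sum being "equal to" x% are
  implemented as ≥, since exact equality is generically unattainable.)
* Contigs are maximal segments between N-runs of ≥ `min_gap_len` (default
  25 bp); shorter N-runs stay inside contigs. `gap_length` counts **all**
  N/n bases, independent of the splitting threshold — the two notions serve
  different purposes (one gap figure per assembly vs. a contig definition).
* Case-insensitive base handling; IUPAC ambiguity codes other than N count
  as sequence.
* Report renderings (Mbp added, coverage folds, percentages) round half-up
  — 99.325 → 99.33 — because Python's bankers' rounding does not match how
  assembly reports print numbers. Raw values are always retained.

## K-mer completeness (spectra-cn)

* Canonical k-mer = min(k-mer, reverse complement); k = 27 by default, k ≤
  31 enforced by the 2-bit packing. Windows containing N are skipped.
* Counting is in-memory and numpy-vectorized (2-bit codes, sorted unique);
  sequences are batched into ~4 Mb N-joined blocks to amortize per-read
  overhead. This is sized for desk-scale genomes (tens of Mbp); mammalian-
  scale read sets need a disk-backed counter behind the same
  `KmerCountTable` interface, which is deliberately pluggable.
* The spectra matrix bins distinct read k-mers by read multiplicity
  (1..200, open top bin) × assembly copy number (0..6, open top bin).
  Missing content weights **distinct** k-mers, not occurrences, matching
  the standard reading of spectra-cn "missing" bars; assembly-only k-mers
  are reported separately, never mixed into the matrix.
* `error_cutoff` places the error/genome boundary at the minimum of the
  multiplicity histogram below its main peak (the peak search ignores
  multiplicity 1 so a dominant error spike cannot hide the genomic peak).
  Unimodal or monotone histograms return 1 — nothing is cut. This is
  intentionally simple; it is not a mixture-model fit.

## Alignment filtering, ordering, orientation

* The dot-plot filter drops a match iff block length ≤ `width_fraction` ×
  (summed distinct target lengths) or identity ≤ `min_identity`. Both
  bounds are strict ("≤ removed"), and "plot width" is interpreted as the
  total target-axis span, which is how dot-plot viewers compute it. The
  filter is idempotent.
* Query order is keyed by (target with the largest summed matching bases,
  base-weighted median of match midpoints on that target). A weighted
  median was chosen over best-match position because it is stable when a
  query has many small matches; this choice is one of several defensible
  sorts and is isolated in `order_queries`.
* Orientation is the strand carrying the majority of matching bases;
  support is that majority share; exact ties call '+' at support 0.5.
  Applying calls twice is the identity (reverse complement is an
  involution), which is property-tested.
* Synthetic alignments for tests are derived *analytically* from the
  TruthMap (exact fragment coordinates), so no external aligner is a test
  dependency; real PAF from any aligner is accepted (columns 1–12, tags
  ignored).

## Probe-vote chromosome assignment

* Best hit per probe = lowest numeric E-value (ties: higher bit score, then
  lexicographic scaffold), after discarding hits with E > 1e−30. Probes
  with no passing hit are excluded from concordance denominators and
  counted separately.
* Voting: per chromosome, tally best-hit scaffolds over its labelled probe
  set; primary = most votes (ties: summed bit score, then name).
  Concordance = primary votes / passing probes of that chromosome. A
  scaffold may be primary for at most one chromosome; conflicts resolve in
  favour of the higher-concordance claimant, the loser falls back to its
  next-ranked scaffold, iterated to a fixpoint. All tie-breaks are total
  orders, so assignment is deterministic.
* The concordance summary uses the sample SD (ddof = 1) by default with a
  population-SD flag, since either convention appears in reports.
* The built-in aligner exists so the procedure runs self-contained: exact
  seeds (16 bp), ungapped ±1/−2 extension with X-drop 20, best hit per
  (probe, scaffold) over both strands, identity floor 0.9. E-values use
  the published ungapped Karlin–Altschul parameters for +1/−2 DNA scoring
  (λ = 1.33, K = 0.621). It handles substitution noise only — the
  generator emits no indels, by design — and one test cross-checks its
  best-scaffold calls against NCBI blastn on a small fixture. Real
  analyses can supply BLAST tabular hits instead.

## Annotation QC

* GFF3 parsing is delegated to gffutils (in-memory database). Intron
  lengths derive from gaps between consecutive exons per mRNA, matching
  annotations without explicit intron features. A header-only GFF3 maps to
  an inert sentinel record because the backend cannot represent an empty
  feature set.
* AED filtering is inclusive at the threshold (0.50 kept at 0.50); the
  attribute key may be `_AED` (MAKER dialect) or `AED`. mRNAs lacking the
  attribute are dropped with a warning by default (configurable), and
  genes left without mRNAs are removed; the filter is idempotent.
* The truncation window [0.85, 1.15] on query/subject length ratios is
  inclusive at both ends, and window percentages round half-up to whole
  percent — the combination that reproduces the worked percentages from
  their printed numerators and denominators.
* Complete-ortholog proportion = (single-copy + duplicated) / total,
  half-up to 3 decimals.

## Synthetic-data generator

What it emulates — and where each knob sits:

| parameter | default | meaning |
|---|---|---|
| n_chrom, length range | 12, 60–120 kb | desk-scale stand-in for a multi-chromosome karyotype |
| repeat_fraction | 0.05 | interspersed copies of a small repeat family library |
| mean_contig_len | 8 kb | exponential fragment spacing of the draft |
| gap_len_range | 50–500 | draft N-gap placeholders |
| missing_span_range | 0–2,000 | sequence withheld between draft scaffolds (unassembled content behind gaps) |
| join_gap | 1,000 | fixed-size N placeholder inserted at every scaffolding join |
| join_error_rate | 0.02 | probability a join is inverted/out of order (logged `correct=False`) |
| fill_rate | 0.8 | probability a fillable gap is replaced by its true sequence |
| coverage, read_len, error_rate | 25×, 100 bp, 0.005 | paired short reads, substitution errors only |
| probes/chrom, probe_len | 30, 120 bp | marker panel |
| probe mutation / mislabel rate | 0.01 / 0.05 | per-base substitutions; wrong-chromosome labels |
| n_genes | 300 | nested gene/mRNA/exon/CDS models; AED ~ 0.8·Beta(2,8) + 0.2·U(0,1); 30% truncated proteins |

Design choices that were genuinely open:

* **Withheld spans.** With `missing_span_range=(0,0)` fragments tile each
  chromosome and strand-applied concatenation via the TruthMap reconstructs
  the genome exactly (property-tested across seeds). A nonzero range
  withholds sequence between draft scaffolds; reconstruction is then exact
  up to those spans. This is what makes gap **over-filling** reproducible:
  a 1,000-N join placeholder whose true span is longer grows the assembly
  when filled, and the fill ledger's (placeholder, true length) pairs make
  the size change exactly auditable.
* Gaps created by an incorrect join have no true inter-fragment sequence
  and are never filled — mirroring the fact that a gap filler cannot span
  a misjoin.
* Probes avoid annotated repeat intervals by default, as real marker
  panels are designed away from repetitive sequence; `avoid_repeats=False`
  restores fully uniform sampling.
* Each generator draws from its own numpy Generator seeded per call, so
  adding one call never perturbs another at the same seed; every emitted
  byte is deterministic per seed.

What the generator does **not** emulate — hence what passing tests do not
show about real data: indels and structural errors inside contigs,
realistic quality profiles and coverage biases, heterozygosity/diploidy,
segmental duplications beyond the simple repeat library, and chimeric
reads. Recovery results on synthetic data bound the method's behaviour
under its stated noise model, not under every failure mode of a real
sequencing project.

## Problem sizes and runtime

Tests run on a shared ~150 kb, 5-chromosome fixture (seconds per module);
the pipeline demo and the reproduction script use the default ~1.1 Mb,
12-chromosome scale with 25× reads and complete in well under a minute on
one CPU. These sizes were chosen as the smallest at which every effect of
interest (repeats, join errors, over-filling, probe noise, error k-mer
peaks) is comfortably observable above sampling noise.

## Known limitations

* The probe aligner is ungapped; indel-containing probes would need a
  gapped aligner (supply BLAST tabular output in that case).
* `error_cutoff` is a histogram-valley heuristic, not a model fit, and can
  be unstable when error and genomic peaks overlap (very low coverage or
  very high error rates).
* In-memory k-mer counting bounds the practical genome size; see above.
* The conflict-resolution fixpoint in voting assumes chromosome-scale
  scaffolds; on highly fragmented assemblies many chromosomes legitimately
  share scaffolds and the one-chromosome-per-scaffold rule is too strict.
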