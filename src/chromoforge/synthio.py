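"""Synthetic genome, read, probe and annotation generators with ground truth.

This module manufactures every input the QC pipeline consumes — a
multi-chromosome truth genome with interspersed repeats, a fragmented draft
with N-gaps, a scaffolded version with fixed-size joins (and optional join
errors), a gap-filled version with over/under-filled gaps, chromosome-labelled
probes, short reads, and a GFF3 annotation — together with a
:class:`TruthMap` recording exactly where every emitted fragment came from.
That ground truth is what parameter-recovery tests measure against.

All generators are deterministic for a fixed seed and draw from their own
``numpy`` Generator, so adding one generator call never perturbs another at
the same seed.

The scale defaults are desk-scale stand-ins for a mammalian genome project
(a ~2 Mbp genome over tens of chromosomes rather than 2.27 Gbp over 37);
every size is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assembly import Assembly, reverse_complement

__all__ = [
    "TruthGenome",
    "TruthMap",
    "Placement",
    "Segment",
    "JoinRecord",
    "FillRecord",
    "generate_truth_genome",
    "fragment_genome",
    "scaffold_draft",
    "fill_gaps_synthetic",
    "generate_probes",
    "generate_reads",
    "generate_annotation",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply substitution errors at a per-base rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Truth containers


@dataclass(frozen=True)
class TruthGenome:
    """The simulated genome every downstream version derives from."""

    chromosomes: Assembly
    #: (chrom, start, end, family) intervals, 0-based half-open
    repeats: tuple[tuple[str, int, int, int], ...] = ()

    def repeat_fraction(self) -> float:
        total = self.chromosomes.total_size
        rep = sum(e - s for _, s, e, _ in self.repeats)
        return rep / total if total else 0.0


@dataclass(frozen=True)
class Placement:
    """Where an emitted fragment sits on the truth genome.

    The emitted fragment sequence equals ``chrom[start:end]`` on '+' and its
    reverse complement on '-'. Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class Segment:
    """One run of an emitted scaffold: a fragment or an N-gap."""

    frag_id: str | None  # None marks a gap run
    length: int
    strand: str = "+"

    @property
    def is_gap(self) -> bool:
        return self.frag_id is None


@dataclass(frozen=True)
class JoinRecord:
    scaffold: str
    fragments: tuple[str, ...]  # fragment ids appended by this join
    gap: int
    correct: bool


@dataclass(frozen=True)
class FillRecord:
    scaffold: str
    gap_index: int
    placeholder_len: int
    true_len: int
    filled: bool


@dataclass
class TruthMap:
    """Ground truth linking an emitted assembly version back to the genome."""

    placements: dict[str, Placement] = field(default_factory=dict)
    #: scaffold name -> ordered segments in emitted orientation
    layouts: dict[str, list[Segment]] = field(default_factory=dict)
    probe_labels: dict[str, str] = field(default_factory=dict)
    #: true origin chromosome per probe (differs from label when mislabelled)
    probe_truth: dict[str, str] = field(default_factory=dict)
    join_ledger: list[JoinRecord] = field(default_factory=list)
    fill_ledger: list[FillRecord] = field(default_factory=list)

    # -- derived views ------------------------------------------------------

    def fragment_offsets(self, scaffold: str) -> dict[str, tuple[int, int]]:
        """Fragment id -> (start, end) within the emitted scaffold."""
        out = {}
        pos = 0
        for seg in self.layouts[scaffold]:
            if not seg.is_gap:
                out[seg.frag_id] = (pos, pos + seg.length)
            pos += seg.length
        return out

    def scaffold_of(self, frag_id: str) -> str:
        for scaffold, segs in self.layouts.items():
            if any(s.frag_id == frag_id for s in segs):
                return scaffold
        raise KeyError(frag_id)

    def gap_count(self) -> int:
        return sum(seg.is_gap for segs in self.layouts.values() for seg in segs)

    def emit_scaffold(self, scaffold: str, truth: TruthGenome) -> str:
        """Rebuild a scaffold's sequence from its layout and the truth genome."""
        parts = []
        for seg in self.layouts[scaffold]:
            if seg.is_gap:
                parts.append("N" * seg.length)
            else:
                p = self.placements[seg.frag_id]
                s = truth.chromosomes[p.chrom][p.start : p.end]
                parts.append(s if p.strand == "+" else reverse_complement(s))
        return "".join(parts)

    def reconstruct(self, assembly: Assembly) -> Assembly:
        """Rebuild chromosomes by strand-applied concatenation of fragments.

        Exact when fragments tile each chromosome (no withheld spans);
        otherwise the result is each chromosome minus the withheld spans.
        """
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for scaffold, segs in self.layouts.items():
            offsets = self.fragment_offsets(scaffold)
            for seg in segs:
                if seg.is_gap:
                    continue
                p = self.placements[seg.frag_id]
                lo, hi = offsets[seg.frag_id]
                emitted = assembly[scaffold][lo:hi]
                truth_oriented = emitted if p.strand == "+" else reverse_complement(emitted)
                by_chrom.setdefault(p.chrom, []).append((p.start, truth_oriented))
        rebuilt = Assembly()
        for chrom in sorted(by_chrom):
            pieces = sorted(by_chrom[chrom])
            rebuilt.add(chrom, "".join(seq for _, seq in pieces))
        return rebuilt


# ---------------------------------------------------------------------------
# Generators


def generate_truth_genome(
    n_chrom: int,
    length_range: tuple[int, int],
    repeat_fraction: float = 0.0,
    seed: int = 0,
    n_repeat_families: int = 5,
    repeat_len_range: tuple[int, int] = (200, 800),
) -> TruthGenome:
    """Simulate a genome of random chromosomes with interspersed repeats.

    Repeats are copies of a small family library pasted at random
    non-overlapping positions until the requested base fraction is reached
    (realized fraction within one family-length of the target).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if not 0 <= repeat_fraction < 0.5:
        raise ValueError("repeat_fraction must be in [0, 0.5)")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_chrom)
    chroms = {f"chr{i + 1}": _random_seq(rng, int(L)) for i, L in enumerate(lengths)}

    repeats: list[tuple[str, int, int, int]] = []
    if repeat_fraction > 0:
        families = [
            _random_seq(rng, int(rng.integers(repeat_len_range[0], repeat_len_range[1] + 1)))
            for _ in range(n_repeat_families)
        ]
        total = sum(len(s) for s in chroms.values())
        target = repeat_fraction * total
        placed = 0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        names = sorted(chroms)
        probs = np.array([len(chroms[c]) for c in names], dtype=float)
        probs /= probs.sum()
        attempts = 0
        mutable = {c: list(s) for c, s in chroms.items()}
        while placed < target and attempts < 50 * n_chrom * 1000:
            attempts += 1
            fam = int(rng.integers(0, len(families)))
            rep = families[fam]
            chrom = names[rng.choice(len(names), p=probs)]
            L = len(mutable[chrom])
            if len(rep) >= L:
                continue
            start = int(rng.integers(0, L - len(rep)))
            end = start + len(rep)
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            mutable[chrom][start:end] = rep
            occupied[chrom].append((start, end))
            repeats.append((chrom, start, end, fam))
            placed += len(rep)
        chroms = {c: "".join(s) for c, s in mutable.items()}

    asm = Assembly((name, chroms[name]) for name in sorted(chroms, key=lambda c: int(c[3:])))
    return TruthGenome(chromosomes=asm, repeats=tuple(sorted(repeats)))


def fragment_genome(
    truth: TruthGenome,
    mean_contig_len: int,
    gap_len_range: tuple[int, int] = (50, 500),
    seed: int = 0,
    fragments_per_scaffold: tuple[int, int] = (1, 5),
    missing_span_range: tuple[int, int] = (0, 0),
) -> tuple[Assembly, TruthMap]:
    """Cut the truth genome into a fragmented draft assembly.

    Chromosomes are cut at random (exponentially spaced) points; consecutive
    fragments are grouped into scaffolds whose internal gaps are N-runs with
    lengths drawn uniformly from ``gap_len_range``. Each scaffold is emitted
    on a random strand. With the default ``missing_span_range=(0, 0)``
    fragments tile each chromosome exactly, so strand-applied concatenation
    via the TruthMap reconstructs the genome; a nonzero range withholds
    sequence between scaffolds (emulating content the draft failed to
    assemble), which is what later makes gap over-filling possible.
    """
    shortest = min(len(s) for _, s in truth.chromosomes)
    if mean_contig_len >= shortest:
        raise ValueError("mean_contig_len must be below the shortest chromosome")
    if gap_len_range[0] < 0 or gap_len_range[1] < gap_len_range[0]:
        raise ValueError(f"invalid gap_len_range {gap_len_range}")
    rng = np.random.default_rng(seed)
    assembly = Assembly()
    tmap = TruthMap()
    scaffold_idx = 0
    for chrom, seq in truth.chromosomes:
        L = len(seq)
        # cut points: exponential spacing around the requested mean
        cuts: list[tuple[int, int]] = []
        pos = 0
        while pos < L:
            flen = max(1, int(round(rng.exponential(mean_contig_len))))
            cuts.append((pos, min(pos + flen, L)))
            pos += flen
        # group consecutive fragments into scaffolds
        groups: list[list[tuple[int, int]]] = []
        i = 0
        while i < len(cuts):
            k = int(rng.integers(fragments_per_scaffold[0], fragments_per_scaffold[1] + 1))
            groups.append(cuts[i : i + k])
            i += k
        # optionally withhold sequence between scaffolds
        if missing_span_range != (0, 0):
            for g in groups[1:]:
                miss = int(rng.integers(missing_span_range[0], missing_span_range[1] + 1))
                s0, e0 = g[0]
                if e0 - s0 > miss + 1:
                    g[0] = (s0 + miss, e0)
        frag_counter = 0
        for group in groups:
            scaffold_idx += 1
            name = f"scaffold_{scaffold_idx}"
            strand = "+" if rng.random() < 0.5 else "-"
            frag_ids = []
            for s, e in group:
                frag_counter += 1
                fid = f"{chrom}_frag{frag_counter}"
                tmap.placements[fid] = Placement(chrom, s, e, strand)
                frag_ids.append(fid)
            gaps = [
                int(rng.integers(gap_len_range[0], gap_len_range[1] + 1))
                for _ in range(len(group) - 1)
            ]
            if strand == "-":
                frag_ids = frag_ids[::-1]
                gaps = gaps[::-1]
            segs: list[Segment] = []
            for j, fid in enumerate(frag_ids):
                p = tmap.placements[fid]
                segs.append(Segment(fid, p.end - p.start, strand))
                if j < len(gaps) and gaps[j] > 0:
                    segs.append(Segment(None, gaps[j]))
            tmap.layouts[name] = segs
            assembly.add(name, tmap.emit_scaffold(name, truth))
    return assembly, tmap


def _normalized(segs: list[Segment]) -> tuple[list[Segment], bool]:
    """Flip a scaffold layout to '+' orientation if it was emitted on '-'."""
    frag_strands = {s.strand for s in segs if not s.is_gap}
    if frag_strands == {"-"}:
        flipped = [replace(s, strand="+") if not s.is_gap else s for s in reversed(segs)]
        return flipped, True
    return list(segs), False


def scaffold_draft(
    draft: Assembly,
    truth_map: TruthMap,
    join_gap: int = 1000,
    join_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Assembly, TruthMap]:
    """Join draft scaffolds chromosome-by-chromosome with fixed-size N gaps.

    Emulates proximity-ligation scaffolding: scaffolds belonging to the same
    chromosome are oriented and concatenated in truth order, every join
    bridged by ``join_gap`` Ns (the fixed placeholder such scaffolders emit).
    With probability ``join_error_rate`` a join is made wrong — the appended
    scaffold is inverted or out of order — and logged ``correct=False``.
    """
    if not 0 <= join_error_rate <= 1:
        raise ValueError("join_error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # bucket scaffolds by chromosome, in truth order
    order: dict[str, list[tuple[int, str]]] = {}
    for scaffold, segs in truth_map.layouts.items():
        frag_ids = [s.frag_id for s in segs if not s.is_gap]
        starts = [truth_map.placements[f].start for f in frag_ids]
        chrom = truth_map.placements[frag_ids[0]].chrom
        order.setdefault(chrom, []).append((min(starts), scaffold))

    new_map = TruthMap(
        placements=dict(truth_map.placements),
        probe_labels=dict(truth_map.probe_labels),
        probe_truth=dict(truth_map.probe_truth),
        fill_ledger=list(truth_map.fill_ledger),
    )
    out = Assembly()
    for chrom in sorted(order, key=lambda c: (len(c), c)):
        queue = [scaf for _, scaf in sorted(order[chrom])]
        name = f"scf_{chrom}"
        merged: list[Segment] = []
        flip_next = False
        i = 0
        while i < len(queue):
            scaffold = queue[i]
            segs, flipped = _normalized(truth_map.layouts[scaffold])
            correct = True
            if merged and rng.random() < join_error_rate:
                correct = False
                mode = rng.choice(["invert", "swap"]) if i + 1 < len(queue) else "invert"
                if mode == "swap":
                    queue[i], queue[i + 1] = queue[i + 1], queue[i]
                    scaffold = queue[i]
                    segs, flipped = _normalized(truth_map.layouts[scaffold])
                else:
                    # append inverted: reverse segments, flip strands
                    segs = [
                        s if s.is_gap else replace(s, strand="-" if s.strand == "+" else "+")
                        for s in reversed(segs)
                    ]
                    flipped = not flipped
            # record final strands in placements
            for s in segs:
                if not s.is_gap:
                    p = new_map.placements[s.frag_id]
                    new_map.placements[s.frag_id] = replace(p, strand=s.strand)
            if merged:
                merged.append(Segment(None, join_gap))
                new_map.join_ledger.append(
                    JoinRecord(
                        scaffold=name,
                        fragments=tuple(s.frag_id for s in segs if not s.is_gap),
                        gap=join_gap,
                        correct=correct,
                    )
                )
            merged.extend(segs)
            i += 1
        new_map.layouts[name] = merged
        # emitting needs the truth genome; rebuild from the draft instead so
        # the op only needs the draft assembly it was given
        parts = []
        for seg, src in _segments_with_source(merged, truth_map, draft):
            parts.append(src)
        out.add(name, "".join(parts))
    return out, new_map


def _segments_with_source(
    segs: list[Segment], old_map: TruthMap, draft: Assembly
):
    """Yield (segment, sequence) pulling fragment sequence out of the draft."""
    # fragment -> (scaffold, lo, hi, emitted strand in draft)
    index: dict[str, tuple[str, int, int, str]] = {}
    for scaffold in old_map.layouts:
        offsets = old_map.fragment_offsets(scaffold)
        for seg in old_map.layouts[scaffold]:
            if not seg.is_gap:
                lo, hi = offsets[seg.frag_id]
                index[seg.frag_id] = (scaffold, lo, hi, seg.strand)
    for seg in segs:
        if seg.is_gap:
            yield seg, "N" * seg.length
        else:
            scaffold, lo, hi, old_strand = index[seg.frag_id]
            s = draft[scaffold][lo:hi]
            if old_strand != seg.strand:
                s = reverse_complement(s)
            yield seg, s


def fill_gaps_synthetic(
    scaffolded: Assembly,
    truth: TruthGenome,
    truth_map: TruthMap,
    fill_rate: float = 1.0,
    seed: int = 0,
) -> tuple[Assembly, TruthMap]:
    """Replace N-gap placeholders with the true inter-fragment sequence.

    Each gap flanked by fragments that are truth-adjacent on the same strand
    is, with probability ``fill_rate``, replaced by the genuine sequence
    between them — which may be longer (over-fill) or shorter (under-fill,
    down to zero) than the placeholder. Gaps created by an incorrect join
    have no true fill and are left untouched. The fill ledger records
    placeholder and true lengths for every gap considered.
    """
    if not 0 <= fill_rate <= 1:
        raise ValueError("fill_rate must be in [0, 1]")
    if truth_map.gap_count() == 0:
        raise ValueError("assembly has no gaps to fill")
    rng = np.random.default_rng(seed)
    new_map = TruthMap(
        placements=dict(truth_map.placements),
        probe_labels=dict(truth_map.probe_labels),
        probe_truth=dict(truth_map.probe_truth),
        join_ledger=list(truth_map.join_ledger),
        fill_ledger=list(truth_map.fill_ledger),
    )
    out = Assembly()
    for scaffold in truth_map.layouts:
        segs = list(truth_map.layouts[scaffold])  # working copy; input untouched
        new_segs: list[Segment] = []
        gap_index = -1
        for k, seg in enumerate(segs):
            if not seg.is_gap:
                new_segs.append(seg)
                continue
            gap_index += 1
            left = segs[k - 1] if k > 0 else None
            right = segs[k + 1] if k + 1 < len(segs) else None
            true_len = _true_fill_length(left, right, new_map)
            fillable = true_len is not None
            do_fill = fillable and rng.random() < fill_rate
            new_map.fill_ledger.append(
                FillRecord(
                    scaffold=scaffold,
                    gap_index=gap_index,
                    placeholder_len=seg.length,
                    true_len=true_len if true_len is not None else -1,
                    filled=bool(do_fill),
                )
            )
            if not do_fill:
                new_segs.append(seg)
                continue
            # merge left + fill + right into one extended fragment
            lp = new_map.placements[left.frag_id]
            rp = new_map.placements[right.frag_id]
            lo = min(lp.start, rp.start)
            hi = max(lp.end, rp.end)
            merged = Placement(lp.chrom, lo, hi, lp.strand)
            # drop right fragment; extend left
            new_map.placements[left.frag_id] = merged
            del new_map.placements[right.frag_id]
            # left is already in new_segs: replace it with the merged span and
            # mark the upcoming right fragment consumed
            new_segs[-1] = Segment(left.frag_id, hi - lo, lp.strand)
            segs[k + 1] = Segment(left.frag_id, 0, lp.strand)  # sentinel, skipped
        new_segs = [s for s in new_segs if s.length > 0]
        # collapse duplicate ids introduced by chained fills
        collapsed: list[Segment] = []
        for s in new_segs:
            if collapsed and not s.is_gap and collapsed[-1].frag_id == s.frag_id:
                continue
            collapsed.append(s)
        # refresh lengths from placements (chained merges grow the span)
        refreshed = [
            s
            if s.is_gap
            else Segment(
                s.frag_id,
                new_map.placements[s.frag_id].end - new_map.placements[s.frag_id].start,
                s.strand,
            )
            for s in collapsed
        ]
        new_map.layouts[scaffold] = refreshed
        out.add(scaffold, new_map.emit_scaffold(scaffold, truth))
    return out, new_map


def _true_fill_length(
    left: Segment | None, right: Segment | None, tmap: TruthMap
) -> int | None:
    """Length of the genuine sequence behind a gap, or None if unfillable."""
    if left is None or right is None or left.is_gap or right.is_gap:
        return None
    if left.frag_id not in tmap.placements or right.frag_id not in tmap.placements:
        return None
    lp = tmap.placements[left.frag_id]
    rp = tmap.placements[right.frag_id]
    if lp.chrom != rp.chrom or lp.strand != rp.strand:
        return None
    if lp.strand == "+":
        span = rp.start - lp.end
    else:
        span = lp.start - rp.end
    return span if span >= 0 else None


def generate_probes(
    truth: TruthGenome,
    n_per_chrom: int,
    probe_len: int = 120,
    mutation_rate: float = 0.0,
    mislabel_rate: float = 0.0,
    seed: int = 0,
    avoid_repeats: bool = True,
) -> tuple[Assembly, dict[str, str], dict[str, str]]:
    """Draw chromosome-labelled marker probes from the truth genome.

    Emulates a radiation-hybrid marker panel: each probe is a substring of a
    known chromosome with per-base substitutions at ``mutation_rate``; with
    probability ``mislabel_rate`` the recorded label is swapped to a
    different chromosome (the true origin is returned separately). Marker
    panels are designed away from repetitive sequence, so by default probe
    positions overlapping annotated repeat intervals are rejected
    (``avoid_repeats=False`` disables the rejection).

    Returns ``(probes, labels, true_origin)`` where labels maps probe id to
    its (possibly wrong) chromosome label.
    """
    shortest = min(len(s) for _, s in truth.chromosomes)
    if probe_len >= shortest:
        raise ValueError("probe_len must be below the shortest chromosome")
    rng = np.random.default_rng(seed)
    names = truth.chromosomes.names
    repeat_ivs: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    if avoid_repeats:
        for chrom, s, e, _ in truth.repeats:
            repeat_ivs[chrom].append((s, e))
    probes = Assembly()
    labels: dict[str, str] = {}
    true_origin: dict[str, str] = {}
    for chrom in names:
        seq = truth.chromosomes[chrom]
        for j in range(n_per_chrom):
            pid = f"probe_{chrom}_{j + 1}"
            start = int(rng.integers(0, len(seq) - probe_len))
            for _ in range(200):  # reject repeat-overlapping positions
                end = start + probe_len
                if not any(s < end and start < e for s, e in repeat_ivs[chrom]):
                    break
                start = int(rng.integers(0, len(seq) - probe_len))
            probes.add(pid, _mutate(rng, seq[start : start + probe_len], mutation_rate))
            true_origin[pid] = chrom
            label = chrom
            if len(names) > 1 and rng.random() < mislabel_rate:
                others = [c for c in names if c != chrom]
                label = others[int(rng.integers(0, len(others)))]
            labels[pid] = label
    return probes, labels, true_origin


def generate_reads(
    truth: TruthGenome,
    coverage: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    insert_range: tuple[int, int] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Simulate paired-end short reads with substitution errors.

    The pair count is ``round(coverage * genome_size / (2 * read_len))``;
    pairs are placed uniformly, the mate read reverse-complemented, errors
    are substitutions only. Returns (R1, R2) lists of (read id, sequence).
    """
    shortest = min(len(s) for _, s in truth.chromosomes)
    if read_len > shortest:
        raise ValueError("read_len must not exceed the shortest chromosome")
    if coverage < 0 or error_rate < 0:
        raise ValueError("coverage and error_rate must be non-negative")
    genome_size = truth.chromosomes.total_size
    n_pairs = int(round(coverage * genome_size / (2 * read_len)))
    if n_pairs == 0:
        return [], []
    if insert_range is None:
        insert_range = (2 * read_len, min(3 * read_len, shortest))
    rng = np.random.default_rng(seed)
    names = truth.chromosomes.names
    lens = np.array([len(truth.chromosomes[c]) for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_pairs, p=lens / lens.sum())
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    for i in range(n_pairs):
        chrom = names[chrom_idx[i]]
        seq = truth.chromosomes[chrom]
        insert = int(rng.integers(insert_range[0], insert_range[1] + 1))
        insert = min(insert, len(seq))
        pos = int(rng.integers(0, len(seq) - insert + 1))
        fwd = seq[pos : pos + read_len]
        rev = reverse_complement(seq[pos + insert - read_len : pos + insert])
        r1.append((f"read_{i + 1}/1", _mutate(rng, fwd, error_rate)))
        r2.append((f"read_{i + 1}/2", _mutate(rng, rev, error_rate)))
    return r1, r2


def write_fastq(reads: list[tuple[str, str]], path, quality: str = "I") -> None:
    """Write reads as FASTQ with a flat Phred+33 quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")


def generate_annotation(
    truth: TruthGenome,
    n_genes: int,
    seed: int = 0,
    truncated_fraction: float = 0.3,
    aed_uniform_weight: float = 0.2,
) -> tuple[str, pd.DataFrame]:
    """Emit a nested gene/mRNA/exon/CDS GFF3 annotation plus a protein table.

    AED (annotation edit distance, the [0,1] disagreement between a gene
    model and its evidence) is drawn per mRNA from a mixture: a Beta(2, 8)
    component peaked near 0.2 (well-supported models) plus a uniform tail
    with weight ``aed_uniform_weight``. The protein table holds
    (query_id, subject_id, query_len, subject_len) rows in which a
    ``truncated_fraction`` of predicted proteins are shorter than 0.85x
    their database subject.
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    rows = []
    names = truth.chromosomes.names
    gene_id = 0
    attempts = 0
    while gene_id < n_genes and attempts < 50 * max(n_genes, 1):
        attempts += 1
        chrom = names[int(rng.integers(0, len(names)))]
        L = len(truth.chromosomes[chrom])
        n_exons = int(rng.integers(1, 11))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(100, 1001, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        if span + 2 >= L:
            continue
        gene_id += 1
        gid = f"gene{gene_id}"
        gstart = int(rng.integers(1, L - span))  # 1-based
        strand = "+" if rng.random() < 0.5 else "-"
        gend = gstart + span - 1
        lines.append(
            f"{chrom}\tsynth\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        n_mrna = int(rng.integers(1, 4))
        for m in range(n_mrna):
            mid = f"{gid}.m{m + 1}"
            if rng.random() < aed_uniform_weight:
                aed = float(rng.uniform(0, 1))
            else:
                aed = float(rng.beta(2, 8))
            lines.append(
                f"{chrom}\tsynth\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={mid};Parent={gid};_AED={aed:.3f}"
            )
            pos = gstart
            for e in range(n_exons):
                estart = pos
                eend = pos + int(exon_lens[e]) - 1
                lines.append(
                    f"{chrom}\tsynth\texon\t{estart}\t{eend}\t.\t{strand}\t.\t"
                    f"ID={mid}.e{e + 1};Parent={mid}"
                )
                lines.append(
                    f"{chrom}\tsynth\tCDS\t{estart}\t{eend}\t.\t{strand}\t0\t"
                    f"ID={mid}.c;Parent={mid}"
                )
                if e < n_exons - 1:
                    pos = eend + 1 + int(intron_lens[e])
                else:
                    pos = eend + 1
            # protein hit row for this mRNA
            subject_len = int(rng.integers(120, 1200))
            if rng.random() < truncated_fraction:
                ratio = float(rng.uniform(0.25, 0.80))
                query_len = max(1, int(np.floor(ratio * subject_len)))
            else:
                ratio = float(rng.uniform(0.87, 1.13))
                query_len = int(np.clip(round(ratio * subject_len),
                                        np.ceil(0.85 * subject_len),
                                        np.floor(1.15 * subject_len)))
            rows.append((mid, f"sp|{mid}", query_len, subject_len))
    table = pd.DataFrame(rows, columns=["query_id", "subject_id", "query_len", "subject_len"])
    return "\n".join(lines) + "\n", table
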