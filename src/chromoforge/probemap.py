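"""Chromosome assignment of scaffolds by marker-probe best-hit voting.

Short marker probes with known chromosome labels (e.g. from a radiation-
hybrid map of a karyotypically conserved relative) are aligned to the
scaffolds of an assembly; per probe only the most significant hit passing an
E-value ceiling (1e-30 by default) is kept, and each chromosome is assigned
the scaffold collecting the most best hits from its probe set. Per-
chromosome concordance (majority share of the vote) and the unassigned
residue of the assembly are reported.

Hits may come from BLAST tabular output (outfmt 6) or from the built-in
ungapped seed-and-extend aligner, which exists so the whole procedure runs
self-contained on synthetic data. The built-in aligner uses exact seeding,
+1/-2 ungapped extension with an X-drop, and Karlin-Altschul E-values with
the published ungapped DNA parameters (lambda = 1.33, K = 0.621), so its
scores rank hits the same way blastn's do on substitution-only data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .asmstats import AssemblyStats, round_half_up
from .assembly import Assembly, reverse_complement

__all__ = [
    "ProbeHit",
    "ChromosomeAssignment",
    "AssignmentReport",
    "align_probes",
    "best_hit_per_probe",
    "vote_assignments",
    "assignment_report",
    "read_blast_tab",
    "write_blast_tab",
]

_LAMBDA = 1.33  # ungapped Karlin-Altschul, match +1 / mismatch -2
_K = 0.621
_MATCH = 1
_MISMATCH = -2
_XDROP = 20


@dataclass(frozen=True)
class ProbeHit:
    """One probe-vs-scaffold local alignment, BLAST outfmt-6 shaped.

    Coordinates are 1-based inclusive; minus-strand hits carry
    ``s_start > s_end`` as in BLAST tabular output.
    """

    probe: str
    scaffold: str
    identity_pct: float
    length: int
    mismatches: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"


def read_blast_tab(path: str | Path) -> list[ProbeHit]:
    """Parse BLAST tabular outfmt 6 (12 standard columns; gapopen ignored)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                ProbeHit(
                    probe=f[0], scaffold=f[1],
                    identity_pct=float(f[2]), length=int(f[3]),
                    mismatches=int(f[4]),
                    q_start=int(f[6]), q_end=int(f[7]),
                    s_start=int(f[8]), s_end=int(f[9]),
                    e_value=float(f[10]), bit_score=float(f[11]),
                )
            )
    return hits


def write_blast_tab(hits: list[ProbeHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.probe}\t{h.scaffold}\t{h.identity_pct:.2f}\t{h.length}\t"
                f"{h.mismatches}\t0\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
                f"{h.s_end}\t{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Built-in aligner


def _seed_index(assembly: Assembly, seed_len: int) -> dict[int, list[tuple[str, int]]]:
    """seed hash -> [(scaffold, start position), ...] over forward strands."""
    index: dict[int, list[tuple[str, int]]] = {}
    for name, seq in assembly:
        s = seq.upper()
        for pos in range(len(s) - seed_len + 1):
            window = s[pos : pos + seed_len]
            if "N" in window:
                continue
            index.setdefault(hash(window), []).append((name, pos))
    return index


def _extend(query: str, subject: str, q_anchor: int, s_anchor: int, seed_len: int):
    """Ungapped X-drop extension of an exact seed in both directions.

    Returns (score, q_start, q_end, matches, length), query coords 0-based
    half-open.
    """
    score = seed_len * _MATCH
    best = score
    # right
    qi, si = q_anchor + seed_len, s_anchor + seed_len
    best_q_end = qi
    cur = score
    while qi < len(query) and si < len(subject):
        cur += _MATCH if query[qi] == subject[si] else _MISMATCH
        qi += 1
        si += 1
        if cur > best:
            best, best_q_end = cur, qi
        elif best - cur > _XDROP:
            break
    # left
    cur = best
    final = best
    qi, si = q_anchor - 1, s_anchor - 1
    best_q_start = q_anchor
    while qi >= 0 and si >= 0:
        cur += _MATCH if query[qi] == subject[si] else _MISMATCH
        if cur > final:
            final, best_q_start = cur, qi
        elif final - cur > _XDROP:
            break
        qi -= 1
        si -= 1
    length = best_q_end - best_q_start
    # matches from score: score = matches*1 + mismatches*(-2), length = m + mm
    mismatches = (length - final) // (_MATCH - _MISMATCH)
    matches = length - mismatches
    return final, best_q_start, best_q_end, matches, length


def _bit_score(score: int) -> float:
    return (_LAMBDA * score - math.log(_K)) / math.log(2)


def _e_value(score: int, m: int, n: int) -> float:
    return _K * m * n * math.exp(-_LAMBDA * score)


def align_probes(
    probes: Assembly,
    assembly: Assembly,
    seed_len: int = 16,
    min_identity: float = 0.9,
) -> list[ProbeHit]:
    """Map probes to scaffolds with the built-in ungapped aligner.

    Exact seeds of ``seed_len`` are extended both ways (+1 match / -2
    mismatch, X-drop 20); the best-scoring local match per (probe, scaffold)
    over both strands is reported when its identity exceeds
    ``min_identity``. Probes shorter than the seed are skipped with a
    warning. Substitution-only data is the intended regime (the extension
    is ungapped).
    """
    if len(probes) == 0:
        raise ValueError("no probes given")
    index = _seed_index(assembly, seed_len)
    db_len = assembly.total_size
    upper = {name: seq.upper() for name, seq in assembly}
    hits: list[ProbeHit] = []
    for pid, pseq in probes:
        if len(pseq) < seed_len:
            warnings.warn(f"probe {pid} shorter than seed length; skipped", stacklevel=2)
            continue
        best_per_scaffold: dict[str, tuple[int, ProbeHit]] = {}
        for strand, query in (("+", pseq.upper()), ("-", reverse_complement(pseq).upper())):
            tried: set[tuple[str, int]] = set()
            for q_pos in range(len(query) - seed_len + 1):
                window = query[q_pos : q_pos + seed_len]
                if "N" in window:
                    continue
                for scaffold, s_pos in index.get(hash(window), ()):
                    subject = upper[scaffold]
                    if subject[s_pos : s_pos + seed_len] != window:
                        continue  # hash collision guard
                    diag = s_pos - q_pos
                    if (scaffold, diag) in tried:
                        continue
                    tried.add((scaffold, diag))
                    score, q0, q1, matches, length = _extend(
                        query, subject, q_pos, s_pos, seed_len
                    )
                    if length == 0 or matches / length <= min_identity:
                        continue
                    s0 = diag + q0
                    s1 = diag + q1
                    if strand == "+":
                        q_start, q_end = q0 + 1, q1
                        s_start, s_end = s0 + 1, s1
                    else:
                        # query was the reverse complement: map back
                        q_start = len(pseq) - q1 + 1
                        q_end = len(pseq) - q0
                        s_start, s_end = s1, s0 + 1
                    hit = ProbeHit(
                        probe=pid,
                        scaffold=scaffold,
                        identity_pct=100.0 * matches / length,
                        length=length,
                        mismatches=length - matches,
                        q_start=q_start,
                        q_end=q_end,
                        s_start=s_start,
                        s_end=s_end,
                        e_value=_e_value(score, len(pseq), db_len),
                        bit_score=round(_bit_score(score), 1),
                    )
                    prev = best_per_scaffold.get(scaffold)
                    if prev is None or score > prev[0]:
                        best_per_scaffold[scaffold] = (score, hit)
        hits.extend(v[1] for _, v in sorted(best_per_scaffold.items()))
    return hits


# ---------------------------------------------------------------------------
# Best-hit filtering and voting


def best_hit_per_probe(
    hits: list[ProbeHit], e_max: float = 1e-30
) -> dict[str, ProbeHit]:
    """Keep each probe's most significant hit passing the E-value ceiling.

    Most significant means lowest numeric E-value; ties break by higher bit
    score, then lexicographic scaffold name. Probes whose hits all fail
    ``e_max`` are absent from the result.
    """
    best: dict[str, ProbeHit] = {}
    for h in hits:
        if h.e_value > e_max:
            continue
        cur = best.get(h.probe)
        if cur is None or (h.e_value, -h.bit_score, h.scaffold) < (
            cur.e_value,
            -cur.bit_score,
            cur.scaffold,
        ):
            best[h.probe] = h
    return best


@dataclass
class ChromosomeAssignment:
    """Voted chromosome -> scaffold map with concordance bookkeeping."""

    #: chromosome -> (primary scaffold, primary votes)
    primary: dict[str, tuple[str, int]] = field(default_factory=dict)
    #: chromosome -> runner-up (scaffold, votes) list, votes descending
    runners_up: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    #: chromosome -> primary votes / passing probes for that chromosome
    concordance: dict[str, float] = field(default_factory=dict)
    unassigned_chromosomes: list[str] = field(default_factory=list)
    probes_without_hit: int = 0


def vote_assignments(
    best_hits: dict[str, ProbeHit],
    probe_labels: dict[str, str],
) -> ChromosomeAssignment:
    """Assign each chromosome the scaffold its probe set hits most often.

    Vote ties break by larger summed bit score, then lexicographic scaffold
    name. A scaffold may be primary for at most one chromosome: when two
    chromosomes top-vote the same scaffold, the higher-concordance
    chromosome keeps it and the other falls back to its next-best scaffold,
    iterated to a fixpoint. Chromosomes whose probes all lack passing hits
    are reported unassigned.
    """
    unlabeled = [p for p in best_hits if p not in probe_labels]
    if unlabeled:
        raise ValueError(f"probes without a chromosome label: {sorted(unlabeled)[:5]}")
    votes: dict[str, dict[str, int]] = {}
    bits: dict[str, dict[str, float]] = {}
    passing: dict[str, int] = {}
    for probe, hit in best_hits.items():
        chrom = probe_labels[probe]
        votes.setdefault(chrom, {})
        bits.setdefault(chrom, {})
        votes[chrom][hit.scaffold] = votes[chrom].get(hit.scaffold, 0) + 1
        bits[chrom][hit.scaffold] = bits[chrom].get(hit.scaffold, 0.0) + hit.bit_score
        passing[chrom] = passing.get(chrom, 0) + 1

    all_chroms = sorted(set(probe_labels.values()))
    ranked: dict[str, list[tuple[str, int]]] = {}
    for chrom in votes:
        order = sorted(
            votes[chrom],
            key=lambda s: (-votes[chrom][s], -bits[chrom][s], s),
        )
        ranked[chrom] = [(s, votes[chrom][s]) for s in order]

    # iterate: each chromosome takes its best-ranked scaffold not yet owned
    # by a stronger claim (higher concordance, then more votes, then name)
    choice_idx = {c: 0 for c in ranked}
    while True:
        claims: dict[str, list[str]] = {}
        for chrom in ranked:
            if choice_idx[chrom] < len(ranked[chrom]):
                scaffold = ranked[chrom][choice_idx[chrom]][0]
                claims.setdefault(scaffold, []).append(chrom)
        moved = False
        for scaffold, claimants in claims.items():
            if len(claimants) <= 1:
                continue

            def strength(c: str) -> tuple:
                v = ranked[c][choice_idx[c]][1]
                return (v / passing[c], v, c)

            winner = max(claimants, key=strength)
            for c in claimants:
                if c != winner:
                    choice_idx[c] += 1
                    moved = True
        if not moved:
            break

    assignment = ChromosomeAssignment(
        probes_without_hit=len(probe_labels) - len(best_hits)
    )
    for chrom in all_chroms:
        if chrom not in ranked or choice_idx[chrom] >= len(ranked[chrom]):
            assignment.unassigned_chromosomes.append(chrom)
            continue
        scaffold, v = ranked[chrom][choice_idx[chrom]]
        assignment.primary[chrom] = (scaffold, v)
        assignment.runners_up[chrom] = [
            (s, n) for s, n in ranked[chrom] if s != scaffold
        ]
        assignment.concordance[chrom] = v / passing[chrom]
    return assignment


@dataclass(frozen=True)
class AssignmentReport:
    """Summary of a chromosome assignment against assembly totals."""

    mean_concordance: float
    sd_concordance: float
    assigned_bases: int
    unassigned_bases: int
    unassigned_percent: float  # of total size, half-up 2 decimals
    rename_table: dict[str, str]  # chromosome label -> primary scaffold


def assignment_report(
    assignment: ChromosomeAssignment,
    stats: AssemblyStats,
    assembly: Assembly,
    population_sd: bool = False,
) -> AssignmentReport:
    """Concordance summary and unassigned-content accounting.

    Unassigned bases are the assembly total minus the summed lengths of the
    primary scaffolds; the percentage is rendered half-up to 2 decimals.
    SD of concordance is the sample SD by default (``ddof=1``).
    """
    conc = np.array(sorted(assignment.concordance.values()), dtype=float)
    if conc.size == 0:
        raise ValueError("assignment has no concordance values")
    ddof = 0 if population_sd or conc.size == 1 else 1
    lengths = assembly.lengths()
    assigned = sum(lengths[s] for s, _ in assignment.primary.values())
    unassigned = stats.total_size - assigned
    return AssignmentReport(
        mean_concordance=float(conc.mean()),
        sd_concordance=float(conc.std(ddof=ddof)),
        assigned_bases=assigned,
        unassigned_bases=unassigned,
        unassigned_percent=round_half_up(100.0 * unassigned / stats.total_size, 2),
        rename_table={c: s for c, (s, _) in assignment.primary.items()},
    )
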