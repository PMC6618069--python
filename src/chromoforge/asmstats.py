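"""Assembly contiguity statistics and version-to-version comparison.

Implements the standard scaffold/contig metric set used to benchmark genome
assembly upgrades: total size, gap content, N50/N90 and L50/L90 at both the
scaffold and contig level (contigs obtained by splitting scaffolds at N-runs
of at least ``min_gap_len`` bases, 25 by default), cumulative-length curves,
and a comparison ledger between two assembly versions (bases added, gaps
closed, scaffolds merged, fold changes).

N50 is the length of the shortest sequence in the smallest set of longest
sequences that together cover at least 50% of the assembly; L50 is the size
of that set. N90/L90 are the same at 90%.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .assembly import Assembly

__all__ = [
    "AssemblyStats",
    "ComparisonReport",
    "split_into_contigs",
    "nx_lx",
    "compute_stats",
    "compare_stats",
    "cumulative_curve",
    "sequencing_coverage",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as report tables expect.

    Python's built-in round() is banker's rounding; assembly reports
    conventionally print 99.325 as 99.33, not 99.32.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def split_into_contigs(sequence: str, min_gap_len: int = 25) -> list[str]:
    """Split a scaffold into contigs at N-runs of length >= ``min_gap_len``.

    Runs of N/n shorter than the threshold are retained inside a contig;
    leading/trailing gap runs produce no empty contigs. A sequence that is
    all Ns yields an empty list.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    parts = re.split(f"[Nn]{{{min_gap_len},}}", sequence)
    return [p for p in parts if p]


def nx_lx(lengths: Sequence[int], fraction: float) -> tuple[int, int]:
    """Return (Nx, Lx) for a length multiset at the given fraction.

    Lengths are sorted descending; Nx is the length at which the running sum
    first reaches ``fraction`` of the total, Lx its 1-based rank.
    """
    if not lengths:
        raise ValueError("empty length collection")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if any(l < 1 for l in lengths):
        raise ValueError("lengths must be >= 1")
    ordered = sorted(lengths, reverse=True)
    threshold = fraction * sum(ordered)
    running = 0
    for rank, length in enumerate(ordered, start=1):
        running += length
        if running >= threshold:
            return length, rank
    # unreachable: running sum ends at the total >= threshold
    raise AssertionError("running sum never reached threshold")


@dataclass(frozen=True)
class AssemblyStats:
    """Table of contiguity metrics for one assembly version."""

    total_size: int
    gap_length: int
    scaffold_count: int
    longest_scaffold: int
    scaffold_n50: int
    scaffold_l50: int
    scaffold_n90: int
    scaffold_l90: int
    contig_count: int
    longest_contig: int
    contig_n50: int
    contig_l50: int
    contig_n90: int
    contig_l90: int
    min_gap_len: int = 25

    def to_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_stats(assembly: Assembly, min_gap_len: int = 25) -> AssemblyStats:
    """Compute scaffold- and contig-level statistics for an assembly.

    ``gap_length`` counts every N/n base in the assembly (independent of the
    contig-splitting threshold); contig metrics are computed over the
    concatenation of ``split_into_contigs`` output across scaffolds.
    """
    scaffold_lengths = [len(s) for _, s in assembly]
    if not scaffold_lengths:
        raise ValueError("assembly has no sequences")
    contig_lengths: list[int] = []
    gap_length = 0
    for _, seq in assembly:
        gap_length += seq.count("N") + seq.count("n")
        contig_lengths.extend(len(c) for c in split_into_contigs(seq, min_gap_len))
    s_n50, s_l50 = nx_lx(scaffold_lengths, 0.5)
    s_n90, s_l90 = nx_lx(scaffold_lengths, 0.9)
    if contig_lengths:
        c_n50, c_l50 = nx_lx(contig_lengths, 0.5)
        c_n90, c_l90 = nx_lx(contig_lengths, 0.9)
        longest_contig = max(contig_lengths)
    else:  # all-N assembly
        c_n50 = c_l50 = c_n90 = c_l90 = longest_contig = 0
    return AssemblyStats(
        total_size=sum(scaffold_lengths),
        gap_length=gap_length,
        scaffold_count=len(scaffold_lengths),
        longest_scaffold=max(scaffold_lengths),
        scaffold_n50=s_n50,
        scaffold_l50=s_l50,
        scaffold_n90=s_n90,
        scaffold_l90=s_l90,
        contig_count=len(contig_lengths),
        longest_contig=longest_contig,
        contig_n50=c_n50,
        contig_l50=c_l50,
        contig_n90=c_n90,
        contig_l90=c_l90,
        min_gap_len=min_gap_len,
    )


_FOLD_STATS = (
    "total_size",
    "longest_scaffold",
    "scaffold_n50",
    "scaffold_n90",
    "longest_contig",
    "contig_n50",
    "contig_n90",
)


@dataclass(frozen=True)
class ComparisonReport:
    """Version-to-version delta ledger between two AssemblyStats."""

    bases_added: int  # signed, B - A
    gap_bases_delta: int  # signed, B - A
    scaffolds_merged: int  # A count - B count, negative if B has more
    contigs_delta: int
    fold_changes: dict[str, float] = field(default_factory=dict)
    deltas: dict[str, int] = field(default_factory=dict)

    @property
    def bases_added_mbp(self) -> float:
        """Signed size change rendered in Mbp, half-up to 2 decimals."""
        return round_half_up(self.bases_added / 1e6, 2)


def compare_stats(a: AssemblyStats, b: AssemblyStats) -> ComparisonReport:
    """Compare two versions of the same genome (A = before, B = after)."""
    if a.min_gap_len != b.min_gap_len:
        raise ValueError(
            "incomparable statistics: min_gap_len "
            f"{a.min_gap_len} != {b.min_gap_len}"
        )
    deltas = {k: getattr(b, k) - getattr(a, k) for k in a.to_dict() if k != "min_gap_len"}
    folds = {}
    for k in _FOLD_STATS:
        va, vb = getattr(a, k), getattr(b, k)
        if va > 0 and vb > 0:
            folds[k] = vb / va
    return ComparisonReport(
        bases_added=b.total_size - a.total_size,
        gap_bases_delta=b.gap_length - a.gap_length,
        scaffolds_merged=a.scaffold_count - b.scaffold_count,
        contigs_delta=b.contig_count - a.contig_count,
        fold_changes=folds,
        deltas=deltas,
    )


def cumulative_curve(lengths: Sequence[int]) -> list[tuple[int, int]]:
    """(rank, cumulative bp) pairs over descending-sorted lengths.

    The final point is (n, total size); plotting these reproduces the
    standard cumulative assembly-length figure, with L50/L90 recoverable
    via :func:`nx_lx`.
    """
    if not lengths:
        raise ValueError("empty length collection")
    ordered = sorted(lengths, reverse=True)
    points = []
    running = 0
    for rank, length in enumerate(ordered, start=1):
        running += length
        points.append((rank, running))
    return points


def sequencing_coverage(total_bases: int, genome_size_estimate: int) -> float:
    """Fold coverage of a read set over a genome-size estimate.

    Returns the raw quotient; render with ``round_half_up(x, 2)`` for
    report parity (e.g. 24,832,304,602 bases over 2.27 Gbp -> 10.94x).
    """
    if genome_size_estimate <= 0:
        raise ValueError("genome size estimate must be positive")
    return total_bases / genome_size_estimate
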