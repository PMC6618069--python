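"""Whole-genome-alignment ingestion, dot-plot filtering and orientation calls.

Consumes pairwise alignments in PAF (minimap2 dialect, 0-based half-open),
applies the dot-plot match filters used when comparing assembly versions
(drop matches spanning <= a fraction of the plot width or <= an identity
floor), orders query sequences along the reference the way dot-plot viewers
sort contigs, infers per-query orientation by strand-weighted majority of
matching bases, and applies reverse-complement + renaming to an assembly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .assembly import Assembly, reverse_complement
from .synthio import TruthGenome, TruthMap

__all__ = [
    "AlignMatch",
    "OrientationCall",
    "read_paf",
    "write_paf",
    "filter_matches",
    "order_queries",
    "infer_orientation",
    "apply_orientations",
    "dotplot_export",
    "matches_from_truth",
]


@dataclass(frozen=True)
class AlignMatch:
    """One alignment block (PAF columns 1-12)."""

    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    block_len: int
    mapq: int = 255

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query interval in match {self.query}")
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(f"bad target interval in match {self.query}->{self.target}")
        if self.n_match > self.block_len:
            raise ValueError("n_match exceeds block_len")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.n_match / self.block_len


def read_paf(path: str | Path) -> list[AlignMatch]:
    """Parse PAF columns 1-12; SAM-style tag columns are ignored."""
    matches = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{line_no}: PAF needs >= 12 columns")
            matches.append(
                AlignMatch(
                    query=f[0], query_len=int(f[1]),
                    query_start=int(f[2]), query_end=int(f[3]),
                    strand=f[4],
                    target=f[5], target_len=int(f[6]),
                    target_start=int(f[7]), target_end=int(f[8]),
                    n_match=int(f[9]), block_len=int(f[10]), mapq=int(f[11]),
                )
            )
    return matches


def write_paf(matches: Iterable[AlignMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.query, m.query_len, m.query_start, m.query_end,
                        m.strand,
                        m.target, m.target_len, m.target_start, m.target_end,
                        m.n_match, m.block_len, m.mapq,
                    )
                )
                + "\n"
            )


def filter_matches(
    matches: Sequence[AlignMatch],
    width_fraction: float = 1e-5,
    min_identity: float = 0.75,
) -> list[AlignMatch]:
    """Dot-plot match filter: drop small and low-identity matches.

    A match is kept iff ``block_len > width_fraction * total_target_length``
    and ``identity > min_identity`` (both thresholds strict, so a match at
    exactly the boundary is removed). The plot width is the summed length of
    the distinct target sequences appearing in the input. Idempotent.
    """
    if not matches:
        return []
    total_target = sum({m.target: m.target_len for m in matches}.values())
    min_block = width_fraction * total_target
    return [m for m in matches if m.block_len > min_block and m.identity > min_identity]


def _query_key(matches_of_query: list[AlignMatch]) -> tuple[str, float]:
    """(best target, base-weighted median target position) sort key."""
    by_target: dict[str, int] = {}
    for m in matches_of_query:
        by_target[m.target] = by_target.get(m.target, 0) + m.n_match
    best = max(by_target, key=lambda t: (by_target[t], t))
    spans = sorted(
        ((m.target_start + m.target_end) / 2, m.n_match)
        for m in matches_of_query
        if m.target == best
    )
    total = sum(w for _, w in spans)
    running = 0.0
    for mid, w in spans:
        running += w
        if running >= total / 2:
            return best, mid
    return best, spans[-1][0]


def order_queries(
    matches: Sequence[AlignMatch],
    target_order: Sequence[str] | None = None,
) -> list[str]:
    """Sort query names along the reference, dot-plot-viewer style.

    Each query is keyed by the target holding most of its matching bases and
    the base-weighted median of its match midpoints on that target; queries
    are sorted by (target rank, median position). Targets default to
    lexicographic order; pass ``target_order`` to impose reference order.
    Queries with no matches are absent (callers append them as they wish).
    """
    grouped: dict[str, list[AlignMatch]] = {}
    for m in matches:
        grouped.setdefault(m.query, []).append(m)
    if target_order is None:
        keyed = {q: _query_key(ms) for q, ms in grouped.items()}
        return sorted(keyed, key=lambda q: keyed[q])
    rank = {t: i for i, t in enumerate(target_order)}
    keyed2 = {}
    for q, ms in grouped.items():
        t, mid = _query_key(ms)
        keyed2[q] = (rank.get(t, len(rank)), mid)
    return sorted(keyed2, key=lambda q: keyed2[q])


@dataclass(frozen=True)
class OrientationCall:
    """Majority-strand orientation of one query against the reference."""

    query: str
    orientation: str  # '+' or '-'
    support: float  # fraction of matching bases on the majority strand
    target: str


def infer_orientation(matches: Sequence[AlignMatch], query: str) -> OrientationCall:
    """Call a query's orientation from the strand-weighted base majority.

    Support is the majority fraction of summed matching bases; an exact tie
    is called '+' with support 0.5.
    """
    mine = [m for m in matches if m.query == query]
    if not mine:
        raise KeyError(f"no matches for query {query!r}")
    fwd = sum(m.n_match for m in mine if m.strand == "+")
    rev = sum(m.n_match for m in mine if m.strand == "-")
    by_target: dict[str, int] = {}
    for m in mine:
        by_target[m.target] = by_target.get(m.target, 0) + m.n_match
    target = max(by_target, key=lambda t: (by_target[t], t))
    total = fwd + rev
    if rev > fwd:
        return OrientationCall(query, "-", rev / total, target)
    return OrientationCall(query, "+", fwd / total if total else 0.5, target)


def apply_orientations(
    assembly: Assembly,
    calls: Iterable[OrientationCall],
    rename_map: dict[str, str] | None = None,
) -> Assembly:
    """Reverse-complement '-'-called records and optionally rename.

    Applying the same calls twice returns the original assembly; total size
    and the strand-adjusted base multiset are preserved.
    """
    flip = {c.query for c in calls if c.orientation == "-"}
    unknown = flip - set(assembly.names)
    if unknown:
        raise KeyError(f"orientation calls for absent sequences: {sorted(unknown)}")
    rename_map = rename_map or {}
    new_names = [rename_map.get(n, n) for n in assembly.names]
    if len(set(new_names)) != len(new_names):
        raise ValueError("rename collision")
    out = Assembly()
    for name, seq in assembly:
        out.add(rename_map.get(name, name), reverse_complement(seq) if name in flip else seq)
    return out


def dotplot_export(
    matches: Sequence[AlignMatch],
    query_order: Sequence[str],
    path: str | Path,
    tsv_path: str | Path | None = None,
) -> list[tuple[str, str, float, float, float, float]]:
    """Draw a dot plot in cumulative coordinates and dump its segments.

    One segment per match; '-'-strand matches slope downwards. Returns the
    segment rows (query, target, x0, x1, y0, y1) and writes them as TSV
    next to the figure (or at ``tsv_path``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if tsv_path is None:
        tsv_path = path.with_suffix(".tsv")
    q_lens = {m.query: m.query_len for m in matches}
    t_lens = {m.target: m.target_len for m in matches}
    q_off, acc = {}, 0
    for q in query_order:
        if q in q_lens:
            q_off[q] = acc
            acc += q_lens[q]
    for q in sorted(q_lens):
        if q not in q_off:
            q_off[q] = acc
            acc += q_lens[q]
    t_off, acc_t = {}, 0
    for t in sorted(t_lens):
        t_off[t] = acc_t
        acc_t += t_lens[t]

    rows = []
    fig, ax = plt.subplots(figsize=(6, 6))
    for m in matches:
        x0 = q_off[m.query] + m.query_start
        x1 = q_off[m.query] + m.query_end
        if m.strand == "+":
            y0 = t_off[m.target] + m.target_start
            y1 = t_off[m.target] + m.target_end
        else:
            y0 = t_off[m.target] + m.target_end
            y1 = t_off[m.target] + m.target_start
        rows.append((m.query, m.target, float(x0), float(x1), float(y0), float(y1)))
        ax.plot([x0, x1], [y0, y1], color="tab:blue", lw=0.8)
    for off in list(q_off.values())[1:]:
        ax.axvline(off, color="0.85", lw=0.4)
    for off in list(t_off.values())[1:]:
        ax.axhline(off, color="0.85", lw=0.4)
    ax.set_xlabel("query (cumulative bp)")
    ax.set_ylabel("target (cumulative bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["query", "target", "x0", "x1", "y0", "y1"])
        w.writerows(rows)
    return rows


def matches_from_truth(
    truth: TruthGenome, truth_map: TruthMap, assembly: Assembly
) -> list[AlignMatch]:
    """Derive exact scaffold-vs-chromosome alignments from the ground truth.

    Emits one perfect match per fragment (scaffold as query, chromosome as
    target), with coordinates taken from the TruthMap. This is the
    analytically exact stand-in for running an aligner on synthetic data.
    """
    chrom_lens = truth.chromosomes.lengths()
    scaf_lens = assembly.lengths()
    out = []
    for scaffold, segs in truth_map.layouts.items():
        offsets = truth_map.fragment_offsets(scaffold)
        for seg in segs:
            if seg.is_gap:
                continue
            p = truth_map.placements[seg.frag_id]
            lo, hi = offsets[seg.frag_id]
            out.append(
                AlignMatch(
                    query=scaffold,
                    query_len=scaf_lens[scaffold],
                    query_start=lo,
                    query_end=hi,
                    strand=p.strand,
                    target=p.chrom,
                    target_len=chrom_lens[p.chrom],
                    target_start=p.start,
                    target_end=p.end,
                    n_match=hi - lo,
                    block_len=hi - lo,
                )
            )
    return out
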