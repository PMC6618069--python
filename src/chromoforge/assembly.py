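"""Named-sequence container shared by every pipeline stage.

An :class:`Assembly` is an ordered collection of (name, sequence) records —
scaffolds of a genome assembly, chromosomes of a truth genome, or probe sets.
Sequences are plain Python strings over ``{A, C, G, T, N}`` (lower case
allowed, other IUPAC codes tolerated and treated as ordinary sequence).
"""

from __future__ import annotations

import gzip
import io
from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Assembly", "reverse_complement"]

_COMPLEMENT = str.maketrans(
    "ACGTUacgtuNnRYSWKMBDHVryswkmbdhv",
    "TGCAAtgcaaNnYRSWMKVHDByrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


class Assembly:
    """Ordered, name-unique collection of sequences.

    Parameters
    ----------
    records:
        Iterable of ``(name, sequence)`` pairs. Names must be unique and
        sequences non-empty.
    """

    def __init__(self, records: Iterable[tuple[str, str]] = ()):
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in records:
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate sequence name: {name!r}")
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
        self._names.append(name)
        self._seqs[name] = seq

    # -- mapping-ish surface -------------------------------------------------

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for name in self._names:
            yield name, self._seqs[name]

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self}

    @property
    def total_size(self) -> int:
        return sum(len(s) for _, s in self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Assembly):
            return NotImplemented
        return self._names == other._names and self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Assembly({len(self)} sequences, {self.total_size} bp)"

    # -- FASTA I/O -----------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Assembly":
        """Read FASTA, plain or gzip-compressed (by .gz suffix)."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            return cls((rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta"))

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        """Write FASTA with ``width``-column wrapping."""
        records = (SeqRecord(Seq(s), id=n, description="") for n, s in self)
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    def to_fasta_string(self, width: int = 60) -> str:
        buf = io.StringIO()
        records = (SeqRecord(Seq(s), id=n, description="") for n, s in self)
        SeqIO.FastaIO.FastaWriter(buf, wrap=width).write_file(records)
        return buf.getvalue()
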