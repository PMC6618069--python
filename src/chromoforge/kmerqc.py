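"""Read-vs-assembly k-mer completeness spectra (KAT spectra-cn style).

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k = 27 by default) are counted in a read set and in an assembly;
each distinct read k-mer is then binned by its read multiplicity and its
copy number in the assembly. The copy-number-zero column is sequencing
content missing from the assembly; after cutting away the low-multiplicity
sequencing-error peak, its share of distinct k-mers estimates the missing
fraction of the genome.

Counting is in-memory (2-bit numpy encoding, sorted unique codes), sized for
desk-scale genomes up to a few tens of Mbp; real mammalian-scale read sets
need a disk-backed counter behind the same :class:`KmerCountTable` surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KmerCountTable",
    "KmerSpectra",
    "count_kmers",
    "spectra_cn",
    "error_cutoff",
    "missing_content",
    "canonical",
]

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 marks invalid (N and friends)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGT"))


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    comp = kmer.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return min(kmer.upper(), comp)


def _encode_windows(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all N-free length-k windows of ``seq``."""
    b = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(b)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    nwin = n - k + 1
    fwd = np.zeros(nwin, dtype=np.uint64)
    rev = np.zeros(nwin, dtype=np.uint64)
    valid = np.ones(nwin, dtype=bool)
    bb = b.astype(np.uint64)
    comp = (np.uint64(3) - bb)  # harmless garbage at invalid positions
    for j in range(k):
        col = bb[j : j + nwin]
        fwd |= (col & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        rev |= (comp[j : j + nwin] & np.uint64(3)) << np.uint64(2 * j)
        valid &= b[j : j + nwin] != 4
    return np.minimum(fwd, rev)[valid]


def _decode(code: int, k: int) -> str:
    idx = [(code >> (2 * (k - 1 - j))) & 3 for j in range(k)]
    return "".join(_DECODE[idx])


@dataclass
class KmerCountTable:
    """Sorted canonical k-mer codes with their occurrence counts."""

    k: int
    codes: np.ndarray  # uint64, sorted ascending, unique
    counts: np.ndarray  # int64, parallel to codes

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def total_occurrences(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, kmer: str) -> int:
        code = _encode_windows(kmer, self.k)
        if len(code) != 1:
            raise KeyError(kmer)
        i = np.searchsorted(self.codes, code[0])
        if i < len(self.codes) and self.codes[i] == code[0]:
            return int(self.counts[i])
        raise KeyError(kmer)

    def as_dict(self) -> dict[str, int]:
        """Decode to a {kmer string: count} mapping (small tables only)."""
        return {_decode(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    def multiplicity_histogram(self, m_max: int | None = None) -> np.ndarray:
        """hist[m] = number of distinct k-mers seen m times (index 0 unused)."""
        top = int(self.counts.max()) if len(self.counts) else 0
        if m_max is not None:
            top = min(top, m_max)
        hist = np.bincount(np.minimum(self.counts, top), minlength=top + 1)
        hist[0] = 0
        return hist


def count_kmers(sequences: Iterable[str] | str, k: int = 27) -> KmerCountTable:
    """Count canonical k-mers across sequences, skipping windows with N.

    ``sequences`` may be a single string or any iterable of strings (e.g.
    assembly sequences or read sequences).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    if isinstance(sequences, str):
        sequences = [sequences]
    # batch sequences into large N-joined blocks: the separator invalidates
    # windows spanning two sequences, and one vectorized pass per block
    # beats per-read encoding by orders of magnitude
    chunks = []
    batch: list[str] = []
    batch_len = 0
    for s in sequences:
        batch.append(s)
        batch_len += len(s) + 1
        if batch_len >= 4_000_000:
            chunks.append(_encode_windows("N".join(batch), k))
            batch, batch_len = [], 0
    if batch:
        chunks.append(_encode_windows("N".join(batch), k))
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        warnings.warn(f"no windows of length {k}; empty k-mer table", stacklevel=2)
        return KmerCountTable(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerCountTable(k, codes, counts.astype(np.int64))


@dataclass
class KmerSpectra:
    """Joint histogram: read multiplicity (rows) x assembly copy number (cols).

    ``matrix[m][c]`` counts distinct read k-mers with read multiplicity m
    (1..m_max, top bin open) and assembly copy number c (0..c_max, top bin
    open). Column 0 is content present in reads but absent from the
    assembly. ``assembly_only`` counts assembly k-mers never seen in reads.
    """

    matrix: np.ndarray  # shape (m_max + 1, c_max + 1); row 0 unused
    k: int
    m_max: int
    c_max: int
    assembly_only: int

    def row_histogram(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def distinct_read_kmers(self) -> int:
        return int(self.matrix.sum())

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.matrix[1:],
            index=pd.RangeIndex(1, self.m_max + 1, name="multiplicity"),
            columns=[f"c{c}" for c in range(self.c_max + 1)],
        )
        df.to_csv(path, sep="\t")


def spectra_cn(
    reads: KmerCountTable,
    asm: KmerCountTable,
    m_max: int = 200,
    c_max: int = 6,
) -> KmerSpectra:
    """Bin distinct read k-mers by (read multiplicity, assembly copy number)."""
    if reads.k != asm.k:
        raise ValueError(f"k mismatch: reads k={reads.k}, assembly k={asm.k}")
    m = np.minimum(reads.counts, m_max)
    idx = np.searchsorted(asm.codes, reads.codes)
    idx_c = np.clip(idx, 0, max(len(asm.codes) - 1, 0))
    present = np.zeros(len(reads.codes), dtype=bool)
    if len(asm.codes):
        present = asm.codes[idx_c] == reads.codes
    c = np.zeros(len(reads.codes), dtype=np.int64)
    if len(asm.codes):
        c[present] = np.minimum(asm.counts[idx_c[present]], c_max)
    matrix = np.zeros((m_max + 1, c_max + 1), dtype=np.int64)
    np.add.at(matrix, (m, c), 1)
    shared = int(present.sum())
    return KmerSpectra(
        matrix=matrix,
        k=reads.k,
        m_max=m_max,
        c_max=c_max,
        assembly_only=len(asm.codes) - shared,
    )


def error_cutoff(multiplicity_histogram: Sequence[int] | np.ndarray) -> int:
    """Multiplicity separating the sequencing-error peak from real content.

    Locates the valley of the distinct-k-mer multiplicity histogram between
    the low-multiplicity error peak and the dominant genomic peak: the
    multiplicity of the minimum count below the histogram's main peak
    (ignoring multiplicity 1 when finding that peak). Returns 1 when the
    histogram is unimodal, flat or rising from the start — there is no
    error peak to cut away.
    """
    h = np.asarray(multiplicity_histogram, dtype=float)
    if h.size == 0:
        raise ValueError("empty histogram")
    # accept either a raw histogram starting at multiplicity 1 or a
    # bincount-style array whose index 0 slot is unused (zero)
    vals = h[1:] if h.size > 1 and h[0] == 0 else h
    if vals.size < 3:
        return 1
    peak_idx = 1 + int(np.argmax(vals[1:]))  # main peak, multiplicity >= 2
    if peak_idx < 2:
        return 1
    return 1 + int(np.argmin(vals[:peak_idx]))


def missing_content(spectra: KmerSpectra, m_err: int = 1) -> float:
    """Fraction of genuine distinct read k-mers absent from the assembly.

    Restricts to read multiplicity >= ``m_err`` (discarding the sequencing-
    error peak) and returns the copy-number-zero share of what remains.
    """
    if m_err < 1:
        raise ValueError("m_err must be >= 1")
    if spectra.distinct_read_kmers() == 0:
        raise ValueError("empty spectra")
    sub = spectra.matrix[m_err:]
    denom = sub.sum()
    if denom == 0:
        return 0.0
    return float(sub[:, 0].sum() / denom)
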