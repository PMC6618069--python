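"""Annotation-derived QC: GFF3 summaries, AED filtering, truncation profile.

Works on MAKER-style GFF3 (gene -> mRNA -> exon/CDS via Parent attributes,
per-mRNA annotation edit distance in an ``_AED`` or ``AED`` attribute).
AED is a [0,1] measure of disagreement between a gene model and its
supporting evidence; lower is better, and annotation QC conventionally
keeps models with AED <= 0.50 and plots the cumulative AED curve.

Protein truncation is profiled from a (query length, subject length) hit
table — predicted protein vs database subject — as the frequency polygon of
the length ratio; ratios inside [0.85, 1.15] count as full-length. A
benchmark-ortholog (BUSCO-style) count vector is reduced to its complete
proportion.

GFF3 parsing is delegated to :mod:`gffutils` (in-memory database).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd

from .asmstats import round_half_up

__all__ = [
    "AnnotationSummary",
    "TruncationProfile",
    "BuscoCounts",
    "load_gff",
    "summarize_gff",
    "filter_aed",
    "get_aed",
    "aed_cumulative",
    "truncation_profile",
    "busco_proportion",
]


_EMPTY_SENTINEL = "__chromoforge_empty__\tchromoforge\tregion\t1\t1\t.\t.\t.\tID=__empty__"


def load_gff(source: str) -> gffutils.FeatureDB:
    """Build an in-memory feature database from GFF3 text or a file path.

    A header-only annotation (no features) yields a database containing a
    single inert ``region`` sentinel, since the backend cannot represent a
    feature-less file; summaries and filters ignore it.
    """
    from_string = "\n" in source or source.lstrip().startswith("##gff")
    try:
        return gffutils.create_db(
            source,
            dbfn=":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return gffutils.create_db(
            f"##gff-version 3\n{_EMPTY_SENTINEL}\n",
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
        )


def get_aed(feature: gffutils.Feature) -> float | None:
    """AED of an mRNA feature; accepts the `_AED` (MAKER) and `AED` keys."""
    for key in ("_AED", "AED"):
        if key in feature.attributes:
            return float(feature.attributes[key][0])
    return None


@dataclass
class AnnotationSummary:
    """Feature counts, length distributions and per-feature means."""

    n_genes: int = 0
    n_mrnas: int = 0
    n_exons: int = 0
    n_introns: int = 0
    n_cds: int = 0
    #: feature type -> (mean, min, max) of lengths (1-based inclusive spans)
    length_stats: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    mean_mrnas_per_gene: float = 0.0
    mean_exons_per_mrna: float = 0.0
    mean_introns_per_mrna: float = 0.0

    def to_dict(self) -> dict:
        return {
            "genes": self.n_genes,
            "mRNAs": self.n_mrnas,
            "exons": self.n_exons,
            "introns": self.n_introns,
            "CDS": self.n_cds,
            "mean_mRNAs_per_gene": self.mean_mrnas_per_gene,
            "mean_exons_per_mRNA": self.mean_exons_per_mrna,
            "mean_introns_per_mRNA": self.mean_introns_per_mrna,
            "length_stats": self.length_stats,
        }


def _span(f: gffutils.Feature) -> int:
    return f.end - f.start + 1  # GFF3 is 1-based inclusive


def summarize_gff(db: gffutils.FeatureDB) -> AnnotationSummary:
    """Count features and derive length distributions, introns from exon gaps.

    Intron lengths are the gaps between consecutive exons of each mRNA
    (exons sorted by start), matching annotations that do not emit explicit
    intron features. Means are rounded to whole bases in ``length_stats``
    for report parity with annotation-summary tools.
    """
    lengths: dict[str, list[int]] = {"gene": [], "mRNA": [], "exon": [], "intron": [], "CDS": []}
    mrnas_per_gene: list[int] = []
    exons_per_mrna: list[int] = []
    introns_per_mrna: list[int] = []

    for gene in db.features_of_type("gene"):
        lengths["gene"].append(_span(gene))
        children = list(db.children(gene, featuretype="mRNA"))
        mrnas_per_gene.append(len(children))
        for mrna in children:
            lengths["mRNA"].append(_span(mrna))
            exons = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
            exons_per_mrna.append(len(exons))
            introns_per_mrna.append(max(len(exons) - 1, 0))
            for ex in exons:
                lengths["exon"].append(_span(ex))
            for a, b in zip(exons, exons[1:]):
                gap = b.start - a.end - 1
                if gap < 0:
                    raise ValueError(f"overlapping exons under {mrna.id}")
                lengths["intron"].append(gap)
            for cds in db.children(mrna, featuretype="CDS"):
                lengths["CDS"].append(_span(cds))

    # orphan check: every mRNA/exon/CDS must hang off the hierarchy
    for ftype in ("mRNA", "exon", "CDS"):
        for f in db.features_of_type(ftype):
            if "Parent" not in f.attributes:
                raise ValueError(f"orphan {ftype} feature {f.id}: no Parent")

    stats = {
        ftype: (int(round(float(np.mean(vals)))), min(vals), max(vals))
        for ftype, vals in lengths.items()
        if vals
    }
    n_mrnas = len(lengths["mRNA"])
    return AnnotationSummary(
        n_genes=len(lengths["gene"]),
        n_mrnas=n_mrnas,
        n_exons=len(lengths["exon"]),
        n_introns=len(lengths["intron"]),
        n_cds=len(lengths["CDS"]),
        length_stats=stats,
        mean_mrnas_per_gene=float(np.mean(mrnas_per_gene)) if mrnas_per_gene else 0.0,
        mean_exons_per_mrna=float(np.mean(exons_per_mrna)) if exons_per_mrna else 0.0,
        mean_introns_per_mrna=float(np.mean(introns_per_mrna)) if introns_per_mrna else 0.0,
    )


def filter_aed(
    db: gffutils.FeatureDB,
    max_aed: float = 0.50,
    keep_missing: bool = False,
) -> gffutils.FeatureDB:
    """Drop mRNAs with AED above the threshold (inclusive keep at the bound).

    Child exons/CDS of dropped mRNAs go with them, and genes left without
    any mRNA are removed. mRNAs with no AED attribute are dropped with a
    warning unless ``keep_missing``.
    """
    kept_lines: list[str] = []
    for gene in db.features_of_type("gene"):
        gene_lines: list[str] = []
        survivors = 0
        for mrna in db.children(gene, featuretype="mRNA"):
            aed = get_aed(mrna)
            if aed is None:
                if not keep_missing:
                    warnings.warn(f"mRNA {mrna.id} has no AED attribute; dropped", stacklevel=2)
                    continue
            elif aed > max_aed:
                continue
            survivors += 1
            gene_lines.append(str(mrna))
            for child in db.children(mrna):
                gene_lines.append(str(child))
        if survivors:
            kept_lines.append(str(gene))
            kept_lines.extend(gene_lines)
    text = "##gff-version 3\n" + "\n".join(kept_lines) + ("\n" if kept_lines else "")
    return load_gff(text)


def aed_cumulative(
    aed_values: Sequence[float], thresholds: Sequence[float]
) -> list[float]:
    """Proportion of values <= t for each threshold t (non-decreasing in t)."""
    vals = np.asarray(aed_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no AED values")
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("AED values must lie in [0, 1]")
    return [float((vals <= t).mean()) for t in thresholds]


@dataclass(frozen=True)
class TruncationProfile:
    """Frequency polygon of predicted/subject protein length ratios."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_hits: int
    n_rejected: int  # rows with non-positive subject length
    fraction_in_window: float
    window: tuple[float, float]

    @property
    def percent_in_window(self) -> int:
        """Window share as a whole percent, half-up."""
        return int(round_half_up(100.0 * self.fraction_in_window, 0))


def truncation_profile(
    hit_table: pd.DataFrame,
    bin_width: float = 0.05,
    window: tuple[float, float] = (0.85, 1.15),
) -> TruncationProfile:
    """Bin query/subject protein length ratios and score the full-length window.

    ``hit_table`` needs ``query_len`` and ``subject_len`` columns. Ratios in
    the inclusive window count as full-length (untruncated); ratios below it
    indicate truncated predictions (e.g. reading frames broken by
    uncorrected indels). Rows with non-positive subject length are rejected
    and counted.
    """
    q = pd.to_numeric(hit_table["query_len"])
    s = pd.to_numeric(hit_table["subject_len"])
    bad = ~(s > 0) | ~(q >= 1)
    n_rejected = int(bad.sum())
    ratios = (q[~bad] / s[~bad]).to_numpy(dtype=float)
    if ratios.size == 0:
        raise ValueError("no usable hit rows")
    r_max = max(float(ratios.max()), window[1])
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    freq, edges = np.histogram(ratios, bins=edges)
    in_window = ((ratios >= window[0]) & (ratios <= window[1])).sum()
    return TruncationProfile(
        bin_edges=edges,
        frequencies=freq,
        n_hits=int(ratios.size),
        n_rejected=n_rejected,
        fraction_in_window=float(in_window / ratios.size),
        window=window,
    )


@dataclass(frozen=True)
class BuscoCounts:
    """Benchmark-ortholog category counts (complete single/duplicated, etc.)."""

    single_copy: int
    duplicated: int
    fragmented: int
    missing: int

    @property
    def total(self) -> int:
        return self.single_copy + self.duplicated + self.fragmented + self.missing


def busco_proportion(counts: BuscoCounts) -> float:
    """Proportion of complete orthologs, half-up to 3 decimals.

    Complete means single-copy or duplicated; e.g. counts
    (3851, 24, 133, 96) give 3875/4104 = 0.944.
    """
    if counts.total <= 0:
        raise ValueError("ortholog counts sum to zero")
    if min(counts.single_copy, counts.duplicated, counts.fragmented, counts.missing) < 0:
        raise ValueError("negative ortholog count")
    return round_half_up((counts.single_copy + counts.duplicated) / counts.total, 3)
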