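"""End-to-end orchestration of the QC stages on synthetic (or user) data.

Runs the stages in assembly-project order — synthesize inputs, assembly
statistics and version comparison, k-mer completeness, whole-genome-
alignment ordering/orientation, probe-vote chromosome assignment, annotation
summary — writing per-stage artifacts plus one consolidated JSON/Markdown
report. All randomness flows from a single seed recorded in the report, and
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import alnmap, annosum, asmstats, kmerqc, probemap, synthio
from .assembly import Assembly

__all__ = ["PipelineConfig", "run_pipeline", "demo"]

ALL_STAGES = ("synthesize", "stats", "kmerqc", "alnmap", "probemap", "annosum")


@dataclass
class PipelineConfig:
    """Parameters for one pipeline run; defaults are the desk-scale demo."""

    outdir: str = "chromoforge_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    # synthetic genome
    n_chrom: int = 12
    chrom_length_range: tuple[int, int] = (60_000, 120_000)
    repeat_fraction: float = 0.05

    # draft fragmentation / scaffolding / gap filling
    mean_contig_len: int = 8_000
    gap_len_range: tuple[int, int] = (50, 500)
    missing_span_range: tuple[int, int] = (0, 2_000)
    join_gap: int = 1_000
    join_error_rate: float = 0.02
    fill_rate: float = 0.8

    # reads and k-mers
    coverage: float = 25.0
    read_len: int = 100
    read_error_rate: float = 0.005
    k: int = 27

    # probes
    probes_per_chrom: int = 30
    probe_len: int = 120
    probe_mutation_rate: float = 0.01
    probe_mislabel_rate: float = 0.05
    e_max: float = 1e-30

    # alignment dot-plot filters
    width_fraction: float = 1e-5
    min_alignment_identity: float = 0.75

    # annotation
    n_genes: int = 300
    max_aed: float = 0.50
    min_gap_len: int = 25

    # optional user-supplied assemblies for a stats-only run
    assembly_a: str | None = None
    assembly_b: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        for name in ("chrom_length_range", "gap_len_range", "missing_span_range", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; return (and write) the report.

    Artifacts land under ``config.outdir``; the consolidated report is
    written as ``report.json`` and ``report.md``. The first failing stage
    aborts the run with :class:`StageError`; artifacts of completed stages
    are retained.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(asdict(config))}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        runner = _STAGES[stage]
        try:
            report[stage] = runner(config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            _write_report(report, outdir)
            raise StageError(stage, exc) from exc
    _write_report(report, outdir)
    return report


def demo(seed: int, outdir: str | Path) -> dict:
    """All-synthetic end-to-end run at the default desk scale."""
    return run_pipeline(PipelineConfig(outdir=str(outdir), seed=seed))


# ---------------------------------------------------------------------------
# Stages


def _stage_synthesize(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    seed = cfg.seed
    truth = synthio.generate_truth_genome(
        cfg.n_chrom, cfg.chrom_length_range, cfg.repeat_fraction, seed=seed
    )
    draft, map_draft = synthio.fragment_genome(
        truth, cfg.mean_contig_len, cfg.gap_len_range,
        seed=seed + 1, missing_span_range=cfg.missing_span_range,
    )
    scaffolded, map_scaf = synthio.scaffold_draft(
        draft, map_draft, join_gap=cfg.join_gap,
        join_error_rate=cfg.join_error_rate, seed=seed + 2,
    )
    filled, map_fill = synthio.fill_gaps_synthetic(
        scaffolded, truth, map_scaf, fill_rate=cfg.fill_rate, seed=seed + 3
    )
    probes, labels, true_origin = synthio.generate_probes(
        truth, cfg.probes_per_chrom, cfg.probe_len,
        cfg.probe_mutation_rate, cfg.probe_mislabel_rate, seed=seed + 4,
    )
    r1, r2 = synthio.generate_reads(
        truth, cfg.coverage, cfg.read_len, cfg.read_error_rate, seed=seed + 5
    )
    gff_text, protein_table = synthio.generate_annotation(
        truth, cfg.n_genes, seed=seed + 6
    )

    truth.chromosomes.to_fasta(outdir / "truth.fa")
    draft.to_fasta(outdir / "draft.fa")
    scaffolded.to_fasta(outdir / "scaffolded.fa")
    filled.to_fasta(outdir / "filled.fa")
    probes.to_fasta(outdir / "probes.fa")
    with open(outdir / "probe_labels.tsv", "w") as fh:
        fh.write("probe_id\tchrom\n")
        for pid in probes.names:
            fh.write(f"{pid}\t{labels[pid]}\n")
    synthio.write_fastq(r1, outdir / "reads_1.fastq")
    synthio.write_fastq(r2, outdir / "reads_2.fastq")
    (outdir / "annotation.gff3").write_text(gff_text)
    protein_table.to_csv(outdir / "protein_hits.tsv", sep="\t", index=False)

    state.update(
        truth=truth, draft=draft, scaffolded=scaffolded, filled=filled,
        map_draft=map_draft, map_scaf=map_scaf, map_fill=map_fill,
        probes=probes, probe_labels=labels, probe_truth=true_origin,
        reads=(r1, r2), gff_text=gff_text, protein_table=protein_table,
    )
    return {
        "genome_size": truth.chromosomes.total_size,
        "n_chromosomes": cfg.n_chrom,
        "repeat_fraction_realized": round(truth.repeat_fraction(), 4),
        "draft_scaffolds": len(draft),
        "read_pairs": len(r1),
        "probes": len(probes),
    }


def _stage_stats(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    if "draft" in state:
        versions = {k: state[k] for k in ("draft", "scaffolded", "filled")}
    else:  # stats-only run on user-supplied assemblies
        if cfg.assembly_a is None:
            raise ValueError("stats stage needs synthesize output or assembly_a")
        versions = {"a": Assembly.from_fasta(cfg.assembly_a)}
        if cfg.assembly_b is not None:
            versions["b"] = Assembly.from_fasta(cfg.assembly_b)
    stats = {k: asmstats.compute_stats(v, cfg.min_gap_len) for k, v in versions.items()}
    rows = []
    for name, st in stats.items():
        rows.append({"assembly": name, **st.to_dict()})
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "assembly_stats.tsv", sep="\t", index=False)

    report = {"stats": {k: st.to_dict() for k, st in stats.items()}}
    if "draft" in stats:
        cmp_join = asmstats.compare_stats(stats["draft"], stats["scaffolded"])
        cmp_fill = asmstats.compare_stats(stats["scaffolded"], stats["filled"])
        fills = [f for f in state["map_fill"].fill_ledger if f.filled]
        over = sum(1 for f in fills if f.true_len > f.placeholder_len)
        report["scaffolding"] = {
            "bases_added": cmp_join.bases_added,
            "scaffolds_merged": cmp_join.scaffolds_merged,
            "n50_fold": round(cmp_join.fold_changes.get("scaffold_n50", 1.0), 2),
        }
        report["gap_filling"] = {
            "bases_added": cmp_fill.bases_added,
            "bases_added_mbp": cmp_fill.bases_added_mbp,
            "gaps_closed": len(fills),
            "gaps_over_filled": over,
            "gap_bases_delta": cmp_fill.gap_bases_delta,
        }
    elif "b" in stats:
        cmp_ab = asmstats.compare_stats(stats["a"], stats["b"])
        report["comparison"] = {
            "bases_added": cmp_ab.bases_added,
            "bases_added_mbp": cmp_ab.bases_added_mbp,
            "gap_bases_delta": cmp_ab.gap_bases_delta,
            "scaffolds_merged": cmp_ab.scaffolds_merged,
            "fold_changes": {k: round(v, 3) for k, v in cmp_ab.fold_changes.items()},
        }
    state["stats"] = stats
    return report


def _stage_kmerqc(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    r1, r2 = state["reads"]
    read_tab = kmerqc.count_kmers((seq for _, seq in r1 + r2), k=cfg.k)
    asm_tab = kmerqc.count_kmers((seq for _, seq in state["filled"]), k=cfg.k)
    spectra = kmerqc.spectra_cn(read_tab, asm_tab)
    spectra.to_tsv(outdir / "kmer_spectra.tsv")
    m_err = kmerqc.error_cutoff(spectra.row_histogram())
    missing = kmerqc.missing_content(spectra, m_err)
    return {
        "k": cfg.k,
        "distinct_read_kmers": spectra.distinct_read_kmers(),
        "assembly_only_kmers": spectra.assembly_only,
        "error_cutoff": m_err,
        "missing_content": round(missing, 5),
    }


def _stage_alnmap(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    matches = alnmap.matches_from_truth(state["truth"], state["map_fill"], state["filled"])
    alnmap.write_paf(matches, outdir / "truth_alignment.paf")
    kept = alnmap.filter_matches(matches, cfg.width_fraction, cfg.min_alignment_identity)
    order = alnmap.order_queries(kept, target_order=state["truth"].chromosomes.names)
    calls = [alnmap.infer_orientation(kept, q) for q in order]
    alnmap.dotplot_export(kept, order, outdir / "dotplot.png")
    oriented = alnmap.apply_orientations(state["filled"], calls)
    oriented.to_fasta(outdir / "oriented.fa")
    state["orientation_calls"] = calls
    return {
        "matches": len(matches),
        "matches_kept": len(kept),
        "query_order": order,
        "orientations": {c.query: c.orientation for c in calls},
        "mean_orientation_support": round(
            float(np.mean([c.support for c in calls])), 4
        ),
    }


def _stage_probemap(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    hits = probemap.align_probes(state["probes"], state["filled"])
    probemap.write_blast_tab(hits, outdir / "probe_hits.tsv")
    best = probemap.best_hit_per_probe(hits, e_max=cfg.e_max)
    assignment = probemap.vote_assignments(best, state["probe_labels"])
    stats = state.get("stats") or {
        "filled": asmstats.compute_stats(state["filled"], cfg.min_gap_len)
    }
    rep = probemap.assignment_report(assignment, stats["filled"], state["filled"])
    with open(outdir / "chromosome_assignment.tsv", "w") as fh:
        fh.write("chromosome\tscaffold\tvotes\tconcordance\n")
        for chrom in sorted(assignment.primary):
            scaf, v = assignment.primary[chrom]
            fh.write(f"{chrom}\t{scaf}\t{v}\t{assignment.concordance[chrom]:.3f}\n")
    return {
        "probes_with_passing_hit": len(best),
        "probes_without_hit": assignment.probes_without_hit,
        "chromosomes_assigned": len(assignment.primary),
        "chromosomes_unassigned": assignment.unassigned_chromosomes,
        "mean_concordance": round(rep.mean_concordance, 4),
        "sd_concordance": round(rep.sd_concordance, 4),
        "unassigned_bases": rep.unassigned_bases,
        "unassigned_percent": rep.unassigned_percent,
        "rename_table": rep.rename_table,
    }


def _stage_annosum(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    db = annosum.load_gff(state["gff_text"])
    before = annosum.summarize_gff(db)
    filtered = annosum.filter_aed(db, cfg.max_aed)
    after = annosum.summarize_gff(filtered)
    aeds = [annosum.get_aed(m) for m in db.features_of_type("mRNA")]
    aeds = [a for a in aeds if a is not None]
    thresholds = [round(0.05 * i, 2) for i in range(21)]
    curve = annosum.aed_cumulative(aeds, thresholds)
    profile = annosum.truncation_profile(state["protein_table"])
    return {
        "summary": before.to_dict(),
        "summary_after_aed_filter": after.to_dict(),
        "aed_thresholds": thresholds,
        "aed_cumulative": [round(c, 4) for c in curve],
        "truncation_percent_in_window": profile.percent_in_window,
        "truncation_n_hits": profile.n_hits,
    }


_STAGES = {
    "synthesize": _stage_synthesize,
    "stats": _stage_stats,
    "kmerqc": _stage_kmerqc,
    "alnmap": _stage_alnmap,
    "probemap": _stage_probemap,
    "annosum": _stage_annosum,
}


# ---------------------------------------------------------------------------
# Report output


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["# chromoforge pipeline report", ""]
    for section, payload in report.items():
        lines.append(f"## {section}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
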