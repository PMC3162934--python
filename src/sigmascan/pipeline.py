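"""End-to-end pipeline: activator identification, promoter scanning,
taxonomic survey, and genomic-context analysis, in that order."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as sio
from dataclasses import replace as dc_replace

from .context import (
    build_units,
    cog_category_representation,
    collect_annotations,
    context_window,
    extract_conserved_tendencies,
    promoter_context,
)
from .ebp import (
    Seed,
    SeedSet,
    build_evalue_profiles,
    classify_protein,
    detect_sigma54,
)
from .promoters import (
    distance_histogram,
    filter_promoters,
    link_hits_to_genes,
    rank_hits,
    scan_genome,
)
from .survey import bin_by_genome_size, motility_and_ebp_fractions, summarize_phylum

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus the analysis constants; defaults follow the published
    strategy (85% score threshold, -50..300 window, top-15 rank, 300-nt
    gaps, +/-10-gene context, 1e-20 / product<1e-5 / sum<1 e-value cuts)."""

    genome_fastas: list = field(default_factory=list)
    genome_gffs: list = field(default_factory=list)
    pfm: str = ""
    proteins: str = ""
    blast: str = ""
    seeds: str = ""
    domains: str = ""
    annotations: str = ""
    metadata: str = ""
    background: str = ""
    outdir: str = "results"

    threshold_fraction: float = 0.85
    promoter_window: tuple = (-50, 300)
    top_rank: int = 15
    max_gap: int = 300
    context_up: int = 10
    context_down: int = 10
    promoter_context_down: int = 10
    sigma54_cutoff: float = 1e-20
    log10_product_max: float = -5.0
    sum_max: float = 1.0
    k_small: int = 10
    k_large: int = 20
    large_threshold: int = 10
    min_phyla: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError(
                f"threshold_fraction {self.threshold_fraction} outside (0, 1]"
            )
        lo, hi = self.promoter_window
        if lo > hi:
            raise ValueError("promoter_window is not ordered")
        if self.top_rank < 1 or self.max_gap < 0 or self.min_phyla < 1:
            raise ValueError("threshold out of documented range")

    @classmethod
    def from_bundle_dir(cls, indir, outdir="results", **overrides):
        """Point every input at the files a synthetic bundle emits."""
        indir = Path(indir)
        fastas = sorted(str(p) for p in indir.glob("genome*.fasta"))
        gffs = sorted(str(p) for p in indir.glob("genome*.gff3"))
        cfg = cls(
            genome_fastas=fastas,
            genome_gffs=gffs,
            pfm=str(indir / "pfm.tsv"),
            proteins=str(indir / "proteins.faa"),
            blast=str(indir / "blast.tsv"),
            seeds=str(indir / "seeds.tsv"),
            domains=str(indir / "domains.tsv"),
            annotations=str(indir / "annotations.tsv"),
            metadata=str(indir / "metadata.tsv"),
            background=str(indir / "background.tsv"),
            outdir=str(outdir),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write result TSVs plus a run-summary JSON.

    Output coordinates are 1-based inclusive; any stage failure removes the
    partially written outputs and raises a stage-named error.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        _write_tsv(df, path)
        written.append(path)

    try:
        results = _run_stages(config, summary, emit)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        stage = summary.get("_stage", "unknown")
        raise StageError(stage, exc) from exc
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return results


def _run_stages(config: PipelineConfig, summary: dict, emit) -> dict:
    # ---------------- stage 1: activator identification
    summary["_stage"] = "ebp"
    seed_rows = sio.read_seed_tsv(config.seeds)
    ebp_seeds = SeedSet(
        seeds=tuple(
            Seed(seed_id=sid, group=group)
            for sid, group, role in seed_rows if role == "ebp"
        )
    )
    sigma_ids = {sid for sid, _, role in seed_rows if role == "sigma54"}
    blast = sio.read_blast_tab(config.blast)
    sigma_rows = [r for r in blast if r.query_id in sigma_ids]
    ebp_rows = [r for r in blast if r.query_id not in sigma_ids]
    sequences = sio.read_protein_fasta(config.proteins)
    domains = sio.read_domain_tsv(config.domains) if config.domains else {}

    genome_of = {}
    for pid in sequences:
        genome_of[pid] = pid.split("_", 1)[0]
    sigma_orthologs, sigma_per_genome = detect_sigma54(
        sigma_rows, cutoff=config.sigma54_cutoff, genome_of=genome_of
    )
    profiles = build_evalue_profiles(ebp_rows, ebp_seeds)
    records = []
    for prof in profiles:
        seqn = sequences.get(prof.protein_id, "")
        if not seqn:
            logger.warning("no sequence for %s; skipped", prof.protein_id)
            continue
        records.append(
            classify_protein(
                protein_id=prof.protein_id,
                sequence=seqn,
                profile=prof,
                seeds=ebp_seeds,
                domains=domains.get(prof.protein_id, []),
                genome_id=genome_of.get(prof.protein_id, ""),
            )
        )
    ebp_df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "genome_id": r.genome_id,
                "pass_filter": int(r.passed_evalue_filter),
                "gaftga_window": r.gaftga.window if r.gaftga else "",
                "gaftga_status": r.gaftga.overall if r.gaftga else "",
                "status": r.status,
                "architecture": r.architecture,
                "annotation_group": r.annotation_group or "",
                "length": r.length,
            }
            for r in sorted(records, key=lambda r: r.protein_id)
        ]
    )
    emit(ebp_df, "ebp_table.tsv")

    metadata = sio.read_metadata_tsv(config.metadata) if config.metadata else []
    presence = {m.genome_id: m.genome_id in sigma_per_genome for m in metadata}
    sigma_df = pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "sigma54_present": int(presence[m.genome_id]),
                "n_copies": len(sigma_per_genome.get(m.genome_id, [])),
                "protein_ids": ",".join(sigma_per_genome.get(m.genome_id, [])),
            }
            for m in metadata
        ]
    )
    emit(sigma_df, "sigma54_presence.tsv")

    true_ebps = [r for r in records if r.status in ("true_ebp", "putative_ebp")]
    ebp_counts: dict[str, int] = {}
    for r in true_ebps:
        ebp_counts[r.genome_id] = ebp_counts.get(r.genome_id, 0) + 1

    # ---------------- stage 2: promoter scan
    summary["_stage"] = "promoters"
    pfm = sio.read_pfm(config.pfm)
    all_links: dict[str, list] = {}
    genes_by_genome: dict[str, list] = {}
    promoter_rows = []
    for fa_path, gff_path in zip(config.genome_fastas, config.genome_gffs):
        genome = sio.read_fasta(fa_path)
        genes = sio.read_gff3(gff_path)
        genes_by_genome[genome.genome_id] = genes
        hits = rank_hits(scan_genome(pfm, genome, config.threshold_fraction))
        links = link_hits_to_genes(hits, genes)
        all_links[genome.genome_id] = links
        kept = {
            (id(l)) for l in filter_promoters(links, config.promoter_window)
        }
        for link in links:
            promoter_rows.append(
                {
                    "genome_id": genome.genome_id,
                    "contig": link.hit.contig_id,
                    "start": link.hit.start + 1,
                    "end": link.hit.end,
                    "strand": link.hit.strand,
                    "score": link.hit.score,
                    "rank": link.hit.rank,
                    "gene_id": link.gene_id,
                    "distance": link.distance,
                    "orientation": link.orientation,
                    "passes_window": int(id(link) in kept),
                }
            )
    promoter_df = pd.DataFrame(
        promoter_rows,
        columns=["genome_id", "contig", "start", "end", "strand", "score",
                 "rank", "gene_id", "distance", "orientation", "passes_window"],
    )
    if not promoter_df.empty:
        promoter_df = promoter_df.sort_values(
            ["genome_id", "contig", "start", "strand", "gene_id"]
        ).reset_index(drop=True)
    emit(promoter_df, "promoters.tsv")

    hist = distance_histogram(
        [l for links in all_links.values() for l in links]
    )
    hist_df = pd.DataFrame(
        [
            {"orientation": orient, "bin_start": b, "fraction": f}
            for orient, series in sorted(hist.items())
            for b, f in series.items()
        ],
        columns=["orientation", "bin_start", "fraction"],
    )
    emit(hist_df, "distance_histogram.tsv")

    # ---------------- stage 3: taxonomic survey
    summary["_stage"] = "survey"
    phylum_df, exclusions = summarize_phylum(metadata, presence, ebp_counts)
    emit(phylum_df, "survey_phylum.tsv")
    emit(bin_by_genome_size(metadata, presence), "survey_sizebins.tsv")
    mot_df, surface_df = motility_and_ebp_fractions(metadata, presence, ebp_counts)
    emit(mot_df, "survey_motility.tsv")
    emit(surface_df, "survey_ebp_fractions.tsv")
    summary["survey_exclusions"] = exclusions

    # ---------------- stage 4: genomic context and tendencies
    summary["_stage"] = "context"
    annotations = (
        sio.read_annotation_tsv(config.annotations) if config.annotations else {}
    )
    phylum_of = {m.genome_id: m.phylum_or_class for m in metadata}
    genome_counts: dict[str, int] = {}
    for m in metadata:
        genome_counts[m.phylum_or_class] = genome_counts.get(m.phylum_or_class, 0) + 1

    sigma_windows = []
    ebp_windows = []
    prom_windows = []
    for genome_id, genes in genes_by_genome.items():
        gene_ids = {g.gene_id for g in genes}
        units = build_units(genes, max_gap=config.max_gap)
        for pid in sigma_per_genome.get(genome_id, []):
            if pid in gene_ids:
                w = context_window(genes, pid, config.context_up, config.context_down)
                sigma_windows.append(dc_replace(w, genome_id=genome_id))
        for r in true_ebps:
            if r.genome_id == genome_id and r.protein_id in gene_ids:
                w = context_window(
                    genes, r.protein_id, config.context_up, config.context_down
                )
                ebp_windows.append(dc_replace(w, genome_id=genome_id))
        links = filter_promoters(
            all_links.get(genome_id, []),
            config.promoter_window,
            top_rank=config.top_rank,
        )
        for link in links:
            w = promoter_context(link, genes, units, config.promoter_context_down)
            prom_windows.append(dc_replace(w, genome_id=genome_id))

    tendency_frames = {}
    coverage_rows = []
    profiles3 = {}
    for label, windows in (
        ("sigma54", sigma_windows), ("ebp", ebp_windows), ("promoter", prom_windows)
    ):
        profile = collect_annotations(windows, annotations, phylum_of)
        profiles3[label] = (windows, profile)
        tendencies = extract_conserved_tendencies(
            profile,
            genome_counts,
            k_small=config.k_small,
            k_large=config.k_large,
            large_threshold=config.large_threshold,
            min_phyla=config.min_phyla,
        )
        tendency_frames[label] = pd.DataFrame(
            [
                {
                    "term": t.term,
                    "type": t.term_type,
                    "phyla": ",".join(t.phyla),
                    "ranks": ",".join(
                        f"{p}:{t.ranks[p]}" for p in sorted(t.ranks)
                    ),
                }
                for t in tendencies
            ],
            columns=["term", "type", "phyla", "ranks"],
        )
        emit(tendency_frames[label], f"tendencies_{label}.tsv")
        for t, frac in profile.coverage.items():
            coverage_rows.append(
                {"context": label, "type": t, "coverage": frac}
            )
    emit(
        pd.DataFrame(coverage_rows, columns=["context", "type", "coverage"]),
        "coverage.tsv",
    )

    background = (
        sio.read_background_tsv(config.background) if config.background else {}
    )
    if background:
        rep_rows = []
        flags = {
            label: cog_category_representation(windows, annotations, background)
            for label, (windows, _) in profiles3.items()
        }
        for cat in sorted(background):
            rep_rows.append(
                {
                    "category": cat,
                    "sigma54_context": flags["sigma54"][cat],
                    "ebp_context": flags["ebp"][cat],
                    "promoter_context": flags["promoter"][cat],
                }
            )
        emit(
            pd.DataFrame(
                rep_rows,
                columns=["category", "sigma54_context", "ebp_context",
                         "promoter_context"],
            ),
            "cog_representation.tsv",
        )

    summary.pop("_stage", None)
    summary["n_sigma54_orthologs"] = len(sigma_orthologs)
    summary["n_ebp_candidates"] = len(records)
    summary["n_true_ebps"] = sum(1 for r in records if r.status == "true_ebp")
    summary["n_putative_ebps"] = sum(
        1 for r in records if r.status == "putative_ebp"
    )
    summary["n_promoter_links"] = len(promoter_rows)
    return {
        "ebp_records": records,
        "sigma_per_genome": sigma_per_genome,
        "links": all_links,
        "tendencies": tendency_frames,
        "summary": summary,
    }
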