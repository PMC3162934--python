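"""Transcriptional units, context windows, and cross-phylum tendencies.

Operons are maximal same-strand gene runs with intergenic gaps of at most
300 nt; divergons pair adjacent oppositely-oriented units that share an
upstream region of at most 300 nt.  Annotations harvested from context
windows are aggregated per phylum and terms that rank in the top K of at
least two phyla are reported as conserved function tendencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import binomtest

from .promoters import PromoterGeneLink
from .records import GeneRecord, sort_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptionalUnit:
    unit_id: str
    kind: str  # operon | divergon
    gene_ids: tuple[str, ...]
    contig_id: str
    strand: str | None = None


@dataclass(frozen=True)
class ContextWindow:
    anchor: str
    gene_ids: tuple[str, ...]
    genome_id: str = ""


@dataclass
class AnnotationProfile:
    counts: dict          # phylum -> (type, term) -> gene-occurrence count
    coverage: dict        # annotation type -> fraction of occurrences covered
    n_occurrences: int


@dataclass(frozen=True)
class ConservedTendency:
    term: str
    term_type: str
    phyla: tuple[str, ...]
    ranks: dict = field(hash=False, compare=False, default_factory=dict)


# ---------------------------------------------------------------------------
# unit construction


def build_units(
    genes: list[GeneRecord], max_gap: int = 300
) -> list[TranscriptionalUnit]:
    """Operons plus divergons; every gene lands in exactly one operon."""
    ordered = sort_genes(genes)
    operons: list[list[GeneRecord]] = []
    current: list[GeneRecord] = []
    for g in ordered:
        if current:
            prev = current[-1]
            same_contig = g.contig_id == prev.contig_id
            same_strand = g.strand == prev.strand
            gap = g.start - prev.end
            if same_contig and same_strand and gap <= max_gap:
                if gap < 0:
                    logger.info(
                        "overlapping same-strand genes %s/%s merged into one unit",
                        prev.gene_id, g.gene_id,
                    )
                current.append(g)
                continue
            operons.append(current)
            current = [g]
        else:
            current = [g]
    if current:
        operons.append(current)

    units = [
        TranscriptionalUnit(
            unit_id=f"operon_{k + 1}",
            kind="operon",
            gene_ids=tuple(g.gene_id for g in run),
            contig_id=run[0].contig_id,
            strand=run[0].strand,
        )
        for k, run in enumerate(operons)
    ]

    # divergons: a minus-strand unit followed by a plus-strand unit whose
    # transcription starts face away from each other across a short gap
    n_div = 0
    for a, b in zip(operons, operons[1:]):
        if a[0].contig_id != b[0].contig_id:
            continue
        if a[0].strand == "-" and b[0].strand == "+":
            gap = b[0].start - a[-1].end
            if gap <= max_gap:
                n_div += 1
                units.append(
                    TranscriptionalUnit(
                        unit_id=f"divergon_{n_div}",
                        kind="divergon",
                        gene_ids=tuple(
                            g.gene_id for g in list(a) + list(b)
                        ),
                        contig_id=a[0].contig_id,
                        strand=None,
                    )
                )
    return units


def context_window(
    genes: list[GeneRecord], anchor_gene: str, n_up: int = 10, n_down: int = 10
) -> ContextWindow:
    """Up to n genes on each side of the anchor by genomic order."""
    ordered = sort_genes(genes)
    pos = next(
        (k for k, g in enumerate(ordered) if g.gene_id == anchor_gene), None
    )
    if pos is None:
        raise KeyError(f"anchor gene {anchor_gene!r} not found")
    contig = ordered[pos].contig_id
    left = [
        g.gene_id for g in ordered[max(0, pos - n_up) : pos]
        if g.contig_id == contig
    ]
    right = [
        g.gene_id for g in ordered[pos + 1 : pos + 1 + n_down]
        if g.contig_id == contig
    ]
    return ContextWindow(anchor=anchor_gene, gene_ids=tuple(left + right))


def promoter_context(
    link: PromoterGeneLink,
    genes: list[GeneRecord],
    units: list[TranscriptionalUnit],
    max_down: int = 10,
) -> ContextWindow:
    """Genes of the unit downstream of a promoter (reading order, capped)
    plus the single gene upstream of the unit."""
    ordered = sort_genes(genes)
    by_id = {g.gene_id: k for k, g in enumerate(ordered)}
    unit = next(
        (
            u for u in units
            if u.kind == "operon" and link.gene_id in u.gene_ids
        ),
        None,
    )
    if unit is None:
        downstream = [link.gene_id]
    else:
        ids = list(unit.gene_ids)
        if unit.strand == "-":
            ids = ids[::-1]
        # start reading at the linked (unit-leading) gene
        if link.gene_id in ids:
            ids = ids[ids.index(link.gene_id):]
        downstream = ids[:max_down]
    anchor_idx = by_id[downstream[0]]
    gene = ordered[anchor_idx]
    # the one gene upstream of the promoter, i.e. the genomic neighbor on
    # the far side of the unit's transcription start
    step = -1 if gene.strand == "+" else 1
    up_idx = anchor_idx + step
    upstream = []
    if 0 <= up_idx < len(ordered) and ordered[up_idx].contig_id == gene.contig_id:
        upstream = [ordered[up_idx].gene_id]
    return ContextWindow(
        anchor=f"promoter@{link.hit.contig_id}:{link.hit.minus11_pos}",
        gene_ids=tuple(upstream + downstream),
    )


# ---------------------------------------------------------------------------
# annotation aggregation


def collect_annotations(
    windows: list[ContextWindow],
    annotations: dict,        # gene_id -> list of (type, term)
    phylum_of: dict,          # genome_id -> phylum label
) -> AnnotationProfile:
    """Per-phylum term counts over context genes (once per window occurrence)
    plus per-annotation-type coverage fractions."""
    counts: dict[str, dict[tuple[str, str], int]] = {}
    types = set()
    for w in windows:
        for gid in w.gene_ids:
            for t, _ in annotations.get(gid, []):
                types.add(t)
    covered = {t: 0 for t in types}
    n_occ = 0
    for w in windows:
        phylum = phylum_of.get(w.genome_id, w.genome_id or "unknown")
        per_phylum = counts.setdefault(phylum, {})
        for gid in w.gene_ids:
            n_occ += 1
            terms = annotations.get(gid, [])
            seen_types = set()
            for t, term in terms:
                per_phylum[(t, term)] = per_phylum.get((t, term), 0) + 1
                seen_types.add(t)
            for t in seen_types:
                covered[t] += 1
    coverage = {
        t: (covered[t] / n_occ if n_occ else 0.0) for t in sorted(types)
    }
    return AnnotationProfile(counts=counts, coverage=coverage, n_occurrences=n_occ)


def _top_k_terms(term_counts: dict, k: int) -> dict:
    """Terms in the top k by count, boundary ties included; term -> rank."""
    if not term_counts:
        return {}
    ordered = sorted(term_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) > k:
        cutoff_count = ordered[k - 1][1]
        ordered = [kv for kv in ordered if kv[1] >= cutoff_count]
    ranks = {}
    for key, count in ordered:
        # rank = 1 + number of terms with a strictly greater count
        ranks[key] = 1 + sum(1 for c in term_counts.values() if c > count)
    return ranks


def extract_conserved_tendencies(
    profile: AnnotationProfile,
    genome_counts: dict,
    k_small: int = 10,
    k_large: int = 20,
    large_threshold: int = 10,
    min_phyla: int = 2,
) -> list[ConservedTendency]:
    """Terms that are top-K within at least ``min_phyla`` phyla.

    K is ``k_large`` for phyla with at least ``large_threshold`` genomes and
    ``k_small`` otherwise; ties at the boundary are all included.
    """
    support: dict[tuple[str, str], dict[str, int]] = {}
    for phylum, term_counts in profile.counts.items():
        k = k_large if genome_counts.get(phylum, 0) >= large_threshold else k_small
        for key, rank in _top_k_terms(term_counts, k).items():
            support.setdefault(key, {})[phylum] = rank
    out = []
    for (t, term) in sorted(support):
        ranks = support[(t, term)]
        if len(ranks) >= min_phyla:
            out.append(
                ConservedTendency(
                    term=term,
                    term_type=t,
                    phyla=tuple(sorted(ranks)),
                    ranks=ranks,
                )
            )
    return out


def cog_category_representation(
    windows: list[ContextWindow],
    annotations: dict,         # gene_id -> list of (type, term)
    background: dict,          # COG category -> background fraction
    alpha: float = 0.05,
    category_type: str = "COG_category",
) -> dict:
    """Over-representation flag per COG functional category.

    '+' when the observed category fraction among context-gene category
    annotations exceeds the background and a one-sided binomial test is
    significant at ``alpha``; '-' otherwise; blank ('') with no data.
    """
    if sum(background.values()) > 1 + 1e-9:
        raise ValueError("background fractions must sum to at most 1")
    observed: dict[str, int] = {}
    n = 0
    for w in windows:
        for gid in w.gene_ids:
            for t, term in annotations.get(gid, []):
                if t == category_type:
                    observed[term] = observed.get(term, 0) + 1
                    n += 1
    flags = {}
    for cat in sorted(background):
        if n == 0:
            flags[cat] = ""
            continue
        x = observed.get(cat, 0)
        p_bg = background[cat]
        if x / n > p_bg and p_bg < 1:
            p = binomtest(x, n, p_bg, alternative="greater").pvalue
            flags[cat] = "+" if p < alpha else "-"
        else:
            flags[cat] = "-"
    return flags
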