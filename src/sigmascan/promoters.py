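"""Genome scanning with a frequency matrix and promoter/gene linkage.

Both strands of every contig are scored at every offset; hits above a
fraction of the maximum attainable score are kept (overlaps and both-strand
matches included).  Hits are linked to the nearest gene on each chromosomal
side with a signed distance measured from the matrix's -11 anchor column to
the gene's translation start, along the hit's reading direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .motif import PositionFrequencyMatrix, max_score, reverse_complement
from .records import GeneRecord, GenomeSequence, sort_genes

logger = logging.getLogger(__name__)

INLINE = "inline"
OPPOSING = "opposing"


@dataclass(frozen=True)
class MotifHit:
    contig_id: str
    start: int
    end: int
    strand: str
    score: float
    minus11_pos: int
    rank: int | None = None


@dataclass(frozen=True)
class PromoterGeneLink:
    hit: MotifHit
    gene_id: str
    distance: int
    orientation: str


def _window_scores(pfm: PositionFrequencyMatrix, seq: str) -> np.ndarray:
    """Score of every length-i window of seq, in window-start order."""
    i = pfm.length
    idx = pfm.encode(seq)
    n = len(seq) - i + 1
    total = np.zeros(n, dtype=float)
    # pad a zero row so out-of-alphabet symbols (index -1) contribute 0
    padded = np.vstack([pfm.freqs, np.zeros((1, pfm.freqs.shape[1]))])
    for j in range(i):
        total += padded[j, idx[j : j + n]]
    return total / i


def scan_genome(
    pfm: PositionFrequencyMatrix,
    genome: GenomeSequence,
    threshold_fraction: float = 0.85,
) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold_fraction * max_score."""
    if pfm.tss_offset is None:
        raise ValueError("matrix needs a tss_offset anchor for genome scanning")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    i = pfm.length
    cutoff = threshold_fraction * max_score(pfm) - 1e-12
    hits: list[MotifHit] = []
    for contig_id, seq in genome.contigs:
        L = len(seq)
        if L < i:
            logger.warning(
                "contig %s (%d nt) shorter than motif (%d nt); skipped",
                contig_id, L, i,
            )
            continue
        fwd = _window_scores(pfm, seq)
        for s in np.nonzero(fwd >= cutoff)[0]:
            s = int(s)
            hits.append(
                MotifHit(
                    contig_id=contig_id,
                    start=s,
                    end=s + i,
                    strand="+",
                    score=float(fwd[s]),
                    minus11_pos=s + pfm.tss_offset,
                )
            )
        rev = _window_scores(pfm, reverse_complement(seq))
        for p in np.nonzero(rev >= cutoff)[0]:
            p = int(p)
            start = L - p - i
            hits.append(
                MotifHit(
                    contig_id=contig_id,
                    start=start,
                    end=start + i,
                    strand="-",
                    score=float(rev[p]),
                    # column tss_offset sits i-1-tss_offset in from the
                    # forward-strand start of a minus-strand match
                    minus11_pos=start + (i - 1 - pfm.tss_offset),
                )
            )
    return hits


def rank_hits(hits: list[MotifHit]) -> list[MotifHit]:
    """Dense 1-based ranks, descending score, position-deterministic ties."""
    ordered = sorted(
        hits, key=lambda h: (-h.score, h.contig_id, h.start, h.strand)
    )
    return [replace(h, rank=k + 1) for k, h in enumerate(ordered)]


def _signed_distance(hit: MotifHit, gene: GeneRecord) -> int:
    """Distance from the -11 anchor to the gene's translation start, read
    along the hit's strand; positive means the start lies downstream."""
    delta = gene.translation_start - hit.minus11_pos
    return delta if hit.strand == "+" else -delta


def link_hits_to_genes(
    hits: list[MotifHit], genes: list[GeneRecord]
) -> list[PromoterGeneLink]:
    """Up to two links per hit: nearest gene on each chromosomal side.

    Genes whose translation start coincides with or precedes the -11 anchor
    count as the left side.  A gene containing the element ends up with a
    negative distance because its start lies behind the anchor.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sort_genes(genes):
        by_contig.setdefault(g.contig_id, []).append(g)
    links: list[PromoterGeneLink] = []
    for hit in hits:
        contig_genes = by_contig.get(hit.contig_id)
        if not contig_genes:
            logger.info("no genes on contig %s; hit at %d unlinked",
                        hit.contig_id, hit.start)
            continue
        left = None
        right = None
        for g in contig_genes:
            ts = g.translation_start
            if ts <= hit.minus11_pos:
                if left is None or ts > left.translation_start:
                    left = g
            else:
                if right is None or ts < right.translation_start:
                    right = g
        for g in (left, right):
            if g is None:
                continue
            orientation = INLINE if g.strand == hit.strand else OPPOSING
            links.append(
                PromoterGeneLink(
                    hit=hit,
                    gene_id=g.gene_id,
                    distance=_signed_distance(hit, g),
                    orientation=orientation,
                )
            )
    return links


def filter_promoters(
    links: list[PromoterGeneLink],
    window: tuple[int, int] = (-50, 300),
    top_rank: int | None = None,
) -> list[PromoterGeneLink]:
    """Keep inline links whose distance falls inside ``window``.

    The rank cut (``top_rank``) is opt-in: the genome-wide promoter table
    uses the window alone while the context stage adds ``top_rank=15``.
    """
    lo, hi = window
    out = []
    for link in links:
        if link.orientation != INLINE:
            continue
        if not lo <= link.distance <= hi:
            continue
        if top_rank is not None:
            if link.hit.rank is None or link.hit.rank > top_rank:
                continue
        out.append(link)
    return out


def distance_histogram(
    links: list[PromoterGeneLink], bin_width: int = 100
) -> dict[str, dict[int, float]]:
    """Distance counts per half-open bin [k*w, (k+1)*w), split by orientation.

    The grand total over both orientation series is normalized to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[str, dict[int, int]] = {INLINE: {}, OPPOSING: {}}
    total = 0
    for link in links:
        b = (link.distance // bin_width) * bin_width
        series = counts[link.orientation]
        series[b] = series.get(b, 0) + 1
        total += 1
    if total == 0:
        return {INLINE: {}, OPPOSING: {}}
    return {
        orient: {b: c / total for b, c in sorted(series.items())}
        for orient, series in counts.items()
    }
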