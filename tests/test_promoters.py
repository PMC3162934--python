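import numpy as np
import pytest

from conftest import random_pfm
from sigmascan.motif import (
    AlignedSiteSet,
    build_pfm,
    max_score,
    reverse_complement,
    score_sequence,
)
from sigmascan.promoters import (
    INLINE,
    OPPOSING,
    MotifHit,
    PromoterGeneLink,
    distance_histogram,
    filter_promoters,
    link_hits_to_genes,
    rank_hits,
    scan_genome,
)
from sigmascan.records import GeneRecord, GenomeSequence


def brute_force_scan(pfm, genome, threshold_fraction):
    """All-windows oracle: score every window on both strands directly."""
    cutoff = threshold_fraction * max_score(pfm) - 1e-12
    i = pfm.length
    hits = []
    for contig_id, seq in genome.contigs:
        if len(seq) < i:
            continue
        for s in range(len(seq) - i + 1):
            sc = score_sequence(pfm, seq[s : s + i])
            if sc >= cutoff:
                hits.append((contig_id, s, "+", sc))
            sc = score_sequence(pfm, reverse_complement(seq[s : s + i]))
            if sc >= cutoff:
                hits.append((contig_id, s, "-", sc))
    return sorted(hits)


def informative_pfm(tss_offset=3):
    sites = AlignedSiteSet(sites=("TGGCAC", "TGGCAC", "TGGCAT"))
    return build_pfm(sites, tss_offset=tss_offset)


class TestScanGenome:
    def test_planted_site_in_a_background(self):
        pfm = informative_pfm()
        background = "A" * 500
        site = pfm.argmax_string()
        seq = background[:200] + site + background[206:]
        genome = GenomeSequence(genome_id="g", contigs=[("c1", seq)])
        hits = [h for h in scan_genome(pfm, genome, 0.85) if h.strand == "+"]
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (200, 206)
        assert hits[0].score == max_score(pfm)
        assert hits[0].minus11_pos == 203

    def test_threshold_one_absent_argmax_empty(self):
        pfm = informative_pfm()
        genome = GenomeSequence(genome_id="g", contigs=[("c1", "A" * 300)])
        assert scan_genome(pfm, genome, 1.0) == []

    def test_palindromic_motif_two_hits(self):
        pfm = build_pfm(AlignedSiteSet(sites=("ACGT",)), tss_offset=0)
        genome = GenomeSequence(genome_id="g", contigs=[("c1", "GGACGTGG")])
        hits = scan_genome(pfm, genome, 1.0)
        spans = sorted((h.start, h.end, h.strand) for h in hits)
        assert spans == [(2, 6, "+"), (2, 6, "-")]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            pfm = random_pfm(rng, length=int(rng.integers(4, 10)), tss_offset=0)
            seq = "".join("ACGT"[k] for k in rng.integers(4, size=2000))
            genome = GenomeSequence(genome_id="g", contigs=[("c1", seq)])
            got = sorted(
                (h.contig_id, h.start, h.strand, h.score)
                for h in scan_genome(pfm, genome, 0.9)
            )
            expected = brute_force_scan(pfm, genome, 0.9)
            assert len(got) == len(expected)
            for (c1, s1, st1, sc1), (c2, s2, st2, sc2) in zip(got, expected):
                assert (c1, s1, st1) == (c2, s2, st2)
                assert sc1 == pytest.approx(sc2, abs=1e-12)

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(29)
        pfm = random_pfm(rng, length=6, tss_offset=2)
        seq = "".join("ACGT"[k] for k in rng.integers(4, size=800))
        genome = GenomeSequence(genome_id="g", contigs=[("c1", seq)])
        mirrored = GenomeSequence(
            genome_id="g", contigs=[("c1", reverse_complement(seq))]
        )
        fwd = scan_genome(pfm, genome, 0.85)
        rev = scan_genome(pfm, mirrored, 0.85)
        L = len(seq)
        mapped = sorted(
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+",
             round(h.score, 12))
            for h in rev
        )
        original = sorted(
            (h.start, h.end, h.strand, round(h.score, 12)) for h in fwd
        )
        assert mapped == original

    def test_short_contig_skipped(self, caplog):
        pfm = informative_pfm()
        genome = GenomeSequence(genome_id="g", contigs=[("tiny", "ACG")])
        assert scan_genome(pfm, genome, 0.85) == []

    def test_requires_tss_offset(self):
        pfm = build_pfm(AlignedSiteSet(sites=("ACGT",)))
        genome = GenomeSequence(genome_id="g", contigs=[("c1", "ACGTACGT")])
        with pytest.raises(ValueError):
            scan_genome(pfm, genome, 0.85)


class TestRankHits:
    def _hit(self, start, score):
        return MotifHit(
            contig_id="c1", start=start, end=start + 6, strand="+",
            score=score, minus11_pos=start,
        )

    def test_sorting_contract(self):
        hits = [self._hit(0, 0.9), self._hit(10, 0.95), self._hit(20, 0.9)]
        ranked = sorted(rank_hits(hits), key=lambda h: h.start)
        assert [h.rank for h in ranked] == [2, 1, 3]

    def test_empty(self):
        assert rank_hits([]) == []

    def test_equal_scores_positional_order(self):
        hits = [self._hit(s, 0.9) for s in (0, 10, 20)]
        ranked = rank_hits(hits)
        assert [(h.start, h.rank) for h in ranked] == [(0, 1), (10, 2), (20, 3)]


class TestLinkHitsToGenes:
    def _hit(self, minus11, strand="+"):
        return MotifHit(
            contig_id="c1", start=minus11 - 3, end=minus11 + 3, strand=strand,
            score=0.9, minus11_pos=minus11,
        )

    def test_downstream_inline_positive_distance(self):
        genes = [GeneRecord("g1", "c1", 1100, 1400, "+")]
        links = link_hits_to_genes([self._hit(1000)], genes)
        assert len(links) == 1
        assert links[0].distance == 100
        assert links[0].orientation == INLINE

    def test_hit_inside_gene_negative_distance(self):
        genes = [GeneRecord("g1", "c1", 900, 1200, "+")]
        links = link_hits_to_genes([self._hit(1000)], genes)
        assert links[0].distance == -100
        assert links[0].distance < 0

    def test_opposing_gene_on_left(self):
        genes = [GeneRecord("g1", "c1", 700, 951, "-")]  # start codon at 950
        links = link_hits_to_genes([self._hit(1000)], genes)
        assert links[0].orientation == OPPOSING
        assert links[0].distance == -50

    def test_two_links_one_per_side(self):
        genes = [
            GeneRecord("gL", "c1", 500, 800, "+"),
            GeneRecord("gR", "c1", 1200, 1500, "+"),
        ]
        links = link_hits_to_genes([self._hit(1000)], genes)
        assert sorted(l.gene_id for l in links) == ["gL", "gR"]
        by_id = {l.gene_id: l.distance for l in links}
        assert by_id == {"gL": -500, "gR": 200}

    def test_minus_strand_hit_distance_sign(self):
        # minus-strand gene with start codon at 1199; promoter -11 at 1300
        genes = [GeneRecord("g1", "c1", 900, 1200, "-")]
        links = link_hits_to_genes([self._hit(1300, strand="-")], genes)
        assert links[0].distance == 101
        assert links[0].orientation == INLINE

    def test_contig_without_genes(self):
        assert link_hits_to_genes([self._hit(1000)], []) == []


class TestFilterPromoters:
    def _link(self, distance, orientation, rank=1):
        hit = MotifHit(
            contig_id="c1", start=0, end=6, strand="+", score=0.9,
            minus11_pos=3, rank=rank,
        )
        return PromoterGeneLink(
            hit=hit, gene_id="g", distance=distance, orientation=orientation
        )

    def test_inline_in_window_retained(self):
        links = [self._link(250, INLINE, rank=3)]
        assert filter_promoters(links) == links

    def test_outside_window_removed(self):
        assert filter_promoters([self._link(350, INLINE)]) == []

    def test_opposing_removed(self):
        assert filter_promoters([self._link(100, OPPOSING)]) == []

    def test_rank_cut_opt_in(self):
        links = [self._link(100, INLINE, rank=20)]
        assert filter_promoters(links) == links
        assert filter_promoters(links, top_rank=15) == []

    def test_subset_and_idempotent(self):
        links = [
            self._link(d, o)
            for d in (-100, -50, 0, 150, 300, 301)
            for o in (INLINE, OPPOSING)
        ]
        kept = filter_promoters(links)
        assert set(map(id, kept)) <= set(map(id, links))
        assert filter_promoters(kept) == kept


class TestDistanceHistogram:
    def _links(self, distances, orientation=INLINE):
        hit = MotifHit("c1", 0, 6, "+", 0.9, 3)
        return [
            PromoterGeneLink(hit=hit, gene_id="g", distance=d, orientation=orientation)
            for d in distances
        ]

    def test_hand_count(self):
        hist = distance_histogram(self._links([10, 20, 150, 250]))
        assert hist[INLINE] == {0: 0.5, 100: 0.25, 200: 0.25}
        assert hist[OPPOSING] == {}

    def test_empty(self):
        assert distance_histogram([]) == {INLINE: {}, OPPOSING: {}}

    def test_negative_bin_convention(self):
        hist = distance_histogram(self._links([-30, 30]))
        assert hist[INLINE] == {-100: 0.5, 0: 0.5}

    def test_grand_total_normalized_across_series(self):
        links = self._links([10, 110]) + self._links([50], OPPOSING)
        hist = distance_histogram(links)
        total = sum(hist[INLINE].values()) + sum(hist[OPPOSING].values())
        assert total == pytest.approx(1.0)
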