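import numpy as np
import pytest

from sigmascan.context import (
    AnnotationProfile,
    ContextWindow,
    build_units,
    cog_category_representation,
    collect_annotations,
    context_window,
    extract_conserved_tendencies,
    promoter_context,
)
from sigmascan.promoters import INLINE, MotifHit, PromoterGeneLink
from sigmascan.records import GeneRecord


def gene(gid, start, end, strand="+", contig="c1"):
    return GeneRecord(gid, contig, start, end, strand)


def brute_force_operons(genes, max_gap=300):
    """Independent grouping oracle: pairwise adjacency closure."""
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    groups = []
    for g in ordered:
        if (
            groups
            and groups[-1][-1].contig_id == g.contig_id
            and groups[-1][-1].strand == g.strand
            and g.start - groups[-1][-1].end <= max_gap
        ):
            groups[-1].append(g)
        else:
            groups.append([g])
    return [tuple(x.gene_id for x in grp) for grp in groups]


class TestBuildUnits:
    def test_small_gap_one_operon(self):
        genes = [gene("a", 0, 300), gene("b", 500, 800)]
        ops = [u for u in build_units(genes) if u.kind == "operon"]
        assert len(ops) == 1
        assert ops[0].gene_ids == ("a", "b")

    def test_large_gap_two_operons(self):
        genes = [gene("a", 0, 300), gene("b", 700, 1000)]
        ops = [u for u in build_units(genes) if u.kind == "operon"]
        assert len(ops) == 2

    def test_boundary_300_joins_301_splits(self):
        joined = [gene("a", 0, 300), gene("b", 600, 900)]
        split = [gene("a", 0, 300), gene("b", 601, 901)]
        assert len([u for u in build_units(joined) if u.kind == "operon"]) == 1
        assert len([u for u in build_units(split) if u.kind == "operon"]) == 2

    def test_singleton(self):
        ops = [u for u in build_units([gene("a", 10, 100)]) if u.kind == "operon"]
        assert len(ops) == 1 and ops[0].gene_ids == ("a",)

    def test_strand_change_splits(self):
        genes = [gene("a", 0, 300), gene("b", 350, 600, "-")]
        ops = [u for u in build_units(genes) if u.kind == "operon"]
        assert len(ops) == 2

    def test_divergon_detected(self):
        genes = [gene("a", 0, 300, "-"), gene("b", 450, 800, "+")]
        divs = [u for u in build_units(genes) if u.kind == "divergon"]
        assert len(divs) == 1
        assert divs[0].gene_ids == ("a", "b")

    def test_convergent_pair_not_divergon(self):
        genes = [gene("a", 0, 300, "+"), gene("b", 450, 800, "-")]
        assert [u for u in build_units(genes) if u.kind == "divergon"] == []

    def test_overlapping_same_strand_merge(self):
        genes = [gene("a", 0, 300), gene("b", 200, 500)]
        ops = [u for u in build_units(genes) if u.kind == "operon"]
        assert len(ops) == 1

    def test_every_gene_in_exactly_one_operon(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            genes, pos = [], 0
            for k in range(int(rng.integers(1, 20))):
                pos += int(rng.integers(0, 600))
                length = int(rng.integers(100, 500))
                genes.append(
                    gene(f"g{k}", pos, pos + length,
                         "+" if rng.random() < 0.5 else "-")
                )
                pos += length
            ops = [u for u in build_units(genes) if u.kind == "operon"]
            all_ids = [gid for u in ops for gid in u.gene_ids]
            assert sorted(all_ids) == sorted(g.gene_id for g in genes)
            assert len(all_ids) == len(set(all_ids))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            genes, pos = [], 0
            for k in range(int(rng.integers(1, 15))):
                pos += int(rng.integers(0, 700))
                length = int(rng.integers(50, 400))
                genes.append(
                    gene(f"g{k}", pos, pos + length,
                         "+" if rng.random() < 0.5 else "-",
                         contig=f"c{int(rng.integers(1, 3))}")
                )
                pos += length
            got = [
                u.gene_ids for u in build_units(genes) if u.kind == "operon"
            ]
            assert got == brute_force_operons(genes)


class TestContextWindow:
    def _genes(self, n=30):
        return [gene(f"g{k:02d}", k * 1000, k * 1000 + 500) for k in range(n)]

    def test_full_window(self):
        w = context_window(self._genes(), "g15")
        assert len(w.gene_ids) == 20
        assert "g15" not in w.gene_ids

    def test_truncated_at_start(self):
        w = context_window(self._genes(), "g03")
        assert len(w.gene_ids) == 13

    def test_lone_anchor_empty(self):
        w = context_window([gene("solo", 0, 100)], "solo")
        assert w.gene_ids == ()

    def test_absent_anchor_raises(self):
        with pytest.raises(KeyError):
            context_window(self._genes(), "nope")


class TestPromoterContext:
    def _link(self, gene_id, minus11=100):
        hit = MotifHit("c1", minus11 - 13, minus11 + 3, "+", 0.9, minus11, rank=1)
        return PromoterGeneLink(hit=hit, gene_id=gene_id, distance=50,
                                orientation=INLINE)

    def test_operon_plus_one_upstream(self):
        genes = [gene("up", 0, 300, "-")] + [
            gene(f"op{k}", 600 + k * 400, 900 + k * 400) for k in range(4)
        ]
        units = build_units(genes)
        w = promoter_context(self._link("op0", minus11=550), genes, units)
        assert w.gene_ids == ("up", "op0", "op1", "op2", "op3")

    def test_long_operon_capped_at_ten(self):
        genes = [gene("up", 0, 300, "-")] + [
            gene(f"op{k:02d}", 600 + k * 400, 900 + k * 400) for k in range(12)
        ]
        units = build_units(genes)
        w = promoter_context(self._link("op00", minus11=550), genes, units)
        assert len(w.gene_ids) == 11  # 10 downstream + 1 upstream
        assert w.gene_ids[0] == "up"

    def test_contig_start_no_upstream(self):
        genes = [gene(f"op{k}", 100 + k * 400, 400 + k * 400) for k in range(3)]
        units = build_units(genes)
        w = promoter_context(self._link("op0", minus11=50), genes, units)
        assert w.gene_ids == ("op0", "op1", "op2")


class TestCollectAnnotations:
    def _windows(self):
        return [
            ContextWindow(anchor="a", gene_ids=("g1", "g2", "g3", "g4"),
                          genome_id="gen1")
        ]

    def test_counts(self):
        annotations = {
            "g1": [("COG", "COG0642")],
            "g2": [("COG", "COG0642")],
        }
        profile = collect_annotations(
            self._windows(), annotations, {"gen1": "PhylumA"}
        )
        assert profile.counts["PhylumA"][("COG", "COG0642")] == 2

    def test_coverage(self):
        annotations = {
            "g1": [("COG", "X")], "g2": [("COG", "Y")], "g3": [("COG", "Z")],
        }
        profile = collect_annotations(
            self._windows(), annotations, {"gen1": "PhylumA"}
        )
        assert profile.coverage["COG"] == pytest.approx(0.75)

    def test_empty_windows(self):
        profile = collect_annotations([], {}, {})
        assert profile.counts == {}
        assert profile.n_occurrences == 0

    def test_gene_counted_once_per_window_occurrence(self):
        windows = [
            ContextWindow(anchor="a", gene_ids=("g1",), genome_id="gen1"),
            ContextWindow(anchor="b", gene_ids=("g1",), genome_id="gen1"),
        ]
        profile = collect_annotations(
            windows, {"g1": [("COG", "X")]}, {"gen1": "P"}
        )
        assert profile.counts["P"][("COG", "X")] == 2


def profile_from(counts):
    return AnnotationProfile(
        counts={
            phylum: {("COG", term): c for term, c in terms.items()}
            for phylum, terms in counts.items()
        },
        coverage={},
        n_occurrences=sum(sum(t.values()) for t in counts.values()),
    )


class TestExtractConservedTendencies:
    def test_two_phyla_retained(self):
        profile = profile_from(
            {"P1": {"X": 5, "Y": 1}, "P2": {"X": 4, "Z": 1}}
        )
        out = extract_conserved_tendencies(profile, {"P1": 3, "P2": 3})
        assert [t.term for t in out] == ["X"]
        assert out[0].phyla == ("P1", "P2")

    def test_single_phylum_dropped(self):
        profile = profile_from({"P1": {"X": 5}, "P2": {"Z": 3}})
        out = extract_conserved_tendencies(profile, {"P1": 1, "P2": 1})
        assert out == []

    def test_boundary_ties_included(self):
        terms = {f"t{k:02d}": 20 - k for k in range(9)}
        terms.update({"tieA": 1, "tieB": 1})
        profile = profile_from({"P1": terms, "P2": {"tieA": 9, "tieB": 8}})
        out = extract_conserved_tendencies(
            profile, {"P1": 1, "P2": 1}, k_small=10
        )
        names = {t.term for t in out}
        # both rank-10 ties in P1 survive the cut and match P2's top terms
        assert {"tieA", "tieB"} <= names

    def test_k_switches_on_genome_count(self):
        terms_p1 = {f"t{k:02d}": 40 - k for k in range(15)}
        profile = profile_from({"P1": terms_p1, "P2": {"t14": 2}})
        small = extract_conserved_tendencies(profile, {"P1": 2, "P2": 2})
        large = extract_conserved_tendencies(profile, {"P1": 20, "P2": 2})
        # t14 is rank 15 in P1: only top-20 (large phylum) lets it through
        assert "t14" not in {t.term for t in small}
        assert "t14" in {t.term for t in large}

    def test_monotone_in_min_phyla(self):
        rng = np.random.default_rng(47)
        counts = {
            f"P{p}": {f"t{int(k)}": int(rng.integers(1, 30)) for k in rng.integers(0, 30, size=12)}
            for p in range(4)
        }
        profile = profile_from(counts)
        genome_counts = {p: 5 for p in counts}
        sizes = []
        for mp in (2, 3, 4):
            out = extract_conserved_tendencies(
                profile, genome_counts, min_phyla=mp
            )
            sizes.append({t.term for t in out})
        assert sizes[1] <= sizes[0]
        assert sizes[2] <= sizes[1]


class TestCogCategoryRepresentation:
    def _windows(self, categories):
        genes = tuple(f"g{k}" for k in range(len(categories)))
        annotations = {
            g: [("COG_category", c)] for g, c in zip(genes, categories)
        }
        return [ContextWindow(anchor="a", gene_ids=genes)], annotations

    def test_enriched_category_flagged(self):
        windows, annotations = self._windows(["M"] * 60 + ["C"] * 140)
        background = {"M": 0.1, "C": 0.7}
        flags = cog_category_representation(windows, annotations, background)
        assert flags["M"] == "+"  # 30% observed vs 10% background, n=200
        assert flags["C"] == "-"

    def test_observed_equal_background_minus(self):
        windows, annotations = self._windows(["M"] * 10 + ["C"] * 90)
        flags = cog_category_representation(
            windows, annotations, {"M": 0.1, "C": 0.9}
        )
        assert flags["M"] == "-"

    def test_no_data_blank(self):
        flags = cog_category_representation([], {}, {"M": 0.1})
        assert flags["M"] == ""
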