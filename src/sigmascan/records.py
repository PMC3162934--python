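"""Shared genome-level record types (0-based half-open coordinates)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """A gene on the forward-strand coordinate system of its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def translation_start(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeSequence:
    genome_id: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id}: duplicate contig ids")
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {cid} is empty")

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)


def sort_genes(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Genomic order: by contig then start then end."""
    return sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
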