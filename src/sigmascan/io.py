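"""Readers and writers for the standard formats the pipeline consumes.

Coordinates are 1-based inclusive on disk (GFF3 convention, and the result
TSVs follow suit) and 0-based half-open in memory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .motif import PositionFrequencyMatrix
from .records import GeneRecord, GenomeSequence, sort_genes
from .survey import GenomeMetadata


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, genome_id: str | None = None) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return GenomeSequence(
        genome_id=genome_id or Path(path).stem,
        contigs=[(r.id, str(r.seq).upper()) for r in records],
    )


def read_protein_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, entries: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path, feature_types: tuple[str, ...] = ("gene", "CDS")
) -> list[GeneRecord]:
    """Genes from a GFF3 file, sorted per contig; skipped types are counted."""
    genes = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                skipped += 1
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            attr_map = {}
            for part in attrs.split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("Name") or f"feature_{lineno}"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                )
            )
    return sort_genes(genes)


def write_gff3(path, genes: list[GeneRecord], source: str = "sigmascan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sort_genes(genes):
            fh.write(
                "\t".join(
                    [
                        g.contig_id, source, "gene",
                        str(g.start + 1), str(g.end), ".",
                        g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6)


@dataclass(frozen=True)
class BlastRow:
    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_blast_tab(path) -> list[BlastRow]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                rows.append(
                    BlastRow(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        length=int(fields[3]),
                        mismatch=int(fields[4]),
                        gapopen=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_blast_tab(path, rows: list[BlastRow]) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.query_id, r.subject_id, f"{r.pident:.1f}",
                        str(r.length), str(r.mismatch), str(r.gapopen),
                        str(r.qstart), str(r.qend), str(r.sstart), str(r.send),
                        f"{r.evalue:.3g}", f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PFM TSV


def write_pfm(path, pfm: PositionFrequencyMatrix, digits: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name {pfm.name}\n")
        fh.write(f"#alphabet {pfm.alphabet}\n")
        if pfm.tss_offset is not None:
            fh.write(f"#tss_offset_minus11 {pfm.tss_offset}\n")
        for j in range(pfm.length):
            vals = "\t".join(f"{v:.{digits}f}" for v in pfm.freqs[j])
            fh.write(f"{j + 1}\t{vals}\n")


def read_pfm(path) -> PositionFrequencyMatrix:
    name = "motif"
    alphabet = None
    tss_offset = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(" ")
                if key == "name":
                    name = value
                elif key == "alphabet":
                    alphabet = value
                elif key == "tss_offset_minus11":
                    tss_offset = int(value)
                continue
            fields = line.split("\t")
            if alphabet is None:
                raise ParseError(f"{path}: missing #alphabet header")
            if len(fields) != len(alphabet) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(alphabet) + 1} columns"
                )
            freqs = [float(v) for v in fields[1:]]
            if abs(sum(freqs) - 1.0) > 1e-6:
                raise ParseError(
                    f"{path}:{lineno}: column frequencies sum to {sum(freqs)}"
                )
            rows.append(freqs)
    if alphabet is None:
        raise ParseError(f"{path}: missing #alphabet header")
    if not rows:
        raise ParseError(f"{path}: no frequency rows")
    freqs = np.array(rows, dtype=float)
    # renormalize the <=1e-6 write-precision slack so invariants hold exactly
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    return PositionFrequencyMatrix(
        freqs=freqs, alphabet=alphabet, name=name, tss_offset=tss_offset
    )


# ---------------------------------------------------------------------------
# tabular inputs


def read_metadata_tsv(path) -> list[GenomeMetadata]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            motile_raw = (row.get("motile") or "").strip().lower()
            motile = {"1": True, "true": True, "yes": True,
                      "0": False, "false": False, "no": False}.get(motile_raw)
            out.append(
                GenomeMetadata(
                    genome_id=row["genome_id"],
                    phylum_or_class=row["phylum_or_class"],
                    size_bp=int(row["size_bp"]),
                    motile=motile,
                    membrane=row.get("membrane", "other"),
                    lps=row.get("lps", "unknown"),
                )
            )
    return out


def read_annotation_tsv(path) -> dict[str, list[tuple[str, str]]]:
    """gene_id -> list of (annotation type, term)."""
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["gene_id"], []).append((row["type"], row["term"]))
    return out


def read_domain_tsv(path) -> dict[str, list[str]]:
    """protein_id -> domain terms in N-to-C order."""
    entries: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.setdefault(row["protein_id"], []).append(
                (int(row["start"]), row["term"])
            )
    return {
        pid: [term for _, term in sorted(doms)]
        for pid, doms in entries.items()
    }


def read_seed_tsv(path):
    """Rows of (seed_id, group, role) where role is 'ebp' or 'sigma54'."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                (row["seed_id"], row.get("group", ""), row.get("role", "ebp"))
            )
    return out


def read_background_tsv(path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["category"]] = float(row["fraction"])
    return out
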