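"""Seeded synthetic genomes, proteins, and annotation tables with ground truth.

Everything the pipeline consumes can be generated here with known answers:
genomes carry operon structure and promoter sites planted at chosen
distances and orientations, proteins carry chosen activator-loop variants
and per-seed e-value profiles engineered to pass or fail the filters, and
annotation tables carry terms enriched in the context of chosen anchors.
A single integer seed makes the emitted files byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .ebp import (
    CANONICAL_LOOP,
    SubstitutionRuleTable,
    FUNCTIONAL,
    INACTIVE,
    PUTATIVE,
)
from .motif import PositionFrequencyMatrix, reverse_complement
from .records import GeneRecord, GenomeSequence

# 34 experimentally characterized activator families used to seed searches
EBP_SEED_NAMES = (
    "AcoR", "AdnA", "AlgB", "AtoC", "BkdR", "CbrB", "CelR", "DctD",
    "FhlA", "FleQ", "FleR", "FlgR", "FlrA", "FlrC", "FrgC", "GabR",
    "HrpR", "HrpS", "HydG", "HyfR", "LafK", "LevR", "NorR", "NtrC",
    "PhhR", "PrpR", "PspF", "QseF", "Rrp2", "TouR", "VnfA", "XylR",
    "YfhJ", "ZraR",
)
SIGMA54_SEED_NAMES = ("rpoN_Eco", "sigL_Bsu")

# scaffold residues are inactive at every loop position, so the planted
# variant is always the best-scoring window and flanking residues can never
# upgrade a deleted loop to a putative substitution
SCAFFOLD_RESIDUES = "KLPQRW"

ARCHITECTURE_CYCLE = ("Ia", "Ib", "Ic", "II")


def default_promoter_pfm() -> PositionFrequencyMatrix:
    """A 16-column bipartite motif: two conserved blocks around a degenerate
    spacer, with the -11 anchor inside the downstream block."""
    base = {"A": 0, "C": 1, "G": 2, "T": 3}
    consensus = "TGGCACGNNNNTTGCA"
    freqs = np.full((16, 4), 0.25)
    for j, b in enumerate(consensus):
        if b == "N":
            continue
        col = np.full(4, 0.01)
        col[base[b]] = 0.97
        freqs[j] = col
    return PositionFrequencyMatrix(
        freqs=freqs, alphabet="ACGT", name="synthetic-24-12", tss_offset=13
    )


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_genomes: int = 3
    genome_length: int = 200_000
    gc: float = 0.5
    n_genes: int = 120
    gene_length: tuple[int, int] = (300, 900)
    operon_size: tuple[int, int] = (1, 5)
    within_operon_gap: tuple[int, int] = (20, 250)
    between_operon_gap: tuple[int, int] = (400, 800)
    pfm: PositionFrequencyMatrix | None = None
    n_planted_promoters: int = 20
    planted_distance: tuple[int, int] = (0, 250)
    plant_mode: str = "argmax"  # argmax | sample
    n_decoy_sites: int = 5
    n_true_ebps: int = 9
    n_decoy_proteins: int = 9
    gaftga_variants: tuple[str, ...] = ("GAFTGA",)
    phyla: tuple[str, ...] = ("PhylumA", "PhylumB", "PhylumC")
    sigma54_presence: tuple[bool, ...] | None = None  # default: all present
    enriched_terms: dict = field(default_factory=dict)
    baseline_terms: int = 40
    cog_categories: str = "CEGMNOTU"

    def __post_init__(self) -> None:
        if self.pfm is None:
            self.pfm = default_promoter_pfm()
        for name in ("gene_length", "operon_size", "within_operon_gap",
                     "between_operon_gap", "planted_distance"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: range ({lo}, {hi}) is not ordered")
        if self.within_operon_gap[1] > 300:
            raise ValueError("within-operon gaps must stay at or below 300 nt")
        if self.between_operon_gap[0] <= 300:
            raise ValueError("between-operon gaps must exceed 300 nt")
        for v in self.gaftga_variants:
            if len(v) not in (5, 6):
                raise ValueError(f"loop variant {v!r} must have length 5 or 6")
        if self.plant_mode not in ("argmax", "sample"):
            raise ValueError("plant_mode must be 'argmax' or 'sample'")


def _intended_loop_status(variant: str) -> str:
    if len(variant) == 5:
        return INACTIVE
    rules = SubstitutionRuleTable()
    statuses = [rules.status(j, variant[j]) for j in range(6)]
    if all(s == FUNCTIONAL for s in statuses):
        return FUNCTIONAL
    if all(s != INACTIVE for s in statuses):
        return PUTATIVE
    return INACTIVE


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _sample_site(rng: np.random.Generator, pfm: PositionFrequencyMatrix) -> str:
    return "".join(
        pfm.alphabet[rng.choice(len(pfm.alphabet), p=pfm.freqs[j])]
        for j in range(pfm.length)
    )


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int):
    return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


class SyntheticBundle:
    """In-memory result of a generation run; write_to() emits the files."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.genomes: list[GenomeSequence] = []
        self.genes: dict[str, list[GeneRecord]] = {}
        self.metadata_rows: list[dict] = []
        self.proteins: list[tuple[str, str]] = []
        self.domains_rows: list[dict] = []
        self.blast_rows: list[sio.BlastRow] = []
        self.seeds_rows: list[dict] = []
        self.annotation_rows: list[dict] = []
        self.background: dict[str, float] = {}
        self.manifest: dict = {
            "seed": spec.seed,
            "promoters": [],
            "proteins": [],
            "enriched_terms": [],
        }

    def write_to(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for genome in self.genomes:
            fa = outdir / f"{genome.genome_id}.fasta"
            sio.write_fasta(fa, genome.contigs)
            gff = outdir / f"{genome.genome_id}.gff3"
            sio.write_gff3(gff, self.genes[genome.genome_id])
            paths[f"fasta:{genome.genome_id}"] = str(fa)
            paths[f"gff3:{genome.genome_id}"] = str(gff)
        sio.write_pfm(outdir / "pfm.tsv", self.spec.pfm)
        paths["pfm"] = str(outdir / "pfm.tsv")

        with open(outdir / "metadata.tsv", "w") as fh:
            fh.write("genome_id\tphylum_or_class\tsize_bp\tmotile\tmembrane\tlps\tsigma54_present\n")
            for row in self.metadata_rows:
                fh.write(
                    "\t".join(
                        str(row[k]) for k in
                        ("genome_id", "phylum_or_class", "size_bp", "motile",
                         "membrane", "lps", "sigma54_present")
                    ) + "\n"
                )
        paths["metadata"] = str(outdir / "metadata.tsv")

        sio.write_fasta(outdir / "proteins.faa", self.proteins)
        paths["proteins"] = str(outdir / "proteins.faa")

        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("protein_id\tterm\tstart\tend\n")
            for row in self.domains_rows:
                fh.write(f"{row['protein_id']}\t{row['term']}\t{row['start']}\t{row['end']}\n")
        paths["domains"] = str(outdir / "domains.tsv")

        sio.write_blast_tab(outdir / "blast.tsv", self.blast_rows)
        paths["blast"] = str(outdir / "blast.tsv")

        with open(outdir / "seeds.tsv", "w") as fh:
            fh.write("seed_id\tgroup\trole\n")
            for row in self.seeds_rows:
                fh.write(f"{row['seed_id']}\t{row['group']}\t{row['role']}\n")
        paths["seeds"] = str(outdir / "seeds.tsv")

        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("gene_id\ttype\tterm\n")
            for row in self.annotation_rows:
                fh.write(f"{row['gene_id']}\t{row['type']}\t{row['term']}\n")
        paths["annotations"] = str(outdir / "annotations.tsv")

        with open(outdir / "background.tsv", "w") as fh:
            fh.write("category\tfraction\n")
            for cat in sorted(self.background):
                fh.write(f"{cat}\t{self.background[cat]:.6f}\n")
        paths["background"] = str(outdir / "background.tsv")

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = str(outdir / "manifest.json")
        return paths


def _gene_layout(rng: np.random.Generator, spec: SyntheticSpec, genome_id: str):
    """Place genes in operon-structured runs; returns (genes, operon starts)."""
    genes: list[GeneRecord] = []
    leading: list[int] = []  # indices of unit-leading genes (reading order)
    pos = int(rng.integers(900, 1400))
    k = 0
    while k < spec.n_genes and pos < spec.genome_length - 2500:
        size = int(rng.integers(spec.operon_size[0], spec.operon_size[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        for _ in range(size):
            if k >= spec.n_genes or pos >= spec.genome_length - 2500:
                break
            length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            g = GeneRecord(
                gene_id=f"{genome_id}_g{k + 1:04d}",
                contig_id=f"{genome_id}_c1",
                start=pos,
                end=pos + length,
                strand=strand,
            )
            genes.append(g)
            members.append(len(genes) - 1)
            pos += length + int(
                rng.integers(spec.within_operon_gap[0], spec.within_operon_gap[1] + 1)
            )
            k += 1
        if members:
            leading.append(members[0] if strand == "+" else members[-1])
        pos += int(
            rng.integers(spec.between_operon_gap[0], spec.between_operon_gap[1] + 1)
        )
    return genes, leading


def _plant_site(seq: np.ndarray, site: str, start: int) -> None:
    seq[start : start + len(site)] = np.frombuffer(site.encode(), dtype="S1")


def generate_genomes(spec: SyntheticSpec, bundle: SyntheticBundle,
                     rng: np.random.Generator) -> None:
    pfm = spec.pfm
    i = pfm.length
    tss = pfm.tss_offset
    for gidx in range(spec.n_genomes):
        genome_id = f"genome{gidx + 1:02d}"
        grng = np.random.default_rng(rng.integers(2**63))
        seq = _random_dna(grng, spec.genome_length, spec.gc)
        genes, leading = _gene_layout(grng, spec, genome_id)
        occupied: list[tuple[int, int]] = []

        def try_plant(gene: GeneRecord, distance: int, flip: bool):
            """Span for a site at `distance` from the gene start; None if it
            does not fit or collides with an earlier plant."""
            strand = gene.strand
            if flip:
                strand = "-" if strand == "+" else "+"
            if strand == "+":
                minus11 = gene.translation_start - distance if gene.strand == "+" \
                    else gene.translation_start + distance
                start = minus11 - tss
            else:
                minus11 = gene.translation_start + distance if gene.strand == "-" \
                    else gene.translation_start - distance
                start = minus11 - (i - 1 - tss)
            if start < 0 or start + i > spec.genome_length:
                return None
            for s, e in occupied:
                if start < e and s < start + i:
                    return None
            return start, minus11, strand

        # promoters, planted inline upstream of unit-leading genes
        order = grng.permutation(len(leading))
        planted = 0
        for li in order:
            if planted >= spec.n_planted_promoters:
                break
            gene = genes[leading[li]]
            distance = int(
                grng.integers(spec.planted_distance[0], spec.planted_distance[1] + 1)
            )
            placed = try_plant(gene, distance, flip=False)
            if placed is None:
                continue
            start, minus11, strand = placed
            site = (
                pfm.argmax_string() if spec.plant_mode == "argmax"
                else _sample_site(grng, pfm)
            )
            _plant_site(seq, site if strand == "+" else reverse_complement(site), start)
            occupied.append((start, start + i))
            planted += 1
            bundle.manifest["promoters"].append(
                {
                    "genome_id": genome_id,
                    "contig_id": f"{genome_id}_c1",
                    "start": start,
                    "end": start + i,
                    "strand": strand,
                    "minus11_pos": minus11,
                    "gene_id": gene.gene_id,
                    "distance": distance,
                    "site": site,
                    "kind": "promoter",
                }
            )

        # decoys: same element in opposing orientation, filtered downstream
        decoys = 0
        for li in order[::-1]:
            if decoys >= spec.n_decoy_sites:
                break
            gene = genes[leading[li]]
            distance = int(
                grng.integers(spec.planted_distance[0] + 30, spec.planted_distance[1] + 31)
            )
            placed = try_plant(gene, distance, flip=True)
            if placed is None:
                continue
            start, minus11, strand = placed
            site = pfm.argmax_string()
            _plant_site(seq, site if strand == "+" else reverse_complement(site), start)
            occupied.append((start, start + i))
            decoys += 1
            bundle.manifest["promoters"].append(
                {
                    "genome_id": genome_id,
                    "contig_id": f"{genome_id}_c1",
                    "start": start,
                    "end": start + i,
                    "strand": strand,
                    "minus11_pos": minus11,
                    "gene_id": gene.gene_id,
                    "distance": distance,
                    "site": site,
                    "kind": "decoy",
                }
            )

        genome = GenomeSequence(
            genome_id=genome_id,
            contigs=[(f"{genome_id}_c1", seq.tobytes().decode())],
        )
        bundle.genomes.append(genome)
        bundle.genes[genome_id] = genes


def generate_proteins(spec: SyntheticSpec, bundle: SyntheticBundle,
                      rng: np.random.Generator) -> None:
    presence = spec.sigma54_presence or tuple([True] * spec.n_genomes)
    for name in EBP_SEED_NAMES:
        bundle.seeds_rows.append(
            {"seed_id": f"seed_{name}", "group": f"{name}-like", "role": "ebp"}
        )
    for name in SIGMA54_SEED_NAMES:
        bundle.seeds_rows.append(
            {"seed_id": f"seed_{name}", "group": "sigma54", "role": "sigma54"}
        )

    def scaffold(n: int) -> str:
        idx = rng.integers(len(SCAFFOLD_RESIDUES), size=n)
        return "".join(SCAFFOLD_RESIDUES[j] for j in idx)

    def blast_row(seed_id: str, protein_id: str, evalue: float) -> sio.BlastRow:
        return sio.BlastRow(
            query_id=seed_id, subject_id=protein_id, pident=35.0,
            length=200, mismatch=100, gapopen=5, qstart=1, qend=200,
            sstart=1, send=200, evalue=float(evalue), bitscore=120.0,
        )

    present_genomes = [
        f"genome{k + 1:02d}" for k in range(spec.n_genomes) if presence[k]
    ]
    # sigma-54 ortholog per present genome, anchored to a real gene
    for gidx in range(spec.n_genomes):
        genome_id = f"genome{gidx + 1:02d}"
        if not presence[gidx]:
            continue
        genes = bundle.genes.get(genome_id)
        pid = f"{genome_id}_rpoN" if not genes else genes[0].gene_id
        bundle.proteins.append((pid, scaffold(450)))
        for seed in SIGMA54_SEED_NAMES:
            e = float(_loguniform(rng, 1e-80, 1e-30, 1)[0])
            bundle.blast_rows.append(blast_row(f"seed_{seed}", pid, e))
        bundle.manifest["proteins"].append(
            {"protein_id": pid, "genome_id": genome_id, "class": "sigma54"}
        )

    # true activators: engineered loop variant, architecture, passing profile
    for k in range(spec.n_true_ebps):
        genome_id = present_genomes[k % len(present_genomes)] if present_genomes \
            else f"genome{k % spec.n_genomes + 1:02d}"
        genes = bundle.genes.get(genome_id)
        # anchor activators to genes past the sigma-54 gene
        pid = (
            genes[2 + k // max(1, len(present_genomes))].gene_id
            if genes and len(genes) > 2 + k // max(1, len(present_genomes))
            else f"{genome_id}_ebp{k + 1}"
        )
        variant = spec.gaftga_variants[k % len(spec.gaftga_variants)]
        arch = ARCHITECTURE_CYCLE[k % len(ARCHITECTURE_CYCLE)]
        if arch == "Ic":
            length = 320
            domain_plan = [("activator", 40, 280)]
        elif arch == "Ia":
            length = 480
            domain_plan = [("receiver", 5, 120), ("activator", 140, 380),
                           ("HTH_8", 420, 470)]
        elif arch == "Ib":
            length = 480
            domain_plan = [("PAS", 5, 110), ("activator", 140, 380),
                           ("HTH_8", 420, 470)]
        else:  # II
            length = 900
            domain_plan = [("HTH_8", 5, 60), ("activator", 80, 320),
                           ("PTS-EII", 340, 440), ("PRD", 450, 550),
                           ("PTS-EII", 560, 660), ("PRD", 670, 770)]
        loop_at = 200 if length >= 480 else 150
        seqn = scaffold(length)
        seqn = seqn[:loop_at] + variant + seqn[loop_at + len(variant):]
        bundle.proteins.append((pid, seqn))
        for term, s, e in domain_plan:
            bundle.domains_rows.append(
                {"protein_id": pid, "term": term, "start": s, "end": e}
            )
        evalues = _loguniform(rng, 1e-150, 1e-25, len(EBP_SEED_NAMES))
        for seed, e in zip(EBP_SEED_NAMES, evalues):
            bundle.blast_rows.append(blast_row(f"seed_{seed}", pid, e))
        bundle.manifest["proteins"].append(
            {
                "protein_id": pid,
                "genome_id": genome_id,
                "class": "true_ebp",
                "gaftga_variant": variant,
                "loop_start": loop_at,
                "intended_loop_status": _intended_loop_status(variant),
                "intended_architecture": arch,
                "intended_filter_outcome": True,
            }
        )

    # decoys: scrambled loop, sparse weak hits, must fail both filters
    for k in range(spec.n_decoy_proteins):
        genome_id = f"genome{k % spec.n_genomes + 1:02d}"
        pid = f"{genome_id}_decoy{k + 1}"
        bundle.proteins.append((pid, scaffold(500)))
        bundle.domains_rows.append(
            {"protein_id": pid, "term": "Mg_chelatase", "start": 20, "end": 420}
        )
        n_hits = int(rng.integers(2, 6))
        hit_seeds = rng.choice(len(EBP_SEED_NAMES), size=n_hits, replace=False)
        for s in sorted(hit_seeds):
            e = float(_loguniform(rng, 1e-6, 1, 1)[0])
            bundle.blast_rows.append(
                blast_row(f"seed_{EBP_SEED_NAMES[s]}", pid, e)
            )
        bundle.manifest["proteins"].append(
            {
                "protein_id": pid,
                "genome_id": genome_id,
                "class": "decoy",
                "intended_filter_outcome": False,
            }
        )


def generate_annotations(spec: SyntheticSpec, bundle: SyntheticBundle,
                         rng: np.random.Generator) -> None:
    if len(spec.phyla) < 2:
        raise ValueError("need at least two phyla for conservation analysis")
    presence = spec.sigma54_presence or tuple([True] * spec.n_genomes)
    phylum_of = {}
    for gidx in range(spec.n_genomes):
        genome_id = f"genome{gidx + 1:02d}"
        phylum = spec.phyla[gidx % len(spec.phyla)]
        phylum_of[genome_id] = phylum
        motile = bool(presence[gidx]) if rng.random() < 0.8 else not presence[gidx]
        bundle.metadata_rows.append(
            {
                "genome_id": genome_id,
                "phylum_or_class": phylum,
                "size_bp": spec.genome_length,
                "motile": int(motile),
                "membrane": "diderm" if presence[gidx] else "monoderm",
                "lps": "present" if presence[gidx] else "absent",
                "sigma54_present": int(presence[gidx]),
            }
        )

    cats = list(spec.cog_categories)
    bundle.background = {c: round(1.0 / len(cats), 6) for c in cats}

    baseline_pool = [f"COG{1000 + t}" for t in range(spec.baseline_terms)]
    anchor_context: dict[str, list[str]] = {g: [] for g in phylum_of}
    for entry in bundle.manifest["proteins"]:
        if entry["class"] in ("sigma54", "true_ebp"):
            genes = bundle.genes.get(entry["genome_id"], [])
            ids = [g.gene_id for g in genes]
            if entry["protein_id"] in ids:
                pos = ids.index(entry["protein_id"])
                lo, hi = max(0, pos - 10), pos + 11
                anchor_context[entry["genome_id"]].extend(ids[lo:hi])

    for genome_id, genes in bundle.genes.items():
        grng = np.random.default_rng(rng.integers(2**63))
        for g in genes:
            if grng.random() < 0.8:
                term = baseline_pool[int(grng.integers(len(baseline_pool)))]
                bundle.annotation_rows.append(
                    {"gene_id": g.gene_id, "type": "COG", "term": term}
                )
            if grng.random() < 0.75:
                cat = cats[int(grng.integers(len(cats)))]
                bundle.annotation_rows.append(
                    {"gene_id": g.gene_id, "type": "COG_category", "term": cat}
                )

    for term, term_phyla in spec.enriched_terms.items():
        for genome_id, context_ids in anchor_context.items():
            if phylum_of[genome_id] not in term_phyla:
                continue
            for gid in context_ids:
                bundle.annotation_rows.append(
                    {"gene_id": gid, "type": "COG", "term": term}
                )
        bundle.manifest["enriched_terms"].append(
            {"term": term, "phyla": sorted(term_phyla)}
        )
    bundle.annotation_rows.sort(key=lambda r: (r["gene_id"], r["type"], r["term"]))


def generate_bundle(spec: SyntheticSpec, outdir=None) -> SyntheticBundle:
    """Run all three generators on one seeded stream; optionally write files."""
    bundle = SyntheticBundle(spec)
    root = np.random.SeedSequence(spec.seed)
    g_rng, p_rng, a_rng = (np.random.default_rng(s) for s in root.spawn(3))
    generate_genomes(spec, bundle, g_rng)
    generate_proteins(spec, bundle, p_rng)
    generate_annotations(spec, bundle, a_rng)
    if outdir is not None:
        bundle.write_to(outdir)
    return bundle
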