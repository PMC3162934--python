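"""Identification and classification of sigma-54 and its activator proteins.

Candidates from a seeded homology search are filtered on the product and sum
of their per-seed e-values, checked for the integrity of the six-residue
activator loop (canonically GAFTGA), typed by domain architecture, and given
a coarse annotation from the closest experimentally verified seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .motif import PROTEIN_ALPHABET, PositionFrequencyMatrix, score_sequence

MISSING_HIT_EVALUE = 10.0
EVALUE_FLOOR = 1e-200

FUNCTIONAL = "functional"
PUTATIVE = "putative"
INACTIVE = "inactive"

CANONICAL_LOOP = "GAFTGA"


@dataclass(frozen=True)
class Seed:
    seed_id: str
    sequence: str = ""
    group: str = ""


@dataclass(frozen=True)
class SeedSet:
    seeds: tuple[Seed, ...]

    def __post_init__(self) -> None:
        ids = [s.seed_id for s in self.seeds]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate seed ids")
        if not ids:
            raise ValueError("seed set is empty")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.seed_id for s in self.seeds)

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    def group_of(self, seed_id: str) -> str:
        for s in self.seeds:
            if s.seed_id == seed_id:
                return s.group or s.seed_id
        raise KeyError(seed_id)


@dataclass
class EvalueProfile:
    protein_id: str
    evalues: np.ndarray  # aligned with the SeedSet order

    def __post_init__(self) -> None:
        self.evalues = np.asarray(self.evalues, dtype=float)
        if np.any(self.evalues <= 0):
            raise ValueError(f"{self.protein_id}: e-values must be positive")


@dataclass(frozen=True)
class GaftgaCall:
    window: str
    window_start: int
    gapped: bool = False
    skipped_column: int | None = None
    per_position_status: tuple[str, ...] = ()
    overall: str = ""


# Substitution rules for the six loop positions.  The canonical residue is
# always functional; residues in neither set abolish the sigma-54 contact.
DEFAULT_RULES: tuple[tuple[frozenset, frozenset], ...] = (
    (frozenset("GN"), frozenset("ADEHS")),        # pos 1 (G)
    (frozenset("AS"), frozenset("TGIVMC")),       # pos 2 (A)
    (frozenset("FY"), frozenset()),               # pos 3 (F)
    (frozenset("TSE"), frozenset("D")),           # pos 4 (T)
    (frozenset("GD"), frozenset("EAHNS")),        # pos 5 (G)
    (frozenset("AS"), frozenset("TGIVMC")),       # pos 6 (A)
)


@dataclass(frozen=True)
class SubstitutionRuleTable:
    rules: tuple[tuple[frozenset, frozenset], ...] = DEFAULT_RULES

    def __post_init__(self) -> None:
        if len(self.rules) != 6:
            raise ValueError("rule table needs exactly six positions")
        for k, (func, puta) in enumerate(self.rules):
            if func & puta:
                raise ValueError(f"position {k + 1}: overlapping rule sets")
            if CANONICAL_LOOP[k] not in func:
                raise ValueError(
                    f"position {k + 1}: canonical residue must be functional"
                )

    def status(self, position: int, residue: str) -> str:
        func, puta = self.rules[position]
        if residue in func:
            return FUNCTIONAL
        if residue in puta:
            return PUTATIVE
        return INACTIVE


@dataclass
class EbpRecord:
    protein_id: str
    genome_id: str = ""
    passed_evalue_filter: bool = False
    gaftga: GaftgaCall | None = None
    status: str = "rejected"
    architecture: str = "unclassified"
    annotation_group: str | None = None
    length: int = 0


# ---------------------------------------------------------------------------
# sigma-54 detection and e-value filtering


def detect_sigma54(rows, cutoff: float = 1e-20, genome_of=None):
    """Sigma-54 orthologs: best e-value against any seed at or below cutoff.

    ``rows`` are parsed homology rows (see io.read_blast_tab).  Returns
    (ortholog protein ids sorted, per-genome dict genome -> sorted ids) where
    the genome of a protein comes from ``genome_of`` (mapping or callable);
    without it the per-genome dict is empty.
    """
    best: dict[str, float] = {}
    for r in rows:
        e = max(r.evalue, EVALUE_FLOOR)
        if r.subject_id not in best or e < best[r.subject_id]:
            best[r.subject_id] = e
    orthologs = sorted(p for p, e in best.items() if e <= cutoff)
    per_genome: dict[str, list[str]] = {}
    if genome_of is not None:
        lookup = genome_of if callable(genome_of) else genome_of.__getitem__
        for p in orthologs:
            per_genome.setdefault(lookup(p), []).append(p)
    return orthologs, per_genome


def build_evalue_profiles(rows, seeds: SeedSet) -> list[EvalueProfile]:
    """One length-n_seeds vector per subject protein.

    Seeds without a reported hit are imputed at 10; duplicate hits keep the
    minimum; a reported e-value of 0 is floored at 1e-200.
    """
    order = {sid: k for k, sid in enumerate(seeds.ids)}
    vectors: dict[str, np.ndarray] = {}
    for r in rows:
        if r.query_id not in order:
            raise ValueError(f"unknown seed id {r.query_id!r} in homology table")
        vec = vectors.get(r.subject_id)
        if vec is None:
            vec = np.full(seeds.n_seeds, MISSING_HIT_EVALUE)
            vectors[r.subject_id] = vec
        e = max(r.evalue, EVALUE_FLOOR)
        k = order[r.query_id]
        if e < vec[k]:
            vec[k] = e
    return [
        EvalueProfile(protein_id=p, evalues=vectors[p])
        for p in sorted(vectors)
    ]


def passes_filters(
    profile: EvalueProfile,
    log10_product_max: float = -5.0,
    sum_max: float = 1.0,
) -> bool:
    """Product filter in log space (sum of log10 e-values) plus sum filter."""
    log_product = float(np.log10(profile.evalues).sum())
    total = float(profile.evalues.sum())
    return log_product < log10_product_max and total < sum_max


def filter_candidates(
    profiles: list[EvalueProfile],
    log10_product_max: float = -5.0,
    sum_max: float = 1.0,
) -> list[EvalueProfile]:
    return [p for p in profiles if passes_filters(p, log10_product_max, sum_max)]


# ---------------------------------------------------------------------------
# activator-loop location and classification


def _strict_loop_pfm() -> PositionFrequencyMatrix:
    freqs = np.zeros((6, len(PROTEIN_ALPHABET)))
    for j, aa in enumerate(CANONICAL_LOOP):
        freqs[j, PROTEIN_ALPHABET.index(aa)] = 1.0
    return PositionFrequencyMatrix(
        freqs=freqs, alphabet=PROTEIN_ALPHABET, name="activator-loop"
    )


def locate_gaftga(
    protein: str, motif: PositionFrequencyMatrix | None = None
) -> GaftgaCall:
    """Best-scoring hexamer window against the loop motif; leftmost on ties.

    Single-residue deletions are caught by also scanning pentamer windows
    with one motif column skipped (score still divided by 6); a gapped window
    wins only when no full hexamer reaches 5/6 of the attainable score.
    """
    if motif is None:
        motif = _strict_loop_pfm()
    if motif.length != 6:
        raise ValueError("loop motif must have six columns")
    if len(protein) < 5:
        raise ValueError("protein too short to carry the activator loop")

    best6, best6_at = -1.0, 0
    if len(protein) >= 6:
        for s in range(len(protein) - 5):
            sc = score_sequence(motif, protein[s : s + 6])
            if sc > best6:
                best6, best6_at = sc, s

    best5, best5_at, best5_skip = -1.0, 0, 0
    for s in range(len(protein) - 4):
        window = protein[s : s + 5]
        for skip in range(6):
            total = 0.0
            w = 0
            for j in range(6):
                if j == skip:
                    continue
                total += motif.frequency(j, window[w])
                w += 1
            sc = total / 6
            if sc > best5:
                best5, best5_at, best5_skip = sc, s, skip

    if best6 >= 5.0 / 6.0 - 1e-12 or best6 >= best5:
        return GaftgaCall(
            window=protein[best6_at : best6_at + 6],
            window_start=best6_at,
            gapped=False,
        )
    return GaftgaCall(
        window=protein[best5_at : best5_at + 5],
        window_start=best5_at,
        gapped=True,
        skipped_column=best5_skip,
    )


def classify_gaftga(
    call: GaftgaCall, rules: SubstitutionRuleTable | None = None
) -> GaftgaCall:
    """Per-position and overall loop status.

    Overall is functional iff all six positions are functional, putative when
    none is inactive and at least one is putative, otherwise inactive.  Any
    deletion makes the loop inactive outright.
    """
    if rules is None:
        rules = SubstitutionRuleTable()
    if call.gapped:
        skip = call.skipped_column if call.skipped_column is not None else 0
        statuses = []
        w = 0
        for j in range(6):
            if j == skip:
                statuses.append(INACTIVE)
            else:
                statuses.append(rules.status(j, call.window[w]))
                w += 1
        return replace(call, per_position_status=tuple(statuses), overall=INACTIVE)
    statuses = tuple(rules.status(j, call.window[j]) for j in range(6))
    if all(s == FUNCTIONAL for s in statuses):
        overall = FUNCTIONAL
    elif all(s != INACTIVE for s in statuses):
        overall = PUTATIVE
    else:
        overall = INACTIVE
    return replace(call, per_position_status=statuses, overall=overall)


# ---------------------------------------------------------------------------
# domain architectures

SIGNAL_DOMAINS = frozenset({"receiver", "RR", "PAS", "GAF", "HPr"})
PTS_DOMAINS = frozenset({"PRD", "PTS-EII"})
DNA_BINDING_DOMAINS = frozenset({"HTH_8"})
ACTIVATOR_DOMAIN = "activator"

SHORT_PROTEIN_CUTOFF = 400


def classify_architecture(domains: list[str], length: int) -> str:
    """Architecture type with precedence II > Ia > Ib > Ic.

    II: any PTS-linked phosphorylatable domain.  Ia: a receiver domain ahead
    of the activator domain plus an HTH_8 DNA-binding domain.  Ib: any other
    signal domain plus HTH_8.  Ic: proteins under 400 residues, or an
    activator domain missing its signal or DNA-binding partner.
    """
    domains = list(domains)
    if any(d in PTS_DOMAINS for d in domains):
        return "II"
    has_hth = any(d in DNA_BINDING_DOMAINS for d in domains)
    has_signal = any(d in SIGNAL_DOMAINS for d in domains)
    has_activator = ACTIVATOR_DOMAIN in domains
    if has_hth and has_activator:
        receiver_first = any(
            d in ("receiver", "RR")
            for d in domains[: domains.index(ACTIVATOR_DOMAIN)]
        )
        if receiver_first:
            return "Ia"
        if has_signal:
            return "Ib"
    if length < SHORT_PROTEIN_CUTOFF:
        return "Ic"
    if has_activator and (not has_signal or not has_hth):
        return "Ic"
    return "unclassified"


# ---------------------------------------------------------------------------
# coarse annotation

COARSE_ANNOTATION_CUTOFF = 1e-20


def annotate_by_seed(
    profile: EvalueProfile,
    seeds: SeedSet,
    cutoff: float = COARSE_ANNOTATION_CUTOFF,
) -> str | None:
    """Group label of the closest seed, or None when no seed is close enough.

    Ties on the minimum e-value go to the lexicographically first seed id.
    """
    emin = float(profile.evalues.min())
    if emin > cutoff:
        return None
    tied = [
        seeds.ids[k]
        for k in np.nonzero(profile.evalues == emin)[0]
    ]
    return seeds.group_of(min(tied))


def classify_protein(
    protein_id: str,
    sequence: str,
    profile: EvalueProfile,
    seeds: SeedSet,
    domains: list[str],
    genome_id: str = "",
    rules: SubstitutionRuleTable | None = None,
) -> EbpRecord:
    """Full per-protein record: filters, loop call, architecture, annotation."""
    passed = passes_filters(profile)
    call = classify_gaftga(locate_gaftga(sequence), rules)
    if passed and call.overall == FUNCTIONAL:
        status = "true_ebp"
    elif passed and call.overall == PUTATIVE:
        status = "putative_ebp"
    else:
        status = "rejected"
    return EbpRecord(
        protein_id=protein_id,
        genome_id=genome_id,
        passed_evalue_filter=passed,
        gaftga=call,
        status=status,
        architecture=classify_architecture(domains, len(sequence)),
        annotation_group=annotate_by_seed(profile, seeds) if passed else None,
        length=len(sequence),
    )
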