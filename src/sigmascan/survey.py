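"""Presence/absence summaries by phylum, genome-size bin, and motility."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    phylum_or_class: str
    size_bp: int
    motile: bool | None = None  # None = unknown
    membrane: str = "other"     # monoderm | diderm | other
    lps: str = "unknown"        # present | absent | atypical | unknown

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"{self.genome_id}: size_bp must be positive")
        if not self.phylum_or_class:
            raise ValueError(f"{self.genome_id}: empty phylum/class label")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _sample_sd(values: list[int]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def summarize_phylum(
    metadata: list[GenomeMetadata],
    presence: dict[str, bool],
    ebp_counts: dict[str, int],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-phylum presence counts and mean +/- discrete SD of activator counts.

    Mean and sample SD of activator counts (over sigma-54-positive genomes)
    are rounded to the nearest integer.  Genomes present in ``presence`` but
    missing metadata are returned as an exclusions list, never dropped
    silently.
    """
    known = {m.genome_id for m in metadata}
    exclusions = sorted(set(presence) - known)
    rows = []
    by_phylum: dict[str, list[GenomeMetadata]] = {}
    for m in metadata:
        by_phylum.setdefault(m.phylum_or_class, []).append(m)
    for phylum in sorted(by_phylum):
        members = by_phylum[phylum]
        positive = [m for m in members if presence.get(m.genome_id, False)]
        counts = [ebp_counts.get(m.genome_id, 0) for m in positive]
        if counts:
            mean = _round_half_up(sum(counts) / len(counts))
            sd = _round_half_up(_sample_sd(counts))
        else:
            mean = None
            sd = None
        rows.append(
            {
                "phylum_or_class": phylum,
                "n_with_sigma54": len(positive),
                "n_total": len(members),
                "ebp_mean": mean,
                "ebp_sd": sd,
            }
        )
    return pd.DataFrame(rows), exclusions


def bin_by_genome_size(
    metadata: list[GenomeMetadata],
    presence: dict[str, bool],
    bin_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Genome counts per half-open size bin [k*bin, (k+1)*bin), per group."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    counts: dict[int, dict[str, int]] = {}
    for m in metadata:
        b = m.size_bp // bin_bp
        row = counts.setdefault(b, {"with_sigma54": 0, "without_sigma54": 0})
        key = "with_sigma54" if presence.get(m.genome_id, False) else "without_sigma54"
        row[key] += 1
    rows = [
        {"bin": b, "bin_start_bp": b * bin_bp, **counts[b]}
        for b in sorted(counts)
    ]
    return pd.DataFrame(rows, columns=["bin", "bin_start_bp", "with_sigma54", "without_sigma54"])


def motility_and_ebp_fractions(
    metadata: list[GenomeMetadata],
    presence: dict[str, bool],
    ebp_counts: dict[str, int],
    bin_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin motile fraction per presence group, and the per-bin fraction
    of sigma-54-positive genomes carrying each activator count.

    Motile fractions are computed over genomes with known motility only; a
    bin where motility is entirely unknown gets a blank (NaN) fraction.
    Activator-count fractions sum to 1 within each bin.
    """
    by_bin: dict[int, list[GenomeMetadata]] = {}
    for m in metadata:
        by_bin.setdefault(m.size_bp // bin_bp, []).append(m)

    motility_rows = []
    surface_rows = []
    for b in sorted(by_bin):
        members = by_bin[b]
        row = {"bin": b}
        for group, flag in (("with_sigma54", True), ("without_sigma54", False)):
            known = [
                m for m in members
                if presence.get(m.genome_id, False) == flag and m.motile is not None
            ]
            if known:
                row[f"motile_fraction_{group}"] = (
                    sum(1 for m in known if m.motile) / len(known)
                )
            else:
                row[f"motile_fraction_{group}"] = float("nan")
        motility_rows.append(row)

        positive = [m for m in members if presence.get(m.genome_id, False)]
        if positive:
            tallies: dict[int, int] = {}
            for m in positive:
                c = ebp_counts.get(m.genome_id, 0)
                tallies[c] = tallies.get(c, 0) + 1
            for c in sorted(tallies):
                surface_rows.append(
                    {"bin": b, "ebp_count": c, "fraction": tallies[c] / len(positive)}
                )
    return (
        pd.DataFrame(motility_rows,
                     columns=["bin", "motile_fraction_with_sigma54",
                              "motile_fraction_without_sigma54"]),
        pd.DataFrame(surface_rows, columns=["bin", "ebp_count", "fraction"]),
    )
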