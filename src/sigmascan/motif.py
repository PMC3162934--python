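"""Position-frequency matrices and the frequency-sum similarity score.

The score of a sequence against a matrix is the mean, over columns, of the
frequency of the sequence's symbol in that column.  It lies in [0, 1], needs
no pseudocounts, and degenerate matrices simply cap the attainable maximum.
Works for DNA and protein alphabets alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentError(ValueError):
    """Input sites are not a gapless equal-length alignment."""


class AlphabetError(ValueError):
    """A site contains a symbol outside the declared alphabet."""


class DegenerateMotifError(ValueError):
    """Trimming removed every column of the matrix."""


@dataclass(frozen=True)
class AlignedSiteSet:
    """A gapless set of equal-length sites over a single alphabet."""

    sites: tuple[str, ...]
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise AlignmentError("site set is empty")
        lengths = {len(s) for s in self.sites}
        if len(lengths) != 1:
            raise AlignmentError(f"sites have unequal lengths: {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("sites have zero length")
        allowed = set(self.alphabet)
        for s in self.sites:
            bad = set(s) - allowed
            if bad:
                raise AlphabetError(
                    f"symbols {sorted(bad)} not in alphabet {self.alphabet!r}"
                )

    @property
    def m(self) -> int:
        return len(self.sites)

    @property
    def length(self) -> int:
        return len(self.sites[0])


@dataclass
class PositionFrequencyMatrix:
    """Per-column symbol frequencies with an optional -11 anchor column.

    ``freqs`` has shape (length, len(alphabet)); each row sums to 1.
    ``tss_offset`` is the 0-based column that sits at genomic position -11
    relative to the transcription start (DNA motifs only).
    """

    freqs: np.ndarray
    alphabet: str = DNA_ALPHABET
    name: str = "motif"
    m: int = 0
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.alphabet):
            raise ValueError(
                f"frequency matrix shape {self.freqs.shape} does not match "
                f"alphabet of size {len(self.alphabet)}"
            )
        if self.freqs.shape[0] < 1:
            raise ValueError("matrix has no columns")
        if np.any(self.freqs < -1e-12) or np.any(self.freqs > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = self.freqs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"column {bad + 1} frequencies sum to {sums[bad]}")
        if self.tss_offset is not None and not 0 <= self.tss_offset < self.length:
            raise ValueError(
                f"tss_offset {self.tss_offset} outside motif of length {self.length}"
            )
        self._index = {sym: k for k, sym in enumerate(self.alphabet)}

    @property
    def length(self) -> int:
        return int(self.freqs.shape[0])

    # kept as a method so callers can ask for single entries symbolically
    def frequency(self, column: int, symbol: str) -> float:
        k = self._index.get(symbol)
        return 0.0 if k is None else float(self.freqs[column, k])

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence to alphabet indices; unknown symbols become -1."""
        return np.array([self._index.get(c, -1) for c in seq], dtype=np.int64)

    def argmax_string(self) -> str:
        """A sequence attaining the maximum score (leftmost symbol on ties)."""
        return "".join(self.alphabet[k] for k in self.freqs.argmax(axis=1))


def build_pfm(
    sites: AlignedSiteSet,
    name: str = "motif",
    tss_offset: int | None = None,
) -> PositionFrequencyMatrix:
    """Count symbols per column and divide by the number of sites.

    No pseudocounts are added: a symbol absent from a column has frequency 0
    and contributes nothing to any score.
    """
    length = sites.length
    counts = np.zeros((length, len(sites.alphabet)), dtype=float)
    index = {sym: k for k, sym in enumerate(sites.alphabet)}
    for s in sites.sites:
        for j, c in enumerate(s):
            counts[j, index[c]] += 1
    return PositionFrequencyMatrix(
        freqs=counts / sites.m,
        alphabet=sites.alphabet,
        name=name,
        m=sites.m,
        tss_offset=tss_offset,
    )


def score_sequence(pfm: PositionFrequencyMatrix, seq: str) -> float:
    """Mean per-column frequency of the sequence's symbols; range [0, 1].

    Symbols outside the alphabet (N, X, ambiguity codes) contribute 0.
    """
    if len(seq) != pfm.length:
        raise ValueError(
            f"sequence length {len(seq)} != motif length {pfm.length}"
        )
    idx = pfm.encode(seq)
    # sequential column order keeps summation bit-identical to the scanner
    total = 0.0
    for j, k in enumerate(idx):
        if k >= 0:
            total += float(pfm.freqs[j, k])
    return total / pfm.length


def max_score(pfm: PositionFrequencyMatrix) -> float:
    """Supremum of score_sequence over all sequences: mean of column maxima."""
    total = 0.0
    for j in range(pfm.length):
        total += float(pfm.freqs[j].max())
    return total / pfm.length


def degeneracy_report(
    pfm: PositionFrequencyMatrix, sites: AlignedSiteSet
) -> list[tuple[str, float, float]]:
    """Score each build-set site; the deviation from 1 reads out degeneracy."""
    if sites.length != pfm.length:
        raise ValueError(
            f"site length {sites.length} != motif length {pfm.length}"
        )
    out = []
    for s in sites.sites:
        sc = score_sequence(pfm, s)
        out.append((s, sc, 1.0 - sc))
    return out


def information_content(
    pfm: PositionFrequencyMatrix, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-column information in bits against a background (0*log0 := 0)."""
    if background is None:
        background = np.full(len(pfm.alphabet), 1.0 / len(pfm.alphabet))
    background = np.asarray(background, dtype=float)
    if background.shape != (len(pfm.alphabet),):
        raise ValueError("background length does not match alphabet")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / background), 0.0)
    return terms.sum(axis=1)


def smooth_and_trim_pfm(
    pfm: PositionFrequencyMatrix,
    info_threshold: float = 0.2,
    background: np.ndarray | None = None,
) -> PositionFrequencyMatrix:
    """Replace uninformative columns by background and trim them off the ends.

    A column is uninformative when its information content (in bits, against
    ``background``; default uniform) falls below ``info_threshold``.  Interior
    uninformative columns are set to the background; maximal uninformative
    runs at either end are removed and the -11 anchor is re-indexed.
    """
    if info_threshold < 0:
        raise ValueError("info_threshold must be >= 0")
    if background is None:
        background = np.full(len(pfm.alphabet), 1.0 / len(pfm.alphabet))
    background = np.asarray(background, dtype=float)
    info = information_content(pfm, background)
    informative = info >= info_threshold
    if not informative.any():
        raise DegenerateMotifError(
            "no column reaches the information threshold; motif is empty"
        )
    first = int(np.argmax(informative))
    last = int(len(informative) - 1 - np.argmax(informative[::-1]))
    new = pfm.freqs[first : last + 1].copy()
    keep_info = informative[first : last + 1]
    new[~keep_info] = background
    tss = pfm.tss_offset
    if tss is not None:
        tss -= first
        if not 0 <= tss < new.shape[0]:
            raise DegenerateMotifError(
                "trimming removed the -11 anchor column"
            )
    return PositionFrequencyMatrix(
        freqs=new,
        alphabet=pfm.alphabet,
        name=pfm.name,
        m=pfm.m,
        tss_offset=tss,
    )
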