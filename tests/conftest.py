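import numpy as np
import pytest

from sigmascan.motif import AlignedSiteSet, PositionFrequencyMatrix, build_pfm


@pytest.fixture
def acgt_pfm():
    return build_pfm(AlignedSiteSet(sites=("ACGT",)))


@pytest.fixture
def two_site_pfm():
    return build_pfm(AlignedSiteSet(sites=("ACGT", "ACGA")))


@pytest.fixture
def uniform_pfm():
    return PositionFrequencyMatrix(freqs=np.full((8, 4), 0.25))


def random_pfm(rng, length=None, alphabet="ACGT", tss_offset=None):
    """Dirichlet-random matrix for property tests."""
    if length is None:
        length = int(rng.integers(1, 20))
    freqs = rng.dirichlet(np.ones(len(alphabet)), size=length)
    return PositionFrequencyMatrix(
        freqs=freqs, alphabet=alphabet, tss_offset=tss_offset
    )


def random_sites(rng, alphabet="ACGT"):
    m = int(rng.integers(1, 12))
    length = int(rng.integers(1, 15))
    letters = list(alphabet)
    return AlignedSiteSet(
        sites=tuple(
            "".join(letters[k] for k in rng.integers(len(letters), size=length))
            for _ in range(m)
        ),
        alphabet=alphabet,
    )
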