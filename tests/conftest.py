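import numpy as np
import pytest

from bgcscan.sfs_core import DerivedAlleleSpectrum, Region, SegregatingSite


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def region_40kb():
    return Region(id="r1", chrom="chr1", start=0, end=40_000)


def make_sites(ks, n=22, klass_alleles=("A", "G"), start_pos=100, spacing=137):
    """Sites at evenly spaced positions with the given derived counts."""
    anc, der = klass_alleles
    return [
        SegregatingSite(pos=start_pos + i * spacing, ancestral=anc, derived=der,
                        k=int(k), n=n)
        for i, k in enumerate(ks)
    ]


def random_spectrum(rng, n):
    return DerivedAlleleSpectrum(n, rng.random(n - 1) + 0.01)
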