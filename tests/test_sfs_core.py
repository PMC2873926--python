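"""Core data model: mutation classes, spectra, projection, summary stats."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgcscan.sfs_core import (
    OTHER,
    S2W,
    W2S,
    DerivedAlleleSpectrum,
    FixedDifference,
    Region,
    SegregatingSite,
    build_spectrum,
    classify_mutation,
    fold_spectrum,
    project_spectrum,
    projection_matrix,
    summary_stats,
)

from conftest import make_sites, random_spectrum

BASES = "ACGT"


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "anc,der,expected",
        [("A", "G", W2S), ("T", "C", W2S), ("C", "T", S2W), ("G", "A", S2W),
         ("A", "T", OTHER), ("G", "C", OTHER), ("a", "g", W2S)],
    )
    def test_examples(self, anc, der, expected):
        assert classify_mutation(anc, der) == expected

    def test_mirror_symmetry(self):
        """Swapping arguments maps W2S <-> S2W and fixes OTHER."""
        mirror = {W2S: S2W, S2W: W2S, OTHER: OTHER}
        for a, d in itertools.permutations(BASES, 2):
            assert classify_mutation(d, a) == mirror[classify_mutation(a, d)]

    @pytest.mark.parametrize("anc,der", [("A", "A"), ("N", "G"), ("A", "-")])
    def test_invalid_inputs_rejected(self, anc, der):
        with pytest.raises(ValueError):
            classify_mutation(anc, der)


class TestRegion:
    def test_center_and_mask(self):
        r = Region(id="x", chrom="1", start=100, end=301, covered=((100, 150), (200, 301)))
        assert r.center == 200
        assert r.covered_length == 151
        assert r.is_covered(149) and not r.is_covered(160)

    @pytest.mark.parametrize(
        "covered", [((50, 150),), ((100, 90),), ((100, 200), (150, 250))]
    )
    def test_bad_masks_rejected(self, covered):
        with pytest.raises(ValueError):
            Region(id="x", chrom="1", start=100, end=300, covered=covered)


class TestSegregatingSite:
    def test_klass_and_daf(self):
        s = SegregatingSite(pos=5, ancestral="A", derived="C", k=3, n=22)
        assert s.klass == W2S and s.daf == 3 / 22

    def test_lowercase_ancestral_flagged_not_rejected(self):
        s = SegregatingSite(pos=5, ancestral="g", derived="T", k=1, n=10)
        assert s.klass == S2W and s.low_confidence_ancestral

    def test_monomorphic_counts_rejected(self):
        with pytest.raises(ValueError):
            SegregatingSite(pos=5, ancestral="A", derived="G", k=22, n=22)


class TestFixedDifference:
    def test_lineage_assignment(self):
        d = FixedDifference(pos=1, human="G", chimp="A", ancestral="A")
        assert d.lineage == "human" and d.klass == W2S and d.derived == "G"
        d2 = FixedDifference(pos=1, human="G", chimp="A", ancestral="G")
        assert d2.lineage == "chimp" and d2.klass == S2W

    def test_ambiguous_polarization_rejected(self):
        with pytest.raises(ValueError):
            FixedDifference(pos=1, human="G", chimp="A", ancestral="C")


def enumerate_projection(n, i, m):
    """Oracle: exhaustive enumeration of all m-subsets of n chromosomes of
    which i carry the derived allele; returns count distribution over j."""
    labels = [1] * i + [0] * (n - i)
    counts = {}
    subs = list(itertools.combinations(range(n), m))
    for sub in subs:
        j = sum(labels[x] for x in sub)
        counts[j] = counts.get(j, 0) + 1
    return {j: c / len(subs) for j, c in counts.items()}


class TestProjection:
    def test_identity_at_equal_size(self, rng):
        spec = random_spectrum(rng, 12)
        assert project_spectrum(spec, 12) == spec

    def test_normalized_total_is_one(self, rng):
        spec = random_spectrum(rng, 47)
        out = project_spectrum(spec, 21, normalize=True)
        assert out.total() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n,m", [(4, 2), (5, 3), (6, 4), (8, 5)])
    def test_weights_match_subset_enumeration(self, n, m):
        """Projection weights equal brute-force subsample enumeration."""
        P = projection_matrix(n, m, include_monomorphic=True)
        for i in range(1, n):
            oracle = enumerate_projection(n, i, m)
            for j in range(m + 1):
                assert P[i - 1, j] == pytest.approx(oracle.get(j, 0.0), abs=1e-12)

    def test_build_spectrum_projects_single_site(self):
        """A (k=1, n=4) site projected to n=2, renormalized over segregating
        draws: enumeration gives weight 1/2 at j=1 among C(4,2) draws, and
        1/4 + 1/4 monomorphic mass, so the renormalized weight is 1."""
        sites = make_sites([1], n=4)
        spec = build_spectrum(sites, 2)
        oracle = enumerate_projection(4, 1, 2)
        expected = oracle[1] / (1 - oracle.get(0, 0) - oracle.get(2, 0))
        assert spec[1] == pytest.approx(expected)
        assert spec.total() == pytest.approx(1.0)

    def test_build_spectrum_identity_and_empty(self):
        spec = build_spectrum(make_sites([3], n=22), 22)
        assert spec[3] == 1.0 and spec.total() == 1.0
        assert build_spectrum([], 22).total() == 0.0

    def test_build_spectrum_rejects_upward_projection(self):
        with pytest.raises(ValueError):
            build_spectrum(make_sites([1], n=4), 8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_projection_composition(self, seed):
        """project(project(s, m1), m2) == project(s, m2) after normalizing
        (the discarded monomorphic mass differs, the shape does not)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        m1 = int(rng.integers(4, n))
        m2 = int(rng.integers(2, m1))
        spec = random_spectrum(rng, n)
        once = project_spectrum(spec, m2, normalize=True)
        twice = project_spectrum(project_spectrum(spec, m1), m2, normalize=True)
        np.testing.assert_allclose(once.counts, twice.counts, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_projection_mirror_symmetry(self, seed):
        """Projection commutes with ancestral/derived relabeling (reversing
        the spectrum), which is what makes it safe to fold before or after."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        m = int(rng.integers(2, n + 1))
        spec = random_spectrum(rng, n)
        mirrored = DerivedAlleleSpectrum(n, spec.counts[::-1].copy())
        np.testing.assert_allclose(
            project_spectrum(mirrored, m).counts,
            project_spectrum(spec, m).counts[::-1],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            fold_spectrum(project_spectrum(mirrored, m)),
            fold_spectrum(project_spectrum(spec, m)),
            atol=1e-12,
        )


class TestFolding:
    def test_definition_n4(self):
        spec = DerivedAlleleSpectrum(4, [2, 5, 1])
        np.testing.assert_allclose(spec.fold(), [3, 5])

    def test_total_preserved(self, rng):
        spec = random_spectrum(rng, 13)
        assert spec.fold().sum() == pytest.approx(spec.total())

    def test_symmetric_spectrum_doubles_lower_half(self):
        spec = DerivedAlleleSpectrum(6, [3, 2, 7, 2, 3])
        np.testing.assert_allclose(spec.fold(), [6, 4, 7])


def tajima_d_oracle(ks, n):
    """Independent textbook implementation of Tajima's D."""
    S = len(ks)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = sum(2 * k * (n - k) for k in ks) / (n * (n - 1))
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_h_oracle(ks, n):
    """Independent implementation of the unnormalized H = pi - theta_H."""
    pi = sum(2 * k * (n - k) for k in ks) / (n * (n - 1))
    th = sum(2 * k * k for k in ks) / (n * (n - 1))
    return pi - th


class TestSummaryStats:
    def test_matches_independent_oracle_n10(self, rng):
        ks = list(rng.integers(1, 10, size=20))
        st_ = summary_stats(ks, 10)
        assert st_.tajima_d == pytest.approx(tajima_d_oracle(ks, 10), abs=1e-10)
        assert st_.fay_wu_h == pytest.approx(fay_wu_h_oracle(ks, 10), abs=1e-10)

    def test_closed_form_at_n2(self):
        st_ = summary_stats([1, 1, 1], 2)
        assert st_.pi == st_.theta_w == 3.0
        assert st_.tajima_d == 0.0 and st_.fay_wu_h == 0.0

    def test_no_sites_reports_absent(self):
        st_ = summary_stats([], 10)
        assert st_.S == 0 and st_.tajima_d is None and st_.fay_wu_h is None

    def test_per_site_scaling(self):
        st_ = summary_stats([2, 5], 10, L=1000)
        assert st_.theta_w_per_site == pytest.approx(st_.theta_w / 1000)

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            summary_stats([1], 1)
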