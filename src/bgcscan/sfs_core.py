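"""Core data model: regions, segregating sites, fixed differences, and
derived-allele-frequency spectra.

The central objects are:

* :class:`Region` — a genomic interval (BED convention: 0-based, half-open)
  with an optional mask of "covered" sub-intervals, i.e. the bases at which
  genotypes could actually be called.
* :class:`SegregatingSite` — one polymorphic position carrying a derived-allele
  count ``k`` out of ``n`` sampled chromosomes, polarized by an ancestral
  allele and classified as weak-to-strong (W2S: A/T -> G/C), strong-to-weak
  (S2W: G/C -> A/T) or OTHER.
* :class:`DerivedAlleleSpectrum` — the unfolded site frequency spectrum, i.e.
  counts of sites at each derived-allele frequency 1..n-1.  Counts are stored
  as reals because hypergeometric projection to a smaller sample size produces
  fractional weights.

The spectrum projection (:func:`project_spectrum`) reduces a spectrum observed
in ``n`` chromosomes to the spectrum expected in a subsample of ``m`` of them:
a site at derived count ``i`` of ``n`` contributes to count ``j`` of ``m``
with the hypergeometric weight C(i,j) C(n-i, m-j) / C(n,m).  Mass landing on
the monomorphic classes j=0 and j=m (sites that are invisible in the
subsample) is discarded and the result can be renormalized to sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "W2S",
    "S2W",
    "OTHER",
    "WEAK",
    "STRONG",
    "Region",
    "SegregatingSite",
    "FixedDifference",
    "DerivedAlleleSpectrum",
    "SummaryStats",
    "classify_mutation",
    "build_spectrum",
    "projection_matrix",
    "project_spectrum",
    "fold_spectrum",
    "summary_stats",
]

NUCLEOTIDES = frozenset("ACGT")
WEAK = frozenset("AT")
STRONG = frozenset("GC")

W2S = "W2S"
S2W = "S2W"
OTHER = "OTHER"


def classify_mutation(ancestral: str, derived: str) -> str:
    """Classify an ancestral->derived change as W2S, S2W or OTHER.

    W2S: weak (A or T) ancestral allele, strong (G or C) derived allele.
    S2W: the reverse.  Weak->weak and strong->strong changes are OTHER.
    Lowercase input (e.g. low-confidence ancestral calls) is accepted.
    """
    a = ancestral.upper()
    d = derived.upper()
    if a not in NUCLEOTIDES or d not in NUCLEOTIDES:
        raise ValueError(f"alleles must be A/C/G/T, got {ancestral!r}->{derived!r}")
    if a == d:
        raise ValueError(f"ancestral and derived alleles are equal: {ancestral!r}")
    if a in WEAK and d in STRONG:
        return W2S
    if a in STRONG and d in WEAK:
        return S2W
    return OTHER


@dataclass(frozen=True)
class Region:
    """A target region with an optional probe-coverage mask.

    Coordinates are 0-based, half-open.  ``covered`` lists the disjoint,
    sorted sub-intervals at which genotypes are callable; an empty list means
    the whole region is covered.
    """

    id: str
    chrom: str
    start: int
    end: int
    covered: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.id}: start must be < end")
        ivs = tuple((int(a), int(b)) for a, b in self.covered)
        object.__setattr__(self, "covered", ivs)
        prev = self.start
        for a, b in ivs:
            if a < prev or b <= a or b > self.end:
                raise ValueError(
                    f"region {self.id}: covered intervals must be disjoint, "
                    f"sorted and contained in [{self.start},{self.end})"
                )
            prev = b

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def mask(self) -> tuple[tuple[int, int], ...]:
        """Covered intervals; the whole region when no mask was given."""
        return self.covered if self.covered else ((self.start, self.end),)

    @property
    def covered_length(self) -> int:
        return sum(b - a for a, b in self.mask)

    def is_covered(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.mask)


@dataclass(frozen=True)
class SegregatingSite:
    """One polymorphic site: derived count k of n chromosomes, with class."""

    pos: int
    ancestral: str
    derived: str
    k: int
    n: int
    klass: str = field(default="")
    low_confidence_ancestral: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n - 1:
            raise ValueError(f"site {self.pos}: need 1 <= k <= n-1, got k={self.k} n={self.n}")
        klass = classify_mutation(self.ancestral, self.derived)
        if self.klass and self.klass != klass:
            raise ValueError(f"site {self.pos}: klass {self.klass} inconsistent with alleles")
        object.__setattr__(self, "klass", klass)
        object.__setattr__(
            self, "low_confidence_ancestral",
            self.low_confidence_ancestral or self.ancestral.islower(),
        )

    @property
    def daf(self) -> float:
        """Derived allele frequency k/n."""
        return self.k / self.n


@dataclass(frozen=True)
class FixedDifference:
    """A human/chimp fixed difference polarized by an outgroup-inferred ancestor."""

    pos: int
    human: str
    chimp: str
    ancestral: str
    lineage: str = field(default="")
    klass: str = field(default="")

    def __post_init__(self) -> None:
        h, c, a = (x.upper() for x in (self.human, self.chimp, self.ancestral))
        if h == c:
            raise ValueError(f"fixed difference at {self.pos}: human == chimp allele")
        if a not in (h, c):
            raise ValueError(
                f"fixed difference at {self.pos}: ancestral allele {self.ancestral!r} "
                "matches neither lineage (ambiguous polarization)"
            )
        lineage = "human" if h != a else "chimp"
        derived = h if lineage == "human" else c
        object.__setattr__(self, "lineage", lineage)
        object.__setattr__(self, "klass", classify_mutation(a, derived))

    @property
    def derived(self) -> str:
        return self.human if self.lineage == "human" else self.chimp


class DerivedAlleleSpectrum:
    """Unfolded site frequency spectrum: real-valued counts at frequencies 1..n-1."""

    def __init__(self, n: int, counts: Sequence[float] | None = None):
        if n < 2:
            raise ValueError("sample size must be >= 2")
        self.n = int(n)
        if counts is None:
            self._counts = np.zeros(self.n - 1)
        else:
            arr = np.asarray(counts, dtype=float)
            if arr.shape != (self.n - 1,):
                raise ValueError(f"counts must have length n-1={self.n - 1}")
            if np.any(arr < 0):
                raise ValueError("spectrum counts must be nonnegative")
            self._counts = arr.copy()

    @property
    def counts(self) -> np.ndarray:
        """Counts indexed by derived frequency minus one (entry 0 is freq 1)."""
        return self._counts

    def __getitem__(self, freq: int) -> float:
        if not 1 <= freq <= self.n - 1:
            raise IndexError(f"frequency must be in 1..{self.n - 1}")
        return float(self._counts[freq - 1])

    def __setitem__(self, freq: int, value: float) -> None:
        if not 1 <= freq <= self.n - 1:
            raise IndexError(f"frequency must be in 1..{self.n - 1}")
        if value < 0:
            raise ValueError("spectrum counts must be nonnegative")
        self._counts[freq - 1] = value

    def total(self) -> float:
        return float(self._counts.sum())

    def normalized(self) -> "DerivedAlleleSpectrum":
        tot = self.total()
        if tot <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return DerivedAlleleSpectrum(self.n, self._counts / tot)

    def fold(self) -> np.ndarray:
        """Folded (minor-allele) spectrum, indices 1..floor(n/2)."""
        half = self.n // 2
        out = np.zeros(half)
        for i in range(1, half + 1):
            if i == self.n - i:
                out[i - 1] = self._counts[i - 1]
            else:
                out[i - 1] = self._counts[i - 1] + self._counts[self.n - i - 1]
        return out

    def copy(self) -> "DerivedAlleleSpectrum":
        return DerivedAlleleSpectrum(self.n, self._counts)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DerivedAlleleSpectrum)
            and self.n == other.n
            and np.array_equal(self._counts, other._counts)
        )

    def __repr__(self) -> str:
        return f"DerivedAlleleSpectrum(n={self.n}, total={self.total():g})"


def build_spectrum(
    sites: Iterable[SegregatingSite],
    n_target: int,
    renormalize_projection: bool = True,
) -> DerivedAlleleSpectrum:
    """Aggregate sites observed at possibly heterogeneous sample sizes into a
    spectrum at common size ``n_target``.

    Sites genotyped in exactly ``n_target`` chromosomes contribute one unit to
    their frequency class; sites with larger n contribute their hypergeometric
    projection weights.  By default the monomorphic-after-subsampling mass is
    redistributed so each site still contributes one unit in total; with
    ``renormalize_projection=False`` the raw weights are kept (each site then
    contributes its probability of remaining polymorphic), which makes
    aggregation commute exactly with :func:`project_spectrum`.
    """
    spec = DerivedAlleleSpectrum(n_target)
    proj_cache: dict[int, np.ndarray] = {}
    for site in sites:
        if site.n < n_target:
            raise ValueError(
                f"site at {site.pos} has n={site.n} < target {n_target}; "
                "cannot project upward"
            )
        if site.n == n_target:
            spec._counts[site.k - 1] += 1.0
        else:
            if site.n not in proj_cache:
                proj_cache[site.n] = projection_matrix(site.n, n_target)
            w = proj_cache[site.n][site.k - 1]
            tot = w.sum()
            if renormalize_projection and tot > 0:
                spec._counts += w / tot
            else:
                spec._counts += w
    return spec


def projection_matrix(n: int, m: int, include_monomorphic: bool = False) -> np.ndarray:
    """Hypergeometric weights mapping frequency classes at n to classes at m.

    Entry [i-1, j-1] (or [i-1, j] with monomorphic classes included) is the
    probability that a site at derived count i of n shows derived count j in a
    random subsample of m chromosomes: C(i,j) C(n-i, m-j) / C(n,m).
    """
    if not 2 <= m <= n:
        raise ValueError(f"need 2 <= m <= n, got m={m} n={n}")
    i = np.arange(1, n)[:, None]
    if include_monomorphic:
        j = np.arange(0, m + 1)[None, :]
    else:
        j = np.arange(1, m)[None, :]
    return hypergeom.pmf(j, n, i, m)


def project_spectrum(
    spec: DerivedAlleleSpectrum, m: int, normalize: bool = False
) -> DerivedAlleleSpectrum:
    """Project a spectrum at sample size n down to sample size m.

    Weights landing on the monomorphic classes (j=0 or j=m) are discarded;
    with ``normalize=True`` the result is rescaled to total one.
    """
    if not 2 <= m <= spec.n:
        raise ValueError(f"target sample size must be in 2..{spec.n}, got {m}")
    if m == spec.n:
        out = spec.copy()
    else:
        out = DerivedAlleleSpectrum(m, spec.counts @ projection_matrix(spec.n, m))
    if normalize:
        out = out.normalized()
    return out


def fold_spectrum(spec: DerivedAlleleSpectrum) -> np.ndarray:
    """Folded spectrum of ``spec``; entry i-1 is the count at minor frequency i."""
    return spec.fold()


@dataclass(frozen=True)
class SummaryStats:
    """Classical SFS summary statistics for one region.

    ``tajima_d`` and ``fay_wu_h`` are None when S = 0 (undefined, not zero).
    Per-site values of the estimators are obtained by dividing by the number
    of callable bases L (reported when L was supplied).
    """

    S: int
    theta_w: float
    pi: float
    theta_h: float
    tajima_d: float | None
    fay_wu_h: float | None
    theta_w_per_site: float | None = None
    pi_per_site: float | None = None


def _tajima_d_constants(n: int) -> tuple[float, float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def summary_stats(
    sites: Iterable[SegregatingSite | int],
    n: int,
    L: float | None = None,
) -> SummaryStats:
    """Watterson's theta, pi, Tajima's D and Fay & Wu's H for one region.

    ``sites`` may be SegregatingSite objects or bare derived counts; all are
    taken at common sample size ``n``.  D follows Tajima's variance
    normalization; H is the unnormalized pi - theta_H difference.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    ks = np.array(
        [s.k if isinstance(s, SegregatingSite) else int(s) for s in sites], dtype=float
    )
    S = len(ks)
    a1, e1, e2 = _tajima_d_constants(n)
    theta_w = S / a1
    pi = float(np.sum(2.0 * ks * (n - ks)) / (n * (n - 1)))
    theta_h = float(np.sum(2.0 * ks**2) / (n * (n - 1)))
    if S == 0:
        d = h = None
    else:
        var = e1 * S + e2 * S * (S - 1)
        if var > 0:
            d = (pi - theta_w) / math.sqrt(var)
        else:
            # at n=2 the variance constants vanish along with pi - theta_w
            d = 0.0 if abs(pi - theta_w) < 1e-12 else None
        h = pi - theta_h
    return SummaryStats(
        S=S,
        theta_w=theta_w,
        pi=pi,
        theta_h=theta_h,
        tajima_d=d,
        fay_wu_h=h,
        theta_w_per_site=(theta_w / L) if L else None,
        pi_per_site=(pi / L) if L else None,
    )
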