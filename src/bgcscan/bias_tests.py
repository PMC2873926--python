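"""Fixation-bias tests on mutation-class-partitioned polymorphism data.

Two complementary tests detect a bias favoring fixation of strong (G/C) over
weak (A/T) alleles, the population-genetic signature of GC-biased gene
conversion:

* **MWU spectrum test** (:func:`mwu_test`): a two-sided Mann-Whitney U /
  Wilcoxon rank-sum test comparing the derived-allele frequencies of W2S
  versus S2W segregating sites.  A positive offset (Hodges-Lehmann shift of
  the two frequency samples, normalized to 22 chromosomes) means W2S
  mutations segregate at higher frequencies — an *ongoing* fixation bias.

* **MK-like test** (:func:`mk_test`): a Fisher exact test on the 2x2 table of
  {fixed differences, segregating sites} x {W2S, S2W}.  Enrichment of W2S
  among fixed differences relative to polymorphism indicates a *historical*
  fixation bias.

Masking scans (:func:`mask_scan`) rerun either test after removing all data
under central masks of 0.5/1/5/10 kb or under fifteen sliding 5 kb windows,
probing whether a signal is driven by a localized element.  Auxiliary
routines cover the site/fixed-difference cleaning filters, pooled tests,
association statistics between the two tests across many regions, an exact
conditional Hardy-Weinberg test, a Poisson substitution-acceleration test,
and the back-of-envelope estimate of how many sweeps would be detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .sfs_core import (
    OTHER,
    S2W,
    W2S,
    FixedDifference,
    Region,
    SegregatingSite,
)

__all__ = [
    "MWUResult",
    "MKResult",
    "MaskScanResult",
    "AssociationResult",
    "DetectableSweeps",
    "RawSite",
    "FixedDifferenceSet",
    "filter_segregating_sites",
    "clean_fixed_differences",
    "mwu_test",
    "fisher_exact_2x2",
    "mk_test",
    "pooled_mwu",
    "pooled_mk",
    "mask_scan",
    "association_tests",
    "hwe_exact_test",
    "poisson_acceleration_test",
    "estimate_detectable_sweeps",
    "split_by_class",
]

DEFAULT_ALPHA = 0.05
CENTRAL_MASK_WIDTHS = (500, 1000, 5000, 10000)
SLIDING_MASK_WIDTH = 5000
SLIDING_MASK_SPACING = 2500

UNDETERMINED = {None, "", ".", "-", "N", "n"}


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class MWUResult:
    """Mann-Whitney comparison of W2S vs S2W derived-allele frequencies.

    ``p`` and ``offset22`` are None when either class is empty.  ``offset22``
    is the Hodges-Lehmann shift between the two frequency samples scaled to
    22 chromosomes; positive values mean W2S sites sit at higher frequencies.
    """

    p: float | None
    offset22: float | None
    n_w2s: int
    n_s2w: int
    method: str = ""

    @property
    def valid(self) -> bool:
        return self.p is not None

    @property
    def direction(self) -> str | None:
        if self.offset22 is None or self.offset22 == 0:
            return None
        return W2S if self.offset22 > 0 else S2W


@dataclass(frozen=True)
class MKResult:
    """MK-like contingency test of fixed vs segregating W2S:S2W ratios.

    ``table`` rows are (fixed, segregating), columns (W2S, S2W).
    ``direction`` names the class enriched among fixed differences.
    """

    p: float | None
    direction: str | None
    table: tuple[tuple[int, int], tuple[int, int]]

    @property
    def valid(self) -> bool:
        return self.p is not None


@dataclass(frozen=True)
class MaskScanResult:
    """Per-mask p-values from central and sliding masking scans."""

    central: dict[int, float | None]
    sliding: list[tuple[int, float | None]]
    unmasked_p: float | None

    @property
    def sliding_max(self) -> float | None:
        ps = [p for _, p in self.sliding if p is not None]
        return max(ps) if ps else None


@dataclass(frozen=True)
class AssociationResult:
    fisher_p: float
    binomial_p: float
    poisson_p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    n_both: int


@dataclass(frozen=True)
class DetectableSweeps:
    expected: float
    adaptive_bound: int


# ---------------------------------------------------------------------------
# cleaning filters


@dataclass(frozen=True)
class RawSite:
    """A pre-filter site record: reference/ancestral calls plus per-allele
    counts over the genotyped chromosomes."""

    pos: int
    ref: str
    ancestral: str | None
    allele_counts: Mapping[str, int]

    @property
    def n(self) -> int:
        return sum(self.allele_counts.values())


def filter_segregating_sites(raw: Iterable[RawSite], min_n: int = 8) -> list[SegregatingSite]:
    """Apply the site-cleaning filters and classify the survivors.

    Removes sites genotyped in fewer than ``min_n`` chromosomes, sites with
    more than two distinct alleles among the reference, ancestral and sample
    alleles, and sites whose ancestral allele is undetermined.  A lowercase
    ancestral call counts as determined (it is carried as a low-confidence
    flag on the site).
    """
    out: list[SegregatingSite] = []
    for rec in raw:
        anc = rec.ancestral
        if anc in UNDETERMINED:
            continue
        if rec.n < min_n:
            continue
        sample_alleles = {a.upper() for a, c in rec.allele_counts.items() if c > 0}
        alleles = sample_alleles | {rec.ref.upper(), anc.upper()}
        if len(alleles) > 2 or len(sample_alleles) != 2:
            continue
        if anc.upper() not in sample_alleles:
            continue
        derived = next(a for a in sample_alleles if a != anc.upper())
        k = sum(c for a, c in rec.allele_counts.items() if a.upper() == derived)
        if not 1 <= k <= rec.n - 1:
            continue
        out.append(
            SegregatingSite(pos=rec.pos, ancestral=anc, derived=derived, k=k, n=rec.n)
        )
    return out


@dataclass(frozen=True)
class FixedDifferenceSet:
    """Cleaned fixed differences with per-class counts and filter accounting."""

    items: tuple[FixedDifference, ...]
    n_input: int = 0
    n_removed: int = 0

    def __post_init__(self) -> None:
        if self.n_input == 0:
            object.__setattr__(self, "n_input", len(self.items))

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def class_counts(self) -> dict[str, int]:
        counts = {W2S: 0, S2W: 0, OTHER: 0}
        for d in self.items:
            counts[d.klass] += 1
        return counts

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def clean_fixed_differences(
    candidates: Iterable[FixedDifference | tuple],
    segregating_positions: set[int] = frozenset(),
    snp_catalog_positions: set[int] = frozenset(),
    callable_positions: set[int] | None = None,
) -> FixedDifferenceSet:
    """Clean candidate human/chimp fixed differences.

    Keeps candidates that fall at callable positions (all positions when
    ``callable_positions`` is None), have a determined ancestral allele, and
    are absent from both the observed segregating sites and the SNP catalog.
    Raw tuples ``(pos, human, chimp, ancestral_or_None)`` are accepted so
    undetermined-ancestral candidates can be counted as removed.
    """
    kept: list[FixedDifference] = []
    n_input = 0
    for cand in candidates:
        n_input += 1
        if isinstance(cand, FixedDifference):
            pos, human, chimp, anc = cand.pos, cand.human, cand.chimp, cand.ancestral
        else:
            pos, human, chimp, anc = cand
        if anc in UNDETERMINED:
            continue
        if callable_positions is not None and pos not in callable_positions:
            continue
        if pos in segregating_positions or pos in snp_catalog_positions:
            continue
        kept.append(FixedDifference(pos=int(pos), human=human, chimp=chimp, ancestral=anc))
    return FixedDifferenceSet(tuple(kept), n_input=n_input, n_removed=n_input - len(kept))


def split_by_class(sites: Iterable[SegregatingSite]) -> dict[str, list[SegregatingSite]]:
    out: dict[str, list[SegregatingSite]] = {W2S: [], S2W: [], OTHER: []}
    for s in sites:
        out[s.klass].append(s)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U test with Hodges-Lehmann offset


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p with midranks, by dynamic programming over
    the permutation distribution; p = min(1, 2 min(P(RS<=obs), P(RS>=obs)))."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    iranks = np.round(ranks * 2).astype(int)  # integers: midranks are halves
    m = len(x)
    obs = int(iranks[:m].sum())
    total = int(iranks.sum())
    # dp[j] maps rank-sum -> number of m-subsets attaining it
    dp: list[dict[int, int]] = [dict() for _ in range(m + 1)]
    dp[0][0] = 1
    for r in iranks:
        for j in range(min(m, len(dp)) - 1, -1, -1):
            if j + 1 > m:
                continue
            for s, c in list(dp[j].items()):
                dp[j + 1][s + r] = dp[j + 1].get(s + r, 0) + c
    dist = dp[m]
    n_total = math.comb(len(pooled), m)
    p_le = sum(c for s, c in dist.items() if s <= obs) / n_total
    p_ge = sum(c for s, c in dist.items() if s >= obs) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.median(np.subtract.outer(x, y)))


def mwu_test(
    w2s: Sequence[SegregatingSite] | Sequence[float],
    s2w: Sequence[SegregatingSite] | Sequence[float],
    method: str = "auto",
    exact_limit: int = 50,
) -> MWUResult:
    """Two-sided MWU test of W2S vs S2W derived-allele frequencies.

    Inputs may be SegregatingSite lists or bare frequencies.  ``method``:

    * ``"auto"`` — exact null distribution when there are no ties and the
      combined sample size is below ``exact_limit``, otherwise the normal
      approximation with midranks, tie correction and continuity correction
      (the behavior of R's ``wilcox.test``).
    * ``"exact"`` — full permutation distribution of the midrank sum.
    * ``"asymptotic"`` — corrected normal approximation always.

    The offset is the Hodges-Lehmann shift (median of pairwise frequency
    differences, W2S minus S2W) scaled to 22 chromosomes.
    """
    x = np.array([s.daf if isinstance(s, SegregatingSite) else float(s) for s in w2s])
    y = np.array([s.daf if isinstance(s, SegregatingSite) else float(s) for s in s2w])
    if len(x) == 0 or len(y) == 0:
        return MWUResult(p=None, offset22=None, n_w2s=len(x), n_s2w=len(y), method="absent")

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        if not has_ties and len(pooled) < exact_limit:
            used = "exact"
        else:
            used = "asymptotic"
    elif method in ("exact", "asymptotic"):
        used = method
    else:
        raise ValueError(f"unknown method {method!r}")

    if used == "exact":
        if has_ties:
            p = _rank_sum_exact_p(x, y)
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    offset22 = 22.0 * _hodges_lehmann(x, y)
    return MWUResult(p=p, offset22=offset22, n_w2s=len(x), n_s2w=len(y), method=used)


# ---------------------------------------------------------------------------
# Fisher / MK


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities no larger than that of the
    observed table (the convention of R's ``fisher.test``).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("table must have at least one nonzero margin")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mk_test(
    fixed: FixedDifferenceSet | Iterable[FixedDifference] | Mapping[str, int],
    segregating: Iterable[SegregatingSite] | Mapping[str, int],
) -> MKResult:
    """MK-like test: Fisher exact on {fixed, segregating} x {W2S, S2W}.

    OTHER-class changes are excluded from the table.  ``direction`` is W2S
    when the fixed-difference W2S:S2W odds exceed the segregating odds.  The
    result is absent (p None) when either stratum has no W2S+S2W entries.
    """
    if isinstance(fixed, Mapping):
        fx_w, fx_s = int(fixed.get(W2S, 0)), int(fixed.get(S2W, 0))
    else:
        items = fixed.items if isinstance(fixed, FixedDifferenceSet) else tuple(fixed)
        fx_w = sum(1 for d in items if d.klass == W2S)
        fx_s = sum(1 for d in items if d.klass == S2W)
    if isinstance(segregating, Mapping):
        sg_w, sg_s = int(segregating.get(W2S, 0)), int(segregating.get(S2W, 0))
    else:
        seg = tuple(segregating)
        sg_w = sum(1 for s in seg if s.klass == W2S)
        sg_s = sum(1 for s in seg if s.klass == S2W)

    table = ((fx_w, fx_s), (sg_w, sg_s))
    if fx_w + fx_s == 0 or sg_w + sg_s == 0:
        return MKResult(p=None, direction=None, table=table)
    p = fisher_exact_2x2(fx_w, fx_s, sg_w, sg_s)
    # compare W2S:S2W odds between strata; ratios compared as cross-products
    # so zero cells are handled without division
    lhs = fx_w * sg_s
    rhs = fx_s * sg_w
    direction = W2S if lhs > rhs else S2W if lhs < rhs else None
    return MKResult(p=p, direction=direction, table=table)


def pooled_mwu(site_lists: Iterable[Iterable[SegregatingSite]], **kw) -> MWUResult:
    """MWU test on segregating sites pooled across regions."""
    pooled = [s for sites in site_lists for s in sites]
    by = split_by_class(pooled)
    return mwu_test(by[W2S], by[S2W], **kw)


def pooled_mk(
    fixed_sets: Iterable[FixedDifferenceSet | Iterable[FixedDifference]],
    site_lists: Iterable[Iterable[SegregatingSite]],
) -> MKResult:
    """MK test on fixed differences and segregating sites pooled across regions."""
    fixed = [d for fs in fixed_sets for d in fs]
    sites = [s for sites in site_lists for s in sites]
    return mk_test(fixed, sites)


# ---------------------------------------------------------------------------
# masking scans


def _run_test(test: str, sites: Sequence[SegregatingSite],
              fixed: Sequence[FixedDifference]) -> float | None:
    if test == "MWU":
        by = split_by_class(sites)
        return mwu_test(by[W2S], by[S2W]).p
    if test == "MK":
        return mk_test(fixed, sites).p
    raise ValueError(f"unknown test {test!r}")


def mask_scan(
    region: Region,
    sites: Sequence[SegregatingSite],
    fixed: Sequence[FixedDifference] = (),
    test: str = "MWU",
    central_widths: Sequence[int] = CENTRAL_MASK_WIDTHS,
) -> MaskScanResult:
    """Rerun a bias test under central and sliding masks.

    A central mask of width w removes all sites and fixed differences within
    w/2 of the region center.  Sliding masks are 5 kb windows centered every
    2.5 kb from the region start (15 windows in a 40 kb region).  Masks that
    empty a required stratum yield a missing p, not p = 1.
    """
    if region.length < max(central_widths):
        raise ValueError("region shorter than the largest central mask")

    def masked(lo: float, hi: float):
        s = [x for x in sites if not lo <= x.pos < hi]
        f = [x for x in fixed if not lo <= x.pos < hi]
        return s, f

    central: dict[int, float | None] = {}
    c = region.center
    for w in central_widths:
        s, f = masked(c - w / 2, c + w / 2)
        central[w] = _run_test(test, s, f)

    sliding: list[tuple[int, float | None]] = []
    center = region.start + SLIDING_MASK_SPACING
    while center + SLIDING_MASK_WIDTH // 2 <= region.end:
        s, f = masked(center - SLIDING_MASK_WIDTH / 2, center + SLIDING_MASK_WIDTH / 2)
        sliding.append((center, _run_test(test, s, f)))
        center += SLIDING_MASK_SPACING

    return MaskScanResult(
        central=central, sliding=sliding, unmasked_p=_run_test(test, list(sites), list(fixed))
    )


# ---------------------------------------------------------------------------
# association and auxiliary tests


def association_tests(
    mwu_flags: Sequence[bool],
    mk_flags: Sequence[bool],
    reference_rate: float | None = None,
) -> AssociationResult:
    """Association between per-region MWU and MK significance calls.

    Fisher exact p comes from the {MWU, notMWU} x {MK, notMK} table.  The
    binomial and Poisson p-values are upper tails for the count of regions
    significant on *both* tests at ``reference_rate`` (defaulting to the
    empirical both-rate, which yields an uninformative p of ~0.5+).
    """
    if len(mwu_flags) != len(mk_flags):
        raise ValueError("flag vectors must have equal length")
    mwu = np.asarray(mwu_flags, dtype=bool)
    mk = np.asarray(mk_flags, dtype=bool)
    n = len(mwu)
    both = int(np.sum(mwu & mk))
    mwu_only = int(np.sum(mwu & ~mk))
    mk_only = int(np.sum(~mwu & mk))
    neither = int(np.sum(~mwu & ~mk))
    fisher_p = fisher_exact_2x2(both, mwu_only, mk_only, neither)
    rate = reference_rate if reference_rate is not None else (both / n if n else 0.0)
    binomial_p = float(stats.binom.sf(both - 1, n, rate)) if rate > 0 else 1.0
    poisson_p = float(stats.poisson.sf(both - 1, n * rate)) if rate > 0 else 1.0
    return AssociationResult(
        fisher_p=fisher_p,
        binomial_p=binomial_p,
        poisson_p=poisson_p,
        table=((both, mwu_only), (mk_only, neither)),
        n_both=both,
    )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one individual")
    n_a_allele = 2 * n_AA + n_Aa
    n_b_allele = 2 * n - n_a_allele
    if n_a_allele == 0 or n_b_allele == 0:
        return 1.0
    hets = range(n_Aa % 2, min(n_a_allele, n_b_allele) + 1, 2)
    logw = {}
    for h in hets:
        haa = (n_a_allele - h) // 2
        hbb = (n_b_allele - h) // 2
        logw[h] = (
            math.lgamma(n + 1)
            - math.lgamma(haa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hbb + 1)
            + h * math.log(2.0)
        )
    mx = max(logw.values())
    probs = {h: math.exp(v - mx) for h, v in logw.items()}
    tot = sum(probs.values())
    p_obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / tot)


def poisson_acceleration_test(observed_subs: int, expected_neutral: float) -> float:
    """Upper-tail Poisson p: P(X >= observed) for X ~ Poisson(expected)."""
    if expected_neutral <= 0:
        raise ValueError("expected neutral substitution count must be positive")
    if observed_subs < 0:
        raise ValueError("observed count must be nonnegative")
    return float(stats.poisson.sf(observed_subs - 1, expected_neutral))


def estimate_detectable_sweeps(
    human_subs: int,
    chimp_subs: int,
    divergence_years: float = 5e6,
    detection_window_years: float = 2e5,
) -> DetectableSweeps:
    """Expected number of sweeps detectable by an SFS scan.

    Treats the excess of human- over chimp-lineage substitutions as an upper
    bound on adaptive events, assumes they occurred uniformly over the
    divergence time, and keeps the fraction falling within the detection
    window of the scan.
    """
    if not human_subs >= chimp_subs >= 0:
        raise ValueError("need human_subs >= chimp_subs >= 0")
    if not 0 < detection_window_years <= divergence_years:
        raise ValueError("detection window must be in (0, divergence]")
    bound = human_subs - chimp_subs
    return DetectableSweeps(
        expected=bound * detection_window_years / divergence_years,
        adaptive_bound=bound,
    )
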