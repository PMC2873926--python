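"""MWU/MK fixation-bias tests, filters, mask scans and auxiliary tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from bgcscan.bias_tests import (
    RawSite,
    association_tests,
    clean_fixed_differences,
    estimate_detectable_sweeps,
    fisher_exact_2x2,
    filter_segregating_sites,
    hwe_exact_test,
    mask_scan,
    mk_test,
    mwu_test,
    poisson_acceleration_test,
    pooled_mk,
    pooled_mwu,
    split_by_class,
)
from bgcscan.sfs_core import S2W, W2S, FixedDifference, Region

from conftest import make_sites


def mwu_exact_oracle(x, y):
    """Exhaustive rank-permutation two-sided p with midranks (itertools)."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    m = len(x)
    obs = ranks[:m].sum()
    sums = [sum(ranks[i] for i in comb)
            for comb in itertools.combinations(range(len(pooled)), m)]
    n_tot = len(sums)
    p_le = sum(1 for s in sums if s <= obs + 1e-9) / n_tot
    p_ge = sum(1 for s in sums if s >= obs - 1e-9) / n_tot
    return min(1.0, 2 * min(p_le, p_ge))


class TestMWU:
    def test_identical_lists_no_shift(self):
        res = mwu_test([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.offset22 == 0 and res.p == pytest.approx(1.0)

    def test_extreme_separation_exact_tail(self):
        """5 sites at 21/22 vs 5 at 1/22: exact permutation tail 2/C(10,5)."""
        res = mwu_test([21 / 22] * 5, [1 / 22] * 5, method="exact")
        assert res.p == pytest.approx(2 / math.comb(10, 5))
        assert res.offset22 == pytest.approx(20.0)

    def test_swap_symmetry(self, rng):
        x = list(rng.random(8))
        y = list(rng.random(11))
        a = mwu_test(x, y)
        b = mwu_test(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.offset22 == pytest.approx(-b.offset22)

    def test_empty_class_absent(self):
        res = mwu_test([], [0.5])
        assert res.p is None and res.offset22 is None and res.n_w2s == 0

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (4, 5), (6, 6)])
    def test_exact_with_ties_matches_enumeration(self, rng, m, n):
        for _ in range(5):
            x = list(rng.integers(1, 5, m) / 6)
            y = list(rng.integers(1, 5, n) / 6)
            assert mwu_test(x, y, method="exact").p == pytest.approx(
                mwu_exact_oracle(x, y), abs=1e-12
            )

    def test_accepts_site_objects(self):
        res = mwu_test(make_sites([20, 21], klass_alleles=("A", "G")),
                       make_sites([1, 2], klass_alleles=("G", "A")))
        assert res.offset22 > 0 and res.direction == W2S


def fisher_oracle(a, b, c, d):
    """Full fixed-margin table enumeration: sum of point hypergeometric
    probabilities <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = None
    probs = []
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = (math.comb(r1, aa) * math.comb(r2, c1 - aa)) / math.comb(n, c1)
        probs.append(p)
        if aa == a:
            p_obs = p
    return sum(p for p in probs if p <= p_obs * (1 + 1e-7))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [((1, 10, 10, 28), 0.42), ((12, 39, 118, 330), 0.74)],
    )
    def test_reference_association_tables(self, table, expected):
        assert round(fisher_exact_2x2(*table), 2) == expected

    def test_proportional_rows_give_one(self):
        assert fisher_exact_2x2(2, 4, 3, 6) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_enumeration_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b + c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )


class TestMK:
    def test_balanced_table_p_one(self):
        res = mk_test({W2S: 10, S2W: 10}, {W2S: 10, S2W: 10})
        assert res.p == pytest.approx(1.0) and res.direction is None

    def test_biased_table_direction_and_p(self):
        res = mk_test({W2S: 30, S2W: 10}, {W2S: 10, S2W: 30})
        assert res.direction == W2S
        assert res.p == pytest.approx(fisher_oracle(30, 10, 10, 30), abs=1e-9)

    def test_direction_flips_when_strata_swapped(self):
        a = mk_test({W2S: 30, S2W: 10}, {W2S: 10, S2W: 30})
        b = mk_test({W2S: 10, S2W: 30}, {W2S: 30, S2W: 10})
        assert a.direction == W2S and b.direction == S2W and a.p == pytest.approx(b.p)

    def test_empty_stratum_absent(self):
        assert mk_test({W2S: 0, S2W: 0}, {W2S: 5, S2W: 5}).p is None

    def test_other_class_excluded(self):
        fixed = [FixedDifference(pos=i, human="G", chimp="A", ancestral="A")
                 for i in range(5)]
        fixed += [FixedDifference(pos=99, human="T", chimp="A", ancestral="A")]
        seg = make_sites([3, 5], klass_alleles=("A", "G")) + make_sites(
            [2, 7], klass_alleles=("G", "T"))
        res = mk_test(fixed, seg)
        assert res.table == ((5, 0), (2, 2))


class TestFilters:
    def test_low_sample_count_removed(self):
        raw = [RawSite(pos=1, ref="A", ancestral="A", allele_counts={"A": 4, "G": 3})]
        assert filter_segregating_sites(raw) == []

    def test_triallelic_removed(self):
        raw = [RawSite(pos=1, ref="A", ancestral="A",
                       allele_counts={"G": 5, "T": 5})]
        assert filter_segregating_sites(raw) == []

    def test_undetermined_ancestral_removed_lowercase_kept(self):
        counts = {"A": 5, "G": 5}
        gone = RawSite(pos=1, ref="A", ancestral=None, allele_counts=counts)
        kept = RawSite(pos=2, ref="A", ancestral="a", allele_counts=counts)
        out = filter_segregating_sites([gone, kept])
        assert [s.pos for s in out] == [2]
        assert out[0].low_confidence_ancestral and out[0].klass == W2S
        assert out[0].k == 5

    def test_clean_fixed_differences_filters(self):
        cands = [
            FixedDifference(pos=1, human="G", chimp="A", ancestral="A"),
            FixedDifference(pos=2, human="G", chimp="A", ancestral="A"),
            FixedDifference(pos=3, human="G", chimp="A", ancestral="A"),
            (4, "G", "A", None),  # undetermined ancestral
        ]
        out = clean_fixed_differences(
            cands,
            segregating_positions={2},
            snp_catalog_positions={3},
            callable_positions={1, 2, 3, 4},
        )
        assert [d.pos for d in out] == [1]
        assert out.n_input == 4 and out.removed_fraction == 0.75

    def test_clean_no_exclusions_identity(self):
        cands = [FixedDifference(pos=i, human="G", chimp="A", ancestral="A")
                 for i in range(7)]
        out = clean_fixed_differences(cands)
        assert len(out) == 7 and out.removed_fraction == 0.0

    def test_clean_uncallable_removed(self):
        cands = [FixedDifference(pos=9, human="G", chimp="A", ancestral="A")]
        out = clean_fixed_differences(cands, callable_positions={1})
        assert len(out) == 0


class TestPooling:
    def test_pooling_single_region_is_identity(self):
        sites = make_sites([2, 9, 15], klass_alleles=("A", "G")) + make_sites(
            [1, 3], klass_alleles=("G", "A"))
        by = split_by_class(sites)
        single = mwu_test(by[W2S], by[S2W])
        pooled = pooled_mwu([sites])
        assert pooled.p == single.p and pooled.offset22 == single.offset22

    def test_pooling_doubles_counts_preserves_odds(self):
        fixed = [FixedDifference(pos=i, human="G", chimp="A", ancestral="A")
                 for i in range(6)]
        sites = make_sites([2, 9], klass_alleles=("A", "G")) + make_sites(
            [1, 3, 4], klass_alleles=("G", "A"))
        once = mk_test(fixed, sites)
        twice = pooled_mk([fixed, fixed], [sites, sites])
        assert twice.table == tuple(tuple(2 * v for v in row) for row in once.table)


class TestMaskScan:
    def _toy(self):
        region = Region(id="r", chrom="1", start=0, end=40_000)
        # W2S cluster inside the central 1 kb, S2W scattered
        w2s = make_sites([15, 18, 20], klass_alleles=("A", "G"),
                         start_pos=19_600, spacing=100)
        s2w = make_sites([2, 3, 4, 5], klass_alleles=("G", "A"),
                         start_pos=1_000, spacing=9_000)
        return region, w2s + s2w

    def test_forty_kb_region_has_fifteen_sliding_windows(self):
        region, sites = self._toy()
        res = mask_scan(region, sites, test="MWU")
        assert len(res.sliding) == 15
        assert [c for c, _ in res.sliding] == list(range(2_500, 40_000, 2_500))

    def test_central_mask_removing_all_w2s_gives_absent(self):
        region, sites = self._toy()
        res = mask_scan(region, sites, test="MWU")
        assert res.central[1000] is None  # W2S stratum emptied, not p = 1
        assert res.unmasked_p is not None

    def test_mask_covering_no_sites_reproduces_unmasked_p(self):
        region = Region(id="r", chrom="1", start=0, end=40_000)
        w2s = make_sites([15, 18], klass_alleles=("A", "G"), start_pos=100)
        s2w = make_sites([2, 3], klass_alleles=("G", "A"), start_pos=35_000)
        res = mask_scan(region, w2s + s2w, test="MWU")
        assert res.central[500] == res.unmasked_p

    def test_region_shorter_than_mask_rejected(self):
        region = Region(id="r", chrom="1", start=0, end=5_000)
        with pytest.raises(ValueError):
            mask_scan(region, [], test="MWU")


class TestAssociation:
    def test_reference_target_region_cross_tabulation(self):
        """49 regions: 11 MWU-significant, 11 MK-significant, 1 both."""
        mwu = [True] * 11 + [False] * 38
        mk = [True] * 1 + [False] * 10 + [True] * 10 + [False] * 28
        res = association_tests(mwu, mk)
        assert round(res.fisher_p, 2) == 0.42
        assert res.table == ((1, 10), (10, 28))

    def test_all_false_fisher_one(self):
        res = association_tests([False] * 10, [False] * 10)
        assert res.fisher_p == pytest.approx(1.0)

    def test_binomial_tail_with_zero_observed_is_one(self):
        res = association_tests([False] * 10, [True] * 10, reference_rate=0.3)
        assert res.binomial_p == pytest.approx(1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            association_tests([True], [True, False])


class TestHWE:
    @pytest.mark.parametrize(
        "counts,expected",
        [((0, 2, 0), 1.0), ((1, 0, 1), 1 / 3), ((5, 0, 0), 1.0)],
    )
    def test_exact_conditional_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected)

    def test_matches_full_enumeration(self):
        """Against a direct conditional-probability enumeration oracle."""
        def oracle(naa, nab, nbb):
            n = naa + nab + nbb
            na = 2 * naa + nab
            nb = 2 * n - na
            if na == 0 or nb == 0:
                return 1.0
            probs = {}
            for h in range(nab % 2, min(na, nb) + 1, 2):
                probs[h] = (
                    math.factorial(n) * 2**h
                    / math.factorial((na - h) // 2)
                    / math.factorial(h)
                    / math.factorial((nb - h) // 2)
                )
            tot = sum(probs.values())
            return sum(p for p in probs.values() if p <= probs[nab] * (1 + 1e-9)) / tot

        for naa, nab, nbb in itertools.product(range(5), repeat=3):
            if naa + nab + nbb == 0:
                continue
            assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                oracle(naa, nab, nbb), abs=1e-9
            )


class TestPoissonAcceleration:
    def test_zero_observed_is_one(self):
        assert poisson_acceleration_test(0, 3.0) == 1.0

    def test_closed_form_one_observed(self):
        assert poisson_acceleration_test(1, 1.0) == pytest.approx(1 - math.exp(-1))

    def test_matches_series_oracle(self):
        mean = 2.0
        series = 1 - sum(math.exp(-mean) * mean**j / math.factorial(j) for j in range(10))
        assert poisson_acceleration_test(10, mean) == pytest.approx(series, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            poisson_acceleration_test(1, 0.0)


class TestDetectableSweeps:
    def test_reference_numbers(self):
        res = estimate_detectable_sweeps(206, 16, 5e6, 2e5)
        assert res.expected == pytest.approx(7.6) and res.adaptive_bound == 190

    def test_equal_substitution_counts_give_zero(self):
        assert estimate_detectable_sweeps(16, 16).expected == 0.0

    def test_window_equals_divergence_returns_bound(self):
        res = estimate_detectable_sweeps(100, 40, 1e6, 1e6)
        assert res.expected == pytest.approx(res.adaptive_bound)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_detectable_sweeps(100, 40, 1e6, 2e6)


class TestPooledPower:
    def test_pooling_beats_median_per_region_p_under_common_shift(self, rng):
        """With a common W2S frequency shift across regions, the pooled MWU
        p-value is smaller than the median per-region p-value."""
        from bgcscan.bias_tests import pooled_mwu

        wins = 0
        reps = 30
        for _ in range(reps):
            region_sites = []
            per_region_p = []
            for _r in range(8):
                w2s_k = np.minimum(21, rng.integers(1, 22, 20) + rng.integers(0, 6, 20))
                s2w_k = rng.integers(1, 22, 20)
                sites = make_sites(w2s_k, klass_alleles=("A", "G")) + make_sites(
                    s2w_k, klass_alleles=("G", "A"), start_pos=5_000)
                region_sites.append(sites)
                by = split_by_class(sites)
                per_region_p.append(mwu_test(by[W2S], by[S2W]).p)
            pooled = pooled_mwu(region_sites)
            if pooled.p < np.median(per_region_p):
                wins += 1
        assert wins > 0.8 * reps
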