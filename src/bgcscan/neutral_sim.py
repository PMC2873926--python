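"""Neutral calibration machinery.

Two simulators generate data under neutrality with the shape of the study's
observations:

* :func:`simulate_neutral_region` — a standard-coalescent simulator (built on
  msprime genealogies) for segregating sites, optionally conditioned on an
  exact segregating-site count S (mutations placed on branches with
  probability proportional to branch length x genomic span, the behavior of
  Hudson's ``ms -s``), with recombination and a probe-coverage mask: site
  positions fall only in covered intervals.

* :func:`simulate_fixed_differences` — a phylogenetic substitution simulator
  on a (human, chimp, outgroup) star tree under an HKY-style reversible model
  with tunable equilibrium GC content.  Alignment columns are drawn until the
  requested number of human-chimp differences with an unambiguous
  outgroup-determined ancestral allele have been collected.

:func:`calibrate_test` wires these into the MWU / MK tests to verify that the
tests' p-values are uniform under neutrality: for each significance level it
reports the fraction of simulated replicates below that level, and the subset
of that fraction in which the W2S class was the one favored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import msprime
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .bias_tests import mk_test, mwu_test, split_by_class
from .sfs_core import OTHER, S2W, W2S, FixedDifference, SegregatingSite

__all__ = [
    "CoalescentConfig",
    "PhyloSimConfig",
    "DEFAULT_W2S_FRACTION",
    "simulate_neutral_region",
    "label_mutation_classes",
    "hky_rate_matrix",
    "simulate_fixed_differences",
    "calibrate_test",
]

# study-wide W2S:S2W segregating-site composition, 2057:2114
DEFAULT_W2S_FRACTION = 2057 / (2057 + 2114)

_CLASS_ALLELES = {W2S: ("A", "G"), S2W: ("G", "A"), OTHER: ("A", "T")}
_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class CoalescentConfig:
    """Configuration for one neutral coalescent region.

    Exactly one of ``S`` (condition on the segregating-site count) or
    ``theta`` (per-site scaled mutation rate 4Nu; S becomes Poisson) must be
    set.  ``rho`` is the population-scaled recombination rate 4Nr for the
    whole region of length ``L``; ``mask`` lists covered intervals in local
    coordinates (None = fully covered).
    """

    n: int
    L: int
    S: int | None = None
    theta: float | None = None
    rho: float = 0.0
    mask: tuple[tuple[int, int], ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 sampled chromosomes")
        if (self.S is None) == (self.theta is None):
            raise ValueError("set exactly one of S or theta")
        if self.S is not None and self.S < 0:
            raise ValueError("S must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def _mask_intersection(
    mask: Sequence[tuple[float, float]], lo: float, hi: float
) -> list[tuple[float, float]]:
    out = []
    for a, b in mask:
        x, y = max(a, lo), min(b, hi)
        if y > x:
            out.append((x, y))
    return out


def simulate_neutral_region(cfg: CoalescentConfig) -> list[SegregatingSite]:
    """Simulate segregating sites for one region under the standard coalescent.

    Returns (pos, k, n) records as SegregatingSite objects with placeholder
    alleles (class OTHER); use :func:`label_mutation_classes` to assign W2S /
    S2W classes.  Conditioning on S places exactly S mutations on the
    genealogy proportionally to branch length and covered span.
    """
    mask = tuple(cfg.mask) if cfg.mask is not None else ((0, cfg.L),)
    covered = sum(b - a for a, b in mask)
    if covered <= 0:
        if cfg.S:
            raise ValueError("empty coverage mask with S > 0")
        return []

    rng = np.random.default_rng(cfg.seed)
    msp_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=cfg.n,
        ploidy=1,
        population_size=1.0,
        sequence_length=cfg.L,
        recombination_rate=cfg.rho / (4.0 * cfg.L) if cfg.rho > 0 else 0.0,
        random_seed=msp_seed,
    )

    weights: list[float] = []
    ks: list[int] = []
    spans: list[list[tuple[float, float]]] = []
    for tree in ts.trees():
        seg = _mask_intersection(mask, tree.interval.left, tree.interval.right)
        span = sum(b - a for a, b in seg)
        if span <= 0:
            continue
        for node in tree.nodes():
            if tree.parent(node) == -1:
                continue
            k = tree.num_samples(node)
            if not 1 <= k <= cfg.n - 1:
                continue
            weights.append(tree.branch_length(node) * span)
            ks.append(k)
            spans.append(seg)
    if not weights:
        raise RuntimeError("genealogy has no branches subtending 1..n-1 samples")

    w = np.asarray(weights)
    p = w / w.sum()
    if cfg.S is not None:
        n_mut = cfg.S
    else:
        n_mut = int(rng.poisson(cfg.theta / 2.0 * w.sum()))
    idx = rng.choice(len(w), size=n_mut, p=p)

    anc, der = _CLASS_ALLELES[OTHER]
    sites = []
    for i in idx:
        seg = spans[i]
        lens = np.array([b - a for a, b in seg])
        j = rng.choice(len(seg), p=lens / lens.sum()) if len(seg) > 1 else 0
        pos = int(rng.uniform(seg[j][0], seg[j][1]))
        sites.append(SegregatingSite(pos=pos, ancestral=anc, derived=der, k=ks[i], n=cfg.n))
    sites.sort(key=lambda s: s.pos)
    return sites


def label_mutation_classes(
    sites: Sequence[SegregatingSite],
    w2s_fraction: float = DEFAULT_W2S_FRACTION,
    seed: int | None = None,
) -> list[SegregatingSite]:
    """Assign W2S / S2W classes to sites by independent Bernoulli trials."""
    if not 0 <= w2s_fraction <= 1:
        raise ValueError("w2s_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(sites)) < w2s_fraction
    out = []
    for site, is_w2s in zip(sites, draws):
        anc, der = _CLASS_ALLELES[W2S if is_w2s else S2W]
        out.append(
            SegregatingSite(pos=site.pos, ancestral=anc, derived=der, k=site.k, n=site.n)
        )
    return out


# ---------------------------------------------------------------------------
# phylogenetic fixed-difference simulator


def hky_rate_matrix(eq_gc: float, kappa: float = 2.0) -> np.ndarray:
    """HKY85 rate matrix (order A,C,G,T) with equilibrium GC content ``eq_gc``
    and transition/transversion rate ratio ``kappa``, normalized to one
    expected substitution per unit branch length."""
    if not 0 < eq_gc < 1:
        raise ValueError("eq_gc must be in (0, 1)")
    pi = np.array([(1 - eq_gc) / 2, eq_gc / 2, eq_gc / 2, (1 - eq_gc) / 2])
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


@dataclass(frozen=True)
class PhyloSimConfig:
    """Substitution simulation on a (human, chimp, outgroup) tree.

    Branch lengths are in expected substitutions per site from the
    human-chimp ancestor; the outgroup branch is the full path from that
    ancestor to the outgroup tip.  A custom reversible ``rate_matrix`` (rows
    summing to zero, order ACGT) overrides the default HKY model.
    """

    eq_gc: float = 0.41
    kappa: float = 2.0
    t_human: float = 0.005
    t_chimp: float = 0.005
    t_outgroup: float = 0.02
    n_fixed_sites: int = 335
    rate_matrix: np.ndarray | None = None
    seed: int | None = None

    def matrix(self) -> np.ndarray:
        if self.rate_matrix is not None:
            Q = np.asarray(self.rate_matrix, dtype=float)
            if Q.shape != (4, 4) or not np.allclose(Q.sum(axis=1), 0, atol=1e-8):
                raise ValueError("rate matrix must be 4x4 with zero row sums")
            if np.any(np.diag(Q) >= 0):
                raise ValueError("degenerate rate matrix: zero diagonal entries")
            return Q
        return hky_rate_matrix(self.eq_gc, self.kappa)

    def stationary(self) -> np.ndarray:
        Q = self.matrix()
        # left null vector of Q
        vals, vecs = np.linalg.eig(Q.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals))])
        pi = v / v.sum()
        if np.any(pi < -1e-9):
            raise ValueError("rate matrix has no valid stationary distribution")
        return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def _sample_children(parent: np.ndarray, T: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    u = rng.random(len(parent))
    return (u[:, None] > cum[parent]).sum(axis=1)


def simulate_fixed_differences(cfg: PhyloSimConfig) -> list[FixedDifference]:
    """Simulate human-chimp fixed differences polarized by an outgroup.

    Alignment columns are drawn at stationarity and evolved down the three
    branches; a column is kept when human and chimp differ and the outgroup
    allele equals exactly one of them (unambiguous ancestral assignment).
    Columns are drawn until ``n_fixed_sites`` are collected.
    """
    if cfg.t_human <= 0 and cfg.t_chimp <= 0:
        raise ValueError("human and chimp branches both zero: no differences can arise")
    Q = cfg.matrix()
    pi = cfg.stationary()
    T_h = expm(Q * cfg.t_human)
    T_c = expm(Q * cfg.t_chimp)
    T_o = expm(Q * cfg.t_outgroup)
    rng = np.random.default_rng(cfg.seed)

    # acceptance rate ~ P(human != chimp); size batches accordingly
    p_diff = max(1e-4, cfg.t_human + cfg.t_chimp)
    batch = max(10_000, int(3 * cfg.n_fixed_sites / p_diff))

    out: list[FixedDifference] = []
    pos = 0
    guard = 0
    while len(out) < cfg.n_fixed_sites:
        guard += 1
        if guard > 1000:
            raise RuntimeError("fixed-difference collection did not converge")
        root = rng.choice(4, size=batch, p=pi)
        h = _sample_children(root, T_h, rng)
        c = _sample_children(root, T_c, rng)
        o = _sample_children(root, T_o, rng)
        keep = (h != c) & ((o == h) | (o == c))
        for hi, ci, oi in zip(h[keep], c[keep], o[keep]):
            out.append(
                FixedDifference(
                    pos=pos,
                    human=_BASES[hi],
                    chimp=_BASES[ci],
                    ancestral=_BASES[oi],
                )
            )
            pos += 1
            if len(out) == cfg.n_fixed_sites:
                break
    return out


# ---------------------------------------------------------------------------
# calibration


def calibrate_test(
    test: str,
    n_reps: int = 2000,
    alpha_grid: Sequence[float] = (0.01, 0.05, 0.10),
    seed: int | None = None,
    n: int = 22,
    S: int = 85,
    n_fixed: int = 335,
    n_seg: int = 101,
    w2s_fraction: float = DEFAULT_W2S_FRACTION,
    phylo_cfg: PhyloSimConfig | None = None,
) -> pd.DataFrame:
    """Empirical p-value calibration of the MWU or MK test under neutrality.

    MWU mode: each replicate is a coalescent region (``n`` chromosomes,
    exactly ``S`` sites) with Bernoulli W2S/S2W labels at ``w2s_fraction``.

    MK mode: each replicate pairs ``n_fixed`` phylogenetically simulated
    fixed differences with ``n_seg`` segregating sites whose class labels are
    Bernoulli draws at the pooled fixed-difference class frequencies across
    *all* replicates, so the null of equal ratios holds exactly.

    Returns a table with columns ``alpha``, ``frac_below`` (fraction of
    replicates with p < alpha) and ``frac_below_w2s`` (subset of that
    fraction with the W2S class favored).
    """
    if test not in ("MWU", "MK"):
        raise ValueError("test must be 'MWU' or 'MK'")
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * n_reps)]

    ps = np.empty(n_reps)
    w2s_dir = np.zeros(n_reps, dtype=bool)

    if test == "MWU":
        for i in range(n_reps):
            cfg = CoalescentConfig(n=n, L=40_000, S=S, seed=child_seeds[2 * i])
            sites = simulate_neutral_region(cfg)
            sites = label_mutation_classes(sites, w2s_fraction, seed=child_seeds[2 * i + 1])
            by = split_by_class(sites)
            res = mwu_test(by[W2S], by[S2W])
            ps[i] = res.p if res.p is not None else 1.0
            w2s_dir[i] = res.offset22 is not None and res.offset22 > 0
    else:
        base = phylo_cfg or PhyloSimConfig()
        fixed_counts = []
        for i in range(n_reps):
            cfg = PhyloSimConfig(
                eq_gc=base.eq_gc, kappa=base.kappa, t_human=base.t_human,
                t_chimp=base.t_chimp, t_outgroup=base.t_outgroup,
                n_fixed_sites=n_fixed, rate_matrix=base.rate_matrix,
                seed=child_seeds[2 * i],
            )
            diffs = simulate_fixed_differences(cfg)
            counts = {W2S: 0, S2W: 0, OTHER: 0}
            for d in diffs:
                counts[d.klass] += 1
            fixed_counts.append(counts)
        pooled = {k: sum(c[k] for c in fixed_counts) for k in (W2S, S2W, OTHER)}
        tot = sum(pooled.values())
        probs = np.array([pooled[W2S], pooled[S2W], pooled[OTHER]]) / tot
        for i in range(n_reps):
            rng = np.random.default_rng(child_seeds[2 * i + 1])
            seg = rng.multinomial(n_seg, probs)
            seg_counts = {W2S: int(seg[0]), S2W: int(seg[1]), OTHER: int(seg[2])}
            res = mk_test(fixed_counts[i], seg_counts)
            ps[i] = res.p if res.p is not None else 1.0
            w2s_dir[i] = res.direction == W2S

    rows = []
    for alpha in alpha_grid:
        below = ps < alpha
        rows.append(
            {
                "alpha": alpha,
                "frac_below": below.mean(),
                "frac_below_w2s": (below & w2s_dir).mean(),
            }
        )
    return pd.DataFrame(rows)
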