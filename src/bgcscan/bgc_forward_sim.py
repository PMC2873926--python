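"""Forward Wright-Fisher simulation of GC-biased gene conversion (BGC).

BGC is modeled as a selection process: each weak-to-strong (W2S) mutation
adds, and each strong-to-weak (S2W) mutation subtracts, a half-normal
fitness deviate on the haplotype where it arises, so strong (G/C) alleles
behave like beneficial mutations of mean population-scaled strength 4NB.
Haplotypes carry a cumulative log-fitness; reproduction is haploid
Wright-Fisher sampling with probability proportional to exp(log-fitness)
(multiplicative/genic selection), with no recombination inside the locus.

Mutations follow the infinite-sites model: each mutation is a new locus
position, labeled W2S or S2W by an independent Bernoulli draw (by default
half each, mirroring the roughly balanced W2S:S2W mutation supply of real
data).  This matters: were classes instead tied to a finite site's current
weak/strong state, compositional stationarity would force the W2S and S2W
fixation fluxes to balance exactly and no divergence-based test could ever
see the bias.  With independent labels, W2S mutations fix at roughly
exp(4NB) times the S2W rate, which is the historical signal the MK test
detects.

Each replicate runs a burn-in from a mutation-free locus to mutation-
selection-drift equilibrium, splits the population in two (a vicariance
event standing in for the human-chimp divergence), evolves both descendant
populations independently, then samples chromosomes from each (by default
50 "human" haplotypes and a single "chimp" haplotype).  Observation is
purely sample-based, as in real data: a mutation carried by 1..49 of the
human samples is a segregating site; one carried by all 50 human samples
but not the chimp chromosome (or by the chimp but no human) is a fixed
difference, classified by its own W2S/S2W label — the simulation analogue
of reliable outgroup polarization.  The MWU and MK fixation-bias tests are
then applied exactly as on real data.

Because the locus does not recombine and sites never back-mutate, the whole
population history is a persistent mutation tree: a haplotype is just a
pointer to its most recent mutation node, reproduction copies pointers, and
a mutation appends one node.  A generation therefore costs O(2N) regardless
of locus length or diversity, and the sampled chromosomes' derived-allele
counts fall out of one bottom-up pass over the tree at the end.  The inner
loop is compiled with numba and uses an inline xorshift128+ generator (RNG
call overhead would otherwise dominate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bias_tests import (
    MKResult,
    MWUResult,
    association_tests,
    mk_test,
    mwu_test,
)
from .sfs_core import S2W, W2S

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        if a and callable(a[0]):
            return a[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "BGCSimConfig",
    "BGCReplicateResult",
    "BGCExperimentSummary",
    "run_bgc_replicate",
    "run_bgc_experiment",
    "single_mutant_fixation_rate",
    "kimura_fixation_probability",
]


@dataclass(frozen=True)
class BGCSimConfig:
    """Parameters of the forward BGC simulation.

    ``scaled_bgc`` is 4NB, the population-scaled mean conversion (disparity)
    strength per mutation.  ``bgc_mut_ratio`` is 4NB : 4Nu with u the
    per-site mutation rate over the notional locus of ``L`` sites, so the
    locus-wide scaled mutation rate is ``L x scaled_bgc / bgc_mut_ratio``;
    the default (L = 2000, ratio = 260) gives a locus theta of 10, sized so
    sampled segregating-site and fixed-difference counts are comparable to a
    resequenced 40 kb region.  ``burnin`` is in multiples of N generations;
    ``split_time`` is the post-split duration per descendant population in
    units of 4N generations.  ``fitness_sd`` overrides the half-normal scale
    of per-mutation effects; by default it is set so the mean scaled effect
    equals ``scaled_bgc``.  ``w2s_mutation_fraction`` is the Bernoulli
    probability that a new mutation is W2S.
    """

    N: int = 10_000
    scaled_bgc: float = 1.3
    bgc_mut_ratio: float = 260.0
    L: int = 2000
    burnin: float = 40.0
    split_time: float = 6.5
    n_human: int = 50
    n_chimp: int = 1
    w2s_mutation_fraction: float = 0.5
    fitness_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be >= 2")
        if self.scaled_bgc < 0:
            raise ValueError("scaled_bgc (4NB) must be >= 0")
        if self.bgc_mut_ratio <= 0:
            raise ValueError("bgc_mut_ratio must be > 0")
        if self.split_time <= 0:
            raise ValueError("split_time must be > 0")
        if not 0 <= self.w2s_mutation_fraction <= 1:
            raise ValueError("w2s_mutation_fraction must be in [0, 1]")
        if self.n_human + self.n_chimp > 2 * self.N:
            raise ValueError("cannot sample more haplotypes than the population holds")

    @property
    def mean_effect(self) -> float:
        """Per-mutation mean fitness effect B = scaled_bgc / 4N."""
        return self.scaled_bgc / (4.0 * self.N)

    @property
    def effect_sd(self) -> float:
        """Half-normal scale sigma with E|N(0, sigma)| = B."""
        if self.fitness_sd is not None:
            return self.fitness_sd
        return self.mean_effect * math.sqrt(math.pi / 2.0)

    @property
    def theta_site(self) -> float:
        """Per-site scaled mutation rate 4Nu.

        Defined through bgc_mut_ratio at the reference strength 4NB = 1.3 so
        that a neutral run (scaled_bgc = 0) keeps the same mutation supply
        as the default biased run.
        """
        ref = self.scaled_bgc if self.scaled_bgc > 0 else 1.3
        return ref / self.bgc_mut_ratio

    @property
    def theta_locus(self) -> float:
        return self.theta_site * self.L

    @property
    def mutations_per_generation(self) -> float:
        # 2N haplotypes x L sites x u = theta_locus / 2
        return self.theta_locus / 2.0

    @property
    def generations(self) -> tuple[int, int]:
        """(burn-in generations, post-split generations per lineage)."""
        return int(round(self.burnin * self.N)), int(round(self.split_time * 4 * self.N))


@dataclass(frozen=True)
class BGCReplicateResult:
    mwu: MWUResult
    mk: MKResult
    segregating_counts: dict[str, int]
    fixed_counts: dict[str, int]
    gc_content: float  # 0.5 + net strong substitutions on the human side / 2L


@dataclass(frozen=True)
class BGCExperimentSummary:
    n_reps: int
    mwu_sig_w2s: int
    mwu_sig_s2w: int
    mk_sig_w2s: int
    mk_sig_s2w: int
    union_w2s: int
    intersection_w2s: int
    association: object
    replicates: tuple[BGCReplicateResult, ...] = field(repr=False, default=())


_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _xs_next(st):  # pragma: no cover - numba
    """xorshift128+ step; st is a 2-element uint64 state array."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << _U64(23)
    st[1] = s1 ^ s0 ^ (s1 >> _U64(18)) ^ (s0 >> _U64(5))
    return st[1] + s0


@njit(cache=True, inline="always")
def _xs_uniform(st):  # pragma: no cover - numba
    return float(_xs_next(st) >> _U64(11)) * _INV_2_53


@njit(cache=True)
def _xs_state(seed):  # pragma: no cover - numba
    """Initialize xorshift state from a seed via splitmix64."""
    st = np.empty(2, dtype=np.uint64)
    z = _U64(seed)
    for i in range(2):
        z = z + _U64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> _U64(27))) * _U64(0x94D049BB133111EB)
        st[i] = t ^ (t >> _U64(31))
    return st


@njit(cache=True)
def _evolve(hap_node, logf, node_parent, node_sign, n_nodes, n_gens,
            mu_pop, sigma, w2s_frac, selection, seed):  # pragma: no cover
    """Advance one population ``n_gens`` generations in place.

    ``hap_node[i]`` is haplotype i's most recent mutation node (-1 for a
    mutation-free chromosome); ``node_parent``/``node_sign`` form the shared
    mutation-tree arena (sign +1 W2S / -1 S2W).  ``logf`` is the cumulative
    log-fitness per haplotype; weights w = exp(logf) are maintained
    incrementally (inheritance permutes them, mutations rescale one entry)
    and parent sampling is exact multinomial by rejection against the
    maximum weight (per-mutation effects are tiny, so acceptance is ~1).

    Returns the new number of arena nodes, or -1 on arena overflow.
    """
    two_n = hap_node.shape[0]
    cap_nodes = node_parent.shape[0]
    st = _xs_state(seed)
    hn_a = hap_node
    hn_b = np.empty_like(hap_node)
    lf_a = logf
    lf_b = np.empty_like(logf)
    w_a = np.empty(two_n)
    w_b = np.empty(two_n)
    wmax = 0.0
    mut_thresh = math.exp(-mu_pop)
    for g in range(n_gens):
        if g % 8192 == 0:  # refresh weights against float drift
            m = lf_a[0]
            for i in range(1, two_n):
                if lf_a[i] > m:
                    m = lf_a[i]
            for i in range(two_n):
                w_a[i] = math.exp(lf_a[i] - m)
            wmax = 1.0
        # --- reproduction: one uniform per attempt; integer part indexes
        # the candidate parent, fractional part is the acceptance draw
        if selection:
            for i in range(two_n):
                while True:
                    u = _xs_uniform(st) * two_n
                    j = int(u)
                    if (u - j) * wmax <= w_a[j]:
                        break
                hn_b[i] = hn_a[j]
                lf_b[i] = lf_a[j]
                w_b[i] = w_a[j]
        else:
            for i in range(two_n):
                j = int(_xs_uniform(st) * two_n)
                hn_b[i] = hn_a[j]
                lf_b[i] = lf_a[j]
                w_b[i] = w_a[j]
        hn_a, hn_b = hn_b, hn_a
        lf_a, lf_b = lf_b, lf_a
        w_a, w_b = w_b, w_a

        # --- mutation: Poisson count via product-of-uniforms inversion
        n_mut = 0
        prod = _xs_uniform(st)
        while prod > mut_thresh:
            n_mut += 1
            prod *= _xs_uniform(st)
        for _ in range(n_mut):
            if n_nodes >= cap_nodes:
                return -1
            r = int(_xs_uniform(st) * two_n)
            sign = 1 if _xs_uniform(st) < w2s_frac else -1
            if sigma > 0.0:
                u1 = 1.0 - _xs_uniform(st)
                u2 = _xs_uniform(st)
                e = abs(
                    sigma * math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
                )
            else:
                e = 0.0
            node_parent[n_nodes] = hn_a[r]
            node_sign[n_nodes] = sign
            hn_a[r] = n_nodes
            n_nodes += 1
            eff = sign * e
            lf_a[r] += eff
            w_a[r] *= math.exp(eff)
            if w_a[r] > wmax:
                wmax = w_a[r]

    # final state must live in the caller's arrays
    if n_gens % 2 == 1:
        hap_node[:] = hn_a
        logf[:] = lf_a
    return n_nodes


@njit(cache=True)
def _sample_counts(sample_nodes, node_parent, n_nodes):  # pragma: no cover
    """Carrier count of every mutation node among the sampled chromosomes:
    seed the sampled tips, then one bottom-up pass (children have larger
    ids than their parents by construction)."""
    counts = np.zeros(n_nodes, dtype=np.int32)
    for v in sample_nodes:
        if v >= 0:
            counts[v] += 1
    for v in range(n_nodes - 1, -1, -1):
        if counts[v] > 0 and node_parent[v] >= 0:
            counts[node_parent[v]] += counts[v]
    return counts


class _MutationArena:
    """Shared append-only mutation tree for one replicate."""

    def __init__(self, capacity: int):
        self.node_parent = np.empty(capacity, dtype=np.int32)
        self.node_sign = np.empty(capacity, dtype=np.int8)
        self.n_nodes = 0


class _Population:
    """Haplotype pointers + fitness for one lineage."""

    def __init__(self, two_n: int):
        self.hap_node = np.full(two_n, -1, dtype=np.int32)
        self.logf = np.zeros(two_n)

    def copy(self) -> "_Population":
        other = object.__new__(_Population)
        other.hap_node = self.hap_node.copy()
        other.logf = self.logf.copy()
        return other

    def evolve(self, n_gens: int, cfg: BGCSimConfig, arena: _MutationArena,
               seed: int) -> None:
        sigma = cfg.effect_sd if cfg.scaled_bgc > 0 else 0.0
        n_nodes = _evolve(
            self.hap_node, self.logf, arena.node_parent, arena.node_sign,
            arena.n_nodes, n_gens, cfg.mutations_per_generation, sigma,
            cfg.w2s_mutation_fraction, cfg.scaled_bgc > 0, seed,
        )
        if n_nodes < 0:
            raise MemoryError("mutation arena exhausted; reduce run length or theta")
        arena.n_nodes = int(n_nodes)


_SIGN_KLASS = {1: W2S, -1: S2W}


def run_bgc_replicate(cfg: BGCSimConfig) -> BGCReplicateResult:
    """Run one burn-in + split + sampling replicate and apply both tests."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(1, 2**31 - 1, size=4)
    two_n = 2 * cfg.N
    n_burn, n_split = cfg.generations

    total_gens = n_burn + 2 * n_split
    capacity = int(3 * cfg.mutations_per_generation * total_gens) + 65_536
    arena = _MutationArena(capacity)

    pop = _Population(two_n)
    pop.evolve(n_burn, cfg, arena, int(seeds[0]))

    human_pop = pop
    chimp_pop = pop.copy()
    human_pop.evolve(n_split, cfg, arena, int(seeds[1]))
    chimp_pop.evolve(n_split, cfg, arena, int(seeds[2]))

    sample_rng = np.random.default_rng(int(seeds[3]))
    h_idx = sample_rng.choice(two_n, size=cfg.n_human, replace=False)
    c_idx = sample_rng.choice(two_n, size=cfg.n_chimp, replace=False)
    n = cfg.n_human

    k_h = _sample_counts(human_pop.hap_node[h_idx], arena.node_parent, arena.n_nodes)
    k_c = _sample_counts(chimp_pop.hap_node[c_idx], arena.node_parent, arena.n_nodes)

    seg_daf = {W2S: [], S2W: []}
    seg_counts = {W2S: 0, S2W: 0}
    fixed_counts = {W2S: 0, S2W: 0}
    net_human = 0
    for v in np.flatnonzero((k_h > 0) | (k_c > 0)):
        k = int(k_h[v])
        c = int(k_c[v])
        klass = _SIGN_KLASS[int(arena.node_sign[v])]
        if 1 <= k <= n - 1:
            seg_counts[klass] += 1
            seg_daf[klass].append(k / n)
        elif k == n and c == 0:  # substitution on the human side
            fixed_counts[klass] += 1
            net_human += int(arena.node_sign[v])
        elif k == 0 and c > 0:  # substitution on the chimp side
            fixed_counts[klass] += 1
        # k == n and c > 0: shared by both lineages, not a difference

    mwu = mwu_test(seg_daf[W2S], seg_daf[S2W])
    mk = mk_test(dict(fixed_counts), dict(seg_counts))
    return BGCReplicateResult(
        mwu=mwu,
        mk=mk,
        segregating_counts=seg_counts,
        fixed_counts=fixed_counts,
        gc_content=0.5 + net_human / (2.0 * cfg.L),
    )


def run_bgc_experiment(
    cfg: BGCSimConfig,
    n_reps: int,
    alpha: float = 0.05,
    keep_replicates: bool = False,
) -> BGCExperimentSummary:
    """Run many replicates and tally significance by test and direction.

    The union and intersection are over the sets of replicates significant
    *with W2S direction* on each test; the association statistics
    cross-tabulate W2S-significance of the two tests.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]
    reps = [run_bgc_replicate(replace(cfg, seed=s)) for s in seeds]

    def sig(p, direction, want):
        return p is not None and p < alpha and direction == want

    mwu_w = np.array([sig(r.mwu.p, r.mwu.direction, W2S) for r in reps])
    mwu_s = np.array([sig(r.mwu.p, r.mwu.direction, S2W) for r in reps])
    mk_w = np.array([sig(r.mk.p, r.mk.direction, W2S) for r in reps])
    mk_s = np.array([sig(r.mk.p, r.mk.direction, S2W) for r in reps])

    assoc = association_tests(list(mwu_w), list(mk_w))
    return BGCExperimentSummary(
        n_reps=n_reps,
        mwu_sig_w2s=int(mwu_w.sum()),
        mwu_sig_s2w=int(mwu_s.sum()),
        mk_sig_w2s=int(mk_w.sum()),
        mk_sig_s2w=int(mk_s.sum()),
        union_w2s=int((mwu_w | mk_w).sum()),
        intersection_w2s=int((mwu_w & mk_w).sum()),
        association=assoc,
        replicates=tuple(reps) if keep_replicates else (),
    )


# ---------------------------------------------------------------------------
# single-locus fixation check


def kimura_fixation_probability(N: int, s: float, p0: float | None = None) -> float:
    """Diffusion fixation probability under genic selection: for a single
    mutant copy, (1 - exp(-2s)) / (1 - exp(-4Ns))."""
    if p0 is None:
        p0 = 1.0 / (2 * N)
    if s == 0:
        return p0
    return float(-math.expm1(-4 * N * s * p0) / -math.expm1(-4 * N * s))


def single_mutant_fixation_rate(
    N: int,
    s: float,
    n_trials: int = 20_000,
    seed: int | None = None,
) -> float:
    """Empirical fixation fraction of a single favored mutant copy.

    Simulates allele-count Wright-Fisher trajectories with relative fitness
    1 + s for the mutant allele (genic selection), starting from one copy in
    2N, vectorized across trials.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    x = np.ones(n_trials, dtype=np.int64)
    active = np.ones(n_trials, dtype=bool)
    fixed = 0
    while active.any():
        xa = x[active]
        p = xa * (1.0 + s) / (two_n + xa * s)
        xa = rng.binomial(two_n, p)
        lost = xa == 0
        fx = xa == two_n
        fixed += int(fx.sum())
        idx = np.flatnonzero(active)
        x[idx] = xa
        active[idx[lost | fx]] = False
    return fixed / n_trials
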