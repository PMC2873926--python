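"""Composite-likelihood-ratio (CLR) scan for completed selective sweeps.

The scan compares, at each point of a grid across a region, a model in which
a selective sweep has just completed at that point against a null in which
derived-allele frequencies follow an arbitrary *background* site frequency
spectrum.  The sweep model uses the star-genealogy approximation: each of
the n sampled lineages at a site a physical distance d from the sweep point
escapes the sweep independently with probability

    p_e = 1 - exp(-alpha * d),

where the intensity parameter alpha absorbs the recombination rate and the
sweep's strength/duration.  Lineages that fail to escape coalesce through
the sweep into a single ancestral lineage, so with b escaped lineages the
site's ancestry is a draw of b + 1 lineages against the background spectrum,
with the swept lineage then expanded to n - b sample copies.  Mixing over
b ~ Binomial(n, p_e) and conditioning on a polymorphic outcome gives the
sweep-model probability of each derived-allele count; the composite
likelihood is the product over sites, and

    CLR(x) = 2 [ max_alpha log CL_sweep(x, alpha) - log CL_background ].

As alpha -> infinity every lineage escapes and the sweep model collapses to
the background, so CLR >= 0 with equality when the data look neutral.
P-values come from rescanning neutral coalescent replicates conditioned on
the observed number of segregating sites, the region's coverage mask, and
its recombination rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .neutral_sim import CoalescentConfig, simulate_neutral_region
from .sfs_core import (
    DerivedAlleleSpectrum,
    Region,
    SegregatingSite,
    build_spectrum,
    projection_matrix,
)

__all__ = [
    "BackgroundSFS",
    "CLRScan",
    "estimate_background",
    "clr_scan",
    "sweep_pvalue",
    "simulate_sweep_sites",
]

DEFAULT_GRID_SIZE = 1000
_ALPHA_GRID_POINTS = 16
_LOG_PROB_FLOOR = -745.0  # log of smallest positive double


@dataclass(frozen=True)
class BackgroundSFS:
    """A normalized background spectrum over derived counts 1..n-1."""

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.n - 1,):
            raise ValueError(f"probs must have length n-1={self.n - 1}")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("background spectrum must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p / p.sum())

    @classmethod
    def from_spectrum(cls, spec: DerivedAlleleSpectrum) -> "BackgroundSFS":
        return cls(n=spec.n, probs=spec.counts / spec.total())

    def project(self, m: int) -> "BackgroundSFS":
        if m == self.n:
            return self
        w = self.probs @ projection_matrix(self.n, m)
        return BackgroundSFS(n=m, probs=w / w.sum())


@dataclass
class CLRScan:
    """Grid of CLR values across one region."""

    grid: np.ndarray
    clr: np.ndarray
    alpha_hat: np.ndarray
    p: float | None = None
    null_max_clrs: np.ndarray | None = field(default=None, repr=False)

    @property
    def max_clr(self) -> float:
        return float(self.clr.max())

    @property
    def argmax_pos(self) -> float:
        # ties broken toward the leftmost grid point
        return float(self.grid[int(np.argmax(self.clr))])


def estimate_background(
    sites: Sequence[SegregatingSite], n_target: int
) -> BackgroundSFS:
    """Aggregate derived-allele frequencies from many regions into a
    normalized background spectrum at sample size ``n_target``.

    Sites at larger sample sizes are projected down hypergeometrically;
    sites at smaller sizes are excluded with a warning.
    """
    usable = [s for s in sites if s.n >= n_target]
    if len(usable) < len(sites):
        warnings.warn(
            f"excluded {len(sites) - len(usable)} sites with n < {n_target} "
            "from the background spectrum"
        )
    if not usable:
        raise ValueError("no sites available for the background spectrum")
    spec = build_spectrum(usable, n_target, renormalize_projection=False)
    return BackgroundSFS.from_spectrum(spec)


# ---------------------------------------------------------------------------
# sweep model internals


def _sweep_class_matrix(bg: BackgroundSFS) -> np.ndarray:
    """Q[b, k]: P(derived count k in the sample | b lineages escaped), for
    b = 0..n and k = 0..n, before conditioning on polymorphism.

    With b < n escaped lineages the ancestry is b + 1 background lineages
    (the +1 is the swept class); drawing j derived among those m = b + 1 is
    the hypergeometric projection of the background.  The swept lineage is
    derived with probability j / m, in which case its n - b descendant
    copies are all derived.
    """
    n = bg.n
    Q = np.zeros((n + 1, n + 1))
    for b in range(n):
        m = b + 1
        # projection of background classes 1..n-1 to counts 0..m of m
        proj = projection_matrix(n, m, include_monomorphic=True) if m >= 2 else None
        if m == 1:
            # one lineage: derived with probability sum_i bg_i * i / n
            p_der = float(np.sum(bg.probs * np.arange(1, n) / n))
            p_jm = np.array([1.0 - p_der, p_der])
        else:
            p_jm = bg.probs @ proj
        for j in range(m + 1):
            w = p_jm[j]
            if w == 0:
                continue
            # swept lineage derived: K = (n - b) + (j - 1)
            if j > 0:
                Q[b, (n - b) + (j - 1)] += w * (j / m)
            # swept lineage ancestral: K = j
            Q[b, j] += w * ((m - j) / m)
    Q[n, 1:n] = bg.probs  # all lineages escape: background itself
    return Q


class _SweepLikelihood:
    """Composite log-likelihood of site derived counts under the sweep model,
    vectorized over sites for a fixed grid point."""

    def __init__(self, bg: BackgroundSFS, ks: np.ndarray):
        self.n = bg.n
        self.Q = _sweep_class_matrix(bg)
        self.ks = ks
        b = np.arange(self.n + 1)
        self.b = b
        self.log_binom = gammaln(self.n + 1) - gammaln(b + 1) - gammaln(self.n - b + 1)
        # floor empty background classes: a simulated site can land on a
        # frequency class the empirical background never observed
        self.null_loglik = float(np.sum(np.log(np.clip(bg.probs[ks - 1], 1e-300, None))))

    def loglik(self, alpha: float, d: np.ndarray) -> float:
        pe = -np.expm1(-alpha * d)  # escape probability per lineage
        pe = np.clip(pe, 1e-300, 1.0)
        qe = np.clip(1.0 - pe, 1e-300, 1.0)
        logw = (
            self.log_binom[None, :]
            + self.b[None, :] * np.log(pe)[:, None]
            + (self.n - self.b)[None, :] * np.log(qe)[:, None]
        )
        W = np.exp(logw - logw.max(axis=1, keepdims=True))
        W /= W.sum(axis=1, keepdims=True)
        M = W @ self.Q  # (sites, n+1)
        poly_mass = 1.0 - M[:, 0] - M[:, self.n]
        pk = M[np.arange(len(self.ks)), self.ks]
        with np.errstate(divide="ignore"):
            ll = np.log(pk) - np.log(np.clip(poly_mass, 1e-300, None))
        ll[~np.isfinite(ll)] = _LOG_PROB_FLOOR
        return float(ll.sum())


def clr_scan(
    sites: Sequence[SegregatingSite],
    region: Region,
    background: BackgroundSFS,
    grid_size: int = DEFAULT_GRID_SIZE,
    refine: bool = True,
) -> CLRScan:
    """Scan a region for a completed sweep against a background spectrum.

    The grid has ``grid_size`` evenly spaced points including both region
    endpoints.  At each point alpha is maximized over a log-spaced grid with
    optional bounded scalar refinement around the best grid value.
    """
    if not sites:
        raise ValueError("need at least one segregating site")
    ns = {s.n for s in sites}
    if len(ns) != 1:
        raise ValueError("all sites must share one sample size; project first")
    n = ns.pop()
    if background.n < n:
        raise ValueError(
            f"background (n={background.n}) smaller than data sample size {n}"
        )
    bg = background.project(n)

    ks = np.array([s.k for s in sites])
    pos = np.array([s.pos for s in sites], dtype=float)
    lik = _SweepLikelihood(bg, ks)

    grid = np.linspace(region.start, region.end, grid_size)
    span = float(region.length)
    alphas = np.logspace(np.log10(1e-2 / span), np.log10(1e3 / span), _ALPHA_GRID_POINTS)

    clr = np.zeros(grid_size)
    a_hat = np.zeros(grid_size)
    for gi, x in enumerate(grid):
        d = np.abs(pos - x)
        lls = np.array([lik.loglik(a, d) for a in alphas])
        best = int(np.argmax(lls))
        best_ll, best_a = lls[best], alphas[best]
        if refine:
            lo = alphas[max(best - 1, 0)]
            hi = alphas[min(best + 1, len(alphas) - 1)]
            if hi > lo:
                res = minimize_scalar(
                    lambda la: -lik.loglik(np.exp(la), d),
                    bounds=(np.log(lo), np.log(hi)),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                if -res.fun > best_ll:
                    best_ll, best_a = -res.fun, float(np.exp(res.x))
        clr[gi] = max(2.0 * (best_ll - lik.null_loglik), 0.0)
        a_hat[gi] = best_a
    return CLRScan(grid=grid, clr=clr, alpha_hat=a_hat)


def sweep_pvalue(
    scan: CLRScan,
    region: Region,
    background: BackgroundSFS,
    observed_S: int,
    n: int,
    rho: float = 0.0,
    mask: tuple[tuple[int, int], ...] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    grid_size: int | None = None,
    refine: bool = True,
) -> CLRScan:
    """Simulation p-value for a scan's maximum CLR.

    Neutral coalescent replicates are generated conditional on the observed
    segregating-site count, the region's coverage mask and its recombination
    rate, each rescanned with the same background; the p-value is the
    fraction of replicates whose maximum CLR is >= the observed maximum.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    if grid_size is None:
        grid_size = len(scan.grid)
    local_mask = mask
    if local_mask is None and region.covered:
        local_mask = tuple((a - region.start, b - region.start) for a, b in region.covered)

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]
    null_region = Region(id=region.id, chrom=region.chrom, start=0, end=region.length)

    obs_max = scan.max_clr
    null_max = np.empty(n_reps)
    for i in range(n_reps):
        cfg = CoalescentConfig(
            n=n, L=region.length, S=observed_S, rho=rho, mask=local_mask, seed=seeds[i]
        )
        rep_sites = simulate_neutral_region(cfg)
        rep_scan = clr_scan(rep_sites, null_region, background,
                            grid_size=grid_size, refine=refine)
        null_max[i] = rep_scan.max_clr
    p = float(np.mean(null_max >= obs_max))
    return CLRScan(
        grid=scan.grid, clr=scan.clr, alpha_hat=scan.alpha_hat, p=p,
        null_max_clrs=null_max,
    )


def simulate_sweep_sites(
    background: BackgroundSFS,
    region: Region,
    sweep_pos: float,
    alpha: float,
    S: int,
    seed: int | None = None,
) -> list[SegregatingSite]:
    """Positive-control generator: draw S polymorphic sites from the sweep
    model itself (sweep at ``sweep_pos`` with intensity ``alpha``)."""
    rng = np.random.default_rng(seed)
    n = background.n
    lik_Q = _sweep_class_matrix(background)
    b = np.arange(n + 1)
    sites = []
    while len(sites) < S:
        pos = rng.uniform(region.start, region.end)
        d = abs(pos - sweep_pos)
        pe = -np.expm1(-alpha * d)
        w = np.exp(
            gammaln(n + 1) - gammaln(b + 1) - gammaln(n - b + 1)
            + b * np.log(max(pe, 1e-300))
            + (n - b) * np.log(max(1 - pe, 1e-300))
        )
        w /= w.sum()
        probs = w @ lik_Q
        poly = probs[1:n].sum()
        if poly <= 0:
            continue
        k = int(rng.choice(np.arange(1, n), p=probs[1:n] / poly))
        sites.append(
            SegregatingSite(pos=int(pos), ancestral="A", derived="T", k=k, n=n)
        )
    sites.sort(key=lambda s: s.pos)
    return sites
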