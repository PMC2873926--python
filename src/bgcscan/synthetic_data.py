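"""Synthetic study generator.

Emulates the statistical shape of a targeted-resequencing fixation-bias
study — a set of 40 kb target regions and a smaller set of control regions,
each with a partial probe-coverage mask, ~100 segregating sites genotyped in
22 chromosomes, ~335 human/chimp fixed differences, and a roughly balanced
W2S:S2W mutation composition — so every analysis module can be exercised
without any external data.

Segregating sites come from the neutral coalescent simulator; fixed
differences from the phylogenetic substitution simulator.  A template can
mark regions as biased, which injects a W2S frequency shift into their
segregating sites (an MWU positive control) and/or relabels part of their
S2W fixed differences as W2S (an MK positive control).  Generation is fully
deterministic given the template seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import io as bio
from .neutral_sim import (
    CoalescentConfig,
    PhyloSimConfig,
    simulate_fixed_differences,
    simulate_neutral_region,
)
from .sfs_core import (
    S2W,
    W2S,
    DerivedAlleleSpectrum,
    FixedDifference,
    Region,
    SegregatingSite,
    build_spectrum,
)

__all__ = [
    "RegionBias",
    "StudyTemplate",
    "StudyData",
    "generate_study",
    "inject_w2s_shift",
    "default_template",
    "biased_template",
]


@dataclass(frozen=True)
class RegionBias:
    """Per-region bias knobs: a W2S derived-frequency shift in [0, 1) and a
    probability of relabeling each S2W fixed difference as W2S."""

    w2s_shift: float = 0.0
    fixed_w2s_enrichment: float = 0.0


@dataclass(frozen=True)
class StudyTemplate:
    """Shape parameters of the emulated study."""

    n_target_regions: int = 49
    n_control_regions: int = 13
    region_length: int = 40_000
    n_chromosomes: int = 22
    mean_segregating: float = 101.0
    mean_fixed: float = 335.0
    w2s_seg_ratio: tuple[int, int] = (2057, 2114)
    classifiable_fraction: float = 85.0 / 101.0  # W2S+S2W share of segregating sites
    coverage_lo: float = 0.65
    coverage_hi: float = 0.98
    bias: Mapping[str, RegionBias] = field(default_factory=dict)
    allow_filter_violations: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_target_regions < 1 or self.n_control_regions < 0:
            raise ValueError("region counts must be positive")
        if not 0 < self.coverage_lo <= self.coverage_hi <= 1:
            raise ValueError("coverage fractions must satisfy 0 < lo <= hi <= 1")

    @property
    def w2s_fraction(self) -> float:
        w, s = self.w2s_seg_ratio
        return w / (w + s)


@dataclass
class StudyData:
    regions: list[Region]
    sites: dict[str, list[SegregatingSite]]
    fixed: dict[str, list[FixedDifference]]
    background: DerivedAlleleSpectrum

    @property
    def target_ids(self) -> list[str]:
        return [r.id for r in self.regions if r.id.startswith("target")]

    @property
    def control_ids(self) -> list[str]:
        return [r.id for r in self.regions if r.id.startswith("control")]


def default_template(seed: int | None = None) -> StudyTemplate:
    return StudyTemplate(seed=seed)


def biased_template(
    seed: int | None = None,
    n_biased: int = 10,
    w2s_shift: float = 0.25,
    fixed_w2s_enrichment: float = 0.5,
) -> StudyTemplate:
    """Template whose first ``n_biased`` target regions carry strong W2S
    bias in both segregating frequencies and fixed differences."""
    bias = {
        f"target{i + 1:02d}": RegionBias(w2s_shift, fixed_w2s_enrichment)
        for i in range(n_biased)
    }
    return StudyTemplate(bias=bias, seed=seed)


def _coverage_mask(
    rng: np.random.Generator, length: int, fraction: float,
    mean_covered_run: float = 2000.0,
) -> tuple[tuple[int, int], ...]:
    """Alternating covered/uncovered geometric runs hitting the coverage
    fraction in expectation."""
    if fraction >= 1.0:
        return ()
    mean_gap = mean_covered_run * (1 - fraction) / fraction
    intervals = []
    pos = 0
    covered_first = rng.random() < fraction
    covered = covered_first
    while pos < length:
        mean_run = mean_covered_run if covered else mean_gap
        run = int(rng.geometric(1.0 / mean_run))
        end = min(pos + run, length)
        if covered and end > pos:
            intervals.append((pos, end))
        pos = end
        covered = not covered
    return tuple(intervals)


def inject_w2s_shift(
    sites: Sequence[SegregatingSite], shift: float, seed: int | None = None
) -> list[SegregatingSite]:
    """Shift W2S site frequencies stochastically upward; S2W/OTHER untouched.

    Each W2S site's derived count moves up by a binomial number of steps
    whose success probability is scaled so the expected derived-allele-
    frequency increase is ``shift`` (saturating near the top of the
    spectrum).  shift = 0 leaves the data unchanged; the shifted W2S
    frequencies are stochastically larger than the originals.
    """
    if not 0 <= shift < 1:
        raise ValueError("shift must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for s in sites:
        if s.klass == W2S and shift > 0:
            room = s.n - 1 - s.k
            q = min(1.0, shift * s.n / room) if room > 0 else 0.0
            k = s.k + int(rng.binomial(room, q))
            out.append(
                SegregatingSite(pos=s.pos, ancestral=s.ancestral, derived=s.derived,
                                k=k, n=s.n)
            )
        else:
            out.append(s)
    return out


_CLASS_ALLELES = {W2S: ("A", "G"), S2W: ("G", "A"), "OTHER": ("A", "T")}


def _label_three_way(
    sites: Sequence[SegregatingSite],
    w2s_fraction: float,
    classifiable_fraction: float,
    rng: np.random.Generator,
) -> list[SegregatingSite]:
    """Assign W2S / S2W / OTHER labels: an OTHER share of
    1 - classifiable_fraction, the rest split at w2s_fraction."""
    probs = np.array([
        classifiable_fraction * w2s_fraction,
        classifiable_fraction * (1 - w2s_fraction),
        1 - classifiable_fraction,
    ])
    labels = rng.choice(3, size=len(sites), p=probs)
    out = []
    for s, lab in zip(sites, labels):
        anc, der = _CLASS_ALLELES[(W2S, S2W, "OTHER")[lab]]
        out.append(SegregatingSite(pos=s.pos, ancestral=anc, derived=der, k=s.k, n=s.n))
    return out


def generate_study(template: StudyTemplate, out_dir: str | None = None) -> StudyData:
    """Generate a full synthetic study; optionally write the standard files.

    When ``out_dir`` is given, writes regions.bed, covered.bed, sites.tsv,
    fixed.tsv and background.sfs in the package's dialects.
    """
    rng = np.random.default_rng(template.seed)
    names = [f"target{i + 1:02d}" for i in range(template.n_target_regions)]
    names += [f"control{i + 1:02d}" for i in range(template.n_control_regions)]

    regions: list[Region] = []
    sites: dict[str, list[SegregatingSite]] = {}
    fixed: dict[str, list[FixedDifference]] = {}

    for idx, name in enumerate(names):
        # coverage fraction in (lo, hi), median near the study's 0.88
        frac = template.coverage_lo + (template.coverage_hi - template.coverage_lo) * float(
            rng.beta(2.2, 1.0)
        )
        mask = _coverage_mask(rng, template.region_length, frac)
        start = 0
        region = Region(
            id=name, chrom=f"chr{idx + 1}", start=start,
            end=start + template.region_length, covered=mask,
        )
        regions.append(region)
        bias = template.bias.get(name, RegionBias())

        S = int(rng.poisson(template.mean_segregating))
        cfg = CoalescentConfig(
            n=template.n_chromosomes, L=template.region_length, S=S,
            mask=mask if mask else None, seed=int(rng.integers(1, 2**31 - 1)),
        )
        reg_sites = simulate_neutral_region(cfg)
        reg_sites = _label_three_way(
            reg_sites, template.w2s_fraction, template.classifiable_fraction, rng
        )
        if bias.w2s_shift > 0:
            reg_sites = inject_w2s_shift(
                reg_sites, bias.w2s_shift, seed=int(rng.integers(1, 2**31 - 1))
            )
        sites[name] = reg_sites

        n_fixed = int(rng.poisson(template.mean_fixed))
        diffs = simulate_fixed_differences(
            PhyloSimConfig(n_fixed_sites=n_fixed, seed=int(rng.integers(1, 2**31 - 1)))
        )
        # scatter fixed differences over the covered intervals
        intervals = region.mask
        lens = np.array([b - a for a, b in intervals], dtype=float)
        placed: list[FixedDifference] = []
        for d in diffs:
            j = rng.choice(len(intervals), p=lens / lens.sum())
            pos = int(rng.uniform(intervals[j][0], intervals[j][1]))
            klass = d.klass
            human, chimp, anc = d.human, d.chimp, d.ancestral
            if klass == S2W and rng.random() < bias.fixed_w2s_enrichment:
                # relabel as W2S by swapping to the mirrored substitution
                anc2, der2 = _CLASS_ALLELES[W2S]
                human, chimp, anc = (
                    (der2, anc2, anc2) if d.lineage == "human" else (anc2, der2, anc2)
                )
            placed.append(FixedDifference(pos=pos, human=human, chimp=chimp, ancestral=anc))
        fixed[name] = placed

    all_sites = [s for name in names for s in sites[name]]
    background = build_spectrum(all_sites, template.n_chromosomes)

    data = StudyData(regions=regions, sites=sites, fixed=fixed, background=background)
    if out_dir is not None:
        bio.ensure_dir(out_dir)
        chrom_by_region = {r.id: r.chrom for r in regions}
        bio.write_regions(
            regions,
            os.path.join(out_dir, "regions.bed"),
            os.path.join(out_dir, "covered.bed"),
        )
        bio.write_sites(sites, os.path.join(out_dir, "sites.tsv"), chrom_by_region)
        bio.write_fixed_differences(
            fixed, os.path.join(out_dir, "fixed.tsv"), chrom_by_region
        )
        bio.write_spectrum(background, os.path.join(out_dir, "background.sfs"))
    return data
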