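"""End-to-end analysis pipeline.

Runs the full fixation-bias analysis on tables in the package's file
dialects: per-region MWU and MK tests, optional masking scans, pooled tests,
MWU x MK association statistics, optional CLR sweep scans with simulation
p-values, and the detectable-sweeps estimate.  Every output table carries a
provenance header (package version, seed, config hash) and all numbers are
plain re-runs of the underlying module functions — the pipeline adds no
computation of its own.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import io as bio
from .bias_tests import (
    CENTRAL_MASK_WIDTHS,
    association_tests,
    estimate_detectable_sweeps,
    mask_scan,
    mk_test,
    mwu_test,
    pooled_mk,
    pooled_mwu,
    split_by_class,
)
from .sfs_core import S2W, W2S, summary_stats
from .sweep_scan import clr_scan, estimate_background, sweep_pvalue

logger = logging.getLogger("bgcscan")

NA = "NA"


@dataclass(frozen=True)
class RunConfig:
    regions_bed: str
    sites_tsv: str
    fixed_tsv: str | None = None
    covered_bed: str | None = None
    background_sfs: str | None = None
    out_dir: str = "bgcscan_out"
    alpha: float = 0.05
    bonferroni: bool = False
    mask_scans: bool = True
    pooled: bool = True
    sweeps: bool = False
    sweep_grid: int = 1000
    sweep_reps: int = 200
    sweep_rho: float = 0.0
    annotations_tsv: str | None = None  # echoed columns (e.g. recomb rates)
    seed: int = 0

    _PATH_FIELDS = frozenset({
        "regions_bed", "sites_tsv", "fixed_tsv", "covered_bed",
        "background_sfs", "annotations_tsv", "out_dir",
    })

    def digest(self) -> str:
        # hash analysis parameters only: file locations are not part of the
        # analysis, so identical inputs staged at different paths (or
        # outputs written to different directories) stay byte-identical
        params = {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}
        return hashlib.sha1(repr(sorted(params.items())).encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    bias_table: pd.DataFrame
    pooled_table: pd.DataFrame | None
    association_table: pd.DataFrame | None
    sweep_table: pd.DataFrame | None
    detectable_sweeps: pd.DataFrame | None
    out_dir: str | None


def _fmt(x) -> str:
    if x is None:
        return NA
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_table(df: pd.DataFrame, path: str, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bgcscan {__version__}\n# seed={cfg.seed}\n# config={cfg.digest()}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA)


def run_full_analysis(cfg: RunConfig, write: bool = True) -> ReportBundle:
    """Execute filters -> per-region tests -> mask scans -> pooled tests ->
    sweep scans -> association -> detectable-sweeps estimate."""
    regions = bio.read_regions(cfg.regions_bed, cfg.covered_bed)
    sites_by = bio.read_sites(cfg.sites_tsv)
    fixed_by = bio.read_fixed_differences(cfg.fixed_tsv) if cfg.fixed_tsv else {}
    if not cfg.fixed_tsv:
        logger.warning("no fixed-difference table: skipping MK tests and sweeps estimate")

    annotations = None
    if cfg.annotations_tsv:
        annotations = pd.read_csv(cfg.annotations_tsv, sep="\t", dtype={"region_id": str})

    m_tests = len(regions) if cfg.bonferroni else 1
    rows = []
    mwu_flags, mk_flags = [], []
    for region in regions:
        sites = sites_by.get(region.id, [])
        fixed = fixed_by.get(region.id, [])
        by = split_by_class(sites)
        mwu = mwu_test(by[W2S], by[S2W])
        mk = mk_test(fixed, sites) if fixed else None
        stats = summary_stats(sites, max((s.n for s in sites), default=2),
                              L=region.covered_length)
        row = {
            "region": region.id,
            "n_sites": len(sites),
            "n_w2s": mwu.n_w2s,
            "n_s2w": mwu.n_s2w,
            "n_fixed": len(fixed),
            "offset22": mwu.offset22,
            "mwu_p": mwu.p,
            "mk_p": mk.p if mk else None,
            "mk_direction": mk.direction if mk else None,
            "theta_w": stats.theta_w,
            "pi": stats.pi,
            "tajima_d": stats.tajima_d,
            "fay_wu_h": stats.fay_wu_h,
        }
        if cfg.bonferroni:
            row["mwu_p_bonf"] = min(1.0, mwu.p * m_tests) if mwu.p is not None else None
            row["mk_p_bonf"] = (
                min(1.0, mk.p * m_tests) if mk and mk.p is not None else None
            )
        if cfg.mask_scans:
            for test, prefix in (("MWU", "mwu"), ("MK", "mk")):
                if test == "MK" and not fixed:
                    continue
                scan = mask_scan(region, sites, fixed, test=test)
                for w in CENTRAL_MASK_WIDTHS:
                    row[f"{prefix}_mask{w}"] = scan.central[w]
                row[f"{prefix}_5kbHi"] = scan.sliding_max
        rows.append(row)
        mwu_flags.append(mwu.p is not None and mwu.p < cfg.alpha)
        mk_flags.append(mk is not None and mk.p is not None and mk.p < cfg.alpha)

    bias_table = pd.DataFrame(rows)
    if annotations is not None:
        bias_table = bias_table.merge(
            annotations, how="left", left_on="region", right_on="region_id"
        ).drop(columns=["region_id"])

    pooled_table = None
    if cfg.pooled:
        pm = pooled_mwu(sites_by.values())
        prow = {
            "pooled_mwu_p": pm.p,
            "pooled_offset22": pm.offset22,
            "pooled_n_w2s": pm.n_w2s,
            "pooled_n_s2w": pm.n_s2w,
        }
        if fixed_by:
            pk = pooled_mk(fixed_by.values(), sites_by.values())
            prow.update(
                pooled_mk_p=pk.p, pooled_mk_direction=pk.direction,
                pooled_mk_table=str(pk.table),
            )
        pooled_table = pd.DataFrame([prow])

    association_table = None
    if fixed_by and len(regions) >= 2:
        assoc = association_tests(mwu_flags, mk_flags)
        association_table = pd.DataFrame(
            [
                {
                    "fisher_p": assoc.fisher_p,
                    "binomial_p": assoc.binomial_p,
                    "poisson_p": assoc.poisson_p,
                    "n_both": assoc.n_both,
                    "n_mwu_sig": int(np.sum(mwu_flags)),
                    "n_mk_sig": int(np.sum(mk_flags)),
                }
            ]
        )

    sweep_table = None
    if cfg.sweeps:
        if cfg.background_sfs:
            from .sweep_scan import BackgroundSFS

            background = BackgroundSFS.from_spectrum(bio.read_spectrum(cfg.background_sfs))
        else:
            all_sites = [s for ss in sites_by.values() for s in ss]
            n_common = min(s.n for s in all_sites)
            background = estimate_background(all_sites, n_common)
        ss = np.random.SeedSequence(cfg.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(regions))]
        srows = []
        for region, rep_seed in zip(regions, seeds):
            sites = sites_by.get(region.id, [])
            if not sites:
                logger.warning("region %s has no sites; skipping sweep scan", region.id)
                continue
            n_min = min(s.n for s in sites)
            scan = clr_scan(sites, region, background, grid_size=cfg.sweep_grid)
            scan = sweep_pvalue(
                scan, region, background, observed_S=len(sites), n=n_min,
                rho=cfg.sweep_rho, n_reps=cfg.sweep_reps, seed=rep_seed,
            )
            srows.append(
                {
                    "region": region.id,
                    "max_clr": scan.max_clr,
                    "argmax_pos": scan.argmax_pos,
                    "p": scan.p,
                }
            )
        sweep_table = pd.DataFrame(srows)

    detectable = None
    if fixed_by:
        all_fixed = [d for ds in fixed_by.values() for d in ds]
        n_h = sum(1 for d in all_fixed if d.lineage == "human")
        n_c = sum(1 for d in all_fixed if d.lineage == "chimp")
        hi, lo = max(n_h, n_c), min(n_h, n_c)
        est = estimate_detectable_sweeps(hi, lo)
        detectable = pd.DataFrame(
            [
                {
                    "human_lineage_subs": n_h,
                    "chimp_lineage_subs": n_c,
                    "adaptive_bound": est.adaptive_bound,
                    "expected_detectable": est.expected,
                }
            ]
        )

    out_dir = None
    if write:
        out_dir = bio.ensure_dir(cfg.out_dir)
        _write_table(bias_table, os.path.join(out_dir, "bias_report.tsv"), cfg)
        if pooled_table is not None:
            _write_table(pooled_table, os.path.join(out_dir, "pooled.tsv"), cfg)
        if association_table is not None:
            _write_table(association_table, os.path.join(out_dir, "association.tsv"), cfg)
        if sweep_table is not None:
            _write_table(sweep_table, os.path.join(out_dir, "sweep_report.tsv"), cfg)
        if detectable is not None:
            _write_table(detectable, os.path.join(out_dir, "detectable_sweeps.tsv"), cfg)

    return ReportBundle(
        bias_table=bias_table,
        pooled_table=pooled_table,
        association_table=association_table,
        sweep_table=sweep_table,
        detectable_sweeps=detectable,
        out_dir=out_dir,
    )
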