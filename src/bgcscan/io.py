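"""Readers and writers for the package's plain-text table dialects.

Formats
-------
Regions
    BED4 (chrom, start, end, id); an optional companion BED of covered
    sub-intervals uses the region id in column 4.
Segregating sites
    TSV with header ``region_id chrom pos ancestral derived k n``.
Fixed differences
    TSV with header ``region_id chrom pos human chimp ancestral``.
Spectra
    Two-column text ``frequency<TAB>count`` preceded by a ``# n=<int>`` line.

Missing values are encoded as ``NA`` throughout.  All readers return plain
dicts keyed by region id so tables for many regions can live in one file.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .sfs_core import DerivedAlleleSpectrum, FixedDifference, Region, SegregatingSite

NA = "NA"

SITE_COLUMNS = ["region_id", "chrom", "pos", "ancestral", "derived", "k", "n"]
FIXED_COLUMNS = ["region_id", "chrom", "pos", "human", "chimp", "ancestral"]


def read_regions(bed_path: str, covered_bed_path: str | None = None) -> list[Region]:
    """Read regions from BED4, optionally attaching a coverage mask BED."""
    bed = pd.read_csv(
        bed_path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "id"], dtype={"chrom": str, "id": str},
    )
    masks: dict[str, list[tuple[int, int]]] = {}
    if covered_bed_path is not None:
        cov = pd.read_csv(
            covered_bed_path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "id"], dtype={"chrom": str, "id": str},
        )
        for row in cov.itertuples(index=False):
            masks.setdefault(row.id, []).append((int(row.start), int(row.end)))
    regions = []
    for row in bed.itertuples(index=False):
        covered = tuple(sorted(masks.get(row.id, [])))
        regions.append(
            Region(id=row.id, chrom=row.chrom, start=int(row.start), end=int(row.end),
                   covered=covered)
        )
    return regions


def write_regions(regions: Iterable[Region], bed_path: str,
                  covered_bed_path: str | None = None) -> None:
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
    if covered_bed_path is not None:
        with open(covered_bed_path, "w") as fh:
            for r in regions:
                for a, b in r.covered:
                    fh.write(f"{r.chrom}\t{a}\t{b}\t{r.id}\n")


def read_sites(path: str) -> dict[str, list[SegregatingSite]]:
    """Read a segregating-site table, returning sites grouped by region id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"region_id": str, "chrom": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns: {sorted(missing)}")
    out: dict[str, list[SegregatingSite]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.region_id, []).append(
            SegregatingSite(pos=int(row.pos), ancestral=str(row.ancestral),
                            derived=str(row.derived), k=int(row.k), n=int(row.n))
        )
    return out


def write_sites(sites_by_region: Mapping[str, Iterable[SegregatingSite]],
                path: str, chrom_by_region: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for rid in sites_by_region:
            chrom = chrom_by_region[rid] if chrom_by_region else "chrN"
            for s in sites_by_region[rid]:
                fh.write(f"{rid}\t{chrom}\t{s.pos}\t{s.ancestral}\t{s.derived}\t{s.k}\t{s.n}\n")


def read_fixed_differences(path: str) -> dict[str, list[FixedDifference]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"region_id": str, "chrom": str})
    missing = set(FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixed-difference table {path} lacks columns: {sorted(missing)}")
    out: dict[str, list[FixedDifference]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.region_id, []).append(
            FixedDifference(pos=int(row.pos), human=str(row.human),
                            chimp=str(row.chimp), ancestral=str(row.ancestral))
        )
    return out


def write_fixed_differences(fixed_by_region: Mapping[str, Iterable[FixedDifference]],
                            path: str,
                            chrom_by_region: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FIXED_COLUMNS) + "\n")
        for rid in fixed_by_region:
            chrom = chrom_by_region[rid] if chrom_by_region else "chrN"
            for d in fixed_by_region[rid]:
                fh.write(f"{rid}\t{chrom}\t{d.pos}\t{d.human}\t{d.chimp}\t{d.ancestral}\n")


def read_spectrum(path: str) -> DerivedAlleleSpectrum:
    """Read a ``frequency<TAB>count`` spectrum with a ``# n=<int>`` header line."""
    n = None
    entries: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("n="):
                    n = int(stripped[2:])
                continue
            freq_s, count_s = line.split("\t")
            entries[int(freq_s)] = float(count_s)
    if n is None:
        raise ValueError(f"spectrum file {path} lacks an 'n=<int>' header line")
    spec = DerivedAlleleSpectrum(n)
    for freq, count in entries.items():
        spec[freq] = count
    return spec


def write_spectrum(spec: DerivedAlleleSpectrum, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n={spec.n}\n")
        for freq in range(1, spec.n):
            fh.write(f"{freq}\t{spec[freq]:.12g}\n")


def read_sites_vcf(path: str, ancestral_tag: str = "AA") -> list[SegregatingSite]:
    """Ingest biallelic SNVs from a VCF with an ancestral-allele INFO tag.

    Genotyped allele counts are taken from the GT fields; sites whose
    ancestral allele is missing or matches neither REF nor ALT are skipped.
    Requires cyvcf2 (optional dependency).
    """
    from cyvcf2 import VCF  # lazy: optional extra

    sites = []
    for var in VCF(path):
        if not var.is_snp or len(var.ALT) != 1:
            continue
        anc = var.INFO.get(ancestral_tag)
        if anc is None:
            continue
        anc = str(anc)
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if anc.upper() not in (ref, alt):
            continue
        gts = [a for pair in var.genotypes for a in pair[:2] if a in (0, 1)]
        n = len(gts)
        n_alt = sum(gts)
        derived_is_alt = anc.upper() == ref
        k = n_alt if derived_is_alt else n - n_alt
        if not 1 <= k <= n - 1:
            continue
        sites.append(
            SegregatingSite(pos=var.POS - 1, ancestral=anc,
                            derived=alt if derived_is_alt else ref, k=k, n=n)
        )
    return sites


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
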