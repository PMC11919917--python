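"""Readers and writers for the formats the pipeline touches.

Covers: multi-sample VCF 4.2 (genotypes with AD/DP), the packaged
pedigree/embryo linkage-table fixture, per-bin read-count TSVs,
seg-style segment TSVs, the per-embryo report TSV, and BED export of a
region.  VCF parsing goes through cyvcf2; everything tabular goes
through pandas.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import NO_CALL, CallMap, GenotypeCall, SampleCalls, SnpSite
from .regions import GenomicRegion

__all__ = [
    "FormatError",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "LinkageTable",
    "read_table1_tsv",
    "packaged_table1_path",
    "read_bins_tsv",
    "write_bins_tsv",
    "write_segments",
    "read_segments",
    "write_report",
    "write_region_bed",
]

TABLE1_SAMPLES = ("Male", "Female", "Proband", "E1", "E2", "E3", "E4", "E5")

_TABLE1_COLUMNS = ["RSID", "POS", "Male", "Female", "Proband",
                   "E1", "E2", "E3", "E4", "E5"]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


# ---------------------------------------------------------------------------
# VCF

def read_genotypes_vcf(path: str) -> CallMap:
    """Read a multi-sample VCF into per-sample genotype call maps.

    Each record must be biallelic (the linkage method uses biallelic
    SNPs only; multiallelic records raise :class:`FormatError` — split
    them upstream with ``bcftools norm`` if needed).  Missing genotypes
    map to the no-call state.  AD depths, when present, are attached to
    the call.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    out: CallMap = {s: {} for s in samples}
    for var in vcf:
        if var.ALT is None or len(var.ALT) != 1:
            raise FormatError(
                f"{path}: multiallelic or ALT-less record at "
                f"{var.CHROM}:{var.POS}; only biallelic SNPs are supported"
            )
        site = SnpSite(
            rsid=var.ID or f"{var.CHROM}:{var.POS}",
            chrom=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_allele=var.ALT[0],
        )
        if "GT" not in (var.FORMAT or []):
            raise FormatError(f"{path}: record without GT at {var.CHROM}:{var.POS}")
        gts = var.genotypes  # [a0, a1, phased] per sample
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        alleles = (var.REF, var.ALT[0])
        for k, sample in enumerate(samples):
            a0, a1 = gts[k][0], gts[k][1]
            depths = None
            if ad is not None and ad[k][0] >= 0:
                depths = {var.REF: int(ad[k][0]), var.ALT[0]: int(ad[k][1])}
            if a0 < 0 or a1 < 0:
                out[sample][site] = NO_CALL if depths is None else GenotypeCall(
                    alleles=None, depth_per_allele=depths)
            else:
                out[sample][site] = GenotypeCall(
                    alleles=(alleles[a0], alleles[a1]),
                    depth_per_allele=depths,
                )
    return out


def write_genotypes_vcf(
    path: str,
    sites: Sequence[SnpSite],
    calls: CallMap,
    sample_order: Optional[Sequence[str]] = None,
) -> None:
    """Write genotype calls to an uncompressed VCF 4.2 with GT:AD:DP."""
    samples = list(sample_order) if sample_order is not None else sorted(calls)
    contigs = []
    for s in sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgtdup\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            cols = [site.chrom, str(site.pos), site.rsid,
                    site.ref_allele, site.alt_allele, ".", "PASS", ".",
                    "GT:AD:DP"]
            for sample in samples:
                call = calls.get(sample, {}).get(site, NO_CALL)
                cols.append(_vcf_sample_field(site, call))
            fh.write("\t".join(cols) + "\n")


def _vcf_sample_field(site: SnpSite, call: GenotypeCall) -> str:
    if call.depth_per_allele is not None:
        ad_ref = call.depth_per_allele.get(site.ref_allele, 0)
        ad_alt = call.depth_per_allele.get(site.alt_allele, 0)
        ad = f"{ad_ref},{ad_alt}"
        dp = str(ad_ref + ad_alt)
    else:
        ad, dp = ".", "."
    if call.alleles is None:
        return f"./.:{ad}:{dp}"
    idx = []
    for a in call.alleles:
        if a == site.ref_allele:
            idx.append("0")
        elif a == site.alt_allele:
            idx.append("1")
        else:
            raise ValueError(
                f"{site.rsid}: allele {a!r} is neither REF nor ALT")
    return f"{'/'.join(sorted(idx))}:{ad}:{dp}"


# ---------------------------------------------------------------------------
# Linkage-table fixture

@dataclass
class LinkageTable:
    """The pedigree + embryo genotype table used for linkage analysis.

    ``calls`` holds genotypes for the 8 individuals; the printed
    ``Distance`` / paternal-haplotype columns, when present in the file,
    are retained so they can be cross-checked against recomputation.
    """

    sites: list[SnpSite]
    calls: CallMap
    printed_distance: dict[str, Optional[int]] = field(default_factory=dict)
    printed_hap1: dict[str, Optional[str]] = field(default_factory=dict)
    printed_hap2: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def embryo_ids(self) -> list[str]:
        return [s for s in self.calls if s.startswith("E")]


def packaged_table1_path():
    """Path to the packaged linkage-table fixture (GRCh37 chr1 markers)."""
    return importlib.resources.files("pgtdup") / "data" / "table1.tsv"


def read_table1_tsv(path, chrom: str = "chr1") -> LinkageTable:
    """Load a linkage genotype table (RSID/POS + 8 genotype columns).

    Genotypes are ``X/Y`` strings; ``./`` is a no-call.  REF/ALT for
    each marker are taken in the order of the carrier male's genotype
    string (the table does not distinguish reference from alternate,
    and the linkage analysis never needs it).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty linkage table")
    missing = [c for c in _TABLE1_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing columns {missing}; expected header with "
            f"{_TABLE1_COLUMNS}"
        )
    hap_cols = ("Paternal hap 1", "Paternal hap 2")
    table = LinkageTable(sites=[], calls={s: {} for s in TABLE1_SAMPLES})
    for _, row in df.iterrows():
        rsid = row["RSID"].replace(",", "").strip()
        pos = int(row["POS"].replace(",", ""))
        male = GenotypeCall.from_string(row["Male"])
        if male.is_call:
            ref, alt = row["Male"].strip().split("/")
        else:  # fall back on any het column for the allele pair
            ref, alt = "N", "N"
        site = SnpSite(rsid=rsid, chrom=chrom, pos=pos,
                       ref_allele=ref, alt_allele=alt)
        table.sites.append(site)
        for sample in TABLE1_SAMPLES:
            table.calls[sample][site] = GenotypeCall.from_string(row[sample])
        if "Distance" in df.columns:
            d = row["Distance"].replace(",", "").replace("−", "-").strip()
            table.printed_distance[rsid] = int(d) if d else None
        for col, store in zip(hap_cols, (table.printed_hap1, table.printed_hap2)):
            if col in df.columns:
                v = row[col].strip()
                store[rsid] = v or None
    return table


# ---------------------------------------------------------------------------
# Bin counts and segments

_BIN_COLUMNS = ["chrom", "start", "end", "count"]


def read_bins_tsv(path) -> pd.DataFrame:
    """Read a per-bin read-count TSV (chrom, start, end, count; 1-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing bin columns {missing}")
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative bin counts")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bins_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_SEG_COLUMNS = ["sample", "chrom", "start", "end",
                "n_bins", "mean_log2ratio", "cn", "call"]


def write_segments(segments: Iterable, path, sample: str = "sample") -> None:
    """Write segments as a seg-style TSV (one row per segment)."""
    rows = []
    for seg in segments:
        ratio = max(seg.mean_ratio, 1e-6)
        rows.append({
            "sample": getattr(seg, "sample", sample),
            "chrom": seg.chrom,
            "start": seg.start,
            "end": seg.end,
            "n_bins": seg.n_bins,
            "mean_log2ratio": round(float(np.log2(ratio)), 6),
            "cn": round(2.0 * seg.mean_ratio, 4),
            "call": getattr(seg, "call", ""),
        })
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing segment columns {missing}")
    return df


def write_report(report_df: pd.DataFrame, path) -> None:
    """Write the per-embryo summary report TSV."""
    report_df.to_csv(path, sep="\t", index=False)


def write_region_bed(region: GenomicRegion, path, name: str = "region") -> None:
    """Export a region as BED (0-based half-open conversion happens here)."""
    chrom, start0, end = region.to_bed_fields()
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{start0}\t{end}\t{name}\n")
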