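"""Synthetic pedigree, embryo, genotype and read-count generator.

Emulates the data a tandem-microduplication PGT cycle produces: a
carrier father (one extra copy of the duplicated segment on haplotype
1), a non-carrier mother, an affected proband that inherited paternal
haplotype 1, and biopsied embryos genotyped after whole-genome
amplification at shallow depth.  Two observation layers sit on the
transmission truth:

* per-SNP allele depths — Poisson total depth, reads drawn from the
  alleles present in proportion to their copy-number dosage (a
  heterozygous site inside the duplicated segment has allele fractions
  1/3 and 2/3), with per-allele amplification dropout (ADO) and a small
  spurious-read rate;
* per-bin read counts on a 0-anchored grid — Poisson with mean
  ``reads_per_bin x cn/2``, the copy number averaged over each bin by
  overlap length.

Meiosis uses a single-crossover model within the simulated window
(duplication plus flanks): with probability ``recomb_prob`` one
breakpoint is placed uniformly and the transmitted paternal haplotype
switches there.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeCall, SampleCalls, SnpSite
from .regions import GRCH37_AUTOSOME_SIZES, GenomicRegion, parse_region

__all__ = [
    "DUP_REGION",
    "SimConfig",
    "PedigreeTruth",
    "EmbryoTruth",
    "CnInterval",
    "simulate_pedigree",
    "simulate_embryo",
    "simulate_allele_depths",
    "simulate_bin_counts",
    "true_genotypes",
]

# The 1q21.1-q21.2 tandem microduplication studied here (GRCh37).
DUP_REGION = parse_region("chr1:146305863-147992406")

_BASES = np.array(list("ACGT"))

# (chrom, start, end, cn): a copy-number deviation from the diploid baseline
CnInterval = tuple[str, int, int, int]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate a shallow MALBAC PGT cycle."""

    dup_region: GenomicRegion = DUP_REGION
    flank_bp: int = 2_000_000
    n_snps_flank: int = 12          # per flank
    n_snps_inside: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    mean_site_depth: float = 30.0   # targeted SNP depth after amplification
    ado_rate: float = 0.05          # per distinct allele, per site
    false_allele_rate: float = 0.002  # per read
    reads_total: float = 5e6        # genome-wide valid reads
    bin_size_bp: int = 1_000_000
    recomb_prob: float = 0.01       # per meiosis, within the window
    overdispersion: float = 1.0     # 1 = Poisson bin counts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ado_rate", "false_allele_rate", "recomb_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError(f"maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")

    def reads_per_bin(self, chroms: Optional[Sequence[str]] = None) -> float:
        """Expected diploid-bin count implied by ``reads_total``."""
        sizes = GRCH37_AUTOSOME_SIZES if chroms is None else {
            c: GRCH37_AUTOSOME_SIZES[c] for c in chroms}
        genome = sum(sizes.values())
        return self.reads_total * self.bin_size_bp / genome


@dataclass
class PedigreeTruth:
    """Parental haplotypes over the SNP panel; hap1 carries the duplication."""

    snp_panel: list[SnpSite]
    paternal_hap1: list[str]
    paternal_hap2: list[str]
    maternal_hap1: list[str]
    maternal_hap2: list[str]
    dup_region: GenomicRegion
    proband_maternal_hap: int = 1

    def father_cn_profile(self) -> list[CnInterval]:
        r = self.dup_region
        return [(r.chrom, r.start, r.end, 3)]

    def inside_mask(self) -> np.ndarray:
        return np.array([self.dup_region.contains_pos(s.pos)
                         for s in self.snp_panel])


@dataclass
class EmbryoTruth:
    """One embryo's transmission outcome and copy-number profile."""

    paternal_hap_per_site: np.ndarray      # 1 or 2, aligned with the panel
    transmitted_maternal_hap: int          # 1 or 2
    paternal_crossover_pos: Optional[int]
    carries_duplication: bool
    aneuploidies: list[tuple[str, str]] = field(default_factory=list)
    extra_cnvs: list[tuple[GenomicRegion, int]] = field(default_factory=list)
    cn_profile: list[CnInterval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pedigree and meiosis

def simulate_pedigree(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 100,
) -> PedigreeTruth:
    """Draw a SNP panel and phased parental haplotypes.

    SNP positions are uniform within the duplication and within
    ``flank_bp`` on either side; allele frequencies are uniform in
    ``maf_range`` and parental haplotype alleles are drawn from them.
    The panel is redrawn until each flank holds at least one
    informative site (father heterozygous, mother homozygous); failure
    after ``max_tries`` redraws raises, pointing at ``n_snps_flank``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    region, flank = config.dup_region, config.flank_bp
    for _ in range(max_tries):
        positions = np.concatenate([
            np.sort(rng.integers(max(1, region.start - flank), region.start,
                                 size=config.n_snps_flank)),
            np.sort(rng.integers(region.start, region.end + 1,
                                 size=config.n_snps_inside)),
            np.sort(rng.integers(region.end + 1, region.end + flank + 1,
                                 size=config.n_snps_flank)),
        ])
        if len(np.unique(positions)) != len(positions):
            continue
        n = positions.size
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        panel = [SnpSite(rsid=f"sim{i:05d}", chrom=region.chrom,
                         pos=int(p), ref_allele=_BASES[ref_idx[i]],
                         alt_allele=_BASES[alt_idx[i]])
                 for i, p in enumerate(positions)]
        freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
        haps = [np.where(rng.random(n) < freq,
                         _BASES[alt_idx], _BASES[ref_idx]).tolist()
                for _ in range(4)]
        truth = PedigreeTruth(
            snp_panel=panel,
            paternal_hap1=haps[0], paternal_hap2=haps[1],
            maternal_hap1=haps[2], maternal_hap2=haps[3],
            dup_region=region,
            proband_maternal_hap=int(rng.integers(1, 3)),
        )
        if _flanks_informative(truth):
            return truth
    raise RuntimeError(
        f"could not draw an informative panel in {max_tries} tries; "
        f"increase n_snps_flank (currently {config.n_snps_flank})"
    )


def _flanks_informative(truth: PedigreeTruth) -> bool:
    region = truth.dup_region
    has = {"up": False, "down": False}
    for i, site in enumerate(truth.snp_panel):
        father_het = truth.paternal_hap1[i] != truth.paternal_hap2[i]
        mother_hom = truth.maternal_hap1[i] == truth.maternal_hap2[i]
        if not (father_het and mother_hom):
            continue
        if site.pos < region.start:
            has["up"] = True
        elif site.pos > region.end:
            has["down"] = True
    return has["up"] and has["down"]


def simulate_embryo(
    truth: PedigreeTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    aneuploidies: Sequence[tuple[str, str]] = (),
    extra_cnvs: Sequence[tuple[GenomicRegion, int]] = (),
) -> EmbryoTruth:
    """One meiosis: transmitted haplotypes, optional crossover and CNVs.

    ``aneuploidies`` is a list of ``(chrom, "gain"|"loss")`` whole-
    chromosome events; ``extra_cnvs`` installs arbitrary ``(region,
    cn)`` intervals.  The duplication is transmitted iff the paternal
    haplotype covering the duplication locus is haplotype 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    region, flank = truth.dup_region, config.flank_bp
    positions = np.array([s.pos for s in truth.snp_panel])
    base_hap = int(rng.integers(1, 3))
    crossover = None
    if rng.random() < config.recomb_prob:
        crossover = int(rng.integers(region.start - flank,
                                     region.end + flank + 1))
    hap_per_site = np.full(positions.size, base_hap)
    if crossover is not None:
        hap_per_site[positions >= crossover] = 3 - base_hap
    # hap covering the duplication locus decides transmission of the event
    dup_hap = base_hap if crossover is None or crossover > region.start \
        else 3 - base_hap
    carries = dup_hap == 1

    profile: list[CnInterval] = []
    if carries:
        profile.append((region.chrom, region.start, region.end, 3))
    aneu = [(c, k) for c, k in aneuploidies]
    for chrom, kind in aneu:
        if kind not in ("gain", "loss"):
            raise ValueError(f"aneuploidy kind must be gain/loss, got {kind!r}")
        size = GRCH37_AUTOSOME_SIZES[chrom]
        profile.append((chrom, 1, size, 3 if kind == "gain" else 1))
    cnvs = [(r, cn) for r, cn in extra_cnvs]
    for r, cn in cnvs:
        profile.append((r.chrom, r.start, r.end, cn))

    return EmbryoTruth(
        paternal_hap_per_site=hap_per_site,
        transmitted_maternal_hap=int(rng.integers(1, 3)),
        paternal_crossover_pos=crossover,
        carries_duplication=carries,
        aneuploidies=aneu,
        extra_cnvs=cnvs,
        cn_profile=profile,
    )


# ---------------------------------------------------------------------------
# Genotype observations

def _allele_dosage(
    member: str,
    truth: PedigreeTruth,
    embryo: Optional[EmbryoTruth] = None,
) -> list[dict[str, int]]:
    """Per-site allele copy counts for a family member.

    Inside the duplication, the duplicated haplotype-1 allele counts
    twice for whoever carries the event (father, proband, affected
    embryos).
    """
    inside = truth.inside_mask()
    out: list[dict[str, int]] = []
    for i in range(len(truth.snp_panel)):
        dosage: dict[str, int] = {}

        def add(allele: str, copies: int = 1) -> None:
            dosage[allele] = dosage.get(allele, 0) + copies

        if member == "father":
            add(truth.paternal_hap1[i], 2 if inside[i] else 1)
            add(truth.paternal_hap2[i])
        elif member == "mother":
            add(truth.maternal_hap1[i])
            add(truth.maternal_hap2[i])
        elif member == "proband":
            add(truth.paternal_hap1[i], 2 if inside[i] else 1)
            mat = (truth.maternal_hap1 if truth.proband_maternal_hap == 1
                   else truth.maternal_hap2)
            add(mat[i])
        elif member == "embryo":
            if embryo is None:
                raise ValueError("embryo truth required for member='embryo'")
            hap = embryo.paternal_hap_per_site[i]
            pat = (truth.paternal_hap1 if hap == 1 else truth.paternal_hap2)
            dup_here = inside[i] and hap == 1 and embryo.carries_duplication
            add(pat[i], 2 if dup_here else 1)
            mat = (truth.maternal_hap1 if embryo.transmitted_maternal_hap == 1
                   else truth.maternal_hap2)
            add(mat[i])
        else:
            raise ValueError(f"unknown family member {member!r}")
        out.append(dosage)
    return out


def true_genotypes(
    member: str,
    truth: PedigreeTruth,
    embryo: Optional[EmbryoTruth] = None,
) -> SampleCalls:
    """Noise-free diploid-style genotype calls for a family member."""
    calls: SampleCalls = {}
    for site, dosage in zip(truth.snp_panel,
                            _allele_dosage(member, truth, embryo)):
        alleles = sorted(dosage)
        gt = (alleles[0], alleles[0]) if len(alleles) == 1 else tuple(alleles)
        calls[site] = GenotypeCall(alleles=gt)
    return calls


def simulate_allele_depths(
    member: str,
    truth: PedigreeTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    embryo: Optional[EmbryoTruth] = None,
) -> SampleCalls:
    """Observed per-site allele depths for one amplified sample.

    Total depth per site is Poisson(``mean_site_depth``); reads are
    multinomial over the alleles surviving ADO, weighted by dosage;
    each read is then miscalled to the site's other allele with
    probability ``false_allele_rate``.  The returned calls carry a
    naive genotype (alleles seen at least once) plus the depths — run
    them through QC before linkage analysis.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    calls: SampleCalls = {}
    for site, dosage in zip(truth.snp_panel,
                            _allele_dosage(member, truth, embryo)):
        surviving = {a: c for a, c in dosage.items()
                     if rng.random() >= config.ado_rate}
        depth = int(rng.poisson(config.mean_site_depth))
        counts = {site.ref_allele: 0, site.alt_allele: 0}
        if surviving and depth > 0:
            alleles = list(surviving)
            w = np.array([surviving[a] for a in alleles], dtype=float)
            draws = rng.multinomial(depth, w / w.sum())
            for a, d in zip(alleles, draws):
                counts[a] = counts.get(a, 0) + int(d)
            if config.false_allele_rate > 0:
                for a in (site.ref_allele, site.alt_allele):
                    flipped = int(rng.binomial(counts[a],
                                               config.false_allele_rate))
                    if flipped:
                        other = (site.alt_allele if a == site.ref_allele
                                 else site.ref_allele)
                        counts[a] -= flipped
                        counts[other] += flipped
        seen = tuple(sorted(a for a in (site.ref_allele, site.alt_allele)
                            if counts[a] > 0))
        if len(seen) == 1:
            gt = (seen[0], seen[0])
        elif len(seen) == 2:
            gt = seen
        else:
            gt = None
        calls[site] = GenotypeCall(alleles=gt, depth_per_allele=counts)
    return calls


# ---------------------------------------------------------------------------
# Binned read counts

def simulate_bin_counts(
    cn_profile: Sequence[CnInterval],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    chroms: Optional[Sequence[str]] = None,
    reads_per_bin: Optional[float] = None,
) -> pd.DataFrame:
    """Per-bin read counts for a sample with the given copy-number profile.

    Bins are anchored at coordinate 0 in multiples of ``bin_size_bp``.
    Each bin's expected count is ``reads_per_bin x cn/2`` with the copy
    number averaged over the bin by overlap length; counts are Poisson
    (or gamma-mixed Poisson when ``overdispersion > 1``).
    """
    from .cnv import make_bin_grid  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if chroms is None:
        sizes = dict(GRCH37_AUTOSOME_SIZES)
    else:
        sizes = {c: GRCH37_AUTOSOME_SIZES[c] for c in chroms}
    if reads_per_bin is None:
        reads_per_bin = config.reads_per_bin(list(sizes))

    bins = make_bin_grid(sizes, config.bin_size_bp)
    cn = np.full(len(bins), 2.0)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chrom_arr = bins["chrom"].to_numpy()
    for chrom, s, e, level in cn_profile:
        if chrom not in sizes:
            continue
        sel = chrom_arr == chrom
        overlap = (np.minimum(ends, e) - np.maximum(starts, s) + 1).clip(min=0)
        width = ends - starts + 1
        cn = cn + np.where(sel, (level - 2) * overlap / width, 0.0)

    mean = reads_per_bin * cn / 2.0
    if config.overdispersion > 1.0:
        # gamma-Poisson: variance = overdispersion * mean
        shape = mean / (config.overdispersion - 1.0)
        mean = rng.gamma(shape, config.overdispersion - 1.0)
    out = bins.copy()
    out["count"] = rng.poisson(mean)
    return out
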