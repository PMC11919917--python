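"""Informative-SNP selection, paternal phasing and embryo classification.

This is the PGT-M core for a paternally inherited tandem microduplication.
The duplication cannot be genotyped directly at SNP resolution, but its
transmission can be tracked through linked markers:

* **Flanking informative SNPs** — heterozygous in the carrier father and
  homozygous in the mother, within a window (default 2 Mb) on either
  side of the duplication.  At such a site the paternal allele an embryo
  received is deducible by subtracting the obligate maternal allele.
* **Within-duplication informative SNPs** — father heterozygous, mother
  and affected proband homozygous for the same allele.  Because the
  duplicated paternal haplotype carries the mother-matching allele in
  two copies, an embryo that inherited it types homozygous like the
  proband, while an embryo with the other paternal haplotype types
  heterozygous.

Phasing is anchored on an affected proband known to carry the
duplication: the paternal allele transmitted to the proband defines
haplotype 1 (high-risk, duplication-bearing); the father's other allele
defines haplotype 2 (low-risk).  Each embryo then votes per SNP, and a
majority with sufficient consistency yields a high-risk / low-risk
verdict; disagreement between the two flanks signals a possible
recombination between marker and duplication and forces an inconclusive
result rather than a risk call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .genotypes import GenotypeCall, SampleCalls, SnpSite
from .regions import GenomicRegion

__all__ = [
    "InformativeSnp",
    "PhasedPaternalHaplotypes",
    "LinkageVerdict",
    "VerdictThresholds",
    "compute_distance",
    "select_informative_snps",
    "phase_paternal",
    "classify_embryo",
    "linkage_report",
]

logger = logging.getLogger(__name__)

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"
INCONCLUSIVE = "inconclusive"

DEFAULT_FLANK_BP = 2_000_000


def compute_distance(site: SnpSite, region: GenomicRegion) -> Optional[int]:
    """Signed distance (bp) from a site to the nearest region boundary.

    Negative upstream of the region start, positive downstream of the
    region end, ``None`` for sites inside the region (distance is not a
    meaningful quantity there).
    """
    if site.chrom != region.chrom:
        raise ValueError(
            f"{site.rsid} is on {site.chrom}, region on {region.chrom}")
    if site.pos < region.start:
        return site.pos - region.start
    if site.pos > region.end:
        return site.pos - region.end
    return None


@dataclass
class InformativeSnp:
    """A marker usable for linkage, with phased paternal alleles once known."""

    site: SnpSite
    snp_class: str            # "flanking" | "within_dup"
    side: str                 # "upstream" | "downstream" | "inside"
    distance_bp: Optional[int]
    father_alleles: tuple[str, str]
    mother_allele: str
    hap1_allele: Optional[str] = None   # high-risk (duplication-bearing)
    hap2_allele: Optional[str] = None   # low-risk

    @property
    def is_phased(self) -> bool:
        return self.hap1_allele is not None and self.hap2_allele is not None


def select_informative_snps(
    father: SampleCalls,
    mother: SampleCalls,
    proband: SampleCalls,
    region: GenomicRegion,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[InformativeSnp]:
    """Select linkage-informative markers from the trio's genotypes.

    Flanking class: father heterozygous, mother homozygous, within
    ``flank_bp`` of a region boundary.  Within-duplication class:
    father heterozygous, mother homozygous, affected proband homozygous
    for the mother's allele, position inside the region.  Everything
    else is excluded.  An empty result is allowed.
    """
    out: list[InformativeSnp] = []
    for site in sorted(set(father) & set(mother), key=lambda s: (s.chrom, s.pos)):
        f, m = father[site], mother[site]
        if site.chrom != region.chrom or not f.is_het or not m.is_hom:
            continue
        dist = compute_distance(site, region)
        if dist is None:
            p = proband.get(site)
            if p is None or not p.is_hom or p.hom_allele != m.hom_allele:
                continue
            out.append(InformativeSnp(
                site=site, snp_class="within_dup", side="inside",
                distance_bp=None, father_alleles=f.alleles,
                mother_allele=m.hom_allele,
            ))
        elif abs(dist) <= flank_bp:
            out.append(InformativeSnp(
                site=site, snp_class="flanking",
                side="upstream" if dist < 0 else "downstream",
                distance_bp=dist, father_alleles=f.alleles,
                mother_allele=m.hom_allele,
            ))
    return out


@dataclass
class PhasedPaternalHaplotypes:
    """Per-site assignment of the father's high-/low-risk alleles."""

    snps: list[InformativeSnp]
    dropped: list[tuple[SnpSite, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    def as_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the clinical linkage-table layout."""
        rows = []
        for s in self.snps:
            rows.append({
                "RSID": s.site.rsid,
                "POS": s.site.pos,
                "Distance": s.distance_bp if s.distance_bp is not None else "",
                "class": s.snp_class,
                "side": s.side,
                "Male": f"{s.father_alleles[0]}/{s.father_alleles[1]}",
                "Paternal hap 1": s.hap1_allele,
                "Paternal hap 2": s.hap2_allele,
                "Female": f"{s.mother_allele}/{s.mother_allele}",
            })
        return pd.DataFrame(rows)


class PhasingError(RuntimeError):
    """No informative site could be phased."""


def phase_paternal(
    informative: list[InformativeSnp],
    mother: SampleCalls,
    proband: SampleCalls,
) -> PhasedPaternalHaplotypes:
    """Phase the father's haplotypes through the affected proband.

    Flanking sites: the paternal allele the proband received (proband
    genotype minus one obligate maternal allele) becomes haplotype 1;
    the father's other allele becomes haplotype 2.  Within-duplication
    sites: haplotype 1 is the mother-matching allele the proband is
    homozygous for; haplotype 2 is the father's other allele.  Sites
    whose proband call is missing, unusable, or Mendelian-inconsistent
    with the parents are dropped and logged.
    """
    phased: list[InformativeSnp] = []
    dropped: list[tuple[SnpSite, str]] = []

    for snp in informative:
        site = snp.site
        m_allele = snp.mother_allele
        if snp.snp_class == "within_dup":
            # selection already verified proband hom == mother allele
            if m_allele not in snp.father_alleles:
                dropped.append((site, "mother allele absent from father"))
                continue
            hap1 = m_allele
            hap2 = _other(snp.father_alleles, m_allele)
        else:
            p = proband.get(site)
            if p is None or not p.is_call:
                dropped.append((site, "proband no-call"))
                continue
            if not p.contains(m_allele):
                dropped.append((site, "Mendelian inconsistency with mother"))
                continue
            transmitted = p.other_allele(m_allele)
            if transmitted not in snp.father_alleles:
                dropped.append((site, "Mendelian inconsistency with father"))
                continue
            hap1 = transmitted
            hap2 = _other(snp.father_alleles, transmitted)
        phased.append(InformativeSnp(
            site=site, snp_class=snp.snp_class, side=snp.side,
            distance_bp=snp.distance_bp, father_alleles=snp.father_alleles,
            mother_allele=m_allele, hap1_allele=hap1, hap2_allele=hap2,
        ))

    for site, reason in dropped:
        logger.warning("phasing dropped %s: %s", site.rsid, reason)
    if not phased:
        raise PhasingError(
            "no informative site could be phased through the proband")
    return PhasedPaternalHaplotypes(snps=phased, dropped=dropped)


def _other(pair: tuple[str, str], allele: str) -> str:
    return pair[1] if pair[0] == allele else pair[0]


@dataclass(frozen=True)
class VerdictThresholds:
    """Minimum evidence for a clinical-style high/low-risk call.

    Defaults: at least 3 usable SNP votes overall, at least 1 on each
    flank, and at least 90% of votes on the majority haplotype.
    Anything weaker — and any upstream/downstream flank disagreement,
    which suggests a recombination between markers and duplication —
    is reported inconclusive.
    """

    min_votes: int = 3
    min_votes_per_flank: int = 1
    min_consistency: float = 0.9


@dataclass
class LinkageVerdict:
    status: str                       # high_risk | low_risk | inconclusive
    votes: dict[str, str]             # rsid -> hap1 | hap2 | no_call
    upstream_consistency: Optional[float]
    downstream_consistency: Optional[float]
    inside_consistency: Optional[float]
    recombination_flag: bool
    n_informative_used: int


def _vote_for_snp(snp: InformativeSnp, call: Optional[GenotypeCall]) -> str:
    """Map one embryo genotype to a haplotype vote at a phased SNP."""
    if call is None or not call.is_call:
        return "no_call"
    if snp.snp_class == "within_dup":
        if call.is_hom and call.hom_allele == snp.hap1_allele:
            return "hap1"
        if call.is_het and set(call.alleles) == set(snp.father_alleles):
            return "hap2"
        return "no_call"
    m = snp.mother_allele
    if not call.contains(m):
        return "no_call"  # Mendelian-inconsistent with the mother
    paternal = call.other_allele(m)
    if paternal == snp.hap1_allele:
        return "hap1"
    if paternal == snp.hap2_allele:
        return "hap2"
    return "no_call"


def classify_embryo(
    embryo: SampleCalls,
    phased: PhasedPaternalHaplotypes,
    thresholds: VerdictThresholds = VerdictThresholds(),
) -> LinkageVerdict:
    """Vote each phased SNP and call the embryo high-risk / low-risk.

    The verdict is the majority haplotype over all usable votes,
    subject to the evidence thresholds; a disagreement between the
    upstream and downstream flank majorities raises the recombination
    flag and forces an inconclusive verdict.
    """
    votes: dict[str, str] = {}
    by_side: dict[str, list[str]] = {"upstream": [], "downstream": [], "inside": []}
    for snp in phased:
        v = _vote_for_snp(snp, embryo.get(snp.site))
        votes[snp.site.rsid] = v
        if v != "no_call":
            by_side[snp.side].append(v)

    called = [v for vs in by_side.values() for v in vs]
    n = len(called)
    n_hap1 = sum(1 for v in called if v == "hap1")
    majority = "hap1" if n_hap1 * 2 > n else ("hap2" if n_hap1 * 2 < n else None)

    def _consistency(side: str) -> Optional[float]:
        vs = by_side[side]
        if not vs or majority is None:
            return None
        return sum(1 for v in vs if v == majority) / len(vs)

    def _side_majority(side: str) -> Optional[str]:
        vs = by_side[side]
        if not vs:
            return None
        k = sum(1 for v in vs if v == "hap1")
        return "hap1" if 2 * k > len(vs) else ("hap2" if 2 * k < len(vs) else None)

    up_m, down_m = _side_majority("upstream"), _side_majority("downstream")
    recomb = up_m is not None and down_m is not None and up_m != down_m

    status = INCONCLUSIVE
    if (majority is not None
            and not recomb
            and n >= thresholds.min_votes
            and len(by_side["upstream"]) >= thresholds.min_votes_per_flank
            and len(by_side["downstream"]) >= thresholds.min_votes_per_flank
            and sum(1 for v in called if v == majority) / n
            >= thresholds.min_consistency):
        status = HIGH_RISK if majority == "hap1" else LOW_RISK

    return LinkageVerdict(
        status=status,
        votes=votes,
        upstream_consistency=_consistency("upstream"),
        downstream_consistency=_consistency("downstream"),
        inside_consistency=_consistency("inside"),
        recombination_flag=recomb,
        n_informative_used=n,
    )


def linkage_report(verdicts: dict[str, LinkageVerdict]) -> pd.DataFrame:
    """One row per embryo: status, vote tallies, consistencies, flags."""
    rows = []
    for embryo_id, v in verdicts.items():
        tally = {"hap1": 0, "hap2": 0, "no_call": 0}
        for vote in v.votes.values():
            tally[vote] += 1
        rows.append({
            "embryo": embryo_id,
            "status": v.status,
            "n_votes_hap1": tally["hap1"],
            "n_votes_hap2": tally["hap2"],
            "n_no_call": tally["no_call"],
            "n_informative_used": v.n_informative_used,
            "upstream_consistency": v.upstream_consistency,
            "downstream_consistency": v.downstream_consistency,
            "inside_consistency": v.inside_consistency,
            "recombination_flag": v.recombination_flag,
        })
    columns = ["embryo", "status", "n_votes_hap1", "n_votes_hap2",
               "n_no_call", "n_informative_used", "upstream_consistency",
               "downstream_consistency", "inside_consistency",
               "recombination_flag"]
    return pd.DataFrame(rows, columns=columns)
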