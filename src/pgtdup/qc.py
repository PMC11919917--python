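"""Depth and allele-fraction QC for shallow-coverage genotype calls.

Whole-genome-amplified biopsy material is genotyped at a few-fold mean
depth, so raw calls carry substantial sampling noise and allele-dropout
artefacts.  Before linkage analysis, every observation is re-called from
its allele depths with a single decision rule on the alt-allele
fraction ``af``:

* ``depth < min_depth``            -> filtered (too shallow to call)
* ``af <= 0.1``                    -> homozygous reference
* ``af >= 0.9``                    -> homozygous alternate
* ``0.2 <= af <= 0.8``             -> heterozygous
* ``af`` in (0.1, 0.2) or (0.8, 0.9) -> filtered (ambiguous dosage)

The two open gaps are where neither a confident homozygote (outside
(0.1, 0.9)) nor a confident heterozygote (inside [0.2, 0.8]) is
supported; such sites are discarded rather than guessed.  The rule
partitions [0, 1]: every allele fraction maps to exactly one outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genotypes import NO_CALL, GenotypeCall, SampleCalls, SnpSite

__all__ = ["QcThresholds", "call_genotype", "apply_qc", "QcSummary"]


@dataclass(frozen=True)
class QcThresholds:
    """Filtering thresholds for depth/allele-fraction genotype QC.

    Defaults: minimum depth 4 reads; heterozygotes accepted only with
    allele fraction in [0.2, 0.8]; homozygotes accepted only with allele
    fraction outside (0.1, 0.9).
    """

    min_depth: int = 4
    het_af_low: float = 0.2
    het_af_high: float = 0.8
    hom_af_low: float = 0.1
    hom_af_high: float = 0.9

    def __post_init__(self) -> None:
        bounds = (self.hom_af_low, self.het_af_low,
                  self.het_af_high, self.hom_af_high)
        if not all(0.0 <= b <= 1.0 for b in bounds):
            raise ValueError(f"af thresholds must lie in [0,1]: {bounds}")
        if not (self.hom_af_low <= self.het_af_low
                <= self.het_af_high <= self.hom_af_high):
            raise ValueError(
                "het af range must nest inside the hom exclusion band: "
                f"{bounds}"
            )
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")


def call_genotype(
    site: SnpSite,
    ref_depth: int,
    alt_depth: int,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeCall, str]:
    """Call a genotype from allele depths; returns (call, rule).

    ``rule`` names the branch taken: ``hom_ref``, ``het``, ``hom_alt``,
    ``low_depth`` or ``ambiguous_af`` (the latter two yield a no-call).
    All-zero depth is a no-call, not an error.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("negative allele depth")
    depths = {site.ref_allele: int(ref_depth), site.alt_allele: int(alt_depth)}
    total = ref_depth + alt_depth
    if total == 0 or total < thresholds.min_depth:
        return GenotypeCall(alleles=None, depth_per_allele=depths), "low_depth"
    af = alt_depth / total
    if af <= thresholds.hom_af_low:
        gt = (site.ref_allele, site.ref_allele)
        rule = "hom_ref"
    elif af >= thresholds.hom_af_high:
        gt = (site.alt_allele, site.alt_allele)
        rule = "hom_alt"
    elif thresholds.het_af_low <= af <= thresholds.het_af_high:
        gt = (site.ref_allele, site.alt_allele)
        rule = "het"
    else:
        return GenotypeCall(alleles=None, depth_per_allele=depths), "ambiguous_af"
    return GenotypeCall(alleles=gt, depth_per_allele=depths), rule


@dataclass
class QcSummary:
    n_input: int = 0
    n_pass: int = 0
    filtered_by_rule: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict[str, int]:
        row = {"n_input": self.n_input, "n_pass": self.n_pass}
        for rule in ("low_depth", "ambiguous_af", "no_depth"):
            row[f"filtered_{rule}"] = self.filtered_by_rule.get(rule, 0)
        return row


def apply_qc(
    calls: SampleCalls,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[SampleCalls, QcSummary]:
    """Re-call a sample's genotypes from depths and drop failing sites.

    Sites without depth information (e.g. fixture tables) are kept
    as-is: there is nothing to re-call them from.  Sites whose depths
    fail the thresholds are removed from the returned map; the summary
    counts how many each rule removed.
    """
    out: SampleCalls = {}
    summary = QcSummary()
    for site, call in calls.items():
        summary.n_input += 1
        if call.depth_per_allele is None:
            if call.is_call:
                out[site] = call
                summary.n_pass += 1
            else:
                summary.filtered_by_rule["no_depth"] = (
                    summary.filtered_by_rule.get("no_depth", 0) + 1)
            continue
        ref_d = call.depth_per_allele.get(site.ref_allele, 0)
        alt_d = call.depth_per_allele.get(site.alt_allele, 0)
        recalled, rule = call_genotype(site, ref_d, alt_d, thresholds)
        if recalled.is_call:
            out[site] = recalled
            summary.n_pass += 1
        else:
            summary.filtered_by_rule[rule] = (
                summary.filtered_by_rule.get(rule, 0) + 1)
    return out, summary
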