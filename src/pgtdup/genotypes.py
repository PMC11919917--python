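"""SNP sites and diploid genotype calls.

A genotype is an *unordered* pair of allele symbols: ``C/G`` and ``G/C``
are the same call, because phase is what the linkage analysis infers, not
what the caller provides.  A no-call is a distinct state (``alleles is
None``), never an empty genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = ["SnpSite", "GenotypeCall", "NO_CALL", "CallMap", "SampleCalls"]


@dataclass(frozen=True, order=True)
class SnpSite:
    """A biallelic SNP marker."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele and self.ref_allele != "N":
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype with optional per-allele read depths.

    ``alleles`` is an unordered pair (stored sorted) or ``None`` for a
    no-call.  ``depth_per_allele`` maps allele symbol -> read count when
    sequencing evidence is available (Table-style fixtures carry none).
    """

    alleles: Optional[tuple[str, str]] = None
    depth_per_allele: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def from_string(cls, text: str) -> "GenotypeCall":
        """Parse ``"C/G"`` or the no-call spellings ``"./"``, ``"./."``."""
        text = text.strip()
        if text in ("./", "./.", ".", ""):
            return NO_CALL
        parts = text.split("/")
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"unparseable genotype {text!r}")
        return cls(alleles=(parts[0], parts[1]))

    @property
    def is_call(self) -> bool:
        return self.alleles is not None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    @property
    def hom_allele(self) -> str:
        if not self.is_hom:
            raise ValueError("hom_allele requested on a non-homozygous call")
        return self.alleles[0]

    @property
    def total_depth(self) -> Optional[int]:
        if self.depth_per_allele is None:
            return None
        return int(sum(self.depth_per_allele.values()))

    def alt_fraction(self, site: SnpSite) -> Optional[float]:
        """Fraction of reads carrying the site's alt allele, if depths exist."""
        if self.depth_per_allele is None:
            return None
        total = self.total_depth
        if not total:
            return None
        return self.depth_per_allele.get(site.alt_allele, 0) / total

    def contains(self, allele: str) -> bool:
        return self.alleles is not None and allele in self.alleles

    def other_allele(self, allele: str) -> str:
        """The partner of ``allele`` in this genotype (itself if homozygous)."""
        if self.alleles is None:
            raise ValueError("other_allele on a no-call")
        a, b = self.alleles
        if allele == a:
            return b
        if allele == b:
            return a
        raise ValueError(f"allele {allele!r} not in genotype {a}/{b}")

    def __str__(self) -> str:
        if self.alleles is None:
            return "./"
        return f"{self.alleles[0]}/{self.alleles[1]}"


NO_CALL = GenotypeCall(alleles=None)

# A sample's genotypes over a SNP panel, and a cohort of such samples.
SampleCalls = dict[SnpSite, GenotypeCall]
CallMap = dict[str, SampleCalls]
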