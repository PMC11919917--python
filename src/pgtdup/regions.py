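"""Genomic intervals and the GRCh37 coordinate frame.

All coordinates in this package are 1-based and inclusive at both ends
(the VCF / clinical-report convention).  The only place 0-based half-open
coordinates appear is BED export, where the conversion happens at the
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GenomicRegion",
    "RegionParseError",
    "parse_region",
    "format_region",
    "GRCH37_AUTOSOME_SIZES",
    "GRCH37_CHROM_SIZES",
]

# GRCh37/hg19 chromosome lengths (bp), autosomes plus X/Y.
GRCH37_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

GRCH37_AUTOSOME_SIZES: dict[str, int] = {
    c: n for c, n in GRCH37_CHROM_SIZES.items() if c not in ("chrX", "chrY")
}


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A closed genomic interval ``chrom:start-end`` (1-based, inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start > end in {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlap_bp(self, other: "GenomicRegion") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def to_bed_fields(self) -> tuple[str, int, int]:
        """(chrom, 0-based start, exclusive end) for BED output."""
        return self.chrom, self.start - 1, self.end

    def __str__(self) -> str:
        return format_region(self)


_REGION_RE = re.compile(r"^(?P<chrom>[^\s:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region(text: str) -> GenomicRegion:
    """Parse ``"chr1:146305863-147992406"`` into a :class:`GenomicRegion`.

    Thousands separators in the coordinates are tolerated
    (``"chr1:146,305,863-147,992,406"``).  Reversed bounds or anything
    that does not match ``<chrom>:<start>-<end>`` raise
    :class:`RegionParseError` naming the offending token.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    chrom = m.group("chrom")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1:
        raise RegionParseError(f"start coordinate must be >= 1 in {text!r}")
    if start > end:
        raise RegionParseError(
            f"start > end in region {text!r} ({start} > {end})"
        )
    return GenomicRegion(chrom, start, end)


def format_region(region: GenomicRegion) -> str:
    """Canonical ``chrom:start-end`` string (no thousands separators)."""
    return f"{region.chrom}:{region.start}-{region.end}"
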