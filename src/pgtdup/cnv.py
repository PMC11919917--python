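"""Binned copy-number analysis with circular binary segmentation.

Shallow whole-genome read counts are tallied in fixed grid bins
(1 Mb for genome-wide aneuploidy screening, 400 kb for the targeted
small-CNV mode), normalized to the genome-wide median bin so a diploid
bin has copy-ratio 1 and estimated copy number 2, segmented per
chromosome with circular binary segmentation (CBS), and thresholded
into gain/loss calls.

CBS recursively finds the arc ``(i, j]`` of a chromosome's bin sequence
that maximizes a two-sample z statistic between the arc and its
complement, accepts the split when a permutation test drives its
p-value below ``alpha``, and recurses on the resulting pieces.
Adjacent segments whose means differ by less than a pruning epsilon are
re-merged.  Statistics are computed on untransformed copy ratios.

Reporting conventions: the bin grid is anchored at coordinate 0; a
call's size is the number of grid bins involved times the bin size, and
in targeted mode only bins fully contained in the target region count
toward the reported event — a deliberately conservative inner-bin
convention, since partially overlapping boundary bins carry diluted
signal and an uncertain breakpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicRegion

__all__ = [
    "Segment",
    "CnvCall",
    "CbsParams",
    "make_bin_grid",
    "normalize_bins",
    "max_arc_statistic",
    "cbs_segment",
    "segment_genome",
    "call_cnvs",
    "estimate_target_cn",
    "round_cn",
]

GAIN_CN_THRESHOLD = 2.5
LOSS_CN_THRESHOLD = 1.5
MIN_SIZE_GENOME_BP = 4_000_000   # conventional aneuploidy-screen floor
MIN_SIZE_TARGET_BP = 1_000_000   # targeted small-CNV floor


@dataclass(frozen=True)
class CbsParams:
    """CBS tuning: split acceptance level, permutations, segment pruning."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_bins: int = 2
    merge_epsilon: float = 0.05   # on the copy-ratio scale

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")


@dataclass
class Segment:
    """A run of bins with a common mean copy ratio."""

    chrom: str
    first_bin: int        # index within the chromosome's bin sequence
    last_bin: int         # inclusive
    start: int            # genomic, 1-based inclusive
    end: int
    mean_ratio: float
    n_bins: int


@dataclass
class CnvCall:
    """A thresholded gain/loss call derived from a segment."""

    region: GenomicRegion
    type: str             # "gain" | "loss"
    cn: int
    size_bp: int
    n_bins: int
    mean_ratio: float
    whole_chrom: bool = False

    @property
    def label(self) -> str:
        """Compact clinical-style label (``+21`` for whole-chromosome)."""
        chrom_num = self.region.chrom.removeprefix("chr")
        if self.whole_chrom:
            return ("+" if self.type == "gain" else "-") + chrom_num
        kind = "dup" if self.type == "gain" else "del"
        mb = self.size_bp / 1e6
        return (f"{kind}({chrom_num})"
                f"({self.region.start / 1e6:.2f}-{self.region.end / 1e6:.2f}Mb)"
                f"(~{mb:.2f} Mb)")


# ---------------------------------------------------------------------------
# Binning and normalization

def make_bin_grid(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Fixed-width bins anchored at coordinate 0 (1-based inclusive rows).

    The last bin of each chromosome is truncated at the chromosome end.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        n = math.ceil(size / bin_size)
        for k in range(n):
            rows.append((chrom, k * bin_size + 1, min((k + 1) * bin_size, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def normalize_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Add ``ratio`` (count / median autosomal count) and ``cn`` columns.

    The baseline is the sample's own genome-wide median bin count over
    autosomal bins, so a predominantly diploid genome normalizes to
    ratio 1.  A zero baseline (empty or unsequenced input) is an error.
    """
    if bins.empty:
        raise ValueError("no bins to normalize")
    autosomal = ~bins["chrom"].isin(("chrX", "chrY", "X", "Y"))
    if not autosomal.any():
        raise ValueError("no autosomal bins; cannot set a diploid baseline")
    baseline = float(bins.loc[autosomal, "count"].median())
    if baseline <= 0:
        raise ValueError("median bin count is zero; cannot normalize")
    out = bins.copy()
    out["ratio"] = out["count"] / baseline
    out["cn"] = 2.0 * out["ratio"]
    return out


# ---------------------------------------------------------------------------
# Circular binary segmentation

def _bridge(x: np.ndarray) -> np.ndarray:
    """Centered partial-sum process Q with Q[0] = Q[n] = 0."""
    n = x.size
    p = np.concatenate(([0.0], np.cumsum(x)))
    return p - np.arange(n + 1) * (p[-1] / n)


def max_arc_statistic(
    values: Sequence[float], min_bins: int = 1
) -> tuple[float, int, int]:
    """Maximal two-sample z statistic over all arcs of ``values``.

    Considers every arc ``(i, j]`` (``min_bins <= j - i <= n - min_bins``)
    and returns ``(stat, i, j)`` where ``stat`` is
    ``|mean(arc) - mean(complement)| / (sd * sqrt(1/k + 1/(n-k)))``
    with ``sd`` the global standard deviation of ``values``.  Via the
    centered partial-sum process this reduces to
    ``|Q[j] - Q[i]| * sqrt(n) / (sd * sqrt(k (n-k)))``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_bins:
        return 0.0, 0, n
    sd = float(x.std())
    if sd == 0.0:
        return 0.0, 0, n
    q = _bridge(x)
    best = (0.0, 0, n)
    for k in range(min_bins, n - min_bins + 1):
        d = np.abs(q[k:] - q[: n + 1 - k])
        i = int(np.argmax(d))
        stat = d[i] * math.sqrt(n) / (sd * math.sqrt(k * (n - k)))
        if stat > best[0]:
            best = (float(stat), i, i + k)
    return best


def _perm_max_stats(
    x: np.ndarray, n_draws: int, min_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Max arc statistic for ``n_draws`` independent permutations of x."""
    n = x.size
    sd = float(x.std())
    xb = np.tile(x.astype(np.float32), (n_draws, 1))
    xb = rng.permuted(xb, axis=1)
    p = np.concatenate(
        [np.zeros((n_draws, 1), np.float32), np.cumsum(xb, axis=1)], axis=1)
    q = p - np.arange(n + 1, dtype=np.float32) * (p[:, -1:] / n)
    best = np.zeros(n_draws, np.float32)
    for k in range(min_bins, n - min_bins + 1):
        d = np.abs(q[:, k:] - q[:, : n + 1 - k]).max(axis=1)
        np.maximum(best, d / np.float32(math.sqrt(k * (n - k))), out=best)
    return best * np.float32(math.sqrt(n) / sd)


def _split_significant(
    x: np.ndarray,
    stat_obs: float,
    params: CbsParams,
    rng: np.random.Generator,
) -> bool:
    """Permutation test for one candidate split, with early rejection.

    The split is accepted when ``(1 + exceedances) / (1 + n_perm) <
    alpha``.  Permutations are drawn in chunks; as soon as enough
    exceedances have accumulated to make that impossible, the test
    stops early (the decision is identical to running all
    permutations).
    """
    reject_at = params.alpha * (1 + params.n_perm) - 1  # accept iff count < this
    count = 0
    drawn = 0
    while drawn < params.n_perm:
        chunk = min(128, params.n_perm - drawn)
        stats = _perm_max_stats(x, chunk, params.min_bins, rng)
        count += int((stats >= stat_obs).sum())
        drawn += chunk
        if count >= reject_at:
            return False
    return (1 + count) / (1 + params.n_perm) < params.alpha


def cbs_segment(
    values: Sequence[float],
    params: CbsParams = CbsParams(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[int, int, float]]:
    """Segment one chromosome's copy-ratio vector.

    Returns ``(first, last, mean)`` tuples (inclusive bin indices) that
    partition the input.  Deterministic for a fixed seed/generator.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value vector")
    if rng is None:
        rng = np.random.default_rng(seed)

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * params.min_bins or np.ptp(seg) == 0.0:
            return
        stat, i, j = max_arc_statistic(seg, params.min_bins)
        if stat == 0.0 or not _split_significant(seg, stat, params, rng):
            return
        cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
        if not cuts:
            return
        prev = lo
        for c in cuts + [hi]:
            recurse(prev, c)
            prev = c
        boundaries.extend(cuts)

    recurse(0, x.size)
    edges = sorted({0, x.size, *boundaries})
    segments = [(a, b - 1, float(x[a:b].mean()))
                for a, b in zip(edges[:-1], edges[1:])]
    return _merge_segments(x, segments, params.merge_epsilon)


def _merge_segments(
    x: np.ndarray,
    segments: list[tuple[int, int, float]],
    epsilon: float,
) -> list[tuple[int, int, float]]:
    """Greedily merge adjacent segments whose means differ by < epsilon."""
    merged = list(segments)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        diffs = [abs(merged[t + 1][2] - merged[t][2])
                 for t in range(len(merged) - 1)]
        t = int(np.argmin(diffs))
        if diffs[t] < epsilon:
            a, b = merged[t], merged[t + 1]
            lo, hi = a[0], b[1]
            merged[t:t + 2] = [(lo, hi, float(x[lo:hi + 1].mean()))]
            changed = True
    return merged


def segment_genome(
    bins: pd.DataFrame,
    params: CbsParams = CbsParams(),
    seed: Optional[int] = None,
) -> list[Segment]:
    """Run CBS per chromosome over a normalized bin table."""
    if "ratio" not in bins.columns:
        raise ValueError("bins must be normalized first (missing 'ratio')")
    rng = np.random.default_rng(seed)
    out: list[Segment] = []
    for chrom in bins["chrom"].unique():
        sub = bins[bins["chrom"] == chrom].reset_index(drop=True)
        for first, last, mean in cbs_segment(sub["ratio"].to_numpy(),
                                             params, rng=rng):
            out.append(Segment(
                chrom=chrom,
                first_bin=first,
                last_bin=last,
                start=int(sub.loc[first, "start"]),
                end=int(sub.loc[last, "end"]),
                mean_ratio=mean,
                n_bins=last - first + 1,
            ))
    return out


# ---------------------------------------------------------------------------
# Calling

def round_cn(cn: float) -> int:
    """Round to the nearest integer copy number, ties away from diploid."""
    if cn >= 2.0:
        return int(math.floor(cn + 0.5))
    return int(math.ceil(cn - 0.5))


def call_cnvs(
    bins: pd.DataFrame,
    segments: list[Segment],
    mode: str = "genome",
    region: Optional[GenomicRegion] = None,
    gain_threshold: float = GAIN_CN_THRESHOLD,
    loss_threshold: float = LOSS_CN_THRESHOLD,
) -> list[CnvCall]:
    """Threshold segments into gain/loss calls at the mode's size floor.

    ``genome`` mode (1 Mb bins) keeps only events >= 4 Mb — the
    conventional aneuploidy-screen report floor; ``target`` mode
    (400 kb bins) keeps events >= 1 Mb and requires the target
    ``region``: a call overlapping it is reported as the span of the
    segment's grid bins fully contained in the region.  A segment
    covering every bin of its chromosome is a whole-chromosome event.
    """
    if mode not in ("genome", "target"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "target" and region is None:
        raise ValueError("target mode requires the target region")
    min_size = MIN_SIZE_GENOME_BP if mode == "genome" else MIN_SIZE_TARGET_BP

    def state(seg: Segment) -> str:
        cn_mean = 2.0 * seg.mean_ratio
        if cn_mean >= gain_threshold:
            return "gain"
        if cn_mean <= loss_threshold:
            return "loss"
        return "neutral"

    # a call is a maximal run of adjacent same-state segments: CBS may
    # cut a single event into pieces at noisy boundaries, but the event
    # is the contiguous non-neutral run
    runs: list[tuple[str, list[Segment]]] = []
    for seg in segments:
        s = state(seg)
        if (runs and s != "neutral" and runs[-1][0] == s
                and runs[-1][1][-1].chrom == seg.chrom
                and runs[-1][1][-1].last_bin + 1 == seg.first_bin):
            runs[-1][1].append(seg)
        else:
            runs.append((s, [seg]))

    calls: list[CnvCall] = []
    for kind, group in runs:
        if kind == "neutral":
            continue
        chrom = group[0].chrom
        n_bins = sum(g.n_bins for g in group)
        mean_ratio = sum(g.mean_ratio * g.n_bins for g in group) / n_bins
        cn_mean = 2.0 * mean_ratio
        seg_start, seg_end = group[0].start, group[-1].end
        chrom_bins = bins[bins["chrom"] == chrom]
        whole = n_bins == len(chrom_bins)
        span = GenomicRegion(chrom, seg_start, seg_end)
        if (mode == "target" and not whole
                and region is not None and span.overlap_bp(region) > 0):
            inner = chrom_bins[
                (chrom_bins["start"] >= max(seg_start, region.start))
                & (chrom_bins["end"] <= min(seg_end, region.end))
            ]
            if len(inner):
                span = GenomicRegion(chrom,
                                     int(inner["start"].min()),
                                     int(inner["end"].max()))
                n_bins = len(inner)
        size_bp = span.length_bp
        if not whole and size_bp < min_size:
            continue
        calls.append(CnvCall(
            region=span,
            type=kind,
            cn=round_cn(cn_mean),
            size_bp=size_bp,
            n_bins=n_bins,
            mean_ratio=mean_ratio,
            whole_chrom=whole,
        ))
    return calls


def estimate_target_cn(
    bins: pd.DataFrame, region: GenomicRegion
) -> tuple[int, float]:
    """Copy number of the target region from its fully contained bins.

    Returns ``(round(2 x mean ratio), mean ratio)`` over the grid bins
    lying entirely inside the region; ties round away from diploid.
    """
    if "ratio" not in bins.columns:
        raise ValueError("bins must be normalized first (missing 'ratio')")
    inner = bins[
        (bins["chrom"] == region.chrom)
        & (bins["start"] >= region.start)
        & (bins["end"] <= region.end)
    ]
    if inner.empty:
        raise ValueError(
            f"no bin is fully contained in {region}; "
            "re-bin with a smaller bin size"
        )
    mean_ratio = float(inner["ratio"].mean())
    return round_cn(2.0 * mean_ratio), mean_ratio
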