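"""Genome-wide differentiation mapping between two pools.

The scan calls biallelic SNPs from nucleotide counts, applies depth and
minor-allele-frequency filters, computes the absolute allele frequency
difference (AFD) per SNP, smooths it over sliding windows, ranks top
SNPs, and extracts candidate regions around them.

AFD between two pools is half the L1 distance between their
allele-frequency vectors, which reduces to |p1 - p2| at biallelic sites;
it ranges over [0, 1] with 1 meaning fixed for alternative alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .poolio import BASES, SiteBlock, SiteCounts

logger = logging.getLogger(__name__)

SNP_COLUMNS = [
    "chrom",
    "pos",
    "major",
    "minor",
    "depth_1",
    "depth_2",
    "freq_1",
    "freq_2",
    "afd",
]


@dataclass
class SnpRecord:
    """A retained biallelic SNP with per-pool depths/frequencies and AFD.

    ``freq_1``/``freq_2`` are the minor-allele frequencies in the two
    pools; depths count reads at the two retained alleles only.
    """

    chrom: str
    pos: int
    major: str
    minor: str
    depth_1: int
    depth_2: int
    freq_1: float
    freq_2: float
    afd: float


@dataclass
class WindowRecord:
    """Sliding-window average of per-SNP AFD (1-based closed bounds)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_afd: float


@dataclass
class Region:
    """Candidate interval centred on an anchor SNP or cluster midpoint."""

    chrom: str
    start: int
    end: int
    anchor_pos: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(f"bad region bounds [{self.start}, {self.end}]")


@dataclass
class ScanResult:
    """Output of :func:`run_scan`: the SNP table and the genome-wide median AFD.

    ``median_afd`` is None when no SNP survives; the lower median is used
    for even counts.
    """

    snps: pd.DataFrame
    median_afd: float | None


def compute_afd(freqs_1: Sequence[float], freqs_2: Sequence[float]) -> float:
    """Half the L1 distance between two allele-frequency vectors.

    Both vectors must use the same allele ordering and sum to 1 (within
    1e-9).  Symmetric in its arguments; 0 for identical vectors, 1 for a
    fixed difference.
    """
    f1 = np.asarray(freqs_1, dtype=float)
    f2 = np.asarray(freqs_2, dtype=float)
    if f1.shape != f2.shape:
        raise ValidationError(
            f"frequency vectors differ in length: {f1.shape} vs {f2.shape}"
        )
    for name, vec in (("freqs_1", f1), ("freqs_2", f2)):
        total = float(vec.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"{name} sums to {total}, expected 1")
        if (vec < 0).any():
            raise ValidationError(f"{name} has negative entries")
    return 0.5 * float(np.abs(f1 - f2).sum())


def call_biallelic(
    site: SiteCounts,
    pools: tuple[int, int] = (0, 1),
    error_floor: float = 0.01,
) -> SnpRecord | None:
    """Identify the major/minor allele pair at a site from two pools.

    Counts are summed across the two pools; the two highest-count bases
    (ties broken in A<C<G<T order) are retained.  Sites where any third
    base exceeds ``error_floor`` of the combined depth are rejected, as
    are monomorphic sites and sites where either pool has no reads at the
    retained alleles.  Returns None on rejection.
    """
    if not 0.0 <= error_floor <= 0.05:
        raise ConfigError(f"error_floor must be in [0, 0.05], got {error_floor}")
    i, j = pools
    c1 = site.counts[i]
    c2 = site.counts[j]
    combined = c1 + c2
    total = int(combined.sum())
    if total == 0:
        return None
    order = sorted(range(4), key=lambda b: (-combined[b], b))
    maj, mino = order[0], order[1]
    if combined[mino] == 0:
        return None  # monomorphic
    third_max = max(int(combined[order[2]]), int(combined[order[3]]))
    if third_max > error_floor * total:
        return None
    d1 = int(c1[maj] + c1[mino])
    d2 = int(c2[maj] + c2[mino])
    if d1 == 0 or d2 == 0:
        return None
    f1 = c1[mino] / d1
    f2 = c2[mino] / d2
    return SnpRecord(
        chrom=site.chrom,
        pos=site.pos,
        major=BASES[maj],
        minor=BASES[mino],
        depth_1=d1,
        depth_2=d2,
        freq_1=f1,
        freq_2=f2,
        afd=abs(f1 - f2),
    )


def passes_filters(
    snp: SnpRecord,
    depth_min: int,
    depth_max: int,
    maf_min: float,
) -> bool:
    """Depth and pooled-MAF filter.

    Both pools must have retained-allele depth within [depth_min,
    depth_max] (bounds inclusive), and the minor-allele frequency
    computed from the summed read counts of both pools must be at least
    ``maf_min``.
    """
    if depth_min > depth_max:
        raise ConfigError(f"depth_min {depth_min} > depth_max {depth_max}")
    if not (depth_min <= snp.depth_1 <= depth_max):
        return False
    if not (depth_min <= snp.depth_2 <= depth_max):
        return False
    # recover integer minor counts to keep boundary comparisons exact
    minor_count = round(snp.freq_1 * snp.depth_1) + round(snp.freq_2 * snp.depth_2)
    return minor_count / (snp.depth_1 + snp.depth_2) >= maf_min


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for c, p in zip(chrom, pos):
        if c != prev_chrom:
            if c in seen:
                raise ValidationError(
                    f"input not sorted: chromosome {c} re-appears at position {p}"
                )
            seen.add(c)
            prev_chrom, prev_pos = c, int(p)
            continue
        if p <= prev_pos:
            raise ValidationError(
                f"input not sorted at {c}:{p} (previous position {prev_pos})"
            )
        prev_pos = int(p)


def run_scan(
    sites: Iterable[SiteCounts] | SiteBlock,
    pool_pair: tuple[int, int] = (0, 1),
    depth_min: int = 40,
    depth_max: int = 130,
    maf_min: float = 0.2,
    error_floor: float = 0.01,
) -> ScanResult:
    """Run the per-SNP pipeline over a sorted site stream.

    Equivalent to applying :func:`call_biallelic` then
    :func:`passes_filters` per site, but vectorised.  Also reports the
    genome-wide (lower) median AFD of the retained SNPs.
    """
    if depth_min > depth_max:
        raise ConfigError(f"depth_min {depth_min} > depth_max {depth_max}")
    if not 0.0 <= error_floor <= 0.05:
        raise ConfigError(f"error_floor must be in [0, 0.05], got {error_floor}")
    block = sites if isinstance(sites, SiteBlock) else SiteBlock.from_sites(sites)
    if len(block) == 0:
        return ScanResult(snps=pd.DataFrame(columns=SNP_COLUMNS), median_afd=None)
    _check_sorted(block.chrom, block.pos)
    i, j = pool_pair
    c1 = block.counts[:, i, :]
    c2 = block.counts[:, j, :]
    combined = c1 + c2
    n = len(block)
    rows = np.arange(n)
    # descending count order; stable sort breaks ties by base index (A<C<G<T)
    order = np.argsort(-combined, axis=1, kind="stable")
    maj = order[:, 0]
    mino = order[:, 1]
    total = combined.sum(axis=1)
    third_max = np.maximum(combined[rows, order[:, 2]], combined[rows, order[:, 3]])
    d1 = c1[rows, maj] + c1[rows, mino]
    d2 = c2[rows, maj] + c2[rows, mino]
    called = (
        (total > 0)
        & (combined[rows, mino] > 0)
        & (third_max <= error_floor * total)
        & (d1 > 0)
        & (d2 > 0)
    )
    m1 = c1[rows, mino]
    m2 = c2[rows, mino]
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(d1 > 0, m1 / np.maximum(d1, 1), 0.0)
        f2 = np.where(d2 > 0, m2 / np.maximum(d2, 1), 0.0)
        maf = (m1 + m2) / np.maximum(d1 + d2, 1)
    keep = (
        called
        & (d1 >= depth_min)
        & (d1 <= depth_max)
        & (d2 >= depth_min)
        & (d2 <= depth_max)
        & (maf >= maf_min)
    )
    base_chars = np.array(list(BASES))
    snps = pd.DataFrame(
        {
            "chrom": block.chrom[keep],
            "pos": block.pos[keep],
            "major": base_chars[maj[keep]],
            "minor": base_chars[mino[keep]],
            "depth_1": d1[keep],
            "depth_2": d2[keep],
            "freq_1": f1[keep],
            "freq_2": f2[keep],
            "afd": np.abs(f1[keep] - f2[keep]),
        }
    )
    median = lower_median(snps["afd"].to_numpy()) if len(snps) else None
    logger.info("scan retained %d SNPs (median AFD %s)", len(snps), median)
    return ScanResult(snps=snps, median_afd=median)


def lower_median(values: np.ndarray) -> float:
    """Lower median: the element at index (n-1)//2 of the sorted values."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValidationError("median of empty array")
    return float(values[(values.size - 1) // 2])


def smooth_windows(
    snps: pd.DataFrame,
    width: int = 40_000,
    step: int = 20_000,
    min_snps: int = 6,
) -> pd.DataFrame:
    """Average per-SNP AFD over sliding windows anchored at position 1.

    Windows are [1, width], [1+step, width+step], ...; a SNP belongs to a
    window when start <= pos <= end.  Windows with fewer than
    ``min_snps`` SNPs are dropped.  Returns columns chrom, start, end,
    n_snps, mean_afd.
    """
    if width < step:
        raise ConfigError(f"window width {width} < step {step}")
    if width % step != 0:
        raise ConfigError(f"window width {width} is not a multiple of step {step}")
    if min_snps < 1:
        raise ConfigError(f"min_snps must be >= 1, got {min_snps}")
    out_frames = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        afd = sub["afd"].to_numpy(dtype=float)
        if pos.size == 0:
            continue
        starts = np.arange(1, pos[-1] + 1, step, dtype=np.int64)
        ends = starts + width - 1
        left = np.searchsorted(pos, starts, side="left")
        right = np.searchsorted(pos, ends, side="right")
        n_in = right - left
        csum = np.concatenate([[0.0], np.cumsum(afd)])
        with np.errstate(invalid="ignore"):
            means = (csum[right] - csum[left]) / np.maximum(n_in, 1)
        keep = n_in >= min_snps
        out_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": ends[keep],
                    "n_snps": n_in[keep],
                    "mean_afd": means[keep],
                }
            )
        )
    if not out_frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "mean_afd"])
    return pd.concat(out_frames, ignore_index=True)


def top_snps(snps: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k highest-AFD SNPs, ties broken by (chrom, pos) ascending.

    A tie crossing the k-th rank is broken (exactly k returned) with a
    logged note; k larger than the table returns the whole table with a
    warning.
    """
    if k <= 0:
        raise ConfigError(f"k must be positive, got {k}")
    if len(snps) == 0:
        raise ValidationError("top_snps on an empty SNP table")
    ranked = snps.sort_values(
        ["afd", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if k > len(ranked):
        logger.warning("k=%d exceeds table size %d; returning all", k, len(ranked))
        return ranked
    if k < len(ranked) and ranked["afd"].iloc[k - 1] == ranked["afd"].iloc[k]:
        logger.info(
            "AFD tie at rank %d (afd=%g) broken by genomic order",
            k,
            ranked["afd"].iloc[k - 1],
        )
    return ranked.head(k).reset_index(drop=True)


def candidate_regions(
    anchors: pd.DataFrame,
    span: int = 180_000,
    cluster_gap: int = 20_000,
) -> list[Region]:
    """Build candidate regions of ``span`` bp centred on anchor SNPs.

    Anchor SNPs on the same chromosome within ``cluster_gap`` of each
    other are merged into one cluster anchored at the midpoint of its
    outermost members.  Regions are clipped at position 1 and overlapping
    regions on a chromosome are merged.
    """
    if span <= 0 or cluster_gap < 0:
        raise ConfigError("span must be > 0 and cluster_gap >= 0")
    if len(anchors) == 0:
        return []
    half = span // 2
    regions: list[Region] = []
    ordered = anchors.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in ordered.groupby("chrom", sort=True):
        positions = sub["pos"].to_numpy(dtype=np.int64)
        # chain positions into clusters
        clusters: list[list[int]] = [[int(positions[0])]]
        for p in positions[1:]:
            if p - clusters[-1][-1] <= cluster_gap:
                clusters[-1].append(int(p))
            else:
                clusters.append([int(p)])
        chrom_regions: list[Region] = []
        for cluster in clusters:
            anchor = (cluster[0] + cluster[-1]) // 2
            chrom_regions.append(
                Region(
                    chrom=chrom,
                    start=max(1, anchor - half),
                    end=anchor + half,
                    anchor_pos=anchor,
                )
            )
        # merge overlapping regions
        merged: list[Region] = []
        for reg in chrom_regions:
            if merged and reg.start <= merged[-1].end:
                prev = merged[-1]
                merged[-1] = Region(
                    chrom=chrom,
                    start=prev.start,
                    end=max(prev.end, reg.end),
                    anchor_pos=(prev.anchor_pos + reg.anchor_pos) // 2,
                )
            else:
                merged.append(reg)
        regions.extend(merged)
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "anchor_pos": r.anchor_pos}
            for r in regions
        ],
        columns=["chrom", "start", "end", "anchor_pos"],
    )
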