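"""Cross-population allele panels and their frequencies.

Two panel constructions: SNPs fixed between the two scan pools (AFD
exactly 1), and high-AFD SNPs flanking a focal SNP within a region.
Each panel SNP is oriented to a "focal" allele — the allele more
frequent in the reduced-plating pool — whose frequency is then
tabulated in any number of additional population pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .poolio import BASE_INDEX, SiteBlock, SiteCounts
from .scan import Region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelSnp:
    chrom: str
    pos: int
    focal_allele: str
    other_allele: str


@dataclass
class AllelePanel:
    """Oriented SNP panel plus provenance of the orientation rule."""

    snps: list[PanelSnp]
    focal_definition: str
    source_scan: str = ""

    def __len__(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "focal_allele": s.focal_allele,
                    "other_allele": s.other_allele,
                }
                for s in self.snps
            ],
            columns=["chrom", "pos", "focal_allele", "other_allele"],
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, focal_definition: str = "", source_scan: str = ""
    ) -> "AllelePanel":
        snps = [
            PanelSnp(
                chrom=str(r.chrom),
                pos=int(r.pos),
                focal_allele=str(r.focal_allele),
                other_allele=str(r.other_allele),
            )
            for r in df.itertuples()
        ]
        return cls(snps=snps, focal_definition=focal_definition, source_scan=source_scan)


def _reduced_freq(row: pd.Series, reduced_pool: int) -> float:
    """Minor-allele frequency in the reduced-plating pool (1 or 2)."""
    if reduced_pool not in (1, 2):
        raise ValidationError(f"reduced_pool must be 1 or 2, got {reduced_pool}")
    return float(row["freq_1"] if reduced_pool == 1 else row["freq_2"])


def _orient(row: pd.Series, reduced_pool: int) -> PanelSnp:
    freq_red = _reduced_freq(row, reduced_pool)
    if freq_red == 0.5:
        raise ValidationError(
            f"cannot orient {row['chrom']}:{row['pos']}: reduced pool at exactly 0.5"
        )
    if freq_red > 0.5:
        focal, other = str(row["minor"]), str(row["major"])
    else:
        focal, other = str(row["major"]), str(row["minor"])
    return PanelSnp(
        chrom=str(row["chrom"]), pos=int(row["pos"]), focal_allele=focal, other_allele=other
    )


def _restrict(snps: pd.DataFrame, region: Region | None) -> pd.DataFrame:
    if region is None:
        return snps
    mask = (
        (snps["chrom"] == region.chrom)
        & (snps["pos"] >= region.start)
        & (snps["pos"] <= region.end)
    )
    return snps[mask]


def fixed_snp_panel(
    snps: pd.DataFrame,
    reduced_pool: int,
    region: Region | None = None,
    source_scan: str = "",
) -> AllelePanel:
    """Panel of SNPs fixed between the two pools (AFD exactly 1).

    The focal allele is the allele at frequency 1 in the reduced-plating
    pool.  An optional region restriction supports panels limited to a
    candidate interval.
    """
    sub = _restrict(snps, region)
    fixed = sub[sub["afd"] == 1.0]
    entries = []
    for _, row in fixed.iterrows():
        freq_red = _reduced_freq(row, reduced_pool)
        if freq_red == 1.0:
            focal, other = str(row["minor"]), str(row["major"])
        else:
            focal, other = str(row["major"]), str(row["minor"])
        entries.append(
            PanelSnp(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                focal_allele=focal,
                other_allele=other,
            )
        )
    return AllelePanel(
        snps=entries,
        focal_definition=f"allele at frequency 1 in pool {reduced_pool} (reduced plating)",
        source_scan=source_scan,
    )


def high_afd_panel(
    snps: pd.DataFrame,
    focal: tuple[str, int],
    region: Region,
    afd_min: float = 0.35,
    reduced_pool: int = 1,
    source_scan: str = "",
) -> AllelePanel:
    """The focal SNP plus all region SNPs with AFD >= ``afd_min``.

    The focal allele per SNP is the allele more frequent in the
    reduced-plating pool (an exact 0.5/0.5 cannot co-occur with the AFD
    threshold and raises).
    """
    chrom, pos = focal
    if chrom != region.chrom or not (region.start <= pos <= region.end):
        raise ValidationError(
            f"focal SNP {chrom}:{pos} lies outside region "
            f"{region.chrom}:{region.start}-{region.end}"
        )
    sub = _restrict(snps, region)
    focal_mask = (sub["chrom"] == chrom) & (sub["pos"] == pos)
    if not focal_mask.any():
        raise ValidationError(f"focal SNP {chrom}:{pos} not present in the scan table")
    selected = sub[(sub["afd"] >= afd_min) | focal_mask].sort_values(
        ["chrom", "pos"], kind="mergesort"
    )
    entries = [_orient(row, reduced_pool) for _, row in selected.iterrows()]
    return AllelePanel(
        snps=entries,
        focal_definition=(
            f"allele more frequent in pool {reduced_pool} (reduced plating); "
            f"focal SNP {chrom}:{pos}, flanking AFD >= {afd_min}"
        ),
        source_scan=source_scan,
    )


def panel_frequencies(
    panel: AllelePanel,
    pools: Mapping[str, Iterable[SiteCounts] | SiteBlock],
) -> pd.DataFrame:
    """Focal-allele frequency of each panel SNP in each population pool.

    Frequencies use only reads matching the two panel alleles; a missing
    site or zero panel-allele depth yields a missing value (logged).  A
    population with no coverage at any panel site is an error.
    """
    if not panel.snps:
        raise ValidationError("empty panel")
    rows = []
    for population, sites in pools.items():
        lookup: dict[tuple[str, int], np.ndarray] = {}
        wanted = {(s.chrom, s.pos) for s in panel.snps}
        for site in sites:
            key = (site.chrom, site.pos)
            if key in wanted:
                lookup[key] = site.counts.sum(axis=0)  # population pool: all columns
        any_covered = False
        for snp in panel.snps:
            counts = lookup.get((snp.chrom, snp.pos))
            if counts is None:
                logger.warning(
                    "population %s: no site at %s:%d", population, snp.chrom, snp.pos
                )
                freq, depth = np.nan, 0
            else:
                n_focal = int(counts[BASE_INDEX[snp.focal_allele]])
                n_other = int(counts[BASE_INDEX[snp.other_allele]])
                depth = n_focal + n_other
                if depth == 0:
                    logger.warning(
                        "population %s: zero panel-allele depth at %s:%d",
                        population,
                        snp.chrom,
                        snp.pos,
                    )
                    freq = np.nan
                else:
                    freq = n_focal / depth
                    any_covered = True
            rows.append(
                {
                    "population": population,
                    "chrom": snp.chrom,
                    "pos": snp.pos,
                    "focal_allele": snp.focal_allele,
                    "frequency": freq,
                    "depth": depth,
                }
            )
        if not any_covered:
            raise ValidationError(
                f"population {population} has zero coverage at all panel sites"
            )
    return pd.DataFrame(
        rows, columns=["population", "chrom", "pos", "focal_allele", "frequency", "depth"]
    )
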