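"""Intersect candidate regions with gene annotation and flag keywords.

Keyword flagging is a programmatic stand-in for a manual gene-function
database screen: genes whose name or free-text attributes contain a
keyword (case-insensitive substring) are flagged with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .poolio import GeneRecord
from .scan import Region

DEFAULT_KEYWORDS = ("bone", "ectoderm", "tumor necrosis factor", "wnt")


@dataclass
class AnnotatedRegion:
    """A candidate region with its overlapping genes and keyword flags."""

    region: Region
    genes: list[GeneRecord]
    flags: dict[str, list[str]]  # gene_id -> matched keywords


def genes_in_region(genes: list[GeneRecord], region: Region) -> list[GeneRecord]:
    """Genes overlapping the region by at least 1 bp, sorted by start."""
    hits = [
        g
        for g in genes
        if g.chrom == region.chrom and g.start <= region.end and g.end >= region.start
    ]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


def flag_keywords(
    genes: list[GeneRecord], keywords: list[str] | tuple[str, ...]
) -> dict[str, list[str]]:
    """Per-gene list of keywords matching name or attribute text.

    Matching is case-insensitive substring search over the gene name and
    all attribute values; the output preserves the keyword list order.
    """
    flags: dict[str, list[str]] = {}
    for gene in genes:
        haystack = " ".join([gene.name, *gene.attributes.values()]).lower()
        flags[gene.gene_id] = [kw for kw in keywords if kw.lower() in haystack]
    return flags


def annotate_regions(
    regions: list[Region],
    genes: list[GeneRecord],
    keywords: list[str] | tuple[str, ...] = DEFAULT_KEYWORDS,
) -> list[AnnotatedRegion]:
    out = []
    for region in regions:
        hits = genes_in_region(genes, region)
        out.append(AnnotatedRegion(region=region, genes=hits, flags=flag_keywords(hits, keywords)))
    return out


def annotation_table(annotated: list[AnnotatedRegion]) -> pd.DataFrame:
    """Flatten annotated regions into one row per (region, gene)."""
    rows = []
    for ann in annotated:
        reg = ann.region
        label = f"{reg.chrom}:{reg.start}-{reg.end}"
        for gene in ann.genes:
            rows.append(
                {
                    "region": label,
                    "anchor_pos": reg.anchor_pos,
                    "gene_id": gene.gene_id,
                    "name": gene.name,
                    "chrom": gene.chrom,
                    "start": gene.start,
                    "end": gene.end,
                    "strand": gene.strand,
                    "matched_keywords": ",".join(ann.flags.get(gene.gene_id, [])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "anchor_pos",
            "gene_id",
            "name",
            "chrom",
            "start",
            "end",
            "strand",
            "matched_keywords",
        ],
    )
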