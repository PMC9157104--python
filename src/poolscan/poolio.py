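"""Readers and writers for the file formats the pipeline touches.

Supported formats: samtools mpileup text, popoolation2-style sync count
tables, GFF3 gene annotation, and the pipeline's commented TSV result
tables.  All coordinates are 1-based; intervals are closed.  Plain and
gzip-compressed text inputs are both accepted.

Internal nucleotide-count order is A, C, G, T (deletions kept in a
separate slot); sync files use A:T:C:G:N:del column order and are
reordered on the fly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}

# sync count fields are A:T:C:G:N:del; map them onto internal A,C,G,T
_SYNC_TO_INTERNAL = (0, 2, 3, 1)  # internal A<-field0, C<-field2, G<-field3, T<-field1
_INTERNAL_TO_SYNC = (0, 3, 1, 2)  # sync A<-A, T<-T(idx3), C<-C(idx1), G<-G(idx2)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class SiteCounts:
    """Per-pool nucleotide counts at one genomic site.

    ``counts`` has shape (n_pools, 4) in A,C,G,T order; ``dels`` holds the
    optional per-pool deletion tallies (excluded from allele-frequency
    math downstream).
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray
    dels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError(
                f"counts must have shape (n_pools, 4), got {self.counts.shape}"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if (self.counts < 0).any():
            raise ValidationError(f"negative count at {self.chrom}:{self.pos}")
        if self.dels is None:
            self.dels = np.zeros(self.counts.shape[0], dtype=np.int64)
        else:
            self.dels = np.asarray(self.dels, dtype=np.int64)
            if self.dels.shape != (self.counts.shape[0],):
                raise ValidationError("dels must have one entry per pool")
            if (self.dels < 0).any():
                raise ValidationError("negative deletion count")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]


@dataclass
class SiteBlock:
    """Column-oriented batch of sites for vectorised processing.

    Equivalent to a list of :class:`SiteCounts` but stored as arrays:
    ``counts`` has shape (n_sites, n_pools, 4).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    dels: np.ndarray

    @classmethod
    def from_sites(cls, sites: Iterable[SiteCounts]) -> "SiteBlock":
        sites = list(sites)
        if not sites:
            return cls(
                chrom=np.empty(0, dtype=object),
                pos=np.empty(0, dtype=np.int64),
                ref=np.empty(0, dtype="U1"),
                counts=np.empty((0, 0, 4), dtype=np.int64),
                dels=np.empty((0, 0), dtype=np.int64),
            )
        n_pools = sites[0].n_pools
        for s in sites:
            if s.n_pools != n_pools:
                raise ValidationError("inconsistent pool count across sites")
        return cls(
            chrom=np.array([s.chrom for s in sites], dtype=object),
            pos=np.array([s.pos for s in sites], dtype=np.int64),
            ref=np.array([s.ref for s in sites], dtype="U1"),
            counts=np.stack([s.counts for s in sites]),
            dels=np.stack([s.dels for s in sites]),
        )

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1] if len(self) else 0

    def __iter__(self) -> Iterator[SiteCounts]:
        for i in range(len(self)):
            yield SiteCounts(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
                dels=self.dels[i],
            )


@dataclass
class GeneRecord:
    """One gene from a GFF3 annotation (1-based closed interval)."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# mpileup


def decode_pileup_bases(bases: str, ref: str) -> tuple[np.ndarray, int]:
    """Tally one mpileup read-base string into (ACGT counts, deletions).

    ``.``/``,`` count toward the reference base; ``^X`` consumes the
    following mapping-quality character; ``+n``/``-n`` indel sequences are
    skipped entirely; ``*`` is a deletion placeholder; N and reference
    skips are ignored.
    """
    counts = np.zeros(4, dtype=np.int64)
    dels = 0
    ref = ref.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            if ref in BASE_INDEX:
                counts[BASE_INDEX[ref]] += 1
            i += 1
        elif c in "ACGTacgt":
            counts[BASE_INDEX[c.upper()]] += 1
            i += 1
        elif c == "^":
            i += 2  # '^' consumes one mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"indel marker {c!r} not followed by a length")
            i = j + int(bases[i + 1 : j])
        elif c == "*":
            dels += 1
            i += 1
        elif c in "Nn<>":
            i += 1
        else:
            raise FormatError(f"unknown pileup symbol {c!r}")
    return counts, dels


def read_mpileup(path: str | Path, n_pools: int) -> Iterator[SiteCounts]:
    """Stream SiteCounts from samtools mpileup text with ``n_pools`` pools."""
    expected = 3 + 3 * n_pools
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise FormatError(
                    f"{path}, line {lineno}: expected {expected} columns "
                    f"for {n_pools} pools, found {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {lineno}: non-integer position {fields[1]!r}"
                ) from exc
            ref = fields[2].upper()
            counts = np.zeros((n_pools, 4), dtype=np.int64)
            dels = np.zeros(n_pools, dtype=np.int64)
            for p in range(n_pools):
                depth_field, base_field = fields[3 + 3 * p], fields[4 + 3 * p]
                if depth_field == "0":
                    continue  # empty site; '*' placeholder columns
                try:
                    counts[p], dels[p] = decode_pileup_bases(base_field, ref)
                except FormatError as exc:
                    raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            yield SiteCounts(chrom=fields[0], pos=pos, ref=ref, counts=counts, dels=dels)


# ---------------------------------------------------------------------------
# sync


def read_sync(path: str | Path) -> Iterator[SiteCounts]:
    """Stream SiteCounts from a sync file (per-pool A:T:C:G:N:del fields)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}, line {lineno}: expected at least 4 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}, line {lineno}: non-integer position {fields[1]!r}"
                ) from exc
            n_pools = len(fields) - 3
            counts = np.zeros((n_pools, 4), dtype=np.int64)
            dels = np.zeros(n_pools, dtype=np.int64)
            for p, token in enumerate(fields[3:]):
                parts = token.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}, line {lineno}: count field {token!r} must have "
                        "6 colon-separated values (A:T:C:G:N:del)"
                    )
                try:
                    vals = [int(x) for x in parts]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}, line {lineno}: non-integer count in {token!r}"
                    ) from exc
                counts[p] = [vals[j] for j in _SYNC_TO_INTERNAL]
                dels[p] = vals[5]  # N (vals[4]) ignored
            yield SiteCounts(
                chrom=fields[0], pos=pos, ref=fields[2].upper(), counts=counts, dels=dels
            )


def _sync_line(site: SiteCounts) -> str:
    tokens = []
    for p in range(site.n_pools):
        c = site.counts[p]
        sync_counts = [c[j] for j in _INTERNAL_TO_SYNC]
        tokens.append(
            ":".join(str(int(x)) for x in (*sync_counts[:4], 0, site.dels[p]))
        )
    return "\t".join([site.chrom, str(site.pos), site.ref, *tokens])


def write_sync(sites: Iterable[SiteCounts] | SiteBlock, path: str | Path) -> None:
    """Write SiteCounts to a sync file, preserving input order."""
    with open(path, "wt") as fh:
        for site in sites:
            fh.write(_sync_line(site))
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff_genes(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Extract gene records from a GFF3 file.

    Features of a different type are ignored; features lacking an ID
    attribute are skipped with a logged warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        if "ID" not in feat.attributes:
            logger.warning(
                "skipping %s feature at %s:%d-%d with no ID attribute",
                feature_type,
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        attrs = {k: "; ".join(v) for k, v in feat.attributes.items()}
        name = attrs.get("Name", "")
        genes.append(
            GeneRecord(
                gene_id=attrs["ID"],
                name=name,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                attributes=attrs,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with '#'-prefixed header metadata."""
    with open(path, "wt") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
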