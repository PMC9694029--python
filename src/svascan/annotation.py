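"""Transcript models, exon boundaries, and gap-tolerant overlap queries.

Both detectors in this package reduce to proximity questions: is a breakend
within ``maxgap`` of an exon boundary, inside an exonic interval, or near a
known-NUMT region? This module loads GTF/GFF3 transcript annotation into
strand-aware :class:`TranscriptModel` objects, enumerates their donor and
acceptor boundaries in transcript (5'->3') order, and provides point and
interval indexes whose queries are inclusive at the gap boundary
(``|pos - boundary| <= maxgap``).

Coordinates are genomic, 1-based, inclusive throughout; BED input is
converted on load.
"""

from __future__ import annotations

import gzip
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

__all__ = [
    "Strand",
    "BoundarySide",
    "TranscriptModel",
    "ExonBoundary",
    "RegionSet",
    "BoundaryIndex",
    "load_transcripts",
    "load_regions_bed",
    "boundaries_of",
]


class Strand(Enum):
    PLUS = "+"
    MINUS = "-"


class BoundarySide(Enum):
    """DONOR: boundary where the intron begins downstream in transcript
    orientation; ACCEPTOR: boundary where the preceding intron ends."""

    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"


@dataclass
class TranscriptModel:
    """A transcript as an ordered set of genomic exons.

    ``exons`` are 1-based inclusive ``(start, end)`` tuples sorted by genomic
    start; transcript-order exon index 1 is the 5'-most exon (genomic first
    for ``+``, genomic last for ``-``).
    """

    tx_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: Strand
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.tx_id}: transcript with no exons")
        self.exons = sorted(self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(f"{self.tx_id}: overlapping or unsorted exons")
            if end < start:
                raise ValueError(f"{self.tx_id}: exon end < start")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_by_tx_index(self, i: int) -> tuple[int, int]:
        """Exon i in transcript (5'->3') order, 1-based."""
        if not 1 <= i <= self.n_exons:
            raise IndexError(f"exon index {i} out of range for {self.tx_id}")
        if self.strand is Strand.PLUS:
            return self.exons[i - 1]
        return self.exons[self.n_exons - i]

    def genomic_to_tx_index(self, g: int) -> int:
        """Transcript-order index of the g-th genomic exon (1-based)."""
        if self.strand is Strand.PLUS:
            return g
        return self.n_exons + 1 - g

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exonic_midpoint(self) -> float:
        """Genomic midpoint of the transcript's exonic span (used for the
        5'/3' insertion-side heuristic)."""
        s, e = self.span
        return (s + e) / 2


@dataclass(frozen=True)
class ExonBoundary:
    tx_id: str
    exon_index: int  # transcript order, 1-based
    side: BoundarySide
    pos: int  # genomic, 1-based; the exon's terminal base, not the intron


def boundaries_of(tx: TranscriptModel) -> list[ExonBoundary]:
    """Donor/acceptor boundaries of all internal exon junctions.

    For n exons there are 2(n-1) boundaries: each internal junction
    contributes the DONOR of the transcript-upstream exon and the ACCEPTOR
    of the transcript-downstream exon. Positions are the exon's terminal
    retained base (deletion-like SV breakends land on retained sequence).
    On the minus strand the genomic start of an exon is its DONOR and the
    genomic end its ACCEPTOR.
    """
    out: list[ExonBoundary] = []
    n = tx.n_exons
    for g in range(1, n):  # genomic junction between genomic exons g, g+1
        end_g = tx.exons[g - 1][1]
        start_next = tx.exons[g][0]
        if tx.strand is Strand.PLUS:
            out.append(ExonBoundary(tx.tx_id, g, BoundarySide.DONOR, end_g))
            out.append(ExonBoundary(tx.tx_id, g + 1, BoundarySide.ACCEPTOR, start_next))
        else:
            out.append(ExonBoundary(tx.tx_id, tx.genomic_to_tx_index(g + 1),
                                    BoundarySide.DONOR, start_next))
            out.append(ExonBoundary(tx.tx_id, tx.genomic_to_tx_index(g),
                                    BoundarySide.ACCEPTOR, end_g))
    out.sort(key=lambda b: (b.exon_index, b.side.value))
    return out


# --------------------------------------------------------------------------
# Indexes
# --------------------------------------------------------------------------


class BoundaryIndex:
    """Sorted-array index over exon boundaries supporting gap-tolerant point
    queries, inclusive at the threshold."""

    def __init__(self, boundaries_by_chrom: dict[str, list[ExonBoundary]] | None = None):
        self._pos: dict[str, list[int]] = {}
        self._items: dict[str, list[ExonBoundary]] = {}
        if boundaries_by_chrom:
            for chrom, items in boundaries_by_chrom.items():
                ordered = sorted(items, key=lambda b: b.pos)
                self._items[chrom] = ordered
                self._pos[chrom] = [b.pos for b in ordered]

    @classmethod
    def build(cls, transcripts: Iterable[TranscriptModel]) -> "BoundaryIndex":
        by_chrom: dict[str, list[ExonBoundary]] = {}
        for tx in transcripts:
            by_chrom.setdefault(tx.chrom, []).extend(boundaries_of(tx))
        return cls(by_chrom)

    def query_near(self, chrom: str, pos: int, maxgap: int) -> list[ExonBoundary]:
        """All boundaries with ``|pos - boundary.pos| <= maxgap``; unknown
        chromosome yields an empty result."""
        if maxgap < 0:
            raise ValueError("maxgap must be >= 0")
        positions = self._pos.get(chrom)
        if positions is None:
            return []
        lo = bisect_left(positions, pos - maxgap)
        hi = bisect_right(positions, pos + maxgap)
        return self._items[chrom][lo:hi]


@dataclass
class RegionSet:
    """Named per-chromosome interval set (1-based inclusive) with
    gap-tolerant point queries."""

    name: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in self.intervals.items():
            self.intervals[chrom] = sorted(ivs)
            # store half-open [start, end+1) so inclusive ends are hit
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e + 1, (s, e)) for s, e in ivs)

    def query_near(self, chrom: str, pos: int, maxgap: int) -> list[tuple[int, int]]:
        """Intervals within ``maxgap`` of ``pos`` (distance 0 inside)."""
        if maxgap < 0:
            raise ValueError("maxgap must be >= 0")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - maxgap, pos + maxgap + 1)
        return sorted(iv.data for iv in hits)

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.query_near(chrom, pos, 0))


class ExonIndex:
    """Interval index over exons of many transcripts; point query returns
    the transcripts whose exon contains (or is within maxgap of) a
    position."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        for tx in transcripts:
            self.transcripts[tx.tx_id] = tx
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            for idx0, (s, e) in enumerate(tx.exons):
                tree.addi(s, e + 1, (tx.tx_id, idx0 + 1))  # genomic exon no.

    def query_near(self, chrom: str, pos: int, maxgap: int = 0) -> list[tuple[str, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(pos - maxgap, pos + maxgap + 1))


# --------------------------------------------------------------------------
# Parsers
# --------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, _, v = item.partition("=")
            out[k.strip()] = v.strip()
    return out


def _open_text(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(str(path), "rt")
    return open(path)


def _strip_id_prefix(value: str) -> str:
    # GFF3 files from Ensembl prefix IDs with the feature type
    # ("transcript:ENST...", "gene:ENSG...").
    return value.split(":", 1)[1] if ":" in value else value


def load_transcripts(
    annotation_path: str | Path,
    format: str = "gtf",
) -> tuple[list[TranscriptModel], list[tuple[str, str]]]:
    """Load transcript models from GTF or GFF3 (plain or gzip).

    One :class:`TranscriptModel` per transcript; ``gene_symbol`` comes from
    ``gene_name``/``Name`` falling back to the gene id. Transcripts whose
    exons disagree on chromosome or strand are rejected with a diagnostic
    (returned as the second element). The dialect is selected by ``format``
    ("gtf" or "gff3"), never sniffed.
    """
    fmt = format.lower()
    if fmt not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation format {format!r}")

    exons: dict[str, list[tuple[str, str, int, int]]] = {}  # tx -> (chrom, strand, s, e)
    tx_gene: dict[str, str] = {}
    gene_symbol: dict[str, str] = {}
    tx_parent: dict[str, str] = {}  # GFF3: transcript ID -> gene ID
    rejected: list[tuple[str, str]] = []

    with _open_text(annotation_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = f[:9]
            if fmt == "gtf":
                if feature != "exon":
                    continue
                a = _parse_gtf_attrs(attrs)
                tx_id = a.get("transcript_id")
                if not tx_id:
                    rejected.append(("?", "exon without transcript_id"))
                    continue
                gid = a.get("gene_id", tx_id)
                tx_gene[tx_id] = gid
                if "gene_name" in a:
                    gene_symbol[gid] = a["gene_name"]
                exons.setdefault(tx_id, []).append(
                    (chrom, strand, int(start), int(end)))
            else:  # gff3
                a = _parse_gff3_attrs(attrs)
                if feature in ("mRNA", "transcript"):
                    tid = _strip_id_prefix(a.get("ID", ""))
                    parent = _strip_id_prefix(a.get("Parent", ""))
                    if tid:
                        tx_parent[tid] = parent or tid
                elif feature == "gene":
                    gid = _strip_id_prefix(a.get("ID", ""))
                    if gid and ("Name" in a or "gene_name" in a):
                        gene_symbol[gid] = a.get("Name") or a.get("gene_name")
                elif feature == "exon":
                    parent = _strip_id_prefix(a.get("Parent", ""))
                    if not parent:
                        rejected.append(("?", "exon without Parent"))
                        continue
                    exons.setdefault(parent, []).append(
                        (chrom, strand, int(start), int(end)))

    models: list[TranscriptModel] = []
    for tx_id, ex in exons.items():
        chroms = {c for c, _, _, _ in ex}
        strands = {s for _, s, _, _ in ex}
        if len(chroms) > 1:
            rejected.append((tx_id, "exons on multiple chromosomes"))
            continue
        if len(strands) > 1 or not strands <= {"+", "-"}:
            rejected.append((tx_id, "inconsistent or missing exon strand"))
            continue
        gid = tx_gene.get(tx_id) or tx_parent.get(tx_id, tx_id)
        try:
            models.append(TranscriptModel(
                tx_id=tx_id, gene_id=gid,
                gene_symbol=gene_symbol.get(gid, gid),
                chrom=chroms.pop(), strand=Strand(strands.pop()),
                exons=[(s, e) for _, _, s, e in ex],
            ))
        except ValueError as exc:
            rejected.append((tx_id, str(exc)))
    models.sort(key=lambda t: t.tx_id)
    return models, rejected


def load_regions_bed(path: str | Path, name: str = "regions") -> RegionSet:
    """Read a BED file (0-based half-open) into a 1-based inclusive
    :class:`RegionSet`."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start0, end0 = f[0], int(f[1]), int(f[2])
            intervals.setdefault(chrom, []).append((start0 + 1, end0))
    return RegionSet(name=name, intervals=intervals)
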