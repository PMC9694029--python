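"""Detection of retrocopied transcripts (processed-pseudogene insertions).

A retrocopied transcript (RT) arises when a processed mRNA — introns
spliced out, usually polyadenylated — is reverse-transcribed and
reintegrated into the genome. Against the reference, the copy shows two
breakpoint signatures:

* **exon-exon junctions**: deletion-like breakpoints whose breakends align
  (within ``maxgap``) with the donor boundary of exon *i* and the acceptor
  boundary of exon *j > i* of one transcript — each such call evidences the
  loss of introns *i..j-1*. Callers with limited resolution may skip a
  small exon and report the *transitive* call *i -> i+2* directly.
* **insertion sites**: breakpoints joining an exonic position of the source
  transcript to a second genomic location outside the source gene locus.
  Because RTs are frequently 5'-truncated, no gap threshold is applied on
  this signature — any exonic overlap qualifies.

Candidate transcripts are scored by the fraction of their introns covered
by detected junctions; events are grouped by source gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .annotation import (
    BoundaryIndex,
    BoundarySide,
    ExonIndex,
    Strand,
    TranscriptModel,
)
from .breakend_model import Breakend, Breakpoint, Orient

__all__ = [
    "TranscriptSide",
    "JunctionHit",
    "InsertionSiteHit",
    "RTEvent",
    "TranscriptIndex",
    "find_junctions",
    "score_transcript",
    "find_insertion_sites",
    "assemble_rt_events",
    "detect_rt",
    "DEFAULT_MAXGAP",
    "DEFAULT_MINSCORE",
]

#: Junction matching tolerance in bp. Tunable: larger values recover calls
#: from imprecise callers at the cost of specificity.
DEFAULT_MAXGAP = 100
#: Minimum fraction of a transcript's introns that must be covered by
#: junction calls for the transcript to "pass". 0.4 admits 2-of-4 but
#: rejects 1-of-4 intron recovery.
DEFAULT_MINSCORE = 0.4

#: Padding (bp) added around a gene's transcript span when excluding
#: intra-locus rearrangements from the insertion-site signature.
DEFAULT_LOCUS_PAD = 1000


class TranscriptSide(Enum):
    FIVE_PRIME = "5P"
    THREE_PRIME = "3P"


@dataclass
class JunctionHit:
    """One breakpoint matching the exon-exon junction signature of one
    transcript."""

    breakpoint: Breakpoint
    tx_id: str
    from_exon: int  # donor exon, transcript order
    to_exon: int  # acceptor exon, transcript order; > from_exon
    gap_left: int  # |breakend pos - boundary pos| on the lower-coordinate side
    gap_right: int

    @property
    def transitive(self) -> bool:
        return self.to_exon > self.from_exon + 1

    def covered_introns(self) -> set[int]:
        """Introns implied lost by this call (intron i separates exons i
        and i+1 in transcript order)."""
        return set(range(self.from_exon, self.to_exon))


@dataclass
class InsertionSiteHit:
    """A breakpoint joining an exonic position of a source transcript to a
    second genomic location outside the gene locus."""

    breakpoint: Breakpoint
    tx_id: str
    transcript_side: TranscriptSide
    exon_breakend: Breakend
    target_breakend: Breakend
    has_junction_support: bool = False
    single_exon: bool = False


@dataclass
class RTEvent:
    """A gene-level retrocopy call: all junction and insertion-site
    evidence attributed to transcripts of one gene."""

    gene_id: str
    gene_symbol: str
    junctions: list[JunctionHit] = field(default_factory=list)
    insertion_sites: list[InsertionSiteHit] = field(default_factory=list)
    tx_scores: dict[str, float] = field(default_factory=dict)
    passing_transcripts: set[str] = field(default_factory=set)
    single_exon_only: bool = False


class TranscriptIndex:
    """Pre-built lookup structures shared by both RT finders."""

    def __init__(self, transcripts: Sequence[TranscriptModel],
                 locus_pad: int = DEFAULT_LOCUS_PAD):
        self.transcripts = {tx.tx_id: tx for tx in transcripts}
        self.boundaries = BoundaryIndex.build(transcripts)
        self.exons = ExonIndex(transcripts)
        self.locus_pad = locus_pad
        # gene locus: union span of the gene's transcripts, padded
        self.gene_locus: dict[str, tuple[str, int, int]] = {}
        for tx in transcripts:
            s, e = tx.span
            cur = self.gene_locus.get(tx.gene_id)
            if cur is None:
                self.gene_locus[tx.gene_id] = (tx.chrom, s, e)
            elif cur[0] == tx.chrom:
                self.gene_locus[tx.gene_id] = (cur[0], min(cur[1], s), max(cur[2], e))

    def in_gene_locus(self, gene_id: str, chrom: str, pos: int) -> bool:
        locus = self.gene_locus.get(gene_id)
        if locus is None or locus[0] != chrom:
            return False
        return locus[1] - self.locus_pad <= pos <= locus[2] + self.locus_pad


def _pick_boundary(hits, pos: int, side: BoundarySide):
    """Nearest boundary of the required side; exact distance tie broken by
    lower exon index."""
    cands = [b for b in hits if b.side is side]
    if not cands:
        return None
    return min(cands, key=lambda b: (abs(pos - b.pos), b.exon_index))


def find_junctions(
    breakpoints: Iterable[Breakpoint],
    index: TranscriptIndex,
    maxgap: int = DEFAULT_MAXGAP,
    strict_orientation: bool = True,
) -> list[JunctionHit]:
    """Find breakpoints matching the exon-exon junction signature.

    A breakpoint yields a hit for transcript T iff one breakend is within
    ``maxgap`` of a donor boundary of exon *i* of T, the other within
    ``maxgap`` of an acceptor boundary of exon *j > i*, both on T's
    chromosome, and (unless ``strict_orientation`` is off) the breakpoint
    is deletion-like: retained segments point toward each other across the
    lost intron(s). One breakpoint may hit several transcripts.
    """
    out: list[JunctionHit] = []
    for bp in breakpoints:
        if not bp.is_intrachromosomal:
            continue
        l, r = bp.left, bp.right
        if strict_orientation and not (
                l.orient is Orient.RIGHT and r.orient is Orient.LEFT):
            continue
        hits_l = index.boundaries.query_near(l.chrom, l.pos, maxgap)
        if not hits_l:
            continue
        hits_r = index.boundaries.query_near(r.chrom, r.pos, maxgap)
        tx_l = {b.tx_id for b in hits_l}
        tx_r = {b.tx_id for b in hits_r}
        for tx_id in sorted(tx_l & tx_r):
            tx = index.transcripts[tx_id]
            # Genomically the lost intron sits between the lower and higher
            # breakend; which boundary is the donor depends on strand.
            if tx.strand is Strand.PLUS:
                donor_be, acceptor_be = l, r
                donor = _pick_boundary(
                    [b for b in hits_l if b.tx_id == tx_id], l.pos, BoundarySide.DONOR)
                acceptor = _pick_boundary(
                    [b for b in hits_r if b.tx_id == tx_id], r.pos, BoundarySide.ACCEPTOR)
            else:
                donor = _pick_boundary(
                    [b for b in hits_r if b.tx_id == tx_id], r.pos, BoundarySide.DONOR)
                acceptor = _pick_boundary(
                    [b for b in hits_l if b.tx_id == tx_id], l.pos, BoundarySide.ACCEPTOR)
            if donor is None or acceptor is None:
                continue
            if acceptor.exon_index <= donor.exon_index:
                continue
            gap_left = abs(l.pos - (donor.pos if tx.strand is Strand.PLUS else acceptor.pos))
            gap_right = abs(r.pos - (acceptor.pos if tx.strand is Strand.PLUS else donor.pos))
            out.append(JunctionHit(
                breakpoint=bp, tx_id=tx_id,
                from_exon=donor.exon_index, to_exon=acceptor.exon_index,
                gap_left=gap_left, gap_right=gap_right,
            ))
    return out


def score_transcript(
    junctions: Iterable[JunctionHit],
    tx: TranscriptModel,
    mode: str = "union",
) -> float:
    """Fraction of the transcript's introns evidenced as deleted.

    ``mode='union'`` (default): a hit *i -> j* covers introns *i..j-1*;
    coverage is the set union over hits, so a transitive call counts the
    introns it implies lost. ``mode='count'``: each distinct junction call
    counts once regardless of span (capped at the intron count).

    Undefined for single-exon transcripts (``ValueError``); those are
    handled by the insertion-site-only path.
    """
    n_introns = tx.n_exons - 1
    if n_introns < 1:
        raise ValueError(f"{tx.tx_id}: junction score undefined for single-exon transcript")
    hits = [h for h in junctions if h.tx_id == tx.tx_id]
    if mode == "union":
        covered: set[int] = set()
        for h in hits:
            covered |= h.covered_introns()
        num = len(covered)
    elif mode == "count":
        num = min(len({(h.from_exon, h.to_exon) for h in hits}), n_introns)
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    return num / n_introns


def _transcript_side(tx: TranscriptModel, pos: int) -> TranscriptSide:
    """5' if strictly upstream (transcript orientation) of the exonic-span
    midpoint; ties and downstream positions go 3'."""
    mid = tx.exonic_midpoint()
    upstream = pos < mid if tx.strand is Strand.PLUS else pos > mid
    return TranscriptSide.FIVE_PRIME if upstream else TranscriptSide.THREE_PRIME


def find_insertion_sites(
    breakpoints: Iterable[Breakpoint],
    index: TranscriptIndex,
    candidate_txs: set[str] | None = None,
) -> list[InsertionSiteHit]:
    """Find breakpoints matching the insertion-site signature.

    A breakpoint is a hit for transcript T iff exactly one breakend
    overlaps T's exons (no gap tolerance — frequent 5' truncation makes a
    gap threshold inappropriate here) and the mate lies outside T's gene
    locus (transcript-span union padded by ``index.locus_pad``).

    ``candidate_txs`` restricts the search; ``None`` scans all transcripts
    (required to pick up single-exon retrocopies, which have no junction
    signature).
    """
    out: list[InsertionSiteHit] = []
    for bp in breakpoints:
        for be, mate in ((bp.left, bp.right), (bp.right, bp.left)):
            for tx_id, _exon_no in index.exons.query_near(be.chrom, be.pos, 0):
                if candidate_txs is not None and tx_id not in candidate_txs:
                    continue
                tx = index.transcripts[tx_id]
                # both ends exonic for the same transcript -> junction
                # candidate, not an insertion site
                if any(t == tx_id for t, _ in
                       index.exons.query_near(mate.chrom, mate.pos, 0)):
                    continue
                # mate inside the gene locus -> intra-locus rearrangement
                if index.in_gene_locus(tx.gene_id, mate.chrom, mate.pos):
                    continue
                out.append(InsertionSiteHit(
                    breakpoint=bp, tx_id=tx_id,
                    transcript_side=_transcript_side(tx, be.pos),
                    exon_breakend=be, target_breakend=mate,
                    single_exon=tx.n_exons == 1,
                ))
    return out


def assemble_rt_events(
    junctions: Iterable[JunctionHit],
    insertion_sites: Iterable[InsertionSiteHit],
    index: TranscriptIndex,
    minscore: float = DEFAULT_MINSCORE,
    score_mode: str = "union",
) -> list[RTEvent]:
    """Group evidence by source gene into :class:`RTEvent` calls.

    A gene is reported when it has at least one junction or at least one
    retained insertion site. Single-exon transcripts, which cannot show a
    junction signature, are only reported when insertion-site-like
    breakpoints bracket the exon (hits on both the 5' and 3' sides with
    partners elsewhere); such events are flagged ``single_exon_only``.
    ``passing_transcripts`` are those with junction score >= ``minscore``.
    """
    junctions = list(junctions)
    insertion_sites = list(insertion_sites)
    tx_with_junctions = {h.tx_id for h in junctions}

    by_gene_j: dict[str, list[JunctionHit]] = {}
    for h in junctions:
        gene = index.transcripts[h.tx_id].gene_id
        by_gene_j.setdefault(gene, []).append(h)

    by_gene_s: dict[str, list[InsertionSiteHit]] = {}
    for s in insertion_sites:
        s.has_junction_support = s.tx_id in tx_with_junctions
        gene = index.transcripts[s.tx_id].gene_id
        by_gene_s.setdefault(gene, []).append(s)

    events: list[RTEvent] = []
    for gene in sorted(set(by_gene_j) | set(by_gene_s)):
        j_hits = by_gene_j.get(gene, [])
        sites = by_gene_s.get(gene, [])
        # single-exon transcripts: require bracketing (both sides hit)
        kept_sites: list[InsertionSiteHit] = []
        single_exon_sites: dict[str, list[InsertionSiteHit]] = {}
        for s in sites:
            if s.single_exon:
                single_exon_sites.setdefault(s.tx_id, []).append(s)
            else:
                kept_sites.append(s)
        for tx_id, tx_sites in sorted(single_exon_sites.items()):
            sides = {s.transcript_side for s in tx_sites}
            if sides == {TranscriptSide.FIVE_PRIME, TranscriptSide.THREE_PRIME}:
                kept_sites.extend(tx_sites)
        if not j_hits and not kept_sites:
            continue

        scores: dict[str, float] = {}
        for tx_id in sorted({h.tx_id for h in j_hits}):
            scores[tx_id] = score_transcript(
                j_hits, index.transcripts[tx_id], mode=score_mode)
        sym = index.transcripts[
            (j_hits[0].tx_id if j_hits else kept_sites[0].tx_id)].gene_symbol
        events.append(RTEvent(
            gene_id=gene, gene_symbol=sym,
            junctions=j_hits, insertion_sites=kept_sites,
            tx_scores=scores,
            passing_transcripts={t for t, sc in scores.items() if sc >= minscore},
            single_exon_only=not j_hits and all(s.single_exon for s in kept_sites),
        ))
    return events


def detect_rt(
    breakpoints: Sequence[Breakpoint],
    transcripts: Sequence[TranscriptModel],
    maxgap: int = DEFAULT_MAXGAP,
    minscore: float = DEFAULT_MINSCORE,
    locus_pad: int = DEFAULT_LOCUS_PAD,
    strict_orientation: bool = True,
    score_mode: str = "union",
) -> list[RTEvent]:
    """End-to-end RT detection on a parsed breakpoint set."""
    index = TranscriptIndex(transcripts, locus_pad=locus_pad)
    junctions = find_junctions(
        breakpoints, index, maxgap=maxgap, strict_orientation=strict_orientation)
    sites = find_insertion_sites(breakpoints, index, candidate_txs=None)
    return assemble_rt_events(
        junctions, sites, index, minscore=minscore, score_mode=score_mode)
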