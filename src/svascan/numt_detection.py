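"""Detection of nuclear integrations of mitochondrial DNA (NUMTs).

When a fragment of the mitochondrial genome integrates into a nuclear
chromosome, a general-purpose SV caller sees one nuclear<->chrM
translocation breakpoint per insertion junction. Three evidence routes are
recognised here:

* **direct breakends**: breakpoints with exactly one mate on the
  mitochondrial contig;
* **realigned insertions**: sequence-resolved insertion calls (or single
  breakends carrying sequence) whose sequence locally aligns to chrM with
  a length-normalised Smith-Waterman score of at least ``min_align``
  (circular genome and both strands handled);
* **known-NUMT proximity**: nuclear<->nuclear breakpoints with exactly one
  mate within ``maxgap_numts`` of a catalogued reference NUMT region —
  inserted mtDNA reads often map to those nuclear copies instead of chrM.

Candidate insertion sites on the same chromosome with facing orientations
within ``max_ins_dist`` are linked into two-sided events; events are tiered
HIGH / INTERMEDIATE / LOW by how many of their sites carry the PASS filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from scipy.optimize import linear_sum_assignment

from .annotation import RegionSet
from .breakend_model import (
    MT_ALIASES,
    Breakend,
    Breakpoint,
    InsertionRecord,
    Orient,
    chrom_sort_key,
    reverse_complement,
)

__all__ = [
    "Evidence",
    "Confidence",
    "MtFusionCandidate",
    "NUMTEvent",
    "MtAligner",
    "find_mt_breakpoints",
    "realign_insertions",
    "rescue_known_numt",
    "link_sites",
    "assign_confidence",
    "detect_numt",
    "load_mt_sequence",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MIN_ALIGN",
    "DEFAULT_MAX_INS_DIST",
    "DEFAULT_MAXGAP_NUMTS",
    "PRESET_PAPER_SIM",
]

# Defaults; every one is overridable at the API and CLI level.
DEFAULT_MIN_LEN = 20  # bp; minimum insertion-sequence length to realign
DEFAULT_MIN_ALIGN = 0.8  # normalised alignment score threshold in (0, 1]
DEFAULT_MAX_INS_DIST = 1000  # bp; max distance between paired insertion sites
DEFAULT_MAXGAP_NUMTS = 10  # bp; max distance to a known-NUMT region

#: The benchmark preset used for simulated-data evaluation.
PRESET_PAPER_SIM = {"min_len": 8, "min_align": 0.7}

_BIG = 10**9  # assignment cost for incompatible site pairs


class Evidence(Enum):
    DIRECT_BND = "DIRECT_BND"
    REALIGNED_INSERTION = "REALIGNED_INSERTION"
    KNOWN_NUMT_PROXIMITY = "KNOWN_NUMT_PROXIMITY"


class Confidence(Enum):
    HIGH = "HIGH"
    INTERMEDIATE = "INTERMEDIATE"
    LOW = "LOW"


@dataclass
class MtFusionCandidate:
    """One candidate nuclear insertion site of a mitochondrial segment."""

    source: Breakpoint | InsertionRecord | Breakend
    nuclear_chrom: str
    nuclear_pos: int
    nuclear_orient: Orient | None
    evidence: Evidence
    mt_start: int | None = None
    mt_end: int | None = None
    align_score_norm: float | None = None
    site_filter: str = "PASS"


@dataclass
class NUMTEvent:
    """A NUMT integration: one or two insertion sites on one nuclear
    chromosome, optionally linked into a span."""

    nuclear_chrom: str
    sites: list[MtFusionCandidate]
    linked: bool
    insertion_span: tuple[int, int] | None = None
    confidence: Confidence = Confidence.LOW


# --------------------------------------------------------------------------
# Direct breakend route
# --------------------------------------------------------------------------


def find_mt_breakpoints(
    breakpoints: Iterable[Breakpoint],
    mt_aliases: frozenset[str] | set[str] = MT_ALIASES,
    diagnostics: dict | None = None,
) -> list[MtFusionCandidate]:
    """Breakpoints with exactly one mate on the mitochondrial contig.

    Breakpoints joining two mitochondrial positions are intra-mito
    rearrangements, skipped and counted under ``diagnostics['intra_mt']``.
    """
    out: list[MtFusionCandidate] = []
    intra_mt = 0
    for bp in breakpoints:
        l_mt = bp.left.chrom in mt_aliases
        r_mt = bp.right.chrom in mt_aliases
        if l_mt and r_mt:
            intra_mt += 1
            continue
        if not (l_mt or r_mt):
            continue
        mt_be, nuc_be = (bp.left, bp.right) if l_mt else (bp.right, bp.left)
        out.append(MtFusionCandidate(
            source=bp, nuclear_chrom=nuc_be.chrom, nuclear_pos=nuc_be.pos,
            nuclear_orient=nuc_be.orient, evidence=Evidence.DIRECT_BND,
            mt_start=mt_be.pos, mt_end=mt_be.pos,
            site_filter=bp.source_filter,
        ))
    if diagnostics is not None:
        diagnostics["intra_mt"] = diagnostics.get("intra_mt", 0) + intra_mt
    return out


# --------------------------------------------------------------------------
# Insertion-sequence realignment route
# --------------------------------------------------------------------------


def load_mt_sequence(
    fasta_path: str | Path,
    mt_aliases: frozenset[str] | set[str] = MT_ALIASES,
) -> str:
    """Extract the mitochondrial contig from a FASTA file by alias; falls
    back to the only contig if the file has exactly one."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    for rec in records:
        if rec.id in mt_aliases:
            return str(rec.seq).upper()
    if len(records) == 1:
        return str(records[0].seq).upper()
    names = [r.id for r in records]
    raise ValueError(
        f"no mitochondrial contig among {names}; recognised aliases: "
        f"{sorted(mt_aliases)}. Pass the contig name via mt_aliases/--mt-contig.")


def _trim_terminal_homopolymers(seq: str, min_run: int) -> str:
    """Strip terminal poly-A / poly-T runs (polyadenylation tails, either
    strand) before alignment so the tail does not depress the
    length-normalised score."""
    if min_run <= 0:
        return seq
    s = seq
    for base in ("A", "T"):
        n = len(s) - len(s.rstrip(base))
        if n >= min_run:
            s = s[: len(s) - n]
        n = len(s) - len(s.lstrip(base))
        if n >= min_run:
            s = s[n:]
    return s


class MtAligner:
    """Local (Smith-Waterman) aligner against the mitochondrial genome.

    Scoring: match +1, mismatch -2, gap open -3, gap extend -1. The score
    is normalised by ``match * query_length`` so an exact full-length match
    scores 1.0. Circularity is handled by aligning against chrM extended
    with its first ``query_length - 1`` bases; both strands are tried.
    """

    MATCH = 1.0

    def __init__(self, mt_seq: str):
        self.mt_seq = mt_seq.upper()
        self.aligner = Align.PairwiseAligner(
            mode="local", match_score=self.MATCH, mismatch_score=-2.0,
            open_gap_score=-3.0, extend_gap_score=-1.0)

    def _target(self, query_len: int) -> str:
        ext = min(query_len - 1, len(self.mt_seq))
        return self.mt_seq + self.mt_seq[:max(ext, 0)]

    def normalized_score(self, query: str) -> float:
        """Best normalised local alignment score over both strands."""
        query = query.upper()
        if not query:
            return 0.0
        target = self._target(len(query))
        best = max(self.aligner.score(target, query),
                   self.aligner.score(target, reverse_complement(query)))
        return best / (self.MATCH * len(query))

    def best_segment(self, query: str) -> tuple[float, int, int]:
        """Normalised score plus the matched chrM segment as 1-based
        inclusive coordinates (wrapped around the origin if needed, in
        which case start > end)."""
        query = query.upper()
        target = self._target(len(query))
        L = len(self.mt_seq)
        # cheap score pass on both strands; traceback only on the winner
        rc = reverse_complement(query)
        q = query if (self.aligner.score(target, query)
                      >= self.aligner.score(target, rc)) else rc
        try:
            best_aln = self.aligner.align(target, q)[0]
        except IndexError:
            return 0.0, 0, 0
        best_score = best_aln.score
        if best_score <= 0:
            return 0.0, 0, 0
        blocks = best_aln.aligned[0]
        t_start = int(blocks[0][0])  # 0-based
        t_end = int(blocks[-1][1])  # exclusive
        start1 = t_start % L + 1
        end1 = (t_end - 1) % L + 1
        return best_score / (self.MATCH * len(query)), start1, end1


def realign_insertions(
    records: Iterable[InsertionRecord | Breakend],
    mt_seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    min_align: float = DEFAULT_MIN_ALIGN,
    polya_trim_run: int = 8,
) -> list[MtFusionCandidate]:
    """Realign unmapped insertion sequences to the mitochondrial genome.

    ``records`` may be sequence-resolved insertion calls or single
    breakends carrying an inserted sequence. Sequences shorter than
    ``min_len`` (after polyadenylation-tail trimming) are discarded before
    alignment; surviving sequences are kept as candidates iff their
    normalised score is at least ``min_align``.
    """
    aligner = MtAligner(mt_seq)
    out: list[MtFusionCandidate] = []
    for rec in records:
        if isinstance(rec, Breakend):
            seq, chrom, pos, filt = rec.inserted_seq, rec.chrom, rec.pos, rec.filter
            orient = rec.orient
        else:
            seq, chrom, pos, filt = rec.seq, rec.chrom, rec.pos, rec.filter
            orient = None
        seq = _trim_terminal_homopolymers(seq, polya_trim_run)
        if len(seq) < min_len:
            continue
        if aligner.normalized_score(seq) < min_align:
            continue  # score-only pass; skip the costly traceback
        score, mt_start, mt_end = aligner.best_segment(seq)
        if score < min_align:
            continue
        out.append(MtFusionCandidate(
            source=rec, nuclear_chrom=chrom, nuclear_pos=pos,
            nuclear_orient=orient, evidence=Evidence.REALIGNED_INSERTION,
            mt_start=mt_start, mt_end=mt_end, align_score_norm=score,
            site_filter=filt,
        ))
    return out


# --------------------------------------------------------------------------
# Known-NUMT proximity route
# --------------------------------------------------------------------------


def rescue_known_numt(
    breakpoints: Iterable[Breakpoint],
    known_numt_regions: RegionSet,
    maxgap_numts: int = DEFAULT_MAXGAP_NUMTS,
    mt_aliases: frozenset[str] | set[str] = MT_ALIASES,
    diagnostics: dict | None = None,
) -> list[MtFusionCandidate]:
    """Rescue nuclear<->nuclear breakpoints whose inserted mtDNA mapped to
    a catalogued reference NUMT instead of chrM.

    A breakpoint qualifies iff exactly one mate lies within
    ``maxgap_numts`` of a known-NUMT interval; the other mate is the
    candidate insertion site. Breakpoints with both mates near known NUMTs
    are ambiguous and only counted in ``diagnostics['both_in_numt']``.
    """
    out: list[MtFusionCandidate] = []
    ambiguous = 0
    for bp in breakpoints:
        if bp.left.chrom in mt_aliases or bp.right.chrom in mt_aliases:
            continue
        l_hit = bool(known_numt_regions.query_near(
            bp.left.chrom, bp.left.pos, maxgap_numts))
        r_hit = bool(known_numt_regions.query_near(
            bp.right.chrom, bp.right.pos, maxgap_numts))
        if l_hit and r_hit:
            ambiguous += 1
            continue
        if not (l_hit or r_hit):
            continue
        site = bp.right if l_hit else bp.left
        out.append(MtFusionCandidate(
            source=bp, nuclear_chrom=site.chrom, nuclear_pos=site.pos,
            nuclear_orient=site.orient, evidence=Evidence.KNOWN_NUMT_PROXIMITY,
            site_filter=bp.source_filter,
        ))
    if diagnostics is not None:
        diagnostics["both_in_numt"] = diagnostics.get("both_in_numt", 0) + ambiguous
    return out


# --------------------------------------------------------------------------
# Linking and tiering
# --------------------------------------------------------------------------


def _sort_key(c: MtFusionCandidate):
    return (chrom_sort_key(c.nuclear_chrom), c.nuclear_pos,
            c.nuclear_orient.value if c.nuclear_orient else "")


def link_sites(
    candidates: Sequence[MtFusionCandidate],
    max_ins_dist: int = DEFAULT_MAX_INS_DIST,
    orientation_check: bool = True,
) -> list[NUMTEvent]:
    """Pair candidate insertion sites into NUMT events.

    Two sites are compatible when they share a nuclear chromosome, their
    breakends face each other (one RIGHT, one LEFT — the inserted segment
    lies between them; disable with ``orientation_check=False`` for
    imprecise callers) and their distance is at most ``max_ins_dist``.
    Pairing maximises the number of linked pairs and, among those, the
    minimum total distance (exact assignment, deterministic). Each
    candidate joins at most one event; leftovers become single-site
    events. Sequence-resolved insertion candidates already encode both
    junctions and yield a linked zero-width event directly.
    """
    events: list[NUMTEvent] = []
    pairable: list[MtFusionCandidate] = []
    for c in candidates:
        if c.evidence is Evidence.REALIGNED_INSERTION:
            events.append(NUMTEvent(
                nuclear_chrom=c.nuclear_chrom, sites=[c], linked=True,
                insertion_span=(c.nuclear_pos, c.nuclear_pos)))
        else:
            pairable.append(c)

    by_chrom: dict[str, list[MtFusionCandidate]] = {}
    for c in sorted(pairable, key=_sort_key):
        by_chrom.setdefault(c.nuclear_chrom, []).append(c)

    for chrom in sorted(by_chrom, key=chrom_sort_key):
        sites = by_chrom[chrom]
        if orientation_check:
            group_a = [c for c in sites if c.nuclear_orient is Orient.RIGHT]
            group_b = [c for c in sites if c.nuclear_orient is Orient.LEFT]
            pairs = _assign_pairs(group_a, group_b, max_ins_dist)
            used = {id(c) for a, b in pairs for c in (a, b)}
            singles = [c for c in sites if id(c) not in used]
        else:
            pairs, singles = _greedy_pairs(sites, max_ins_dist)
        for a, b in pairs:
            span = (min(a.nuclear_pos, b.nuclear_pos),
                    max(a.nuclear_pos, b.nuclear_pos))
            events.append(NUMTEvent(
                nuclear_chrom=chrom, sites=[a, b], linked=True,
                insertion_span=span))
        for c in singles:
            events.append(NUMTEvent(
                nuclear_chrom=chrom, sites=[c], linked=False))

    for ev in events:
        ev.confidence = assign_confidence(ev)
    events.sort(key=lambda e: (chrom_sort_key(e.nuclear_chrom),
                               e.sites[0].nuclear_pos))
    return events


def _assign_pairs(group_a, group_b, max_ins_dist: int):
    """Exact bipartite pairing: maximise pair count, then minimise total
    distance. Incompatible pairs carry a prohibitive cost, so the optimal
    assignment uses as many valid pairs as possible."""
    if not group_a or not group_b:
        return []
    cost = np.full((len(group_a), len(group_b)), float(_BIG))
    for i, a in enumerate(group_a):
        for j, b in enumerate(group_b):
            d = abs(a.nuclear_pos - b.nuclear_pos)
            if d <= max_ins_dist:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    return [(group_a[i], group_b[j]) for i, j in zip(rows, cols)
            if cost[i, j] < _BIG]


def _greedy_pairs(sites, max_ins_dist: int):
    """Orientation-agnostic fallback: greedy nearest pairs."""
    cand = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            d = abs(sites[i].nuclear_pos - sites[j].nuclear_pos)
            if d <= max_ins_dist:
                cand.append((d, i, j))
    cand.sort()
    used: set[int] = set()
    pairs = []
    for d, i, j in cand:
        if i in used or j in used:
            continue
        pairs.append((sites[i], sites[j]))
        used.update((i, j))
    singles = [s for k, s in enumerate(sites) if k not in used]
    return pairs, singles


def assign_confidence(event: NUMTEvent) -> Confidence:
    """PASS-based tiering: both sites PASS -> HIGH; exactly one PASS ->
    INTERMEDIATE; none -> LOW. A single-site event is INTERMEDIATE when
    PASS, LOW otherwise. A sequence-resolved insertion encodes both
    junctions in one record, so its filter counts for both sites."""
    n_pass = sum(1 for s in event.sites if s.site_filter == "PASS")
    if len(event.sites) == 1 and event.linked:  # resolved insertion
        return Confidence.HIGH if n_pass == 1 else Confidence.LOW
    if event.linked:
        if n_pass == 2:
            return Confidence.HIGH
        if n_pass == 1:
            return Confidence.INTERMEDIATE
        return Confidence.LOW
    return Confidence.INTERMEDIATE if n_pass == 1 else Confidence.LOW


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def detect_numt(
    breakpoints: Sequence[Breakpoint],
    insertions: Sequence[InsertionRecord] = (),
    single_breakends: Sequence[Breakend] = (),
    mt_fasta: str | Path | None = None,
    known_numt_regions: RegionSet | None = None,
    mt_aliases: frozenset[str] | set[str] = MT_ALIASES,
    min_len: int = DEFAULT_MIN_LEN,
    min_align: float = DEFAULT_MIN_ALIGN,
    max_ins_dist: int = DEFAULT_MAX_INS_DIST,
    maxgap_numts: int = DEFAULT_MAXGAP_NUMTS,
    orientation_check: bool = True,
    diagnostics: dict | None = None,
) -> list[NUMTEvent]:
    """End-to-end NUMT detection on a parsed callset.

    Raises ``ValueError`` if sequence-bearing records are present but no
    mitochondrial FASTA was supplied (the realignment route needs it).
    """
    candidates = find_mt_breakpoints(breakpoints, mt_aliases, diagnostics)
    seq_records: list[InsertionRecord | Breakend] = list(insertions)
    seq_records.extend(b for b in single_breakends if b.inserted_seq)
    if seq_records:
        if mt_fasta is None:
            raise ValueError(
                f"{len(seq_records)} sequence-bearing insertion/single-breakend "
                "records present but no mitochondrial FASTA given; supply "
                "mt_fasta/--mt-fasta to enable insertion-sequence realignment.")
        mt_seq = load_mt_sequence(mt_fasta, mt_aliases)
        candidates.extend(realign_insertions(
            seq_records, mt_seq, min_len=min_len, min_align=min_align))
    if known_numt_regions is not None:
        candidates.extend(rescue_known_numt(
            breakpoints, known_numt_regions, maxgap_numts, mt_aliases,
            diagnostics))
    return link_sites(candidates, max_ins_dist=max_ins_dist,
                      orientation_check=orientation_check)
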