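"""Breakend-centric representation of structural-variant callsets.

Structural variant callers report rearrangements as VCF BND records: each
record is one *breakend* (one side of a novel adjacency) and carries a
``MATEID`` pointing at its partner. Two mated breakends form a *breakpoint*,
the unit of SV evidence used by the downstream detectors in this package.
This module parses VCF callsets into that model, preserves all caller
metadata verbatim, and converts between the model and BEDPE.

Coordinate conventions: VCF positions are 1-based and are stored as parsed;
conversion to 0-based half-open happens only in the BEDPE writer/reader.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pysam

__all__ = [
    "Orient",
    "Breakend",
    "Breakpoint",
    "InsertionRecord",
    "CallSet",
    "MalformedBreakendError",
    "parse_bnd_alt",
    "load_callset",
    "make_breakpoint",
    "joint_filter",
    "write_bedpe",
    "read_bedpe",
    "write_annotated_vcf",
    "MT_ALIASES",
    "chrom_sort_key",
    "reverse_complement",
]

#: Contig names recognised as the mitochondrial genome (configurable in all
#: entry points that need the distinction).
MT_ALIASES = frozenset({"chrM", "MT", "chrMT", "M"})

_NUC_RE = re.compile(r"^[ACGTNacgtn]*$")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Orient(Enum):
    """Orientation of a breakend.

    ``RIGHT``: the retained segment extends to lower coordinates and the
    junction is at its right edge (BEDPE strand ``+``).
    ``LEFT``: the retained segment extends to higher coordinates and the
    junction is at its left edge (BEDPE strand ``-``).
    """

    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def strand(self) -> str:
        return "+" if self is Orient.RIGHT else "-"

    @staticmethod
    def from_strand(strand: str) -> "Orient":
        if strand == "+":
            return Orient.RIGHT
        if strand == "-":
            return Orient.LEFT
        raise ValueError(f"unknown strand {strand!r}")


class MalformedBreakendError(ValueError):
    """Raised when a BND ALT string cannot be interpreted."""


@dataclass
class Breakend:
    """One side of a rearrangement junction."""

    record_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    orient: Orient
    mate_id: str | None = None
    inserted_seq: str = ""
    filter: str = "PASS"
    qual: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.record_id}: pos must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError(f"{self.record_id}: empty chromosome name")
        if not _NUC_RE.match(self.inserted_seq):
            raise ValueError(
                f"{self.record_id}: inserted sequence contains non-ACGTN characters"
            )

    @property
    def is_single(self) -> bool:
        return self.mate_id is None


@dataclass
class Breakpoint:
    """An ordered pair of mated breakends.

    ``left`` is the breakend with the lower (chromosome, position) under
    natural chromosome ordering; the junction's inserted sequence is stored
    as read on ``left``.
    """

    left: Breakend
    right: Breakend
    source_filter: str = "PASS"

    @property
    def inserted_seq(self) -> str:
        return self.left.inserted_seq

    def inserted_seq_as_seen_from_right(self) -> str:
        # Mates with opposite orientations read the junction on the same
        # strand; same-orientation mates see each other's insert
        # reverse-complemented.
        if self.left.orient != self.right.orient:
            return self.left.inserted_seq
        return reverse_complement(self.left.inserted_seq)

    def mate_of(self, breakend: Breakend) -> Breakend:
        if breakend is self.left:
            return self.right
        if breakend is self.right:
            return self.left
        raise ValueError("breakend does not belong to this breakpoint")

    @property
    def is_intrachromosomal(self) -> bool:
        return self.left.chrom == self.right.chrom


@dataclass
class InsertionRecord:
    """A sequence-resolved insertion call (symbolic <INS> with a resolvable
    sequence, or a long non-symbolic ALT)."""

    chrom: str
    pos: int  # 1-based anchor base
    seq: str
    filter: str = "PASS"
    info: dict = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.record_id}: empty insertion sequence")
        if self.pos < 1:
            raise ValueError(f"{self.record_id}: pos must be >= 1")


@dataclass
class CallSet:
    """Result of parsing one VCF: paired breakpoints, unpartnered single
    breakends, sequence-resolved insertions, plus parse diagnostics."""

    breakpoints: list[Breakpoint] = field(default_factory=list)
    single_breakends: list[Breakend] = field(default_factory=list)
    insertions: list[InsertionRecord] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    n_bnd_records: int = 0
    n_missing_mates: int = 0


def chrom_sort_key(chrom: str):
    """Natural ordering of chromosome names: chr2 < chr10 < chrX < chrM."""
    parts = re.split(r"(\d+)", chrom)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


# --------------------------------------------------------------------------
# BND ALT grammar (VCF 4.2)
# --------------------------------------------------------------------------

_BND_RE = re.compile(
    r"""^(?P<t1>[ACGTNacgtn]*)          # seq before bracket (forms t[p[ / t]p])
         (?P<b1>[\[\]])(?P<locus1>[^\[\]]+)(?P=b1)
         $
     |
        ^(?P<b2>[\[\]])(?P<locus2>[^\[\]]+)(?P=b2)
         (?P<t2>[ACGTNacgtn]*)$         # seq after bracket (]p]t / [p[t)
    """,
    re.VERBOSE,
)


def parse_bnd_alt(ref_base: str, alt: str) -> tuple[str, int, Orient, Orient, str]:
    """Decompose a bracketed BND ALT into mate locus, orientations and
    novel inserted bases.

    The four ALT forms map to orientations as follows (``t`` contains the
    anchoring REF base):

    ========  ==============  ==============
    ALT form  local orient    mate orient
    ========  ==============  ==============
    t[p[      RIGHT (+)       LEFT  (-)
    t]p]      RIGHT (+)       RIGHT (+)
    ]p]t      LEFT  (-)       RIGHT (+)
    [p[t      LEFT  (-)       LEFT  (-)
    ========  ==============  ==============

    Returns ``(mate_chrom, mate_pos, orient, mate_orient, inserted_seq)``.
    Raises :class:`MalformedBreakendError` on anything else.
    """
    m = _BND_RE.match(alt)
    if not m:
        raise MalformedBreakendError(f"ALT {alt!r} is not a bracketed breakend")
    if m.group("t1") is not None:
        t, bracket, locus = m.group("t1"), m.group("b1"), m.group("locus1")
        orient = Orient.RIGHT
        if not t:
            raise MalformedBreakendError(f"ALT {alt!r} lacks the anchoring base")
        if t[0].upper() != ref_base[0].upper():
            raise MalformedBreakendError(
                f"ALT {alt!r} does not start with REF base {ref_base!r}"
            )
        inserted = t[len(ref_base):]
    else:
        t, bracket, locus = m.group("t2"), m.group("b2"), m.group("locus2")
        orient = Orient.LEFT
        if not t:
            raise MalformedBreakendError(f"ALT {alt!r} lacks the anchoring base")
        if t[-1].upper() != ref_base[-1].upper():
            raise MalformedBreakendError(
                f"ALT {alt!r} does not end with REF base {ref_base!r}"
            )
        inserted = t[: len(t) - len(ref_base)]
    mate_orient = Orient.LEFT if bracket == "[" else Orient.RIGHT
    chrom, _, pos_str = locus.rpartition(":")
    if not chrom or not pos_str.isdigit():
        raise MalformedBreakendError(f"cannot parse mate locus {locus!r} in {alt!r}")
    return chrom, int(pos_str), orient, mate_orient, inserted


_SINGLE_RE = re.compile(
    r"^(?P<seq1>[ACGTNacgtn]+)\.$|^\.(?P<seq2>[ACGTNacgtn]+)$"
)


def _parse_single_alt(ref_base: str, alt: str) -> tuple[Orient, str]:
    """Parse a single-breakend ALT (``t.`` or ``.t``)."""
    m = _SINGLE_RE.match(alt)
    if not m:
        raise MalformedBreakendError(f"ALT {alt!r} is not a single breakend")
    if m.group("seq1") is not None:
        t = m.group("seq1")
        if t[0].upper() != ref_base[0].upper():
            raise MalformedBreakendError(f"ALT {alt!r} does not start with REF base")
        return Orient.RIGHT, t[len(ref_base):]
    t = m.group("seq2")
    if t[-1].upper() != ref_base[-1].upper():
        raise MalformedBreakendError(f"ALT {alt!r} does not end with REF base")
    return Orient.LEFT, t[: len(t) - len(ref_base)]


# --------------------------------------------------------------------------
# VCF loading
# --------------------------------------------------------------------------


def _info_to_dict(rec) -> dict:
    out = {}
    for key, value in rec.info.items():
        if isinstance(value, tuple):
            value = tuple(v for v in value)
            if len(value) == 1:
                value = value[0]
        out[key] = value
    return out


def _filter_string(rec) -> str:
    keys = list(rec.filter.keys())
    if not keys:
        return "."
    return ";".join(keys)


def _gridss_mate_id(record_id: str) -> str | None:
    """GRIDSS-style mate id inference: trailing 'o'/'h' swap, else trailing
    digit 1<->2 swap."""
    if record_id.endswith("o"):
        return record_id[:-1] + "h"
    if record_id.endswith("h"):
        return record_id[:-1] + "o"
    m = re.match(r"^(.*[_:])([12])$", record_id)
    if m:
        return m.group(1) + ("2" if m.group(2) == "1" else "1")
    return None


def _canonical_pair(a: Breakend, b: Breakend) -> tuple[Breakend, Breakend]:
    ka = (chrom_sort_key(a.chrom), a.pos)
    kb = (chrom_sort_key(b.chrom), b.pos)
    return (a, b) if ka <= kb else (b, a)


def joint_filter(f1: str, f2: str) -> str:
    """Breakpoint-level filter: PASS only if both mates PASS; otherwise the
    lexicographically first non-PASS value (needed by per-site confidence
    tiers downstream)."""
    non_pass = sorted(f for f in (f1, f2) if f != "PASS")
    return "PASS" if not non_pass else non_pass[0]


def make_breakpoint(a: Breakend, b: Breakend) -> Breakpoint:
    """Pair two mated breakends into a canonically ordered breakpoint."""
    left, right = _canonical_pair(a, b)
    return Breakpoint(left=left, right=right,
                      source_filter=joint_filter(a.filter, b.filter))


_make_breakpoint = make_breakpoint


def _symbolic_to_breakpoints(rec, info: dict, filt: str) -> list[Breakpoint]:
    """Convert <DEL>/<DUP>/<INV> with END into the equivalent breakend
    pairs. A deletion joining pos to end+1 is the same adjacency the RT
    junction signature looks for."""
    svtype = re.sub(r"[<>]", "", rec.alts[0])
    end = info.get("END", rec.stop)
    pos = rec.pos
    qual = rec.qual

    def be(suffix: str, chrom: str, p: int, orient: Orient, mate_suffix: str) -> Breakend:
        return Breakend(
            record_id=f"{rec.id}_{suffix}", chrom=chrom, pos=p, orient=orient,
            mate_id=f"{rec.id}_{mate_suffix}", filter=filt, qual=qual,
            info=dict(info),
        )

    out: list[Breakpoint] = []
    if svtype == "DEL":
        out.append(_make_breakpoint(
            be("a", rec.chrom, pos, Orient.RIGHT, "b"),
            be("b", rec.chrom, end + 1, Orient.LEFT, "a")))
    elif svtype == "DUP":
        out.append(_make_breakpoint(
            be("a", rec.chrom, end, Orient.RIGHT, "b"),
            be("b", rec.chrom, pos, Orient.LEFT, "a")))
    elif svtype == "INV":
        out.append(_make_breakpoint(
            be("a", rec.chrom, pos - 1 if pos > 1 else 1, Orient.RIGHT, "b"),
            be("b", rec.chrom, end, Orient.RIGHT, "a")))
        out.append(_make_breakpoint(
            be("c", rec.chrom, pos, Orient.LEFT, "d"),
            be("d", rec.chrom, end + 1, Orient.LEFT, "c")))
    return out


def load_callset(
    vcf_path: str | Path,
    dialect: str = "generic",
    convert_symbolic: bool = True,
    min_ins_alt_len: int = 20,
) -> CallSet:
    """Load a VCF callset into the breakend-centric model.

    Every BND record with a resolvable mate appears in exactly one
    :class:`Breakpoint`; BNDs whose mate is absent from the file become
    single breakends (counted in ``n_missing_mates``). Symbolic ``<INS>``
    records with a resolvable full sequence (``SVINSSEQ``/``SEQ``/``INSSEQ``
    INFO keys) and non-symbolic ALT insertions of at least
    ``min_ins_alt_len`` inserted bases become :class:`InsertionRecord`.
    With ``convert_symbolic`` (default), ``<DEL>``/``<DUP>``/``<INV>``
    records with an END are converted to equivalent breakend pairs.

    ``dialect='gridss'`` enables mate-id inference from GRIDSS-style record
    id suffixes when ``MATEID`` is absent; ``'manta'`` and ``'generic'``
    rely on ``MATEID`` alone.

    All INFO/FILTER/QUAL content is preserved verbatim on the model objects.
    Duplicate record ids raise ``ValueError``.
    """
    cs = CallSet()
    breakends: dict[str, Breakend] = {}
    order: list[str] = []

    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) == 0:
                cs.rejected.append((rec.id or "?", "no ALT"))
                continue
            if len(rec.alts) > 1:
                cs.rejected.append((rec.id or "?", "multi-allelic record"))
                continue
            alt = rec.alts[0]
            info = _info_to_dict(rec)
            filt = _filter_string(rec)
            svtype = info.get("SVTYPE", "")

            if "[" in alt or "]" in alt:
                cs.n_bnd_records += 1
                if rec.id is None:
                    cs.rejected.append(("?", "BND record without ID"))
                    continue
                if rec.id in breakends:
                    raise ValueError(f"duplicate record ID {rec.id!r}")
                try:
                    mchrom, mpos, orient, morient, ins = parse_bnd_alt(rec.ref, alt)
                except MalformedBreakendError as exc:
                    cs.rejected.append((rec.id, str(exc)))
                    continue
                mate_id = info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                if mate_id is None and dialect == "gridss":
                    mate_id = _gridss_mate_id(rec.id)
                be = Breakend(
                    record_id=rec.id, chrom=rec.chrom, pos=rec.pos,
                    orient=orient, mate_id=mate_id, inserted_seq=ins,
                    filter=filt, qual=rec.qual, info=info,
                )
                be.info["_MATE_CHROM"] = mchrom  # cross-check only
                be.info["_MATE_POS"] = mpos
                breakends[rec.id] = be
                order.append(rec.id)
            elif alt.startswith(".") or alt.endswith("."):
                cs.n_bnd_records += 1
                try:
                    orient, ins = _parse_single_alt(rec.ref, alt)
                except MalformedBreakendError as exc:
                    cs.rejected.append((rec.id or "?", str(exc)))
                    continue
                cs.single_breakends.append(Breakend(
                    record_id=rec.id or f"sb_{rec.chrom}_{rec.pos}",
                    chrom=rec.chrom, pos=rec.pos, orient=orient,
                    mate_id=None, inserted_seq=ins, filter=filt,
                    qual=rec.qual, info=info,
                ))
            elif alt == "<INS>" or svtype == "INS" and alt.startswith("<"):
                seq = info.get("SVINSSEQ") or info.get("SEQ") or info.get("INSSEQ")
                if isinstance(seq, tuple):
                    seq = seq[0]
                if not seq:
                    cs.rejected.append((rec.id or "?", "<INS> without resolvable sequence"))
                    continue
                cs.insertions.append(InsertionRecord(
                    chrom=rec.chrom, pos=rec.pos, seq=str(seq), filter=filt,
                    info=info, record_id=rec.id or "",
                ))
            elif alt.startswith("<"):
                if convert_symbolic and re.sub(r"[<>]", "", alt) in ("DEL", "DUP", "INV"):
                    cs.breakpoints.extend(_symbolic_to_breakpoints(rec, info, filt))
                else:
                    cs.rejected.append((rec.id or "?", f"unsupported symbolic ALT {alt}"))
            elif (_NUC_RE.match(alt) and len(alt) > len(rec.ref)
                  and len(alt) - len(rec.ref) >= min_ins_alt_len
                  and alt[: len(rec.ref)].upper() == rec.ref.upper()):
                cs.insertions.append(InsertionRecord(
                    chrom=rec.chrom, pos=rec.pos, seq=alt[len(rec.ref):],
                    filter=filt, info=info, record_id=rec.id or "",
                ))
            else:
                cs.rejected.append((rec.id or "?", f"not an SV record (ALT {alt})"))

    # Mate pairing by MATEID (partner-of-partner must agree).
    paired: set[str] = set()
    for rid in order:
        if rid in paired:
            continue
        be = breakends[rid]
        mate = breakends.get(be.mate_id) if be.mate_id else None
        if mate is not None and mate.record_id != rid and (
                mate.mate_id == rid or mate.mate_id is None):
            cs.breakpoints.append(_make_breakpoint(be, mate))
            paired.add(rid)
            paired.add(mate.record_id)
        elif mate is None or mate.record_id == rid:
            cs.n_missing_mates += 1
            cs.single_breakends.append(be)
            paired.add(rid)
        else:
            # partner points elsewhere: asymmetric mating
            cs.rejected.append((rid, f"asymmetric MATEID ({be.mate_id} -> {mate.mate_id})"))
            paired.add(rid)
    return cs


# --------------------------------------------------------------------------
# BEDPE / VCF writers
# --------------------------------------------------------------------------

_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
    "strand1\tstrand2\tfilter\tinserted_seq\tinfo1\tinfo2"
)


def _serialize_info(info: Mapping) -> str:
    clean = {k: v for k, v in info.items() if not k.startswith("_MATE_")}
    if not clean:
        return "."
    return json.dumps(clean, separators=(",", ":"), default=str)


def write_bedpe(breakpoints: Iterable[Breakpoint], out_path: str | Path) -> None:
    """Write breakpoints as BEDPE (0-based half-open per side, strands from
    orientation, metadata after column 10). Round-trips losslessly through
    :func:`read_bedpe` for loci, orientations, ids and INFO."""
    with open(out_path, "w") as fh:
        fh.write(_BEDPE_HEADER + "\n")
        for bp in breakpoints:
            l, r = bp.left, bp.right
            qual = "." if l.qual is None else f"{l.qual:g}"
            fh.write("\t".join([
                l.chrom, str(l.pos - 1), str(l.pos),
                r.chrom, str(r.pos - 1), str(r.pos),
                f"{l.record_id};{r.record_id}", qual,
                l.orient.strand, r.orient.strand,
                bp.source_filter, bp.inserted_seq or ".",
                _serialize_info(l.info), _serialize_info(r.info),
            ]) + "\n")


def read_bedpe(path: str | Path) -> list[Breakpoint]:
    """Parse a BEDPE file written by :func:`write_bedpe` back into
    breakpoints."""
    out: list[Breakpoint] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name1, _, name2 = f[6].partition(";")
            ins = "" if len(f) < 12 or f[11] == "." else f[11]
            info1 = {} if len(f) < 13 or f[12] == "." else json.loads(f[12])
            info2 = {} if len(f) < 14 or f[13] == "." else json.loads(f[13])
            filt = f[10] if len(f) > 10 else "PASS"
            qual = None if f[7] == "." else float(f[7])
            left = Breakend(
                record_id=name1, chrom=f[0], pos=int(f[2]),
                orient=Orient.from_strand(f[8]), mate_id=name2 or None,
                inserted_seq=ins, filter=filt, qual=qual, info=info1)
            right = Breakend(
                record_id=name2, chrom=f[3], pos=int(f[5]),
                orient=Orient.from_strand(f[9]), mate_id=name1,
                inserted_seq=ins, filter=filt, qual=qual, info=info2)
            out.append(Breakpoint(left=left, right=right, source_filter=filt))
    return out


def write_annotated_vcf(
    vcf_in: str | Path,
    memberships: Mapping[str, str],
    out_path: str | Path,
    tag: str = "SVASCAN_EVENT",
) -> None:
    """Echo the input VCF with an event-membership INFO tag added to every
    record whose ID appears in ``memberships``."""
    opener = gzip.open if str(vcf_in).endswith(".gz") else open
    header_line = (
        f'##INFO=<ID={tag},Number=1,Type=String,'
        f'Description="Event membership assigned by svascan">\n'
    )
    with opener(str(vcf_in), "rt") as src, open(out_path, "w") as dst:
        for line in src:
            if line.startswith("##"):
                dst.write(line)
                continue
            if line.startswith("#CHROM"):
                dst.write(header_line)
                dst.write(line)
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) > 7 and fields[2] in memberships:
                extra = f"{tag}={memberships[fields[2]]}"
                fields[7] = extra if fields[7] in (".", "") else fields[7] + ";" + extra
            dst.write("\t".join(fields) + "\n")
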