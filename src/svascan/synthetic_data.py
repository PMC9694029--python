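"""Synthetic references, annotations, and caller-level SV callsets.

The generator builds a desk-scale study system: a pseudo-random nuclear
contig plus a mitochondrial contig, a set of multi-exon transcript models,
and a breakend VCF that emulates what a *perfect* general-purpose SV caller
would emit for planted retrocopy (RT) and NUMT insertions — deletion-like
breakpoints at every exon-exon junction, plus two breakpoints joining the
inserted sequence's ends to the insertion locus (with target-site
duplication and a polyadenylation tail). Caller imperfection is modelled by
explicit corruption operators (dropped junctions, transitive merges,
breakend jitter, unmapped insertion sequences emitted as sequence-bearing
INS records, non-PASS filters) rather than by read-level simulation, which
is deliberately out of scope.

Everything is deterministic given the seed: the same seed and configuration
produce byte-identical FASTA, GTF, VCF and truth files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import (
    BoundarySide,
    Strand,
    TranscriptModel,
    boundaries_of,
)
from .breakend_model import Orient, chrom_sort_key, reverse_complement

__all__ = [
    "TruthEvent",
    "CorruptionConfig",
    "SimulationResult",
    "ScoreReport",
    "DetectionSummary",
    "NUMT_LENGTH_LADDER",
    "make_reference",
    "make_transcripts",
    "write_fasta",
    "write_gtf",
    "simulate",
    "load_truth",
    "score_against_truth",
    "summarize_rt_events",
    "summarize_numt_events",
]

#: mtDNA segment-length ladder used by the simulation design (bp); events
#: cycle through it so each length class is represented equally.
NUMT_LENGTH_LADDER = (10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000)

_BASES = np.array(list("ACGT"))


@dataclass
class TruthEvent:
    """Ground truth for one planted insertion event."""

    event_id: str
    kind: str  # "RT" | "NUMT"
    source: str  # tx_id, or "chrM:start-end" for NUMTs
    source_gene: str  # gene_id for RT, "" for NUMT
    insertion_chrom: str
    insertion_pos: int
    polya_len: int = 0
    tsd_len: int = 0
    five_prime_truncation: int = 0
    emitted_as: str = "bnd"  # "bnd" | "ins"
    emitted_breakpoints: list[str] = field(default_factory=list)
    mt_len: int = 0  # NUMT segment length


@dataclass
class CorruptionConfig:
    """Caller-imperfection model; all probabilities in [0, 1], all
    randomness drawn from the simulation seed."""

    p_drop_junction: float = 0.0
    p_transitive_merge: float = 0.0
    jitter_sd_bp: int = 0
    p_unmap_insertion: float = 0.0
    p_nonpass_filter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_drop_junction", "p_transitive_merge",
                     "p_unmap_insertion", "p_nonpass_filter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.jitter_sd_bp < 0:
            raise ValueError("jitter_sd_bp must be >= 0")


@dataclass
class SimulationResult:
    truth: list[TruthEvent]
    transcripts: list[TranscriptModel]
    reference: dict[str, str]
    ref_fasta: Path | None = None
    gtf: Path | None = None
    vcf: Path | None = None
    truth_tsv: Path | None = None


# --------------------------------------------------------------------------
# Reference and annotation
# --------------------------------------------------------------------------


def make_reference(
    seed: int,
    nuclear_len: int = 1_000_000,
    mt_len: int = 16_569,
    gc: float = 0.41,
    nuclear_name: str = "chr1",
    mt_name: str = "chrM",
) -> dict[str, str]:
    """Deterministic pseudo-random reference sequences at the configured
    GC content."""
    if nuclear_len < 1000 or mt_len < 500:
        raise ValueError("nuclear contig must be >= 1 kb and chrM >= 500 bp")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def draw(n: int) -> str:
        return "".join(_BASES[rng.choice(4, size=n, p=p)])

    return {nuclear_name: draw(nuclear_len), mt_name: draw(mt_len)}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_transcripts(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    n_tx: int = 20,
    exon_count_range: tuple[int, int] = (2, 10),
    exon_len_range: tuple[int, int] = (80, 300),
    intron_len_range: tuple[int, int] = (200, 1500),
    first_gene_start: int = 10_000,
    intergenic_gap: int = 5_000,
) -> list[TranscriptModel]:
    """Lay out non-overlapping single-transcript genes along the contig.

    Every transcript is multi-exon by default (2-10 exons); strand is
    random. Genes are separated by ``intergenic_gap`` so locus-exclusion
    padding in the RT detector never merges neighbours.
    """
    models: list[TranscriptModel] = []
    cursor = first_gene_start
    for k in range(1, n_tx + 1):
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                                   size=max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i]) - 1))
            pos = exons[-1][1] + 1
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        if exons[-1][1] + intergenic_gap >= chrom_len:
            raise ValueError(
                f"contig of {chrom_len} bp too short for {n_tx} genes")
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        models.append(TranscriptModel(
            tx_id=f"TX{k:03d}", gene_id=f"GENE{k:03d}",
            gene_symbol=f"SYNG{k:03d}", chrom=chrom, strand=strand,
            exons=exons))
        cursor = exons[-1][1] + intergenic_gap
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#!genome synthetic\n")
        for tx in transcripts:
            s, e = tx.span
            attrs = (f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}"; '
                     f'gene_name "{tx.gene_symbol}";')
            fh.write("\t".join([
                tx.chrom, "svascan_sim", "transcript", str(s), str(e), ".",
                tx.strand.value, ".", attrs]) + "\n")
            for es, ee in tx.exons:
                fh.write("\t".join([
                    tx.chrom, "svascan_sim", "exon", str(es), str(ee), ".",
                    tx.strand.value, ".", attrs]) + "\n")


# --------------------------------------------------------------------------
# Event planting
# --------------------------------------------------------------------------


def _mrna_pos_to_genomic(tx: TranscriptModel, offset: int) -> int:
    """Genomic coordinate of the 0-based mRNA position ``offset``."""
    if not 0 <= offset < tx.mrna_length:
        raise ValueError("mRNA offset out of range")
    remaining = offset
    for i in range(1, tx.n_exons + 1):
        s, e = tx.exon_by_tx_index(i)
        length = e - s + 1
        if remaining < length:
            return s + remaining if tx.strand is Strand.PLUS else e - remaining
        remaining -= length
    raise AssertionError("unreachable")


def _mrna_sequence(tx: TranscriptModel, reference: dict[str, str]) -> str:
    chrom_seq = reference[tx.chrom]
    parts = [chrom_seq[s - 1:e] for s, e in tx.exons]
    mrna = "".join(parts)
    return mrna if tx.strand is Strand.PLUS else reverse_complement(mrna)


@dataclass
class _VcfRecord:
    chrom: str
    pos: int
    rec_id: str
    ref: str
    alt: str
    filter: str
    info: str


def _bnd_alt(orient: Orient, mate_chrom: str, mate_pos: int,
             mate_orient: Orient, ref_base: str, ins: str) -> str:
    bracket = "[" if mate_orient is Orient.LEFT else "]"
    locus = f"{bracket}{mate_chrom}:{mate_pos}{bracket}"
    if orient is Orient.RIGHT:
        return f"{ref_base}{ins}{locus}"
    return f"{locus}{ins}{ref_base}"


class _Emitter:
    """Accumulates VCF records for planted events."""

    def __init__(self, reference: dict[str, str], rng: np.random.Generator,
                 corruption: CorruptionConfig):
        self.reference = reference
        self.rng = rng
        self.cc = corruption
        self.records: list[_VcfRecord] = []

    def _ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos - 1]

    def _jitter(self, chrom: str, pos: int) -> int:
        if self.cc.jitter_sd_bp > 0:
            pos += int(round(self.rng.normal(0.0, self.cc.jitter_sd_bp)))
        return min(max(pos, 1), len(self.reference[chrom]))

    def _filter(self) -> str:
        if self.cc.p_nonpass_filter > 0 and self.rng.random() < self.cc.p_nonpass_filter:
            return "LOW_QUAL"
        return "PASS"

    def breakpoint(self, event_id: str, label: str,
                   chrom_a: str, pos_a: int, orient_a: Orient,
                   chrom_b: str, pos_b: int, orient_b: Orient,
                   ins_seen_from_a: str = "") -> str:
        """Emit one breakpoint as two mated BND records; returns the
        breakpoint id stem."""
        pos_a = self._jitter(chrom_a, pos_a)
        pos_b = self._jitter(chrom_b, pos_b)
        filt = self._filter()
        stem = f"{event_id}_{label}"
        id_a, id_b = f"{stem}_1", f"{stem}_2"
        ins_b = (ins_seen_from_a if orient_a != orient_b
                 else reverse_complement(ins_seen_from_a))
        ref_a = self._ref_base(chrom_a, pos_a)
        ref_b = self._ref_base(chrom_b, pos_b)
        self.records.append(_VcfRecord(
            chrom_a, pos_a, id_a, ref_a,
            _bnd_alt(orient_a, chrom_b, pos_b, orient_b, ref_a, ins_seen_from_a),
            filt, f"SVTYPE=BND;MATEID={id_b};EVENT={event_id}"))
        self.records.append(_VcfRecord(
            chrom_b, pos_b, id_b, ref_b,
            _bnd_alt(orient_b, chrom_a, pos_a, orient_a, ref_b, ins_b),
            filt, f"SVTYPE=BND;MATEID={id_a};EVENT={event_id}"))
        return stem

    def insertion(self, event_id: str, chrom: str, pos: int, seq: str) -> str:
        pos = self._jitter(chrom, pos)
        filt = self._filter()
        rec_id = f"{event_id}_ins"
        ref = self._ref_base(chrom, pos)
        self.records.append(_VcfRecord(
            chrom, pos, rec_id, ref, ref + seq, filt,
            f"SVTYPE=INS;SVLEN={len(seq)};EVENT={event_id}"))
        return rec_id


def _merge_junctions(n_exons: int, rng: np.random.Generator,
                     p_merge: float) -> list[tuple[int, int]]:
    """Transcript-order junction list with stochastic transitive merging:
    adjacent junctions collapse into a single spanning call."""
    hits: list[tuple[int, int]] = []
    k = 1
    while k <= n_exons - 1:
        j = k
        while j < n_exons - 1 and p_merge > 0 and rng.random() < p_merge:
            j += 1
        hits.append((k, j + 1))
        k = j + 1
    return hits


def _junction_genomic(tx: TranscriptModel, from_exon: int, to_exon: int
                      ) -> tuple[int, int]:
    """Genomic (lower, higher) breakend positions of the deletion-like
    call joining the donor of ``from_exon`` to the acceptor of
    ``to_exon``."""
    donor = acceptor = None
    for b in boundaries_of(tx):
        if b.exon_index == from_exon and b.side is BoundarySide.DONOR:
            donor = b.pos
        if b.exon_index == to_exon and b.side is BoundarySide.ACCEPTOR:
            acceptor = b.pos
    assert donor is not None and acceptor is not None
    return (donor, acceptor) if donor < acceptor else (acceptor, donor)


def _plant_rt(em: _Emitter, event_id: str, tx: TranscriptModel,
              ins_chrom: str, ins_pos: int, polya_len: int, tsd_len: int,
              truncation: int, rng: np.random.Generator) -> TruthEvent:
    truth = TruthEvent(
        event_id=event_id, kind="RT", source=tx.tx_id,
        source_gene=tx.gene_id, insertion_chrom=ins_chrom,
        insertion_pos=ins_pos, polya_len=polya_len, tsd_len=tsd_len,
        five_prime_truncation=truncation)

    # exons wholly removed by 5' truncation leave no junction signature
    first_retained = 1
    if truncation > 0:
        off = truncation
        for i in range(1, tx.n_exons + 1):
            s, e = tx.exon_by_tx_index(i)
            if off < e - s + 1:
                first_retained = i
                break
            off -= e - s + 1

    for from_e, to_e in _merge_junctions(tx.n_exons, rng,
                                         em.cc.p_transitive_merge):
        if from_e < first_retained:
            continue
        if em.cc.p_drop_junction > 0 and rng.random() < em.cc.p_drop_junction:
            continue
        lo, hi = _junction_genomic(tx, from_e, to_e)
        stem = em.breakpoint(event_id, f"j{from_e}_{to_e}",
                             tx.chrom, lo, Orient.RIGHT,
                             tx.chrom, hi, Orient.LEFT)
        truth.emitted_breakpoints.append(stem)

    polya = "A" * polya_len
    if em.cc.p_unmap_insertion > 0 and rng.random() < em.cc.p_unmap_insertion:
        mrna = _mrna_sequence(tx, em.reference)[truncation:]
        truth.emitted_as = "ins"
        truth.emitted_breakpoints.append(
            em.insertion(event_id, ins_chrom, ins_pos, mrna + polya))
        return truth

    g5 = _mrna_pos_to_genomic(tx, truncation)
    g3 = _mrna_pos_to_genomic(tx, tx.mrna_length - 1)
    orient5 = Orient.LEFT if tx.strand is Strand.PLUS else Orient.RIGHT
    orient3 = Orient.RIGHT if tx.strand is Strand.PLUS else Orient.LEFT
    left_junction = ins_pos + tsd_len if tsd_len > 0 else ins_pos
    truth.emitted_breakpoints.append(em.breakpoint(
        event_id, "site5", ins_chrom, left_junction, Orient.RIGHT,
        tx.chrom, g5, orient5))
    truth.emitted_breakpoints.append(em.breakpoint(
        event_id, "site3", tx.chrom, g3, orient3,
        ins_chrom, ins_pos + 1, Orient.LEFT, ins_seen_from_a=polya))
    return truth


def _plant_numt(em: _Emitter, event_id: str, mt_name: str, mt_start: int,
                seg_len: int, ins_chrom: str, ins_pos: int, polya_len: int,
                tsd_len: int, rng: np.random.Generator) -> TruthEvent:
    mt_end = mt_start + seg_len - 1
    truth = TruthEvent(
        event_id=event_id, kind="NUMT",
        source=f"{mt_name}:{mt_start}-{mt_end}", source_gene="",
        insertion_chrom=ins_chrom, insertion_pos=ins_pos,
        polya_len=polya_len, tsd_len=tsd_len, mt_len=seg_len)

    polya = "A" * polya_len
    if em.cc.p_unmap_insertion > 0 and rng.random() < em.cc.p_unmap_insertion:
        seq = em.reference[mt_name][mt_start - 1:mt_end] + polya
        truth.emitted_as = "ins"
        truth.emitted_breakpoints.append(
            em.insertion(event_id, ins_chrom, ins_pos, seq))
        return truth

    left_junction = ins_pos + tsd_len if tsd_len > 0 else ins_pos
    for label, args in (
        ("siteA", (ins_chrom, left_junction, Orient.RIGHT,
                   mt_name, mt_start, Orient.LEFT, "")),
        ("siteB", (mt_name, mt_end, Orient.RIGHT,
                   ins_chrom, ins_pos + 1, Orient.LEFT, polya)),
    ):
        if em.cc.p_drop_junction > 0 and rng.random() < em.cc.p_drop_junction:
            continue
        c1, p1, o1, c2, p2, o2, ins = args
        truth.emitted_breakpoints.append(
            em.breakpoint(event_id, label, c1, p1, o1, c2, p2, o2,
                          ins_seen_from_a=ins))
    return truth


def _insertion_loci(rng: np.random.Generator, nuclear_len: int,
                    transcripts: Sequence[TranscriptModel], n: int,
                    spacing: int = 3000, locus_pad: int = 1500,
                    edge: int = 5000) -> list[int]:
    """Non-overlapping insertion loci outside all (padded) gene loci."""
    grid = np.arange(edge, nuclear_len - edge, spacing)
    mask = np.ones(grid.shape, dtype=bool)
    for tx in transcripts:
        s, e = tx.span
        mask &= ~((grid >= s - locus_pad) & (grid <= e + locus_pad))
    free = grid[mask]
    if len(free) < n:
        raise ValueError(
            f"cannot place {n} non-overlapping events: only {len(free)} "
            "candidate loci available; increase nuclear_len")
    chosen = rng.choice(free, size=n, replace=False)
    return [int(x) for x in np.sort(chosen)]


# --------------------------------------------------------------------------
# Top-level simulation
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svascan-sim
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=EVENT,Number=1,Type=String,Description="ID of the planted event">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of inserted sequence">
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LOW_QUAL,Description="Low quality call">
"""


def simulate(
    seed: int,
    n_rt: int = 100,
    n_numt: int = 100,
    out_dir: str | Path | None = None,
    corruption: CorruptionConfig | None = None,
    numt_length_ladder: Sequence[int] = NUMT_LENGTH_LADDER,
    nuclear_len: int = 1_000_000,
    mt_len: int = 16_569,
    n_tx: int = 20,
    polya_len: int = 20,
    tsd_len: int = 10,
    five_prime_truncation_max: int = 0,
    gc: float = 0.41,
    nuclear_name: str = "chr1",
    mt_name: str = "chrM",
) -> SimulationResult:
    """Plant ``n_rt`` retrocopy and ``n_numt`` NUMT events and emit the
    caller-level VCF plus the ground-truth table.

    With all corruption probabilities zero the emission is perfect-caller
    output: every junction and both insertion-site breakpoints of every
    event appear, PASS-filtered, at exact positions. NUMT segment lengths
    cycle through ``numt_length_ladder``. If ``out_dir`` is given, writes
    ``ref.fa``, ``tx.gtf``, ``calls.vcf`` and ``truth.tsv`` there.
    """
    corruption = corruption or CorruptionConfig()
    if any(l > mt_len for l in numt_length_ladder):
        raise ValueError("NUMT ladder length exceeds the mitochondrial genome")
    if any(l < 1 for l in numt_length_ladder):
        raise ValueError("NUMT ladder lengths must be >= 1")

    reference = make_reference(seed, nuclear_len, mt_len, gc,
                               nuclear_name, mt_name)
    rng = np.random.default_rng(seed + 1)
    transcripts = make_transcripts(rng, nuclear_name, nuclear_len, n_tx=n_tx)
    loci = _insertion_loci(rng, nuclear_len, transcripts, n_rt + n_numt)
    loci_order = rng.permutation(len(loci))

    em = _Emitter(reference, rng, corruption)
    truth: list[TruthEvent] = []

    for k in range(n_rt):
        tx = transcripts[int(rng.integers(0, len(transcripts)))]
        trunc = (int(rng.integers(0, five_prime_truncation_max + 1))
                 if five_prime_truncation_max > 0 else 0)
        trunc = min(trunc, tx.mrna_length - 1)
        pos = loci[int(loci_order[k])]
        truth.append(_plant_rt(
            em, f"RT{k + 1:04d}", tx, nuclear_name, pos,
            polya_len, tsd_len, trunc, rng))

    for k in range(n_numt):
        seg_len = int(numt_length_ladder[k % len(numt_length_ladder)])
        mt_start = int(rng.integers(1, mt_len - seg_len + 2))
        pos = loci[int(loci_order[n_rt + k])]
        truth.append(_plant_numt(
            em, f"NUMT{k + 1:04d}", mt_name, mt_start, seg_len,
            nuclear_name, pos, polya_len, tsd_len, rng))

    result = SimulationResult(truth=truth, transcripts=transcripts,
                              reference=reference)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.ref_fasta = out_dir / "ref.fa"
        result.gtf = out_dir / "tx.gtf"
        result.vcf = out_dir / "calls.vcf"
        result.truth_tsv = out_dir / "truth.tsv"
        write_fasta(reference, result.ref_fasta)
        write_gtf(transcripts, result.gtf)
        _write_vcf(em.records, reference, result.vcf)
        write_truth(truth, result.truth_tsv)
    return result


def _write_vcf(records: list[_VcfRecord], reference: dict[str, str],
               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (chrom_sort_key(r.chrom),
                                                  r.pos, r.rec_id)):
            fh.write("\t".join([
                rec.chrom, str(rec.pos), rec.rec_id, rec.ref, rec.alt,
                "60", rec.filter, rec.info]) + "\n")


_TRUTH_COLUMNS = [
    "event_id", "kind", "source", "source_gene", "insertion_chrom",
    "insertion_pos", "polya_len", "tsd_len", "five_prime_truncation",
    "emitted_as", "emitted_breakpoints", "mt_len",
]


def write_truth(truth: Iterable[TruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            d = asdict(t)
            d["emitted_breakpoints"] = ",".join(t.emitted_breakpoints) or "."
            fh.write("\t".join(str(d[c]) for c in _TRUTH_COLUMNS) + "\n")


def load_truth(path: str | Path) -> list[TruthEvent]:
    out: list[TruthEvent] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = dict(zip(_TRUTH_COLUMNS, line.rstrip("\n").split("\t")))
            out.append(TruthEvent(
                event_id=f["event_id"], kind=f["kind"], source=f["source"],
                source_gene=f["source_gene"],
                insertion_chrom=f["insertion_chrom"],
                insertion_pos=int(f["insertion_pos"]),
                polya_len=int(f["polya_len"]), tsd_len=int(f["tsd_len"]),
                five_prime_truncation=int(f["five_prime_truncation"]),
                emitted_as=f["emitted_as"],
                emitted_breakpoints=(
                    [] if f["emitted_breakpoints"] == "."
                    else f["emitted_breakpoints"].split(",")),
                mt_len=int(f["mt_len"]),
            ))
    return out


# --------------------------------------------------------------------------
# Scoring against truth
# --------------------------------------------------------------------------


@dataclass
class DetectionSummary:
    """Caller-agnostic view of one detected event for truth matching."""

    label: str
    gene_id: str | None  # RT only; None disables the gene-match requirement
    sites: list[tuple[str, int]]  # reported insertion-site loci
    linked: bool = False


@dataclass
class ScoreReport:
    kind: str
    n_truth: int
    n_detected: int
    n_matched_truth: int
    n_true_positive: int
    n_false_positive: int
    n_duplicate: int
    recall: float
    precision: float
    unmatched_by_mode: dict[str, int] = field(default_factory=dict)
    matched_linked: int = 0  # matched detections that were two-sided

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_rt_events(events) -> list[DetectionSummary]:
    out = []
    for ev in events:
        sites = sorted({(s.target_breakend.chrom, s.target_breakend.pos)
                        for s in ev.insertion_sites})
        out.append(DetectionSummary(
            label=ev.gene_id, gene_id=ev.gene_id, sites=sites,
            linked=len(sites) >= 2))
    return out


def summarize_numt_events(events) -> list[DetectionSummary]:
    out = []
    for i, ev in enumerate(events):
        sites = [(ev.nuclear_chrom, s.nuclear_pos) for s in ev.sites]
        out.append(DetectionSummary(
            label=f"numt_{i}", gene_id=None, sites=sorted(set(sites)),
            linked=ev.linked))
    return out


def score_against_truth(
    detections: Sequence[DetectionSummary],
    truth: Sequence[TruthEvent],
    kind: str,
    match_window: int = 100,
) -> ScoreReport:
    """Match detections to planted events.

    A detection matches a truth event iff any of its reported insertion-site
    breakends is within ``match_window`` bp (inclusive) of the true
    insertion locus and, for RT, the source gene agrees. Truth events are
    claimed greedily by distance, each at most once; a single gene-grouped
    RT detection may claim several truth events of the same source gene
    (repeated source transcripts necessarily collapse into one gene-level
    call). Detections whose only matching truth events were already claimed
    by closer detections are flagged duplicates, not false positives.
    """
    truth = [t for t in truth if t.kind == kind]
    cand: list[tuple[int, int, int]] = []  # (dist, truth_idx, det_idx)
    for ti, t in enumerate(truth):
        for di, det in enumerate(detections):
            if kind == "RT" and det.gene_id is not None and \
                    det.gene_id != t.source_gene:
                continue
            dists = [abs(pos - t.insertion_pos)
                     for chrom, pos in det.sites if chrom == t.insertion_chrom]
            if dists and min(dists) <= match_window:
                cand.append((min(dists), ti, di))
    cand.sort()
    claimed_truth: set[int] = set()
    matched_det: set[int] = set()
    had_candidate: set[int] = set()
    for dist, ti, di in cand:
        had_candidate.add(di)
        if ti in claimed_truth:
            continue
        claimed_truth.add(ti)
        matched_det.add(di)

    n_dup = len(had_candidate - matched_det)
    n_fp = len(detections) - len(matched_det) - n_dup
    unmatched = [t for i, t in enumerate(truth) if i not in claimed_truth]
    modes: dict[str, int] = {}
    for t in unmatched:
        mode = ("unmapped_insertion_sequence" if t.emitted_as == "ins"
                else "no_breakpoint_near_site")
        modes[mode] = modes.get(mode, 0) + 1
    n_truth = len(truth)
    n_det = len(detections)
    denom = len(matched_det) + n_fp
    return ScoreReport(
        kind=kind, n_truth=n_truth, n_detected=n_det,
        n_matched_truth=len(claimed_truth),
        n_true_positive=len(matched_det), n_false_positive=n_fp,
        n_duplicate=n_dup,
        recall=len(claimed_truth) / n_truth if n_truth else float("nan"),
        precision=len(matched_det) / denom if denom else float("nan"),
        unmatched_by_mode=modes,
        matched_linked=sum(1 for di in matched_det if detections[di].linked),
    )
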