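"""Shared fixtures: hand-built transcripts, breakpoints and minimal VCFs."""

from __future__ import annotations

from pathlib import Path

import pytest

from svascan.annotation import Strand, TranscriptModel
from svascan.breakend_model import Breakend, Orient, make_breakpoint

VCF_STUB = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Insertion sequence">
##INFO=<ID=CUSTOM,Number=1,Type=String,Description="Caller metadata">
##FILTER=<ID=PASS,Description="ok">
##FILTER=<ID=LOW_QUAL,Description="low">
##contig=<ID=chr1,length=2000000>
##contig=<ID=chr2,length=2000000>
##contig=<ID=chrM,length=16569>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path: Path, body_lines: list[str]) -> Path:
    path.write_text(VCF_STUB + "".join(line + "\n" for line in body_lines))
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(body_lines, name="calls.vcf"):
        return write_vcf(tmp_path / name, body_lines)

    return _write


def bnd_pair(chrom1, pos1, o1, chrom2, pos2, o2, ins="", filt="PASS",
             stem="bp"):
    """Two mated breakends as a canonical breakpoint (library objects,
    bypassing VCF)."""
    a = Breakend(record_id=f"{stem}_1", chrom=chrom1, pos=pos1, orient=o1,
                 mate_id=f"{stem}_2", inserted_seq=ins, filter=filt)
    b = Breakend(record_id=f"{stem}_2", chrom=chrom2, pos=pos2, orient=o2,
                 mate_id=f"{stem}_1", filter=filt)
    return make_breakpoint(a, b)


def deletion_like(chrom, lo, hi, stem="bp", filt="PASS"):
    return bnd_pair(chrom, lo, Orient.RIGHT, chrom, hi, Orient.LEFT,
                    stem=stem, filt=filt)


@pytest.fixture
def three_exon_plus():
    return TranscriptModel(
        tx_id="TX1", gene_id="GENE1", gene_symbol="G1", chrom="chr1",
        strand=Strand.PLUS, exons=[(101, 200), (301, 400), (501, 600)])


@pytest.fixture
def three_exon_minus():
    return TranscriptModel(
        tx_id="TX1M", gene_id="GENE1M", gene_symbol="G1M", chrom="chr1",
        strand=Strand.MINUS, exons=[(101, 200), (301, 400), (501, 600)])


def make_tx(n_exons, strand=Strand.PLUS, chrom="chr1", exon_len=100,
            intron_len=100, start=1001, tx_id="TXN", gene_id="GENEN"):
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    return TranscriptModel(tx_id=tx_id, gene_id=gene_id, gene_symbol=gene_id,
                           chrom=chrom, strand=strand, exons=exons)
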