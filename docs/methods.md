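# Methods

## The breakend model

Every SV call is reduced to breakends. A breakend is `(chrom, pos, orient)`
with 1-based VCF coordinates kept internally; `orient = RIGHT` means the
retained segment extends to lower coordinates and joins at this position
from its right edge (BEDPE strand `+`), `LEFT` the mirror image. The four
bracketed ALT forms map to (local, mate) orientations as
`t[p[ → (RIGHT, LEFT)`, `t]p] → (RIGHT, RIGHT)`, `]p]t → (LEFT, RIGHT)`,
`[p[t → (LEFT, LEFT)`; novel bases between the anchoring REF base and the
bracket are the junction's inserted sequence. Mates are paired by `MATEID`
(with an optional GRIDSS-style id-suffix fallback behind the
`--caller-dialect gridss` flag) and ordered canonically by natural
chromosome order, so a breakpoint is reproducible regardless of record
order in the file. Conversions to 0-based half-open coordinates happen only
in the BED/BEDPE readers and writers, keeping the off-by-one surface in one
place.

Symbolic `<DEL>`/`<DUP>`/`<INV>` records with an `END` are converted to the
equivalent breakend pairs on load (a deletion becomes
`(pos, RIGHT) ↔ (END+1, LEFT)`), because some callers emit the deletion-like
exon-junction signature in symbolic form. Multi-allelic BND records are
rejected with a diagnostic rather than guessed at.

A breakpoint's joint filter is `PASS` only when both mates are `PASS`,
otherwise the lexicographically first non-PASS value; NUMT confidence
tiering consumes this per-site value.

## RT detection

*Junctions.* For each transcript the 2(n−1) internal exon boundaries are
enumerated in transcript (5′→3′) order; boundary positions are the exon's
terminal retained base, not the first intronic base, because deletion-like
breakends from a spliced-out intron land on retained sequence. A breakpoint
supports transcript T when one breakend is within `maxgap` of a donor of
exon *i*, the other within `maxgap` of an acceptor of exon *j > i*, and the
pair is genomically deletion-like (lower breakend `RIGHT`, higher `LEFT`) —
a condition that is strand-invariant even though the donor/acceptor labels
swap ends on the minus strand. `maxgap` is applied per breakend, not to the
sum over both ends. When a breakend is within `maxgap` of several
boundaries of one transcript the nearest wins; exact ties go to the lower
exon index. Strict orientation can be relaxed (`--lenient-orientation`) for
callers that mis-orient small deletions.

*Scoring.* A junction call *i → j* covers introns *i..j−1*; the transcript
score is the size of the union of covered introns over n−1. This makes the
score invariant under transitive merging: replacing *i → i+1* and
*i+1 → i+2* by the single call *i → i+2* changes nothing, which is
exercised exhaustively in the tests for 2–6-exon transcripts. An
alternative numerator that counts calls rather than introns is available
(`--score-mode count`) for users who want transitive calls weighted less.
Defaults: `maxgap = 100` bp (matching the 100 bp truth-window convention of
the simulation design) and `minscore = 0.4`, which admits a transcript with
2 of 4 introns recovered but rejects 1 of 4. Both are tunable and should be
adjusted to the purpose of the detection: low-confidence inputs raise
sensitivity and the false-positive rate together.

*Insertion sites.* A breakpoint is an insertion-site candidate for T when
exactly one breakend overlaps T's exons — with no gap tolerance, because
frequent 5′ truncation moves the 5′ junction an unpredictable distance into
the transcript — and its mate lies outside the gene locus (union of the
gene's transcript spans padded by 1 kb, configurable), which excludes
intra-gene rearrangements. Sites are labelled 5′ when the exonic breakend
is strictly upstream, in transcript orientation, of the midpoint of the
exonic span; ties and downstream positions are 3′. Events with junctions
but no sites are retained (sites may be missed on one or both sides).
Single-exon transcripts, which have no junction signature, are reported
only when insertion-site-like breakpoints bracket the exon on both sides,
and are flagged as such.

## NUMT detection

Three evidence routes feed one candidate pool:

1. **Direct breakends** — breakpoints with exactly one mate on the
   mitochondrial contig (aliases `chrM`/`MT`/`chrMT`/`M` by default,
   extendable with `--mt-contig`). Breakpoints entirely on chrM are
   intra-mitochondrial rearrangements and are only counted in diagnostics.
2. **Realigned insertions** — sequence-resolved INS records and
   sequence-bearing single breakends are aligned to chrM by local
   Smith–Waterman with match +1, mismatch −2, gap open −3, gap extend −1;
   the score is divided by `match × query length`, so it lives in [0, 1]
   and an exact full-length match scores exactly 1.0, which is what makes a
   threshold like `min_Align = 0.7` meaningful. Both strands are tried, and
   circularity is handled by extending the target with the genome's first
   `query length − 1` bases, so origin-spanning segments score full marks.
   Queries shorter than `min_len` are discarded before alignment. Terminal
   poly-A/poly-T runs of ≥ 8 bp are trimmed first: integrations of this
   kind are typically polyadenylated, and an untrimmed 20 bp tail on a
   30 bp mtDNA segment would cap its normalised score at 0.6 regardless of
   a perfect match. The scoring scheme is this package's documented choice;
   it is configurable and not claimed identical to any other
   implementation.
3. **Known-NUMT proximity** — nuclear↔nuclear breakpoints with exactly one
   mate within `maxgap_numts` (default 10 bp) of a catalogued reference
   NUMT interval; the other mate is the candidate insertion site. Pairs
   with both mates near known NUMTs are ambiguous and only counted.

*Linking.* Candidates on one nuclear chromosome with facing orientations
(one `RIGHT`, one `LEFT` — the inserted segment lies between them, which
for a target-site duplication means the `RIGHT` junction sits a few bases
*above* the `LEFT` one) are paired when at most `max_ins_dist` apart.
Pairing is an exact assignment — maximise the number of pairs, then
minimise total distance, via the Hungarian algorithm on the
orientation-bipartite graph — rather than greedy nearest-neighbour, which
can mis-pair interleaved sites; the tests verify equality with exhaustive
enumeration on all instances of up to six sites. A `--no-orientation-check`
escape hatch falls back to greedy pairing over all orientations for
imprecise callers. A realigned insertion already encodes both junctions in
one record and becomes a linked zero-width event directly; its single
FILTER value is taken to speak for both implied junctions when tiering.

*Tiering.* Both sites PASS → HIGH; exactly one PASS (or a lone PASS site)
→ INTERMEDIATE; otherwise LOW.

Defaults `min_len = 20`, `min_align = 0.8` are deliberately stricter than
the benchmark preset `--preset paper-sim` (`min_len = 8`,
`min_align = 0.7`) used for simulated-data evaluation, where the planted
truth makes the permissive setting safe.

## Synthetic data

The generator emulates the output of a perfect SV caller at the VCF level;
read simulation and SV calling are deliberately bypassed, so corruption
operators are the model of caller imperfection. Defaults describe the study
system: one 1 Mb nuclear contig and a 16,569 bp mitochondrial contig at
GC 0.41; 20 non-overlapping single-transcript genes of 2–10 exons (exons
80–300 bp, introns 200–1500 bp); polyadenylation tails of 20 bp and target
site duplications of 10 bp; NUMT segment lengths cycling through the ladder
10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000 bp. Insertion loci sit
on a 3 kb grid outside all gene loci (1.5 kb pad), which encodes the
non-overlapping-events design and guarantees that sites of distinct events
can never cross-link within the default `max_ins_dist`, and that a NUMT
site can never fall inside an exon and masquerade as an RT insertion site.

Per RT event the emission is one deletion-like breakpoint per exon-exon
junction plus two insertion-site breakpoints (the 3′ one carrying the
poly-A as inserted sequence); per NUMT, two nuclear↔chrM breakpoints
bracketing the segment. Corruption: `p_drop_junction` removes individual
breakpoints; `p_transitive_merge` collapses adjacent junctions into
spanning calls; `jitter_sd_bp` adds Gaussian noise to every breakend
position; `p_unmap_insertion` replaces an event's mapped breakpoints with a
single sequence-bearing INS record (segment + poly-A); `p_nonpass_filter`
downgrades FILTER to `LOW_QUAL`. 5′ truncation is available
(`five_prime_truncation_max`) and suppresses the junction signatures of
fully truncated exons; the default is no truncation. All randomness flows
from a single seed and outputs are byte-reproducible.

What passing on this generator shows — and what it does not: the detectors
are exact on their defined signatures, thresholds behave as documented, and
degradation is monotone in each corruption rate. It does not show
performance against the error profile of a real caller on real repeats
(alignability, alternative haplotypes, imprecise homology-driven
breakends), which only read-level benchmarks can.

*Truth matching.* A detection matches a planted event when a reported
insertion-site breakend is within 100 bp (inclusive) of the true locus and,
for RTs, the source gene agrees. Truth events are claimed greedily by
distance, each at most once; one gene-grouped RT detection may claim
several truth events of the same source gene (repeated source transcripts
necessarily collapse into one gene-level call), and a detection whose only
matching truths were claimed by closer detections counts as a flagged
duplicate, not a false positive. Unrecovered truths are categorised by
their emission mode (undetected breakpoint vs unmapped insertion sequence).

## Numerical and degenerate-input choices

* Natural chromosome ordering (`chr2 < chr10 < chrX`) defines breakpoint
  canonical form and all output sorting; detection is deterministic —
  identical inputs and parameters give byte-identical event tables.
* `query_near` is inclusive at the threshold (`|pos − boundary| ≤ maxgap`),
  verified against brute-force scans; unknown chromosomes yield empty
  results, not errors.
* Single-exon transcripts have no junction score; `score_transcript`
  raises rather than returning a sentinel, and the insertion-site path
  handles them.
* Empty callsets, empty region sets and zero-length candidate pools flow
  through every stage and produce empty outputs.
* Sequence-bearing records without a mitochondrial FASTA are a hard error
  with guidance, not a silent skip.

## Problem sizes

The test suite and the acceptance script run the closure experiment at 100
RT + 100 NUMT events on the 1 Mb toy genome, the alignment-normalisation
check at a few hundred shuffled trials, and the exhaustive oracles at ≤ 6
sites and ≤ 200 randomised instances; these sizes exercise every code path
while keeping a full run in the low minutes on a single CPU.

## Known limitations

* No read-level evidence is consulted; the package inherits the
  sensitivity of the upstream caller.
* Poly-A and TSD sequence signatures are emitted by the generator but not
  used as detection evidence.
* No repeat-class annotation, source-element (L1) attribution, mtDNA copy
  number or heteroplasmy estimation.
* The insertion-site rule accepts any exonic overlap; on real annotation
  with dense overlapping transcripts this is permissive by design and
  should be filtered with `minscore`/junction support downstream.
* Linked events assume at most two sites; a third nearby site (tandem
  integrations) is left as a single-site event by the assignment.
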