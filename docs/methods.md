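# Methods

## Read model and coordinate conventions

All coordinates are 1-based and intervals closed, matching CT-file, PDB
and SAM conventions. A deletion is recorded by its **5' site** (last
aligned reference nucleotide before the deleted block) and **3' site**
(first aligned nucleotide after it); `deleted_length = three − five − 1`.
RNA references are normalized U→T at ingest because the sequenced material
is cDNA.

## Preprocessing

Quality trimming scans each read 5'→3' with a 5-nt sliding window (step 1)
and truncates the read immediately before the first window whose mean
Phred score is below 20; trimmed reads shorter than 25 nt are dropped. The
sliding (rather than tiled) window is the stricter reading of the rule and
mirrors common mutational-profiling trimmers. Pair merging
reverse-complements mate 2, chooses the overlap (≥ 10 nt) minimizing
mismatch density (ties → longer overlap), accepts it when the density is
≤ 0.25, keeps the higher-quality base at each overlap position and raises
its quality to min(q1+q2, 41). Pairs that do not overlap are kept
unmerged, not discarded, and travel through alignment separately.

## Alignment

BWA-MEM is driven externally with `-O 2 -B 2 -k 10 -T 15`; the stock
parameters (`-O 6 -B 4 -k 19 -T 30`) remain available as the benchmark
baseline (`AlignerConfig.bwa_defaults()`). The rationale: the
crosslink-jumping polymerase leaves ~3.75% background mutations, so
mismatch and gap-open penalties are softened; deletions can leave very
short aligned flanks, so the seed length and reporting threshold are
lowered. Merged and unmerged reads are aligned in separate invocations and
combined in detection. A user-supplied SAM bypasses invocation entirely.
The aligner version string is recorded in every output table header.

## Deletion detection

Candidates come from two routes: CIGAR `D` ops of length ≥ 10 (with
immediately adjacent `I` ops counted as junction insertion), and adjacent
pairs of split alignments of one read ordered along the read, where the
skipped reference is the deletion and the unaligned query between the
segments the insertion. When the two query spans of a split pair
*overlap* (both local alignments extended through the junction because the
read chance-matches the reference on both sides), the overlap is trimmed
from the downstream segment. The resulting junction is a slid placement of
the true one — precisely the situation the ambiguity and edge-matching
stages are designed to recognize — whereas discarding such pairs would
silently lose every junction flanked by repeated sequence (~14% of reads
in the synthetic benchmark). Reads aligned to the reverse strand are
discarded with a tally; the assay is amplicon-directional.

The correction cascade runs in fixed order:

1. **Edge matching.** The 3 read bases aligned at [five−2, five] and at
   [three, three+2] must equal the reference. While either flank fails,
   that boundary moves one nucleotide outward and the displaced aligned
   base is reclassified as junction insertion; flank positions where the
   read has no aligned base (a 1-nt polymerase deletion, or the interior
   of a second deletion) count as failures, which is what lets the
   procedure walk across insertion-orphan fragments inside a deletion and
   reassemble the true junction. More than 10 cumulative moves, or a flank
   running past the reference or the read's aligned span, drops the
   record. Both flanks are re-examined each iteration (5' first), which
   avoids one-sided drift. The minimum-length filter is applied before and
   after (shifts only grow a deletion).
2. **Ambiguity removal.** A deletion is ambiguous iff
   `ref[five] == ref[three−1]` or `ref[five+1] == ref[three]` — the O(1)
   slide test, which the test suite proves equivalent to exhaustive
   placement enumeration for contiguous blocks (block placements flush
   with a reference end included).
3. **Insertion filter.** Junction insertions > 10 nt remove the record
   (insertion length correlates strongly with placement error).
4. **Dedupe** on (read, five, three): the same molecular event seen in
   both mates or in the merged and unmerged passes counts once.

Ambiguity removal decrements deletion counts only, not read depth.

## Quantification

Depth at position p counts reads whose alignment footprint (first to last
aligned reference position, deleted positions included — a read spanning a
deletion still sequenced through the locus) covers p, once per read. A
deletion's local depth is the median of depth over [three, three+4]
(inclusive of the 3' site so the junction-supporting position contributes;
exposed as a toggle), clipped at the reference end; entries at zero depth
are excluded. Control (mono-adduct) rates are subtracted key-wise;
crosslink-only entries keep their full rate; non-positive net rates are
removed (subtraction is a denoising step; the behavior for negatives is
this package's choice). Finally 5' sites are shifted +2 nt in the 3'
direction — the polymerase lands short of the crosslinked nucleotide —
after subtraction, matching the processing order normalize → subtract →
shift. Shift magnitude/direction are configurable (`ShiftConfig`); the
6×6 shift-AUC grid in `evaluate` is the instrument that justifies the
default empirically.

## Synthetic benchmark generator

The generator emulates the read population of a crosslinking experiment
read out by the jumping polymerase on a single amplicon:

- **Reference**: bundled 325-nt stand-in — a fixed random 268-nt core
  (catalytic-domain scale) between the real 14-nt 5' and 43-nt 3'
  structure cassettes. It is synthetic (the file says so); any user FASTA
  with declared cassette intervals is accepted.
- **Encoded deletion**: (five, three) uniform over all pairs with
  deleted length ≥ 10 and both sites outside the cassettes (rejection
  sampling, exactly uniform).
- **Junction insertion** (deletion-insertion mode): length from a
  truncated geometric distribution (p = 0.5) on 1–9 — a declared substitute
  matching the qualitative decay of observed insertion lengths, since no
  tabulated empirical distribution is available — content uniform random.
- **Mutation model**: each position mutates independently at 0.0375;
  categories 71% mismatch / 26% 1-nt deletion / 3% 1-nt insertion. Event
  draws are exposed (`draw_mutation_events`) so the calibration is
  testable against binomial/multinomial expectations directly.
- **Qualities**: constant Q38, making the trimmer a no-op — the benchmark
  isolates the aligner and detector.

Reads are full-length amplicon reads (no fragmentation or paired-end
model) and carry no instrument-specific error profile; passing benchmarks
therefore demonstrate junction-placement behavior, not robustness to
quality-dependent sequencing error. Datasets are byte-reproducible from
the seed.

## Evaluation

Accuracy binning: exact (both sites equal the encoded ones), close (both
within 3 nt), incorrect. Each read contributes its best detection;
undetected reads are tallied separately; a per-site PPV map (fraction of
detections at a junction that are exact) supports interaction-map export.

Contact distance between nucleotides is the shortest-path length in the
graph with unit edges {k, k+1} (backbone) and {k, pair(k)} (base pairs);
a nested helix is traversed in ~1 step, the standard operationalization of
"sequence distance omitting nested helices". Spatial distance uses the
ribose O2' atom or the base-ring centroid (purines N1,C2,N3,C4,C5,C6,N7,
C8,N9; pyrimidines N1–C6; incomplete rings yield no distance and are
excluded with a tally). ROC analysis labels a profile entry positive when
spatial distance < 15 Å **and** contact distance > 10 — nearby in space
but not secondary-structure neighbors, i.e. a tertiary contact — ranks
entries by net rate, and computes AUC by the trapezoidal rule with tied
rates entering together (an all-tied profile scores exactly 0.5; a
single-class profile has undefined AUC, reported as absent). The shift
grid applies every (5', 3') shift in [0,5]² to an unshifted profile and
reports the AUC surface with its argmax (ties toward smaller shifts).

## Benchmark harness and problem sizes

The four-stage optimization ladder re-detects from the same alignments:
(1) stock aligner parameters, (2) optimized parameters, (3) + ambiguity
removal, (4) + edge matching. Stages 1–2 report exact matches over all
reads; stages 3–4 over reads whose *encoded* junction is unambiguous,
because ambiguity removal eliminates ambiguous encodings by construction.
The acceptance script runs 100,000 reads per set and the test suite
20,000; the exact-match percentages are scale-free (binomial standard
error < 0.4 points at 20,000).

Known limitations, measured on the noise-free benchmark: BWA-MEM emits
neither a gapped CIGAR nor a split alignment for ~2% of reads — mid-length
deletions (shorter than the ~100-nt alignment bandwidth) whose shorter
flank scores below the gap cost, so the flank is soft-clipped and its
chain dropped. Those deletions are unrecoverable without local
realignment, which is out of scope; every deletion that *is* recovered
noise-free on an unambiguous encoding is placed exactly. Edge matching
trades a ~1.5-point exact-match loss on insertion-free reads (junction-
adjacent background mutations trigger shifts of correct junctions) for a
~8-point gain on insertion-bearing reads; both effects are inherent to
flank-consistency enforcement and are visible in the ladder output.
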