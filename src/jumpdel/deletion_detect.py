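"""Turning alignments into filtered, corrected deletion records.

A crosslink jump appears either as a D op inside one alignment (short
deletions) or as two alignments of one read separated by unaligned
reference (long deletions). Candidates then pass through three corrections,
in fixed order: exact edge matching (3-nt flanks must match the reference,
with outward boundary shifting otherwise), removal of ambiguous deletions
(identical nucleotides flanking the deleted block let it slide, so the
placement is not unique), and an insertion-length cutoff. Identical
(read, 5', 3') records arising from mate overlap or merged/unmerged double
counting are deduplicated at the end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io_formats import AlignmentSegment, ReferenceSequence, parse_alignments


@dataclass
class Deletion:
    """A candidate crosslink: ``five_prime_site`` is the last aligned
    reference nucleotide before the deleted block, ``three_prime_site`` the
    first after it (both 1-based); ``insertion_length`` counts read
    nucleotides inserted at the junction."""

    ref_name: str
    five_prime_site: int
    three_prime_site: int
    insertion_length: int = 0
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.three_prime_site <= self.five_prime_site + 1:
            raise ValueError(
                f"degenerate deletion ({self.five_prime_site}, "
                f"{self.three_prime_site})"
            )
        if self.insertion_length < 0:
            raise ValueError("insertion_length must be >= 0")

    @property
    def deleted_length(self) -> int:
        return self.three_prime_site - self.five_prime_site - 1


@dataclass
class DetectConfig:
    min_deletion_length: int = 10
    max_insertion_length: int = 10
    edge_match_flank: int = 3
    max_edge_shift_total: int = 10
    remove_ambiguous: bool = True
    enforce_edges: bool = True

    def __post_init__(self) -> None:
        for name in ("min_deletion_length", "max_insertion_length",
                     "edge_match_flank", "max_edge_shift_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class ReadContext:
    """Aligned blocks of one read: which read base sits at which reference
    position. Built from all forward segments of the read; used by edge
    matching to compare flank bases against the reference."""

    __slots__ = ("blocks", "footprint_min", "footprint_max")

    def __init__(self, segments: Iterable[AlignmentSegment]):
        self.blocks: list[tuple[int, int, int, str]] = []
        for seg in segments:
            seq = seg.query_sequence or ""
            ref_pos = seg.ref_start
            seq_idx = 0
            for n, op in seg.cigar:
                if op in ("M", "=", "X"):
                    self.blocks.append((ref_pos, ref_pos + n - 1, seq_idx, seq))
                    ref_pos += n
                    seq_idx += n
                elif op in ("D", "N"):
                    ref_pos += n
                elif op in ("I", "S"):
                    seq_idx += n
                # H consumes neither SEQ nor reference
        if self.blocks:
            self.footprint_min = min(b[0] for b in self.blocks)
            self.footprint_max = max(b[1] for b in self.blocks)
        else:
            self.footprint_min = self.footprint_max = 0

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned at ``ref_pos``, or None if unaligned there."""
        for start, end, seq_idx, seq in self.blocks:
            if start <= ref_pos <= end:
                return seq[seq_idx + (ref_pos - start)]
        return None


def extract_deletions_from_cigar(
    seg: AlignmentSegment, ref: ReferenceSequence, cfg: DetectConfig = DetectConfig()
) -> list[Deletion]:
    """Deletions reported directly by the aligner as D ops.

    Every D op of length >= ``cfg.min_deletion_length`` yields one Deletion;
    I ops immediately adjacent to a qualifying D contribute to its
    insertion_length. Shorter D ops (reverse-transcriptase slippage scale)
    are ignored.
    """
    out: list[Deletion] = []
    ref_pos = seg.ref_start
    # first pass: locate ops with running reference positions
    events: list[tuple[str, int, int]] = []  # (op, length, ref_pos at op start)
    for n, op in seg.cigar:
        events.append((op, n, ref_pos))
        if op in ("M", "=", "X", "D", "N"):
            ref_pos += n
    if ref_pos - 1 > len(ref):
        raise ValueError(
            f"read {seg.read_id}: CIGAR walks past reference end "
            f"({ref_pos - 1} > {len(ref)})"
        )
    for i, (op, n, pos) in enumerate(events):
        if op != "D" or n < cfg.min_deletion_length:
            continue
        ins = 0
        if i > 0 and events[i - 1][0] == "I":
            ins += events[i - 1][1]
        if i + 1 < len(events) and events[i + 1][0] == "I":
            ins += events[i + 1][1]
        out.append(Deletion(
            ref_name=seg.ref_name,
            five_prime_site=pos - 1,
            three_prime_site=pos + n,
            insertion_length=ins,
            read_id=seg.read_id,
        ))
    return out


def join_split_alignments(
    segments: list[AlignmentSegment],
    ref: ReferenceSequence,
    cfg: DetectConfig = DetectConfig(),
    diagnostics: Counter | None = None,
) -> list[Deletion]:
    """Deletions inferred from two alignments of one read.

    Segments are ordered along the read; for each adjacent pair the skipped
    reference between them is a candidate deletion, and the unaligned read
    nucleotides between them its junction insertion. Sub-threshold gaps are
    discarded. When the two query spans overlap (both alignments extended
    through the junction because the read matches the reference on both
    sides of it), the overlap is trimmed from the downstream segment: the
    resulting junction is a slid placement of the true one, which the
    ambiguity and edge-matching stages are built to recognize; discarding
    such reads would silently lose every junction flanked by repeated
    sequence.
    """
    tally = diagnostics if diagnostics is not None else Counter()
    segs = sorted(segments, key=lambda s: s.query_start)
    out: list[Deletion] = []
    for a, b in zip(segs, segs[1:]):
        if a.ref_name != b.ref_name or a.is_reverse != b.is_reverse:
            tally["split_ref_or_strand_mismatch"] += 1
            continue
        insertion = b.query_start - a.query_end - 1
        three = b.ref_start
        if insertion < 0:
            ref_adv = _trim_query_overlap(b, -insertion)
            if ref_adv is None:
                tally["split_overlap_untrimmable"] += 1
                continue
            tally["split_overlap_trimmed"] += 1
            three = b.ref_start + ref_adv
            insertion = 0
        five = a.ref_end
        deleted = three - five - 1
        if deleted < cfg.min_deletion_length:
            tally["split_gap_below_min"] += 1
            continue
        out.append(Deletion(
            ref_name=a.ref_name,
            five_prime_site=five,
            three_prime_site=three,
            insertion_length=insertion,
            read_id=a.read_id,
        ))
    return out


def _trim_query_overlap(seg: AlignmentSegment, overlap: int) -> int | None:
    """Reference advance when ``overlap`` query bases are trimmed from the
    start of ``seg``'s aligned span; None when the segment is too short."""
    rem = overlap
    ref_adv = 0
    for n, op in seg.cigar:
        if rem == 0:
            break
        if op in ("S", "H"):
            continue
        if op in ("M", "=", "X"):
            take = min(n, rem)
            rem -= take
            ref_adv += take
        elif op == "I":
            rem -= min(n, rem)
        elif op in ("D", "N"):
            ref_adv += n
    if rem > 0:
        return None
    return ref_adv


def is_ambiguous_deletion(d: Deletion, ref: ReferenceSequence) -> bool:
    """Whether the deleted block can slide, making the placement non-unique.

    The block can slide one step 5' iff the base before it equals its last
    base (ref[five] == ref[three-1]) and one step 3' iff its first base
    equals the base after it (ref[five+1] == ref[three]). Either condition
    implies more than one placement reproduces the identical read, which is
    equivalent to full placement enumeration for contiguous blocks.
    """
    five, three = d.five_prime_site, d.three_prime_site
    if five < 1 or three > len(ref):
        raise ValueError(f"deletion ({five}, {three}) outside reference bounds")
    if five >= 1 and ref.base(five) == ref.base(three - 1):
        return True
    return ref.base(five + 1) == ref.base(three)


def enforce_edge_matching(
    d: Deletion,
    ctx: ReadContext,
    ref: ReferenceSequence,
    cfg: DetectConfig = DetectConfig(),
    diagnostics: Counter | None = None,
) -> Deletion | None:
    """Require exact flank matches at the junction, shifting outward otherwise.

    The ``edge_match_flank`` read bases aligned immediately 5' of the
    junction ([five-2..five]) and 3' of it ([three..three+2]) must equal the
    reference. While either flank mismatches, that boundary moves one
    nucleotide to the exterior and the displaced read base is reclassified
    as junction insertion. More than ``max_edge_shift_total`` total moves,
    or a flank running past the reference or the read's aligned span,
    drops the deletion (returns None).
    """
    tally = diagnostics if diagnostics is not None else Counter()
    k = cfg.edge_match_flank
    five, three = d.five_prime_site, d.three_prime_site
    ins = d.insertion_length
    shifts = 0

    def flank_state(positions: list[int]) -> str:
        # 'ok', 'mismatch', or 'out_of_bounds'
        for p in positions:
            if p < 1 or p > len(ref):
                return "out_of_bounds"
            if p < ctx.footprint_min or p > ctx.footprint_max:
                return "out_of_bounds"
            base = ctx.base_at(p)
            if base is None or base != ref.base(p):
                return "mismatch"
        return "ok"

    while True:
        s5 = flank_state(list(range(five - k + 1, five + 1)))
        s3 = flank_state(list(range(three, three + k)))
        if s5 == "out_of_bounds" or s3 == "out_of_bounds":
            tally["edge_out_of_bounds"] += 1
            return None
        if s5 == "ok" and s3 == "ok":
            break
        if s5 == "mismatch":
            if ctx.base_at(five) is not None:
                ins += 1
            five -= 1
            shifts += 1
        if s3 == "mismatch":
            if ctx.base_at(three) is not None:
                ins += 1
            three += 1
            shifts += 1
        if shifts > cfg.max_edge_shift_total:
            tally["edge_shift_exceeded"] += 1
            return None
    if shifts == 0:
        return d
    return Deletion(d.ref_name, five, three, ins, d.read_id)


def group_segments_by_read(
    segments: Iterable[AlignmentSegment],
) -> Iterator[tuple[str, list[AlignmentSegment]]]:
    """Group a qname-grouped segment stream (aligner output order) by read."""
    current_id: str | None = None
    bucket: list[AlignmentSegment] = []
    for seg in segments:
        if seg.read_id != current_id:
            if bucket:
                yield current_id, bucket
            current_id, bucket = seg.read_id, []
        bucket.append(seg)
    if bucket:
        yield current_id, bucket


def deletions_for_read(
    segments: list[AlignmentSegment],
    ref: ReferenceSequence,
    cfg: DetectConfig = DetectConfig(),
    diagnostics: Counter | None = None,
) -> list[Deletion]:
    """Run extraction, joining and the correction cascade for one read."""
    tally = diagnostics if diagnostics is not None else Counter()
    usable = [s for s in segments if not s.is_secondary]
    forward = [s for s in usable if not s.is_reverse]
    n_reverse = len(usable) - len(forward)
    if n_reverse:
        tally["reverse_strand_segments"] += n_reverse
    if not forward:
        return []
    candidates: list[Deletion] = []
    for seg in forward:
        candidates.extend(extract_deletions_from_cigar(seg, ref, cfg))
    if len(forward) >= 2:
        candidates.extend(join_split_alignments(forward, ref, cfg, tally))
    if not candidates:
        return []

    if cfg.enforce_edges:
        ctx = ReadContext(forward)
        corrected = []
        for d in candidates:
            fixed = enforce_edge_matching(d, ctx, ref, cfg, tally)
            if fixed is None:
                continue
            if fixed.deleted_length < cfg.min_deletion_length:
                tally["below_min_after_edges"] += 1
                continue
            corrected.append(fixed)
        candidates = corrected

    if cfg.remove_ambiguous:
        kept = []
        for d in candidates:
            if is_ambiguous_deletion(d, ref):
                tally["ambiguous_removed"] += 1
            else:
                kept.append(d)
        candidates = kept

    final = []
    for d in candidates:
        if d.insertion_length > cfg.max_insertion_length:
            tally["insertion_too_long"] += 1
        else:
            final.append(d)
    return final


def load_segment_groups(
    sam_paths: Iterable[str], ref: ReferenceSequence
) -> list[dict[str, list[AlignmentSegment]]]:
    """Parse SAM/BAM files into per-file {read_id: segments} maps."""
    groups = []
    for path in sam_paths:
        by_read: dict[str, list[AlignmentSegment]] = {}
        for seg in parse_alignments(path, ref):
            by_read.setdefault(seg.read_id, []).append(seg)
        groups.append(by_read)
    return groups


def detect_deletions_from_segments(
    segment_groups: list[dict[str, list[AlignmentSegment]]],
    ref: ReferenceSequence,
    cfg: DetectConfig = DetectConfig(),
) -> tuple[list[Deletion], Counter]:
    """Run the detection cascade over pre-parsed segment groups."""
    tally: Counter = Counter()
    seen: set[tuple[str, int, int]] = set()
    out: list[Deletion] = []
    for by_read in segment_groups:
        tally["reads_seen"] += len(by_read)
        for read_id, segs in by_read.items():
            for d in deletions_for_read(segs, ref, cfg, tally):
                key = (d.read_id, d.five_prime_site, d.three_prime_site)
                if key in seen:
                    tally["duplicates_removed"] += 1
                    continue
                seen.add(key)
                out.append(d)
    return out, tally


def detect_deletions(
    sam_paths: Iterable[str],
    ref: ReferenceSequence,
    cfg: DetectConfig = DetectConfig(),
) -> tuple[list[Deletion], Counter]:
    """Detect deletions across one or more SAM/BAM files of one sample.

    Merged and unmerged alignments are passed as separate paths; their
    outputs are combined and duplicate (read_id, 5', 3') records — the same
    molecular event seen in both mates or both alignment passes — are
    removed. Returns the deletion list and a diagnostics tally.
    """
    return detect_deletions_from_segments(
        load_segment_groups(sam_paths, ref), ref, cfg
    )
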