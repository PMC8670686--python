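"""Quality trimming and paired-read merging.

Trimming scans each read 5'->3' with a sliding window and truncates at the
first window whose mean Phred quality falls below a threshold; reads that
end up shorter than a minimum length are dropped. Merging overlaps each
mate pair (mate 2 reverse-complemented) and, in the overlap, keeps the
higher-quality base while boosting its quality score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TrimConfig:
    """Sliding-window quality trim: truncate before the first ``window``-wide
    window whose mean quality is below ``min_mean_q``; drop reads shorter
    than ``min_len`` afterwards."""

    window: int = 5
    min_mean_q: float = 20.0
    min_len: int = 25

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_len < 1:
            raise ValueError("window and min_len must be >= 1")


@dataclass
class MergeConfig:
    min_overlap: int = 10
    max_mismatch_density: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mismatch_density <= 1.0:
            raise ValueError("max_mismatch_density must be in [0, 1]")


def trim_read_quality(read: Read, cfg: TrimConfig = TrimConfig()) -> Read | None:
    """Trim a read by base-call quality; return None when it is dropped.

    Windows [i, i+window-1] are scanned for i = 1, 2, ... (step 1). At the
    first window whose mean quality is below ``cfg.min_mean_q`` the read is
    truncated to [1, i-1]; the window and everything downstream is removed.
    """
    q = read.qualities
    n = len(q)
    w = cfg.window
    cut = n
    if n >= w:
        window_sum = sum(q[:w])
        threshold = cfg.min_mean_q * w
        i = 0
        while True:
            if window_sum < threshold:
                cut = i
                break
            if i + w >= n:
                break
            window_sum += q[i + w] - q[i]
            i += 1
    if cut < cfg.min_len:
        return None
    if cut == n:
        return read
    return Read(read.read_id, read.sequence[:cut], q[:cut], mate=read.mate)


def _overlap_mismatches(s1: str, s2: str) -> int:
    return sum(a != b for a, b in zip(s1, s2))


def merge_read_pair(
    r1: Read, r2: Read, cfg: MergeConfig = MergeConfig()
) -> Read | tuple[Read, Read]:
    """Merge a mate pair into one read, or return both unchanged.

    Mate 2 is reverse-complemented; the overlap between r1's 3' end and the
    reverse-complemented r2's 5' end that minimizes mismatch density (ties:
    longer overlap) is taken, and accepted if its density does not exceed
    ``cfg.max_mismatch_density``. In the overlap the higher-quality base is
    kept and its quality raised to min(q1+q2, 41).
    """
    seq2 = reverse_complement(r2.sequence)
    qual2 = r2.qualities[::-1]
    l1, l2 = len(r1), len(r2)
    best: tuple[float, int] | None = None  # (density, overlap)
    for o in range(min(l1, l2), cfg.min_overlap - 1, -1):
        mism = _overlap_mismatches(r1.sequence[l1 - o:], seq2[:o])
        density = mism / o
        if best is None or density < best[0]:
            best = (density, o)
    if best is None or best[0] > cfg.max_mismatch_density:
        return (r1, r2)
    _, o = best
    merged_seq = list(r1.sequence[: l1 - o])
    merged_q = list(r1.qualities[: l1 - o])
    for k in range(o):
        b1, q1 = r1.sequence[l1 - o + k], r1.qualities[l1 - o + k]
        b2, q2 = seq2[k], qual2[k]
        base = b1 if q1 >= q2 else b2
        merged_seq.append(base)
        merged_q.append(min(q1 + q2, 41))
    merged_seq.extend(seq2[o:])
    merged_q.extend(qual2[o:])
    return Read(r1.read_id, "".join(merged_seq), merged_q, mate="merged")


def preprocess_pairs(pairs, trim_cfg=TrimConfig(), merge_cfg=MergeConfig()):
    """Trim then merge an iterable of (r1, r2) pairs.

    Returns (merged_reads, unmerged_r1, unmerged_r2, stats). A pair with a
    trimmed-away mate contributes its surviving mate to the unmerged lists.
    """
    merged: list[Read] = []
    un1: list[Read] = []
    un2: list[Read] = []
    stats = {"pairs_in": 0, "merged": 0, "unmerged": 0, "dropped_reads": 0}
    for r1, r2 in pairs:
        stats["pairs_in"] += 1
        t1 = trim_read_quality(r1, trim_cfg)
        t2 = trim_read_quality(r2, trim_cfg)
        if t1 is None:
            stats["dropped_reads"] += 1
        if t2 is None:
            stats["dropped_reads"] += 1
        if t1 is not None and t2 is not None:
            result = merge_read_pair(t1, t2, merge_cfg)
            if isinstance(result, Read):
                merged.append(result)
                stats["merged"] += 1
            else:
                un1.append(result[0])
                un2.append(result[1])
                stats["unmerged"] += 1
        elif t1 is not None:
            un1.append(t1)
            stats["unmerged"] += 1
        elif t2 is not None:
            un2.append(t2)
            stats["unmerged"] += 1
    return merged, un1, un2, stats
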