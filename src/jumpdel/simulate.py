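"""Synthetic-read benchmark generator with an empirical mutation model.

Emulates the read population produced by sequencing cDNA from a
crosslink-traversing reverse transcriptase: full-length amplicon reads each
carrying one encoded deletion (the crosslink jump), optionally with a
junction insertion, on top of the enzyme's background mutation spectrum —
3.75% of nucleotides mutated, split 71% mismatches, 26% single-nucleotide
deletions, 3% single-nucleotide insertions. Three dataset modes mirror the
benchmark designs: ``deletion``, ``deletion_insertion`` (junction
insertions of 1-9 nt) and ``increasing_insertion`` (fixed-size blocks of
reads at each insertion length 0-30).

The bundled default reference is a synthetic stand-in: a random
catalytic-domain-sized core (268 nt) between the real 5' (14 nt) and 3'
(43 nt) flanking structure cassettes, 325 nt total. Encoded deletion sites
never fall inside the cassettes. What this generator does **not** model:
instrument quality profiles (qualities are constant), paired-end reads,
fragmentation, or sequence-dependent mutation bias.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deletion_detect import Deletion, is_ambiguous_deletion
from .io_formats import Read, ReferenceSequence, parse_reference

_BASES = "ACGT"
#: for each base, the three alternatives a mismatch can become
_OTHERS = {b: _BASES.replace(b, "") for b in _BASES}
_OTHERS["N"] = _BASES[:3]


def default_benchmark_reference() -> ReferenceSequence:
    """The bundled 325-nt synthetic stand-in benchmark reference.

    Cassette intervals: 5' [1, 14], 3' [283, 325].
    """
    with importlib.resources.as_file(
        importlib.resources.files("jumpdel") / "data" / "benchmark_reference.fa"
    ) as path:
        return parse_reference(path, cassette_5p=(1, 14), cassette_3p=(283, 325))


def _default_insertion_distribution() -> dict[int, float]:
    # truncated geometric (p = 0.5) on 1..9: matches the qualitative decay of
    # experimentally observed junction-insertion lengths; configurable.
    weights = {k: 0.5 ** k for k in range(1, 10)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


@dataclass
class MutationModel:
    """Per-nucleotide background mutation spectrum of the jumping RT."""

    per_nt_rate: float = 0.0375
    p_mismatch: float = 0.71
    p_del1: float = 0.26
    p_ins1: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_nt_rate <= 1.0:
            raise ValueError("per_nt_rate must be in [0, 1]")
        if abs(self.p_mismatch + self.p_del1 + self.p_ins1 - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")

    @classmethod
    def off(cls) -> "MutationModel":
        return cls(per_nt_rate=0.0)


@dataclass
class SimConfig:
    mode: str = "deletion"  # deletion | deletion_insertion | increasing_insertion
    n_reads: int = 1_000_000
    min_encoded_del: int = 10
    insertion_length_distribution: dict[int, float] = field(
        default_factory=_default_insertion_distribution
    )
    insertion_lengths: list[int] = field(default_factory=lambda: list(range(31)))
    reads_per_length: int = 100_000
    rng_seed: int = 0
    read_quality: int = 38

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.mode not in ("deletion", "deletion_insertion", "increasing_insertion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        total = sum(self.insertion_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("insertion_length_distribution must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth for one synthetic read."""

    read_id: str
    encoded_five: int
    encoded_three: int
    encoded_insertion_length: int
    ambiguous: bool


def _site_bounds(ref: ReferenceSequence) -> tuple[int, int]:
    lo = (ref.cassette_5p[1] + 1) if ref.cassette_5p else 1
    hi = (ref.cassette_3p[0] - 1) if ref.cassette_3p else len(ref)
    return lo, hi


def draw_deletion_sites(
    ref: ReferenceSequence, min_encoded_del: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Uniform draw over (five, three) pairs with the deleted block of at
    least ``min_encoded_del`` nucleotides and both sites outside the
    cassettes (rejection sampling is exactly uniform over legal pairs)."""
    lo, hi = _site_bounds(ref)
    if hi - lo < min_encoded_del + 1:
        raise ValueError("non-cassette region too short for any legal deletion")
    while True:
        five = int(rng.integers(lo, hi + 1))
        three = int(rng.integers(lo, hi + 1))
        if three - five - 1 >= min_encoded_del:
            return five, three


def draw_mutation_events(
    length: int, model: MutationModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw mutation positions and categories for a sequence of ``length``.

    Returns (positions, categories) with categories coded 0 = mismatch,
    1 = 1-nt deletion, 2 = 1-nt insertion. Exposed separately so the event
    statistics can be checked directly against their binomial/multinomial
    expectations.
    """
    hits = np.flatnonzero(rng.random(length) < model.per_nt_rate)
    if hits.size == 0:
        return hits, hits
    cats = rng.choice(
        3, size=hits.size, p=[model.p_mismatch, model.p_del1, model.p_ins1]
    )
    return hits, cats


def mutate_sequence(seq: str, model: MutationModel, rng: np.random.Generator) -> str:
    """Apply the per-nucleotide mutation model to a sequence.

    Each position independently mutates with ``per_nt_rate``; a mutation is
    a mismatch (replace with a different base), a 1-nt deletion, or a 1-nt
    insertion after the position, with the model's category probabilities.
    """
    if model.per_nt_rate <= 0.0 or not seq:
        return seq
    hits, cats = draw_mutation_events(len(seq), model, rng)
    if hits.size == 0:
        return seq
    picks = rng.integers(0, 3, size=hits.size)  # consumed per-event as needed
    ins_picks = rng.integers(0, 4, size=hits.size)
    pieces: list[str] = []
    prev = 0
    for pos, cat, pick, ipick in zip(hits, cats, picks, ins_picks):
        pieces.append(seq[prev:pos])
        base = seq[pos]
        if cat == 0:  # mismatch
            pieces.append(_OTHERS.get(base, _BASES[:3])[pick % 3])
        elif cat == 1:  # 1-nt deletion
            pass
        else:  # 1-nt insertion after the position
            pieces.append(base + _BASES[ipick])
        prev = pos + 1
    pieces.append(seq[prev:])
    return "".join(pieces)


def mutate_read(read: Read, model: MutationModel, rng: np.random.Generator) -> Read:
    """Read-level wrapper around :func:`mutate_sequence`; the mutated read
    keeps a constant quality equal to the mean of the input qualities."""
    seq = mutate_sequence(read.sequence, model, rng)
    q = round(sum(read.qualities) / len(read.qualities)) if read.qualities else 38
    return Read(read.read_id, seq, [q] * len(seq), mate=read.mate)


def _draw_insertion(cfg: SimConfig, rng: np.random.Generator) -> int:
    lengths = sorted(cfg.insertion_length_distribution)
    probs = [cfg.insertion_length_distribution[k] for k in lengths]
    return int(rng.choice(lengths, p=probs))


def generate_deletion_read(
    ref: ReferenceSequence,
    cfg: SimConfig,
    model: MutationModel,
    rng: np.random.Generator,
    read_id: str = "sim0",
    insertion_length: int | None = None,
) -> tuple[Read, TruthRecord]:
    """One full-length amplicon read with an encoded deletion.

    The read is the whole reference with the block (five, three) removed,
    a junction insertion added when the mode (or ``insertion_length``)
    requires one, and the mutation model applied on top.
    """
    five, three = draw_deletion_sites(ref, cfg.min_encoded_del, rng)
    if insertion_length is None:
        if cfg.mode == "deletion_insertion":
            ins_len = _draw_insertion(cfg, rng)
        else:
            ins_len = 0
    else:
        ins_len = insertion_length
    insert = "".join(_BASES[i] for i in rng.integers(0, 4, ins_len)) if ins_len else ""
    seq = ref.sequence[:five] + insert + ref.sequence[three - 1:]
    seq = mutate_sequence(seq, model, rng)
    read = Read(read_id, seq, [cfg.read_quality] * len(seq), mate="single")
    ambiguous = is_ambiguous_deletion(
        Deletion(ref.name, five, three, 0, read_id), ref
    )
    return read, TruthRecord(read_id, five, three, ins_len, ambiguous)


TRUTH_COLUMNS = ("read_id", "encoded_five", "encoded_three",
                 "encoded_insertion_length", "ambiguous")


def generate_dataset(
    ref: ReferenceSequence,
    cfg: SimConfig,
    model: MutationModel,
    out_fastq: str | Path,
    out_truth: str | Path,
) -> tuple[Path, Path, int]:
    """Write a synthetic dataset as single-end FASTQ plus a truth TSV.

    ``deletion`` and ``deletion_insertion`` modes write ``cfg.n_reads``
    reads; ``increasing_insertion`` writes ``cfg.reads_per_length`` reads
    for every length in ``cfg.insertion_lengths``. Fully reproducible from
    ``cfg.rng_seed``. Returns (fastq_path, truth_path, n_reads).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    out_fastq, out_truth = Path(out_fastq), Path(out_truth)
    qual_char = chr(cfg.read_quality + 33)
    n = 0
    with open(out_fastq, "w") as fq, open(out_truth, "w") as tr:
        tr.write("\t".join(TRUTH_COLUMNS) + "\n")

        def emit(read_id: str, forced_len: int | None) -> None:
            nonlocal n
            read, truth = generate_deletion_read(
                ref, cfg, model, rng, read_id, insertion_length=forced_len
            )
            fq.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                     f"{qual_char * len(read.sequence)}\n")
            tr.write(f"{truth.read_id}\t{truth.encoded_five}\t"
                     f"{truth.encoded_three}\t{truth.encoded_insertion_length}\t"
                     f"{int(truth.ambiguous)}\n")
            n += 1

        if cfg.mode == "increasing_insertion":
            for length in cfg.insertion_lengths:
                for i in range(cfg.reads_per_length):
                    emit(f"sim_L{length}_{i}", length)
        else:
            for i in range(cfg.n_reads):
                emit(f"sim{i}", None)
    return out_fastq, out_truth, n


def load_truth(path: str | Path) -> dict[str, TruthRecord]:
    """Read a truth TSV back into a read_id -> TruthRecord map."""
    out: dict[str, TruthRecord] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: not a truth TSV")
        for ln in handle:
            rid, five, three, ins, amb = ln.rstrip("\n").split("\t")
            out[rid] = TruthRecord(rid, int(five), int(three), int(ins),
                                   bool(int(amb)))
    return out
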