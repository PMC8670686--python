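"""Readers and writers for the external formats the pipeline touches.

FASTQ (Phred+33, optionally gzipped), FASTA references, SAM/BAM alignments,
CT and dot-bracket secondary structure, PDB coordinates, and the package's
own tab-delimited deletion table.

Coordinate convention: 1-based, closed intervals everywhere, matching the
CT-file and PDB conventions; SAM's 1-based POS is adopted unchanged.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pysam
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__

# CIGAR op classification (SAM spec)
QUERY_CONSUMING = {"M", "=", "X", "I", "S"}
REF_CONSUMING = {"M", "=", "X", "D", "N"}


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities.

    ``mate`` distinguishes the two ends of a pair, a merged pair, and a
    single-end read: one of ``"1"``, ``"2"``, ``"merged"``, ``"single"``.
    """

    read_id: str
    sequence: str
    qualities: list[int]
    mate: str = "single"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSequence:
    """A reference sequence with optional flanking structure-cassette intervals.

    Cassettes are fixed priming sequences appended to the RNA; the simulator
    never places deletion sites inside them. Intervals are 1-based closed,
    or ``None`` when absent.
    """

    name: str
    sequence: str
    cassette_5p: tuple[int, int] | None = None
    cassette_3p: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for label, iv in (("5'", self.cassette_5p), ("3'", self.cassette_3p)):
            if iv is not None:
                lo, hi = iv
                if not (1 <= lo <= hi <= n):
                    raise ValueError(
                        f"{label} cassette interval {iv} outside [1, {n}]"
                    )
        if self.cassette_5p and self.cassette_3p:
            a, b = self.cassette_5p
            c, d = self.cassette_3p
            if max(a, c) <= min(b, d):
                raise ValueError("cassette intervals overlap")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.sequence[pos - 1]


@dataclass
class AlignmentSegment:
    """One aligned block of a read against the reference.

    ``ref_start`` and ``query_start`` are 1-based inclusive; ``query_start``
    is in original-read coordinates (hard clips counted). ``cigar`` is an
    ordered list of ``(length, op)`` with op in M,=,X,I,D,S,H.
    """

    read_id: str
    ref_name: str
    ref_start: int
    query_start: int
    cigar: list[tuple[int, str]]
    is_reverse: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    mapq: int = 0
    query_sequence: str | None = None  # SEQ column (hard clips absent)

    @property
    def is_secondary_or_supplementary(self) -> bool:
        return self.is_secondary or self.is_supplementary

    @property
    def ref_end(self) -> int:
        """Last reference position covered (1-based inclusive)."""
        return self.ref_start + sum(n for n, op in self.cigar if op in REF_CONSUMING) - 1

    @property
    def query_end(self) -> int:
        """Last read position aligned (1-based inclusive, clips excluded)."""
        aligned = sum(n for n, op in self.cigar if op in ("M", "=", "X", "I"))
        return self.query_start + aligned - 1

    @property
    def read_length(self) -> int:
        """Full read length implied by the CIGAR, clips included."""
        return sum(n for n, op in self.cigar if op in QUERY_CONSUMING or op == "H")


@dataclass
class SecondaryStructure:
    """Base-pair table of a secondary structure.

    ``pair_of`` maps a 1-based position to its partner; unpaired positions
    are absent. The table is symmetric by construction.
    """

    length: int
    pair_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.pair_of.items():
            if i == j:
                raise ValueError(f"position {i} pairs with itself")
            if self.pair_of.get(j) != i:
                raise ValueError(f"pair table asymmetric at ({i}, {j})")
            if not (1 <= i <= self.length and 1 <= j <= self.length):
                raise ValueError(f"pair ({i}, {j}) outside [1, {self.length}]")


@dataclass
class TertiaryCoordinates:
    """Per-nucleotide atom coordinates, keyed by reference position.

    ``atoms[residue][atom_name] -> (x, y, z)`` in Angstroms. Residue numbers
    have already been shifted onto reference coordinates by the parser's
    explicit offset.
    """

    atoms: dict[int, dict[str, tuple[float, float, float]]]

    def residues(self) -> list[int]:
        return sorted(self.atoms)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_reads(path: str | Path, mate: str = "single") -> Iterator[Read]:
    """Stream reads from a FASTQ file (Phred+33; gzip allowed).

    Raises ``ValueError`` naming the 1-based record index on a record whose
    quality string length differs from its sequence length.
    """
    with _open_text(path) as handle:
        for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(handle), 1):
            if len(seq) != len(qual):
                raise ValueError(f"FASTQ record {idx}: seq/qual length mismatch")
            read_id = title.split()[0]
            quals = [ord(c) - 33 for c in qual]
            yield Read(read_id, seq.upper(), quals, mate=mate)


def write_reads(reads, path: str | Path) -> int:
    """Write reads as 4-line FASTQ (Phred+33). Returns the record count."""
    n = 0
    with open(path, "w") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            out.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def parse_reference(
    path: str | Path,
    target_name: str | None = None,
    cassette_5p: tuple[int, int] | None = None,
    cassette_3p: tuple[int, int] | None = None,
) -> ReferenceSequence:
    """Load one reference sequence from FASTA.

    The sequence is uppercased and U is normalized to T so that RNA
    references and DNA (cDNA) reads share one alphabet. With more than one
    record, ``target_name`` selects which to load.
    """
    records = list(SeqIO.parse(_open_text(path), "fasta"))
    if target_name is None:
        if len(records) != 1:
            raise ValueError(
                f"{path}: expected exactly 1 sequence, found {len(records)}; "
                "give a target name"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == target_name]
        if not matches:
            raise ValueError(f"{path}: no sequence named {target_name!r}")
        rec = matches[0]
    seq = str(rec.seq).upper().replace("U", "T")
    return ReferenceSequence(rec.id, seq, cassette_5p, cassette_3p)


def _segment_from_pysam(rec: pysam.AlignedSegment) -> AlignmentSegment:
    ops = "MIDNSHP=X"
    cigar = [(length, ops[op]) for op, length in rec.cigartuples]
    # query_start in original read coordinates: leading S and H clips both count
    qstart = 1
    for length, op in cigar:
        if op in ("S", "H"):
            qstart += length
        else:
            break
    return AlignmentSegment(
        read_id=rec.query_name,
        ref_name=rec.reference_name,
        ref_start=rec.reference_start + 1,
        query_start=qstart,
        cigar=cigar,
        is_reverse=rec.is_reverse,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        mapq=rec.mapping_quality,
        query_sequence=rec.query_sequence,
    )


def parse_alignments(
    path: str | Path, reference: ReferenceSequence | None = None
) -> Iterator[AlignmentSegment]:
    """Stream mapped alignment segments from a SAM/BAM file.

    Unmapped records are skipped. If ``reference`` is given, its name must
    appear in the SAM header.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        if reference is not None and reference.name not in (bam.references or ()):
            raise ValueError(
                f"{path}: reference {reference.name!r} not in SAM header "
                f"(found {list(bam.references or ())})"
            )
        for rec in bam:
            if rec.is_unmapped:
                continue
            yield _segment_from_pysam(rec)


_OPEN = "("
_CLOSE = ")"
_PK_CHARS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") | set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)


def _parse_dotbracket(text: str) -> SecondaryStructure:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    # accept a bare structure line, or name/sequence/structure blocks
    struct = None
    for ln in reversed(lines):
        if ln.startswith((">", "#")):
            continue
        if set(ln) <= set(".()") | _PK_CHARS:
            struct = ln
            break
    if struct is None:
        raise ValueError("no dot-bracket structure line found")
    bad = set(struct) & _PK_CHARS
    if bad:
        raise ValueError(
            f"pseudoknot or unsupported symbols {sorted(bad)} in dot-bracket; "
            "only nested '()' pairs are supported"
        )
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(struct, 1):
        if ch == _OPEN:
            stack.append(pos)
        elif ch == _CLOSE:
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[-1]}")
    return SecondaryStructure(len(struct), pairs)


def _parse_ct(text: str) -> SecondaryStructure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    length = int(header[0])
    pairs: dict[int, int] = {}
    for ln in lines[1 : length + 1]:
        cols = ln.split()
        i, j = int(cols[0]), int(cols[4])
        if j != 0:
            pairs[i] = j
    for i, j in pairs.items():
        if pairs.get(j) != i:
            raise ValueError(f"CT pairing asymmetric: {i}->{j} but {j}->{pairs.get(j)}")
    return SecondaryStructure(length, pairs)


def parse_secondary_structure(path: str | Path) -> SecondaryStructure:
    """Parse a CT or dot-bracket secondary-structure file.

    Format is chosen by extension: ``.ct`` is connectivity-table, anything
    else is treated as dot-bracket (nested brackets only; pseudoknot symbols
    are rejected).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".ct":
        return _parse_ct(text)
    return _parse_dotbracket(text)


def parse_tertiary_coordinates(
    path: str | Path, chain: str, residue_offset: int = 0
) -> TertiaryCoordinates:
    """Extract per-residue atom coordinates for one chain of a PDB file.

    ``residue_offset`` is added to every PDB residue number so residues land
    on reference positions; an explicit offset is required knowledge because
    silent misalignment would corrupt every downstream distance.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise ValueError(f"{path}: chain {chain!r} not found (chains: {chain_ids})")
    atoms: dict[int, dict[str, tuple[float, float, float]]] = {}
    for residue in model[chain]:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue
        amap = {}
        for atom in residue:
            x, y, z = atom.coord
            amap[atom.get_name()] = (float(x), float(y), float(z))
        atoms[resseq + residue_offset] = amap
    return TertiaryCoordinates(atoms)


# ---------------------------------------------------------------------------
# deletion table

TABLE_COLUMNS = (
    "ref_name",
    "five_prime_site",
    "three_prime_site",
    "raw_count",
    "depth",
    "normalized_rate",
    "net_rate",
)


def write_deletion_table(profile, path: str | Path, params: dict | None = None) -> None:
    """Write a DeletionProfile as the package's tab-delimited deletion table.

    One row per deletion: ref_name, 5' site, 3' site, raw count, local depth,
    depth-normalized rate, background-subtracted net rate. Rows are sorted by
    net rate descending, ties by (five, three) ascending. '#' header lines
    record the pipeline version, sample id and parameters so every table is
    self-describing.
    """
    items = sorted(
        profile.entries.items(),
        key=lambda kv: (-(kv[1].net_rate if kv[1].net_rate is not None
                          else kv[1].normalized_rate), kv[0]),
    )
    with open(path, "w") as out:
        out.write(f"# jumpdel v{__version__} deletion table\n")
        out.write(f"# sample_id={profile.sample_id} ref_name={profile.ref_name}\n")
        if params:
            kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            out.write(f"# params: {kv}\n")
        out.write("\t".join(TABLE_COLUMNS) + "\n")
        for (five, three), e in items:
            net = "" if e.net_rate is None else repr(e.net_rate)
            out.write(
                f"{profile.ref_name}\t{five}\t{three}\t{e.count}\t"
                f"{e.depth!r}\t{e.normalized_rate!r}\t{net}\n"
            )


def read_deletion_table(path: str | Path):
    """Read a deletion table written by :func:`write_deletion_table`.

    Returns a DeletionProfile with entries restored exactly; the per-position
    depth vector is not stored in the table and comes back empty.
    """
    from .quantify import DeletionEntry, DeletionProfile

    sample_id = ""
    ref_name = ""
    entries: dict[tuple[int, int], DeletionEntry] = {}
    with open(path) as handle:
        for ln in handle:
            ln = ln.rstrip("\n")
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if tok.startswith("sample_id="):
                        sample_id = tok.split("=", 1)[1]
                    elif tok.startswith("ref_name="):
                        ref_name = tok.split("=", 1)[1]
                continue
            if not ln or ln.startswith("ref_name\t"):
                continue
            cols = ln.split("\t")
            five, three = int(cols[1]), int(cols[2])
            net = float(cols[6]) if cols[6] != "" else None
            entries[(five, three)] = DeletionEntry(
                count=int(cols[3]),
                depth=float(cols[4]),
                normalized_rate=float(cols[5]),
                net_rate=net,
            )
            ref_name = cols[0]
    return DeletionProfile(sample_id=sample_id, ref_name=ref_name, entries=entries)
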