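"""Shared fixtures: small references, alignments and structure models.

Everything is generated programmatically; nothing binary ships with the
package.
"""

from __future__ import annotations

import numpy as np
import pytest

from jumpdel.io_formats import (
    AlignmentSegment,
    ReferenceSequence,
    SecondaryStructure,
    TertiaryCoordinates,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210713)


@pytest.fixture(scope="session")
def small_ref():
    """60-nt reference without cassettes, fixed arbitrary sequence."""
    seq = "ATGCCGTAAGCTTGACCTGAGATCGTACGGATCCAAGTTCGACTGGCATAAGCGTTGCAC"
    return ReferenceSequence("ref60", seq)


def make_segment(
    read_id="r1",
    ref_name="ref60",
    ref_start=1,
    cigar=((16, "M"),),
    query_sequence=None,
    **kw,
):
    qstart = 1
    for n, op in cigar:
        if op in ("S", "H"):
            qstart += n
        else:
            break
    return AlignmentSegment(
        read_id=read_id,
        ref_name=ref_name,
        ref_start=ref_start,
        query_start=qstart,
        cigar=list(cigar),
        query_sequence=query_sequence,
        **kw,
    )


def read_for_deletion(ref: ReferenceSequence, five: int, three: int,
                      insert: str = "") -> str:
    """Read sequence implied by a clean deletion (five, three)."""
    return ref.sequence[:five] + insert + ref.sequence[three - 1:]


@pytest.fixture()
def hairpin_structure():
    """20-nt hairpin: pairs (1,20)...(5,16), loop 6..15."""
    pairs = {}
    for i in range(1, 6):
        pairs[i] = 21 - i
        pairs[21 - i] = i
    return SecondaryStructure(20, pairs)


def linear_coords(n: int, spacing: float = 5.0) -> TertiaryCoordinates:
    """n residues on a straight line, O2' only."""
    return TertiaryCoordinates(
        {i: {"O2'": (spacing * i, 0.0, 0.0)} for i in range(1, n + 1)}
    )
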