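"""Overlapping-triplet index encoding of DNA sequences.

A width-3 window slides along the sequence with step 1, and each
trinucleotide is looked up in a fixed index table: the 64 triplets over
{A, C, G, T} are numbered 1..64 in lexicographic order (AAA=1, TTT=64),
with index 0 reserved for triplets containing N and for right-padding.
A 300 nt window therefore encodes to a vector of 298 indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence

import numpy as np

from .sequence_io import DnaSequence

BASES = "ACGT"


class EncodingError(ValueError):
    """Sequence cannot be encoded (shorter than one window)."""


class DecodeError(ValueError):
    """An index vector is not a consistent overlapping-triplet encoding."""


@dataclass(frozen=True)
class TripletIndexTable:
    """Bijection between the 64 trinucleotides and indices 1..64."""

    entries: Dict[str, int]
    unknown_index: int = 0

    def __post_init__(self) -> None:
        if len(self.entries) != 64 or set(self.entries.values()) != set(range(1, 65)):
            raise ValueError("index table must map the 64 triplets onto 1..64")

    def lookup(self, triplet: str) -> int:
        """Index of a triplet; triplets containing N map to unknown_index."""
        return self.entries.get(triplet, self.unknown_index)

    def reverse(self) -> Dict[int, str]:
        return {v: k for k, v in self.entries.items()}

    def to_tsv(self, path) -> None:
        """Export as a two-column TSV (triplet, index) for audit."""
        with open(path, "w") as handle:
            for triplet, idx in sorted(self.entries.items()):
                handle.write(f"{triplet}\t{idx}\n")


@dataclass
class IndexVector:
    """Ordered triplet indices for one sequence (length = source length - 2)."""

    indices: List[int]
    source_length: int

    def __post_init__(self) -> None:
        if len(self.indices) != self.source_length - 2:
            raise ValueError(
                f"index vector of length {len(self.indices)} inconsistent with "
                f"source length {self.source_length}"
            )
        if any(i < 0 or i > 64 for i in self.indices):
            raise ValueError("indices must lie in [0, 64]")

    def __len__(self) -> int:
        return len(self.indices)


def build_index_table() -> TripletIndexTable:
    """The canonical table: lexicographic order over (A, C, G, T), 1-based."""
    entries = {
        "".join(t): i
        for i, t in enumerate(product(BASES, repeat=3), start=1)
    }
    return TripletIndexTable(entries=entries)


# module-level singleton; the table is deterministic
DEFAULT_TABLE = build_index_table()


def encode(
    seq: DnaSequence, table: TripletIndexTable = DEFAULT_TABLE
) -> IndexVector:
    """Encode a sequence as its overlapping-triplet index vector."""
    residues = seq.residues
    if len(residues) < 3:
        raise EncodingError(
            f"sequence {seq.id!r} of length {len(residues)} is too short to encode"
        )
    indices = [
        table.lookup(residues[i : i + 3]) for i in range(len(residues) - 2)
    ]
    return IndexVector(indices=indices, source_length=len(residues))


def decode(
    vec: IndexVector,
    table: TripletIndexTable = DEFAULT_TABLE,
    id: str = "decoded",
) -> DnaSequence:
    """Reconstruct the unique source sequence of an N-free index vector.

    Consecutive triplets must overlap consistently (the last two letters
    of triplet *i* equal the first two of triplet *i+1*).
    """
    rev = table.reverse()
    if not vec.indices:
        raise DecodeError("empty index vector")
    if any(i == table.unknown_index for i in vec.indices):
        raise DecodeError("cannot decode a vector containing the unknown index")
    triplets = [rev[i] for i in vec.indices]
    residues = [triplets[0]]
    for pos in range(1, len(triplets)):
        if triplets[pos - 1][1:] != triplets[pos][:2]:
            raise DecodeError(
                f"triplets at positions {pos - 1} and {pos} "
                f"({triplets[pos - 1]}, {triplets[pos]}) do not overlap"
            )
        residues.append(triplets[pos][2])
    return DnaSequence(id=id, residues="".join(residues))


def encode_batch(
    seqs: Sequence[DnaSequence],
    table: TripletIndexTable = DEFAULT_TABLE,
    pad_to: Optional[int] = None,
) -> np.ndarray:
    """Encode sequences into an ``n x pad_to`` integer matrix.

    Rows shorter than ``pad_to`` are right-padded with the unknown
    index; a row longer than ``pad_to`` is an error.  ``pad_to``
    defaults to the longest encoded row.
    """
    vectors = [encode(s, table) for s in seqs]
    if pad_to is None:
        pad_to = max((len(v) for v in vectors), default=0)
    out = np.full((len(vectors), pad_to), table.unknown_index, dtype=np.int64)
    for row, vec in enumerate(vectors):
        if len(vec) > pad_to:
            raise ValueError(
                f"row {row} encodes to {len(vec)} indices, longer than pad_to={pad_to}"
            )
        out[row, : len(vec)] = vec.indices
    return out
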