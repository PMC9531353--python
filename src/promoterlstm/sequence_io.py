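"""Read, write and validate fixed-length DNA sequences and labelled datasets.

Sequences are windows around a transcription start site (TSS).  The
benchmark geometry is a 300 nt window covering biological positions
-249..+50 relative to the TSS; internally we use 0-based array
coordinates with the TSS at index 249, and every TSS-relative position
``p`` maps to array index ``tss_index + p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

#: default TSS offset within a 300 nt promoter window (-249..+50)
DEFAULT_TSS_INDEX = 249


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


class EmptyInputError(ValueError):
    """A FASTA file contained no records."""


class WindowBoundsError(ValueError):
    """A requested TSS window extends beyond the source sequence."""


@dataclass
class DnaSequence:
    """A validated nucleotide string with an optional TSS anchor.

    Parameters
    ----------
    id : str
        Free-text record identifier.
    residues : str
        Sequence over ``{A, C, G, T, N}``; lowercase input is uppercased.
    tss_index : int, optional
        0-based offset of the TSS within the window.  ``None`` when the
        sequence carries no anchor.
    """

    id: str
    residues: str
    tss_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: "
                f"{sorted(bad)} (alphabet is A/C/G/T/N)"
            )
        if self.tss_index is not None and not (
            0 <= self.tss_index < len(self.residues)
        ):
            raise ValueError(
                f"tss_index {self.tss_index} outside sequence {self.id!r} "
                f"of length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_n(self) -> bool:
        return "N" in self.residues


@dataclass
class LabelledDataset:
    """An ordered collection of (sequence, binary label) records.

    ``split_tag`` names the role of the dataset: ``"train"``,
    ``"validation"`` or ``"test"``.
    """

    records: List[Tuple[DnaSequence, int]] = field(default_factory=list)
    split_tag: str = "train"

    _SPLIT_TAGS = ("train", "validation", "test")

    def __post_init__(self) -> None:
        if self.split_tag not in self._SPLIT_TAGS:
            raise ValueError(
                f"split_tag must be one of {self._SPLIT_TAGS}, got {self.split_tag!r}"
            )
        seen = set()
        for seq, label in self.records:
            if label not in (0, 1):
                raise ValueError(f"non-binary label {label!r} for record {seq.id!r}")
            if seq.id in seen:
                raise ValueError(f"duplicate record id {seq.id!r}")
            seen.add(seq.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> List[DnaSequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> List[int]:
        return [label for _, label in self.records]

    def class_counts(self) -> Tuple[int, int]:
        """(count of label 0, count of label 1)."""
        labels = self.labels
        n1 = sum(labels)
        return len(labels) - n1, n1

    def is_balanced(self) -> bool:
        n0, n1 = self.class_counts()
        return n0 == n1


def read_fasta(
    path,
    expected_length: Optional[int] = None,
    n_policy: str = "keep",
) -> List[DnaSequence]:
    """Read DNA sequences from a FASTA file.

    Parameters
    ----------
    path : path-like
        FASTA file (multi-record; wrapped or unwrapped sequence lines).
    expected_length : int, optional
        If given, records of any other length are dropped and counted in
        a log summary.
    n_policy : {"keep", "reject"}
        ``"reject"`` drops records containing N (ambiguous base);
        ``"keep"`` retains them.  Training data should use ``"reject"``.

    Returns
    -------
    list of DnaSequence
        Records in file order, residues uppercased.
    """
    if n_policy not in ("keep", "reject"):
        raise ValueError(f"n_policy must be 'keep' or 'reject', got {n_policy!r}")
    path = Path(path)
    records: List[DnaSequence] = []
    n_dropped_n = 0
    n_dropped_len = 0
    with open(path) as handle:
        # reject text before the first header ourselves: SimpleFastaParser
        # silently skips leading junk lines
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}: sequence data before first '>' header at line 1"
            )
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else header
            rec = DnaSequence(id=rec_id, residues=seq)
            if expected_length is not None and len(rec) != expected_length:
                n_dropped_len += 1
                continue
            if n_policy == "reject" and rec.has_n:
                n_dropped_n += 1
                continue
            records.append(rec)
    if n_dropped_len or n_dropped_n:
        logger.info(
            "read_fasta(%s): kept %d records, dropped %d with wrong length, "
            "%d containing N",
            path,
            len(records),
            n_dropped_len,
            n_dropped_n,
        )
    if not records and n_dropped_len == 0 and n_dropped_n == 0:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[DnaSequence], path, line_width: int = 60) -> int:
    """Write sequences to ``path`` in FASTA format.

    Returns the number of records written.  Round-trip property:
    ``read_fasta`` on the output reproduces ids and residues.
    """
    if line_width < 1:
        raise ValueError("line_width must be positive")
    path = Path(path)
    count = 0
    with open(path, "w") as handle:
        for seq in seqs:
            if not seq.residues:
                raise ValueError(f"cannot write empty sequence {seq.id!r}")
            handle.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), line_width):
                handle.write(seq.residues[start : start + line_width] + "\n")
            count += 1
    return count


def extract_window(
    source: DnaSequence,
    tss_position: int,
    upstream: int = 249,
    downstream: int = 50,
) -> DnaSequence:
    """Cut a TSS-anchored window from a longer sequence.

    The window spans array indices ``[tss_position - upstream,
    tss_position + downstream]`` inclusive (length ``upstream +
    downstream + 1``; 300 for the defaults) and the returned sequence
    carries ``tss_index = upstream``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    start = tss_position - upstream
    stop = tss_position + downstream + 1
    if start < 0 or stop > len(source.residues):
        left_over = max(0, -start)
        right_over = max(0, stop - len(source.residues))
        raise WindowBoundsError(
            f"window [{start}, {stop}) outside sequence {source.id!r} of length "
            f"{len(source.residues)} (overhang: {left_over} left, {right_over} right)"
        )
    return DnaSequence(
        id=source.id,
        residues=source.residues[start:stop],
        tss_index=upstream,
    )


def write_manifest(datasets: Sequence[LabelledDataset], path) -> int:
    """Write a dataset manifest: ``id <TAB> label <TAB> split`` per record."""
    count = 0
    with open(path, "w") as handle:
        for ds in datasets:
            for seq, label in ds.records:
                handle.write(f"{seq.id}\t{label}\t{ds.split_tag}\n")
                count += 1
    return count


def read_manifest(path) -> List[Tuple[str, int, str]]:
    """Read a manifest written by :func:`write_manifest`."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            out.append((parts[0], int(parts[1]), parts[2]))
    return out
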