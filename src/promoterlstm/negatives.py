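"""Construct artificial non-promoter training sequences by block recombination.

A promoter window is split into equal-sized blocks (20 blocks of 15 nt
for the 300 nt default).  A random subset of blocks (8 by default) is
selected as "substitutional" and a random permutation of the selected
blocks is written back over the vacated positions; the remaining
"conservative" blocks stay in place.  The recombinant keeps the exact
mononucleotide composition and most local motif content of its template,
so it is a hard negative: the classifier must learn positional structure
rather than mere motif presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .sequence_io import DnaSequence


class BlockSizeError(ValueError):
    """Sequence length is not divisible by the block size."""


class ConstructionError(RuntimeError):
    """No non-identical recombination could be produced for a sequence."""


class PairingError(ValueError):
    """A (promoter, negative) pair does not belong together."""


@dataclass(frozen=True)
class NegativeConfig:
    """Parameters of the block-recombination construction.

    Defaults follow the benchmark geometry: 300 nt windows split into 20
    blocks of 15 nt, of which 8 are repositioned.
    """

    block_size: int = 15
    n_blocks: int = 20
    n_substitutional: int = 8
    forbid_identity: bool = True
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.block_size < 1 or self.n_blocks < 1:
            raise ValueError("block_size and n_blocks must be positive")
        if not (0 <= self.n_substitutional <= self.n_blocks):
            raise ValueError(
                f"n_substitutional must be in [0, {self.n_blocks}], "
                f"got {self.n_substitutional}"
            )
        if self.forbid_identity and self.n_substitutional < 2:
            raise ValueError(
                "forbid_identity requires n_substitutional >= 2 "
                "(a single repositioned block can never move)"
            )
        if self.max_resample < 1:
            raise ValueError("max_resample must be positive")

    @property
    def sequence_length(self) -> int:
        return self.block_size * self.n_blocks


@dataclass
class ArtificialNegative:
    """A constructed non-promoter plus its full construction trace."""

    residues: str
    source_id: str
    selected_blocks: List[int]
    permutation: Dict[int, int]  # gap position (block index) -> source block index
    seed: int

    def as_sequence(self) -> DnaSequence:
        return DnaSequence(id=f"{self.source_id}_neg", residues=self.residues)


def split_blocks(seq: DnaSequence, block_size: int) -> List[str]:
    """Split a sequence into consecutive equal-sized blocks.

    Raises :class:`BlockSizeError` when the length is not divisible by
    ``block_size``; concatenating the returned blocks reproduces the
    sequence.
    """
    if block_size < 1:
        raise ValueError("block_size must be positive")
    n = len(seq.residues)
    if n % block_size != 0:
        raise BlockSizeError(
            f"sequence {seq.id!r} of length {n} is not divisible by "
            f"block_size {block_size} (remainder {n % block_size})"
        )
    return [
        seq.residues[i : i + block_size] for i in range(0, n, block_size)
    ]


def construct_negative(
    seq: DnaSequence,
    config: NegativeConfig = NegativeConfig(),
    rng: np.random.Generator | int | None = None,
) -> ArtificialNegative:
    """Build one artificial negative from a promoter template.

    Selects ``config.n_substitutional`` block indices uniformly without
    replacement and draws a uniform permutation of the selected blocks
    over the vacated positions (fixed points allowed).  When
    ``forbid_identity`` is set and the recombinant equals the template,
    the permutation is redrawn up to ``max_resample`` times before a
    :class:`ConstructionError` is raised (which can only persist when
    the selected blocks all carry identical content).

    Deterministic given ``(seq, config, seed)``; the seed recorded in the
    trace reproduces the construction via ``np.random.default_rng``.
    """
    if isinstance(rng, np.random.Generator):
        # derive a recordable seed so the trace is self-contained
        seed = int(rng.integers(0, 2**32))
    elif rng is None:
        seed = 0
    else:
        seed = int(rng)
    local = np.random.default_rng(seed)

    if len(seq.residues) != config.sequence_length:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq.residues)}, expected "
            f"{config.sequence_length} (= block_size x n_blocks)"
        )
    blocks = split_blocks(seq, config.block_size)
    k = config.n_substitutional
    selected = sorted(int(i) for i in local.choice(config.n_blocks, size=k, replace=False))

    chosen_perm = None
    for _ in range(config.max_resample):
        perm = local.permutation(k)
        new_blocks = list(blocks)
        for gap_pos, src_pos in zip(selected, (selected[p] for p in perm)):
            new_blocks[gap_pos] = blocks[src_pos]
        candidate = "".join(new_blocks)
        if not config.forbid_identity or candidate != seq.residues:
            chosen_perm = perm
            break
    if chosen_perm is None:
        raise ConstructionError(
            f"could not build a non-identical recombinant for {seq.id!r} after "
            f"{config.max_resample} permutation draws (selected blocks may be identical)"
        )
    return ArtificialNegative(
        residues=candidate,
        source_id=seq.id,
        selected_blocks=selected,
        permutation={g: selected[p] for g, p in zip(selected, chosen_perm)},
        seed=seed,
    )


def derive_sequence_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-sequence seeds from a master seed.

    Mixing rule: ``np.random.SeedSequence(master_seed).generate_state(n)``
    — the i-th 32-bit word of the master seed's expansion seeds the i-th
    construction, so any subset of a corpus reproduces independently.
    """
    return np.random.SeedSequence(master_seed).generate_state(n)


def build_training_negatives(
    promoters: Sequence[DnaSequence],
    config: NegativeConfig = NegativeConfig(),
    seed: int = 0,
) -> List[ArtificialNegative]:
    """One artificial negative per promoter, in input order (1:1 ratio)."""
    seeds = derive_sequence_seeds(seed, len(promoters))
    out = []
    for seq, s in zip(promoters, seeds):
        out.append(construct_negative(seq, config, rng=int(s)))
    return out


def _kmer_counts(residues: str, k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        kmer = residues[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def composition_report(
    seq: DnaSequence, negative: ArtificialNegative
) -> pd.DataFrame:
    """Mono- and trinucleotide counts for a template/negative pair.

    Diagnostic for the motif-preservation rationale: block shuffling
    conserves mononucleotide counts exactly, and trinucleotide counts
    can differ only at block junctions.

    Returns a DataFrame indexed by k-mer with columns ``k``, ``source``
    and ``negative``.
    """
    if negative.source_id != seq.id:
        raise PairingError(
            f"negative built from {negative.source_id!r}, not {seq.id!r}"
        )
    if len(negative.residues) != len(seq.residues):
        raise PairingError("template and negative lengths differ")
    rows = []
    for k in (1, 3):
        src = _kmer_counts(seq.residues, k)
        neg = _kmer_counts(negative.residues, k)
        for kmer in sorted(set(src) | set(neg)):
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "source": src.get(kmer, 0),
                    "negative": neg.get(kmer, 0),
                }
            )
    return pd.DataFrame(rows).set_index("kmer")
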