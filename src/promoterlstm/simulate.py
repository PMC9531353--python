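"""Synthetic promoter benchmark with planted regulatory motifs.

Positives are 300 nt windows with the TSS at index 249 and core-promoter
elements planted at their canonical TSS-relative locations: a TATA-box
in the -30..-25 window, a CAAT-box in -80..-70 and a GC-box in
-110..-80.  Each motif is written as its consensus, left-anchored at the
window start, with every position independently redrawn from the
background composition with a configurable mutation probability.
Negatives are background-composition draws with no planted motifs.

The benchmark builder mirrors the training design of the real pipeline:
training negatives are block-recombination artifacts of the training
positives, while validation and test negatives are genuine background
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .negatives import NegativeConfig, build_training_negatives
from .sequence_io import DnaSequence, LabelledDataset

BASES = "ACGT"


@dataclass(frozen=True)
class MotifSpec:
    """A consensus element planted at a TSS-relative window.

    ``position_range`` is (start, end) in TSS-relative coordinates
    (negative upstream); the consensus is left-anchored at ``start`` and
    must fit inside the window.  Each consensus position is redrawn from
    the background with probability ``per_position_mutation_prob``.
    """

    name: str
    consensus: str
    position_range: Tuple[int, int]
    per_position_mutation_prob: float = 0.1

    def __post_init__(self) -> None:
        start, end = self.position_range
        if len(self.consensus) > end - start + 1:
            raise ValueError(
                f"motif {self.name!r}: consensus of length {len(self.consensus)} "
                f"does not fit window {self.position_range}"
            )
        if not 0.0 <= self.per_position_mutation_prob <= 1.0:
            raise ValueError("per_position_mutation_prob must be in [0, 1]")
        if set(self.consensus) - set(BASES):
            raise ValueError(f"motif {self.name!r}: consensus must be over ACGT")


def default_motifs(
    promoter_class: str = "TATA", mutation_prob: float = 0.1
) -> List[MotifSpec]:
    """Canonical core-promoter elements; the TATA class includes all
    three, the nonTATA class drops the TATA-box."""
    motifs = [
        MotifSpec("TATA-box", "TATAAA", (-30, -25), mutation_prob),
        MotifSpec("CAAT-box", "GGCCAATCT", (-80, -70), mutation_prob),
        MotifSpec("GC-box", "GGGCGG", (-110, -80), mutation_prob),
    ]
    if promoter_class == "nonTATA":
        motifs = [m for m in motifs if m.name != "TATA-box"]
    return motifs


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters for one benchmark corpus."""

    seq_length: int = 300
    tss_index: int = 249
    background_composition: Tuple[float, float, float, float] = (
        0.25,
        0.25,
        0.25,
        0.25,
    )
    motifs: Tuple[MotifSpec, ...] = ()
    promoter_class: str = "TATA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.promoter_class not in ("TATA", "nonTATA"):
            raise ValueError("promoter_class must be 'TATA' or 'nonTATA'")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.size != 4 or comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-6:
            raise ValueError(
                "background_composition must be 4 non-negative probabilities "
                "summing to 1"
            )
        if not 0 <= self.tss_index < self.seq_length:
            raise ValueError("tss_index must lie inside the sequence")
        motifs = self.motifs or tuple(default_motifs(self.promoter_class))
        names = [m.name for m in motifs]
        has_tata = "TATA-box" in names
        if self.promoter_class == "TATA" and not has_tata:
            raise ValueError("TATA promoter class requires a TATA-box motif")
        if self.promoter_class == "nonTATA" and has_tata:
            raise ValueError("nonTATA promoter class must not include a TATA-box")
        object.__setattr__(self, "motifs", motifs)
        for m in motifs:
            start = self.tss_index + m.position_range[0]
            if start < 0 or start + len(m.consensus) > self.seq_length:
                raise ValueError(
                    f"motif {m.name!r} maps outside the sequence "
                    f"(start index {start})"
                )

    def motif_start_index(self, motif: MotifSpec) -> int:
        """Array index of the motif's first planted base."""
        return self.tss_index + motif.position_range[0]


def _background_draw(
    cfg: SimConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    return rng.choice(4, size=size, p=np.asarray(cfg.background_composition))


def generate_background(
    cfg: SimConfig, rng: np.random.Generator, id: str = "bg"
) -> DnaSequence:
    """A background-composition sequence with no planted motifs."""
    codes = _background_draw(cfg, rng, cfg.seq_length)
    return DnaSequence(
        id=id,
        residues="".join(BASES[c] for c in codes),
        tss_index=None,
    )


def generate_promoter(
    cfg: SimConfig, rng: np.random.Generator, id: str = "pro"
) -> DnaSequence:
    """A promoter-like sequence: background plus planted, mutated motifs."""
    codes = _background_draw(cfg, rng, cfg.seq_length)
    for motif in cfg.motifs:
        start = cfg.motif_start_index(motif)
        for offset, letter in enumerate(motif.consensus):
            if rng.random() < motif.per_position_mutation_prob:
                codes[start + offset] = _background_draw(cfg, rng, 1)[0]
            else:
                codes[start + offset] = BASES.index(letter)
    return DnaSequence(
        id=id,
        residues="".join(BASES[c] for c in codes),
        tss_index=cfg.tss_index,
    )


def generate_benchmark(
    cfg: SimConfig,
    n_per_class: int,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: Optional[int] = None,
    negative_config: Optional[NegativeConfig] = None,
) -> Tuple[LabelledDataset, LabelledDataset, LabelledDataset]:
    """Three balanced LabelledDatasets mirroring the real training design.

    Positives are simulated promoters; training negatives are
    block-recombination artifacts of the training positives, while
    validation/test negatives are background sequences.  Split sizes are
    ``round(fraction * n_per_class)`` per class with the remainder
    assigned to the training split.  Deterministic given ``seed``
    (defaults to ``cfg.seed``).
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be at least 10")
    f = np.asarray(fractions, dtype=float)
    if f.size != 3 or f.min() <= 0 or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    rng_pos, rng_neg = (np.random.default_rng(c) for c in ss.spawn(2))
    neg_seed = int(ss.generate_state(1)[0])

    n_val = int(round(f[1] * n_per_class))
    n_test = int(round(f[2] * n_per_class))
    n_train = n_per_class - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every split needs at least one sequence per class")

    sizes = {"train": n_train, "validation": n_val, "test": n_test}
    positives = {
        tag: [
            generate_promoter(cfg, rng_pos, id=f"pro_{tag}_{i:05d}")
            for i in range(n)
        ]
        for tag, n in sizes.items()
    }

    if negative_config is None:
        block_size = 15
        if cfg.seq_length % block_size != 0:
            raise ValueError(
                f"seq_length {cfg.seq_length} is not divisible by the default "
                "block size of 15; pass an explicit negative_config"
            )
        negative_config = NegativeConfig(
            block_size=block_size, n_blocks=cfg.seq_length // block_size
        )
    train_negs = [
        neg.as_sequence()
        for neg in build_training_negatives(
            positives["train"], negative_config, seed=neg_seed
        )
    ]
    negatives = {
        "train": train_negs,
        "validation": [
            generate_background(cfg, rng_neg, id=f"bg_validation_{i:05d}")
            for i in range(n_val)
        ],
        "test": [
            generate_background(cfg, rng_neg, id=f"bg_test_{i:05d}")
            for i in range(n_test)
        ],
    }

    out = []
    for tag in ("train", "validation", "test"):
        records = [(s, 1) for s in positives[tag]] + [(s, 0) for s in negatives[tag]]
        out.append(LabelledDataset(records=records, split_tag=tag))
    return tuple(out)
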