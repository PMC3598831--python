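"""Labeled synthetic sequences: planted degenerate motif clusters vs background.

CRM-like records emulate the statistical structure of enhancers — clusters of
binding sites for several transcription factors — by planting mutated copies
of a handful of short consensus motifs at non-overlapping positions in an
i.i.d. background. Background records are pure i.i.d. draws from a
composition model. Nothing about real enhancer grammar, dinucleotide
structure or repeat content is simulated; see the methods note for what that
implies about test coverage.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np

from .sequence_io import DNA_ALPHABET, CompositionModel, RngLike, SequenceRecord, _as_rng

#: per-record placement attempts before giving up on non-overlapping planting
_MAX_PLACEMENT_TRIES = 200


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic sequence.

    ``motifs`` holds the consensus word of each planted motif family (one
    family per transcription factor being emulated); ``copies`` is the number
    of planted sites per family. A single string is accepted for ``motifs``.
    Each planted copy is independently mutated per letter at
    ``mutation_rate``.
    """

    length: int = 1200
    composition: CompositionModel = dataclasses.field(default_factory=CompositionModel.uniform)
    motifs: tuple[str, ...] = ("ACGTA",)
    copies: int = 10
    mutation_rate: float = 0.15
    seed: int = 0
    label: str = "CRM-like"

    def __post_init__(self) -> None:
        if isinstance(self.motifs, str):
            object.__setattr__(self, "motifs", (self.motifs,))
        else:
            object.__setattr__(self, "motifs", tuple(self.motifs))
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"mutation_rate must be in [0, 1], got {self.mutation_rate}")
        total = self.copies * sum(len(w) for w in self.motifs)
        if total > self.length:
            raise ValueError(f"cannot place {total} planted bases in length {self.length}")


def _draw_letters(comp: CompositionModel, n: int, gen: np.random.Generator) -> np.ndarray:
    probs = comp.as_array()
    if (probs < 0).any():
        raise ValueError("invalid composition")
    return gen.choice(4, size=n, p=probs)


def generate_background(spec: SyntheticSpec, rng: Optional[RngLike] = None) -> SequenceRecord:
    """i.i.d. letters from the spec's composition; deterministic for a fixed seed."""
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    gen = _as_rng(spec.seed if rng is None else rng)
    codes = _draw_letters(spec.composition, spec.length, gen)
    seq = "".join(DNA_ALPHABET[c] for c in codes)
    return SequenceRecord(id=f"bg_{spec.seed}", seq=seq, metadata={"label": "background"})


def _mutate(word: str, rate: float, gen: np.random.Generator) -> str:
    out = []
    for ch in word:
        if rate > 0 and gen.random() < rate:
            out.append(gen.choice([b for b in DNA_ALPHABET if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def generate_crm_like(spec: SyntheticSpec, rng: Optional[RngLike] = None) -> SequenceRecord:
    """Background with ``copies`` mutated copies of each motif planted non-overlappingly.

    Plant positions are uniform among non-overlapping placements (rejection
    sampling, bounded retries); positions and planted words are recorded in
    the record metadata under ``"planted"`` as (position, motif_index, word).
    """
    gen = _as_rng(spec.seed if rng is None else rng)
    codes = _draw_letters(spec.composition, spec.length, gen)
    letters = list("".join(DNA_ALPHABET[c] for c in codes))

    occupied: list[tuple[int, int]] = []  # half-open [start, end)
    planted: list[tuple[int, int, str]] = []
    for motif_index, motif in enumerate(spec.motifs):
        w = len(motif)
        for _ in range(spec.copies):
            for _ in range(_MAX_PLACEMENT_TRIES):
                pos = int(gen.integers(0, spec.length - w + 1))
                if all(pos + w <= s or pos >= e for s, e in occupied):
                    break
            else:
                raise ValueError(
                    f"could not place {spec.copies} non-overlapping copies of "
                    f"{len(spec.motifs)} motifs in length {spec.length}"
                )
            word = _mutate(motif, spec.mutation_rate, gen)
            letters[pos : pos + w] = word
            occupied.append((pos, pos + w))
            planted.append((pos, motif_index, word))
    return SequenceRecord(
        id=f"crm_{spec.seed}",
        seq="".join(letters),
        metadata={"label": "CRM-like", "planted": sorted(planted)},
    )


@dataclasses.dataclass(frozen=True)
class BenchmarkTemplate:
    """Per-record parameter ranges for a labeled benchmark.

    Ranges echo a ~100 kb / 60-sequence training corpus of dense enhancers:
    records of 1000-1650 bases, each CRM-like record carrying several motif
    families (distinct random 5-mer consensi) with 8-15 planted sites per
    family, mutated at 10-20% per letter.
    """

    length_range: tuple[int, int] = (1000, 1650)
    n_motifs_range: tuple[int, int] = (4, 8)
    copies_range: tuple[int, int] = (8, 15)
    mutation_range: tuple[float, float] = (0.1, 0.2)
    motif_length: int = 5
    composition: CompositionModel = dataclasses.field(default_factory=CompositionModel.uniform)


def _draw_spec(template: BenchmarkTemplate, label: str, seed: int, gen: np.random.Generator) -> SyntheticSpec:
    length = int(gen.integers(template.length_range[0], template.length_range[1] + 1))
    n_motifs = int(gen.integers(template.n_motifs_range[0], template.n_motifs_range[1] + 1))
    copies = int(gen.integers(template.copies_range[0], template.copies_range[1] + 1))
    mutation = float(gen.uniform(*template.mutation_range))
    motifs = tuple(
        "".join(gen.choice(list(DNA_ALPHABET), size=template.motif_length)) for _ in range(n_motifs)
    )
    return SyntheticSpec(
        length=length,
        composition=template.composition,
        motifs=motifs,
        copies=copies,
        mutation_rate=mutation,
        seed=seed,
        label=label,
    )


def generate_benchmark(
    n_pos: int,
    n_neg: int,
    template: Optional[BenchmarkTemplate] = None,
    rng_seed: int = 0,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """A labeled benchmark: n_pos CRM-like + n_neg background records.

    Record ids (``seq_0001``...) encode nothing about the labels — the truth
    lives only in the returned (id, label) table. Byte-identical regeneration
    for a fixed ``rng_seed``.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one record per class")
    if template is None:
        template = BenchmarkTemplate()
    gen = _as_rng(rng_seed)
    labels = ["CRM-like"] * n_pos + ["background"] * n_neg
    gen.shuffle(labels)
    records: list[SequenceRecord] = []
    truth: list[tuple[str, str]] = []
    for i, label in enumerate(labels):
        child = int(gen.integers(0, 2**31 - 1))
        spec = _draw_spec(template, label, seed=child, gen=gen)
        rec = generate_crm_like(spec) if label == "CRM-like" else generate_background(spec)
        rec = SequenceRecord(id=f"seq_{i:04d}", seq=rec.seq, metadata=rec.metadata)
        records.append(rec)
        truth.append((rec.id, label))
    return records, truth
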