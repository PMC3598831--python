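"""FASTA input/output, alphabet normalization, composition estimation and shuffling.

Sequences are plain uppercase strings over ``A C G T`` plus the sentinel ``N``
standing for any ambiguous symbol kept under the ``skip-ambiguous`` policy.
Windows touching a sentinel are excluded downstream from seed enumeration and
occurrence counting; composition is always estimated over unambiguous
positions only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = "ACGT"
AMBIGUOUS = "N"

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence with a validated alphabet.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    seq : str
        Uppercase sequence over ``ACGT`` plus the ambiguity sentinel ``N``.
    metadata : dict
        Free-form provenance (e.g. planted-motif positions for synthetic
        records). Not compared for equality.
    """

    id: str
    seq: str
    metadata: dict = dataclasses.field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = set(DNA_ALPHABET + AMBIGUOUS)
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: unnormalized symbols {sorted(bad)}; "
                "pass raw text through normalize_sequence first"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class CompositionModel:
    """Per-nucleotide Bernoulli probabilities (the i.i.d. sequence null)."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.probs) != set(DNA_ALPHABET):
            raise ValueError(f"composition keys must be exactly ACGT, got {sorted(self.probs)}")
        vals = np.array([self.probs[b] for b in DNA_ALPHABET], dtype=float)
        if (vals < 0).any():
            raise ValueError("negative nucleotide probability")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {vals.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        """Probabilities in A, C, G, T order."""
        return np.array([self.probs[b] for b in DNA_ALPHABET], dtype=float)

    def __getitem__(self, base: str) -> float:
        return self.probs[base]

    @classmethod
    def uniform(cls) -> "CompositionModel":
        return cls({b: 0.25 for b in DNA_ALPHABET})

    @classmethod
    def from_probs(cls, a: float, c: float, g: float, t: float) -> "CompositionModel":
        return cls({"A": a, "C": c, "G": g, "T": t})


def normalize_sequence(raw: str, policy: str = "skip-ambiguous") -> str:
    """Uppercase a raw sequence and resolve non-ACGT symbols per policy.

    ``strict`` raises on the first non-ACGT symbol, naming it and its
    1-based position. ``skip-ambiguous`` replaces every non-ACGT symbol with
    the sentinel ``N``; downstream word windows overlapping a sentinel are
    skipped.
    """
    if not raw:
        raise ValueError("empty sequence")
    if policy not in ("strict", "skip-ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    up = raw.upper()
    if policy == "strict":
        for pos, ch in enumerate(up, start=1):
            if ch not in DNA_ALPHABET:
                raise ValueError(f"non-ACGT symbol {ch!r} at position {pos}")
        return up
    return "".join(ch if ch in DNA_ALPHABET else AMBIGUOUS for ch in up)


def read_fasta(path: Union[str, Path], policy: str = "skip-ambiguous") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into SequenceRecords in file order.

    An empty file yields an empty list. Sequence data appearing before the
    first header is a format error.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path}: malformed FASTA (sequence data before first '>')")
    records = []
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq), policy)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def composition(seq: SequenceRecord) -> CompositionModel:
    """Mononucleotide frequencies over the unambiguous positions of ``seq``."""
    counts = {b: seq.seq.count(b) for b in DNA_ALPHABET}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"record {seq.id!r}: no unambiguous ACGT positions")
    return CompositionModel({b: counts[b] / total for b in DNA_ALPHABET})


def shuffle_sequence(seq: SequenceRecord, rng: RngLike) -> SequenceRecord:
    """Uniform random permutation of the letters of ``seq`` (Fisher-Yates).

    Preserves the single-nucleotide composition exactly; deterministic for a
    fixed seed.
    """
    gen = _as_rng(rng)
    letters = np.frombuffer(seq.seq.encode("ascii"), dtype=np.uint8)
    permuted = gen.permutation(letters)
    return SequenceRecord(id=seq.id, seq=permuted.tobytes().decode("ascii"))
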