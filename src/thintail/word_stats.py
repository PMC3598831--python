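"""Seed-word enumeration, similar-word sets (Hamming balls) and occurrence counts.

A seed-word is any distinct m-letter word occurring among the overlapping
windows of a sequence. Its similar-word set N_j(W_m) is the Hamming ball of
words within j substitutions, modelling a binding-site motif family. The
family occurrence count n is the number of window positions (overlaps
allowed, single strand) whose word belongs to the set.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb
from typing import Iterable

import numpy as np

from .sequence_io import DNA_ALPHABET, SequenceRecord

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

#: occurrence counting modes: window positions vs distinct member words seen
COUNTING_MODES = ("occurrences", "distinct_words")


def encode(seq: str) -> np.ndarray:
    """Letter codes A,C,G,T -> 0..3; any other symbol -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: Iterable[int]) -> str:
    return "".join(DNA_ALPHABET[c] for c in codes)


def hamming_ball_size(m: int, j: int) -> int:
    """|N_j(W_m)| for the full 4-letter ball: sum_{i<=j} C(m,i) 3^i."""
    return sum(comb(m, i) * 3**i for i in range(j + 1))


@dataclasses.dataclass(frozen=True)
class WordSet:
    """A seed-word with its Hamming ball of similar words N_j(W_m)."""

    seed: str
    j: int
    members: frozenset[str]

    @property
    def m(self) -> int:
        return len(self.seed)

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must belong to its own similar-word set")
        if any(len(w) != len(self.seed) for w in self.members):
            raise ValueError("all members must have the seed's length")


@dataclasses.dataclass(frozen=True)
class SeedIndex:
    """Distinct m-letter words of a sequence, in first-occurrence order."""

    seeds: tuple[str, ...]
    m: int

    @property
    def M(self) -> int:
        return len(self.seeds)


def hamming_ball(seed: str, j: int) -> WordSet:
    """All m-letter words differing from ``seed`` by at most ``j`` substitutions."""
    m = len(seed)
    if not 0 <= j <= m:
        raise ValueError(f"need 0 <= j <= m, got j={j}, m={m}")
    bad = set(seed) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid letters in seed: {sorted(bad)}")
    members = {seed}
    for k in range(1, j + 1):
        for positions in itertools.combinations(range(m), k):
            for subs in itertools.product(*(
                [b for b in DNA_ALPHABET if b != seed[p]] for p in positions
            )):
                w = list(seed)
                for p, b in zip(positions, subs):
                    w[p] = b
                members.add("".join(w))
    return WordSet(seed=seed, j=j, members=frozenset(members))


def _window_codes(codes: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 integer codes of all unambiguous m-windows.

    Returns (positions, wcodes); windows containing a non-ACGT sentinel are
    dropped.
    """
    L = codes.shape[0]
    if m > L:
        raise ValueError(f"sequence shorter than word length (L={L} < m={m})")
    win = np.lib.stride_tricks.sliding_window_view(codes, m)
    valid = (win >= 0).all(axis=1)
    pow4 = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    wcodes = win[valid].astype(np.int64) @ pow4
    positions = np.nonzero(valid)[0]
    return positions, wcodes


def enumerate_seed_words(seq: SequenceRecord, m: int) -> SeedIndex:
    """Distinct m-mers among the L-m+1 overlapping windows, first-occurrence order."""
    if m < 1:
        raise ValueError("word length m must be >= 1")
    codes = encode(seq.seq)
    _, wcodes = _window_codes(codes, m)
    uniq, first = np.unique(wcodes, return_index=True)
    order = np.argsort(first)
    seeds = tuple(_decode_int(c, m) for c in uniq[order])
    return SeedIndex(seeds=seeds, m=m)


def _decode_int(code: int, m: int) -> str:
    out = []
    for i in range(m - 1, -1, -1):
        out.append(DNA_ALPHABET[(code >> (2 * i)) & 3])
    return "".join(out)


def _encode_words(words: Iterable[str]) -> np.ndarray:
    """Base-4 integer codes of equal-length ACGT words."""
    words = list(words)
    m = len(words[0])
    pow4 = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    arr = np.array([[_BASE_INDEX[ch] for ch in w] for w in words], dtype=np.int64)
    return arr @ pow4


def count_set_occurrences(seq: SequenceRecord, ws: WordSet, mode: str = "occurrences") -> int:
    """Occurrences of the similar-word set among overlapping single-strand windows.

    ``occurrences`` counts window positions whose word is a member (the
    default, consistent with the occurrence expectation/variance of the
    Bernoulli null); ``distinct_words`` counts distinct member words seen at
    least once.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    codes = encode(seq.seq)
    _, wcodes = _window_codes(codes, ws.m)
    member_codes = _encode_words(sorted(ws.members))
    if mode == "occurrences":
        return int(np.isin(wcodes, member_codes).sum())
    return int(np.isin(member_codes, wcodes).sum())


def ball_codes(seed_codes: np.ndarray, j: int) -> np.ndarray:
    """Hamming-ball member letter-codes for a batch of seeds.

    seed_codes has shape (S, m) with entries 0..3; the result has shape
    (S, B, m) with B = hamming_ball_size(m, j) and the seed itself first.
    Members are distinct by construction (each substitution changes a letter).
    """
    seed_codes = np.asarray(seed_codes)
    S, m = seed_codes.shape
    if j == 0:
        return seed_codes[:, None, :].copy()
    if j == 1:
        B = 1 + 3 * m
        out = np.repeat(seed_codes[:, None, :], B, axis=1)
        b = 1
        for i in range(m):
            for delta in (1, 2, 3):
                out[:, b, i] = (seed_codes[:, i] + delta) % 4
                b += 1
        return out
    # general j: combinatorial generation, shared pattern across seeds
    patterns = []  # (positions, deltas) with deltas in 1..3 applied mod 4
    for k in range(0, j + 1):
        for positions in itertools.combinations(range(m), k):
            for deltas in itertools.product((1, 2, 3), repeat=k):
                patterns.append((positions, deltas))
    B = len(patterns)
    out = np.repeat(seed_codes[:, None, :], B, axis=1)
    for b, (positions, deltas) in enumerate(patterns):
        for p, d in zip(positions, deltas):
            out[:, b, p] = (seed_codes[:, p] + d) % 4
    return out


def family_counts(
    seq: SequenceRecord, m: int, j: int, mode: str = "occurrences"
) -> tuple[SeedIndex, np.ndarray, np.ndarray]:
    """Per-seed similar-word-set counts for every seed of the sequence.

    Returns (index, seed_letter_codes (S, m), n (S,)). The batch path used by
    Z-profiles; equivalent to count_set_occurrences seed by seed.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    codes = encode(seq.seq)
    _, wcodes = _window_codes(codes, m)
    uniq, first, counts = np.unique(wcodes, return_index=True, return_counts=True)
    order = np.argsort(first)
    uniq, counts = uniq[order], counts[order]
    seeds = tuple(_decode_int(c, m) for c in uniq)
    index = SeedIndex(seeds=seeds, m=m)

    seed_letters = ((uniq[:, None] >> (2 * np.arange(m - 1, -1, -1))) & 3).astype(np.int8)
    members = ball_codes(seed_letters, j)  # (S, B, m)
    pow4 = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    member_ints = members.astype(np.int64) @ pow4  # (S, B)

    lookup_uniq = np.sort(uniq)
    lookup_counts = counts[np.argsort(uniq)]
    idx = np.searchsorted(lookup_uniq, member_ints)
    idx_clipped = np.minimum(idx, len(lookup_uniq) - 1)
    present = lookup_uniq[idx_clipped] == member_ints
    if mode == "occurrences":
        n = np.where(present, lookup_counts[idx_clipped], 0).sum(axis=1)
    else:
        n = present.sum(axis=1)
    return index, seed_letters, n.astype(np.int64)


def family_size_distribution(
    seq: SequenceRecord, m: int, j: int, mode: str = "occurrences"
) -> dict[int, int]:
    """g(n): how many seed-words have similar-word-set count exactly n.

    The histogram partitions the seed index: sum_n g(n) == M.
    """
    _, _, n = family_counts(seq, m, j, mode=mode)
    values, freq = np.unique(n, return_counts=True)
    return {int(v): int(f) for v, f in zip(values, freq)}
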