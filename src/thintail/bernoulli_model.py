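"""Exact occurrence moments of similar-word sets in an i.i.d. (Bernoulli) sequence.

For a word set with per-window membership probability P = sum of member word
probabilities, the occurrence count over the N = L - m + 1 overlapping windows
has

    E = N * P
    V = N * P (1 - P) + 2 * sum_{d=1}^{min(m-1, N-1)} (N - d) * Cov_d

where Cov_d is the covariance of membership indicators at two windows offset
by d. Windows offset by d < m share letters, so Cov_d involves every
overlap-compatible ordered pair (w, w') of members: w occupies the left
window, w' the right one, and they agree on the shared m - d letters, merging
into a single word of length m + d whose probability factorizes under the
i.i.d. letter model:

    Cov_d = sum_{w, w': w[d:] == w'[:m-d]} p(w) * p(w'[m-d:])  -  P^2

This finite-L indicator-covariance expansion is exact (no asymptotics) and is
checked against an exhaustive enumeration oracle in the test suite. Self- and
cross-overlaps of distinct members are both included by default; the
self-overlap-only variant (pairs with w == w') is available via
``include_cross=False``.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .sequence_io import DNA_ALPHABET, CompositionModel, SequenceRecord
from .word_stats import WordSet, count_set_occurrences

#: below this variance the Z-score is treated as undefined and the seed dropped
VARIANCE_FLOOR = 1e-300


@dataclasses.dataclass(frozen=True)
class SetMoments:
    """Occurrence expectation and variance of one similar-word set."""

    expectation: float
    variance: float
    L: int
    ws: WordSet


def word_probability(w: str, c: CompositionModel) -> float:
    """Probability of word ``w`` under i.i.d. letters: product of base probabilities."""
    p = 1.0
    for ch in w:
        p *= c[ch]
    return p


def set_expectation(ws: WordSet, c: CompositionModel, L: int) -> float:
    """E = (L - m + 1) * P; members are distinct, so probabilities add per window."""
    m = ws.m
    if L < m:
        raise ValueError(f"L={L} shorter than word length m={m}")
    P = sum(word_probability(w, c) for w in ws.members)
    return (L - m + 1) * P


def set_variance(ws: WordSet, c: CompositionModel, L: int, include_cross: bool = True) -> float:
    """Exact overlap-corrected variance of the set occurrence count.

    Reference (readable, per-pair) implementation; the vectorized batch path
    in ``batch_moments`` must agree with it (tested).
    """
    m = ws.m
    if L < m:
        raise ValueError(f"L={L} shorter than word length m={m}")
    N = L - m + 1
    members = sorted(ws.members)
    probs = {w: word_probability(w, c) for w in members}
    P = sum(probs.values())
    V = N * P * (1.0 - P)
    for d in range(1, min(m, N)):
        pair_sum = 0.0
        for w in members:
            for w2 in members:
                if not include_cross and w != w2:
                    continue
                if w[d:] == w2[: m - d]:
                    pair_sum += probs[w] * word_probability(w2[m - d :], c)
        V += 2.0 * (N - d) * (pair_sum - P * P)
    return V


def set_moments(ws: WordSet, c: CompositionModel, L: int, include_cross: bool = True) -> SetMoments:
    return SetMoments(
        expectation=set_expectation(ws, c, L),
        variance=set_variance(ws, c, L, include_cross=include_cross),
        L=L,
        ws=ws,
    )


def batch_moments(
    member_codes: np.ndarray,
    probs4: np.ndarray,
    L: int,
    include_cross: bool = True,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized moments for S word sets at once.

    member_codes: (S, B, m) letter codes of the (distinct) members of each
    set; probs4: base probabilities in ACGT order; returns (E, V), each (S,).
    """
    member_codes = np.asarray(member_codes)
    S, B, m = member_codes.shape
    if L < m:
        raise ValueError(f"L={L} shorter than word length m={m}")
    N = L - m + 1
    probs4 = np.asarray(probs4, dtype=float)
    pw = probs4[member_codes].prod(axis=2)  # (S, B) member word probabilities
    P = pw.sum(axis=1)
    E = N * P
    V = N * P * (1.0 - P)
    eye = np.eye(B, dtype=bool)
    for d in range(1, min(m, N)):
        tail = probs4[member_codes[:, :, m - d :]].prod(axis=2)  # (S, B)
        pair_sum = np.empty(S)
        for lo in range(0, S, chunk):
            hi = min(lo + chunk, S)
            left = member_codes[lo:hi, :, None, d:]  # suffix of w
            right = member_codes[lo:hi, None, :, : m - d]  # prefix of w'
            compat = (left == right).all(axis=3)  # (s, B, B)
            if not include_cross:
                compat = compat & eye
            pair_sum[lo:hi] = np.einsum("sab,sa,sb->s", compat, pw[lo:hi], tail[lo:hi])
        V += 2.0 * (N - d) * (pair_sum - P * P)
    return E, V


def oracle_moments(
    ws: WordSet,
    c: CompositionModel,
    L: int,
    alphabet: str = DNA_ALPHABET,
    max_states: int = 10_000_000,
) -> SetMoments:
    """Exact moments by exhaustive enumeration of every length-L sequence.

    Enumerates all |alphabet|^L sequences, weights each by its i.i.d.
    probability under ``c``, and counts set occurrences by direct window
    membership at every position. Test oracle only — shares nothing with the
    analytic covariance expansion above. Members with letters outside
    ``alphabet`` have probability zero and cannot occur, so they are ignored.
    """
    a = len(alphabet)
    n_states = a**L
    if n_states > max_states:
        raise ValueError(f"{a}^{L} sequences exceed enumeration guard {max_states}")
    m = ws.m
    if L < m:
        raise ValueError(f"L={L} shorter than word length m={m}")
    letter_probs = np.array([c[ch] for ch in alphabet], dtype=float)
    letter_index = {ch: i for i, ch in enumerate(alphabet)}
    member_codes = []
    for w in sorted(ws.members):
        if all(ch in letter_index for ch in w):
            code = 0
            for ch in w:
                code = code * a + letter_index[ch]
            member_codes.append(code)
    member_codes = np.array(sorted(member_codes), dtype=np.int64)

    codes = np.arange(n_states, dtype=np.int64)
    counts = np.zeros(n_states, dtype=np.int32)
    for p in range(L - m + 1):
        win = (codes // a ** (L - p - m)) % a**m
        counts += np.isin(win, member_codes)
    prob = np.ones(n_states, dtype=float)
    for p in range(L):
        prob *= letter_probs[(codes // a ** (L - 1 - p)) % a]
    E = float(prob @ counts)
    E2 = float(prob @ (counts.astype(float) ** 2))
    return SetMoments(expectation=E, variance=E2 - E * E, L=L, ws=ws)


def enumeration_moments_slow(ws: WordSet, c: CompositionModel, L: int, alphabet: str = DNA_ALPHABET) -> SetMoments:
    """Tiny-instance enumeration through ``count_set_occurrences`` (cross-checks the oracle)."""
    a = len(alphabet)
    if a**L > 100_000:
        raise ValueError("slow enumeration limited to tiny instances")
    letter_probs = np.array([c[ch] for ch in alphabet], dtype=float)
    E = 0.0
    E2 = 0.0
    for digits in itertools.product(range(a), repeat=L):
        p = float(np.prod(letter_probs[list(digits)]))
        if p == 0.0:
            continue
        seq = "".join(alphabet[d] for d in digits)
        n = count_set_occurrences(SequenceRecord(id="oracle", seq=seq), ws)
        E += p * n
        E2 += p * n * n
    return SetMoments(expectation=E, variance=E2 - E * E, L=L, ws=ws)
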