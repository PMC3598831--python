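"""The fluffy-tail baseline: most-abundant similar-word family vs shuffles.

The earlier content-based test scores a sequence by the size of its largest
similar-word family rather than by the shape of the Z distribution:

    F_r = (L0 - mean(L_shuffles)) / sd(L_shuffles)

where L is, in the default reading, the occurrence count of the most abundant
similar-word set (mode ``max_n``); the alternative reading, the number of
seed-words attaining that maximum, is mode ``count_at_max``. A sequence with
F_r > 2 is called a CRM. Shuffles preserve mononucleotide composition.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import word_stats
from .sequence_io import RngLike, SequenceRecord, _as_rng, shuffle_sequence
from .thin_tail import DEFAULT_J, DEFAULT_M, DEFAULT_R, LABEL_CRM, LABEL_NCNR, UndefinedStatisticError

L_MODES = ("max_n", "count_at_max")
DEFAULT_THRESHOLD_F = 2.0


@dataclasses.dataclass(frozen=True)
class FluffyResult:
    id: str
    L0: float
    r: int
    shuffle_Ls: tuple[float, ...]
    s_r: float
    F_coef: Optional[float]
    label: Optional[str]
    mode: str


def _L_from_counts(n: np.ndarray, mode: str) -> int:
    if n.size == 0:
        raise ValueError("no seeds")
    if mode == "max_n":
        return int(n.max())
    if mode == "count_at_max":
        return int((n == n.max()).sum())
    raise ValueError(f"unknown tail-statistic mode {mode!r}")


def tail_statistic_L(
    seq: SequenceRecord, m: int = DEFAULT_M, j: int = DEFAULT_J, mode: str = "max_n"
) -> int:
    """L: size of the most abundant similar-word family (or how many attain it)."""
    _, _, n = word_stats.family_counts(seq, m, j)
    return _L_from_counts(n, mode)


def fluffiness_F(L0: float, shuffle_Ls: Sequence[float]) -> float:
    """F = (L0 - mean(Ls)) / sd(Ls), sample sd (ddof=1)."""
    Ls = np.asarray(shuffle_Ls, dtype=float)
    if Ls.size < 2:
        raise ValueError(f"need at least 2 shuffle statistics, got {Ls.size}")
    sd = Ls.std(ddof=1)
    if sd == 0 or np.all(Ls == Ls[0]):
        raise UndefinedStatisticError("F undefined: shuffle statistics are constant")
    return float((L0 - Ls.mean()) / sd)


def classify_fluffy(F_coef: float, threshold: float = DEFAULT_THRESHOLD_F) -> str:
    """CRM iff F > threshold (strict); NCNR otherwise."""
    return LABEL_CRM if F_coef > threshold else LABEL_NCNR


def fluffy_tail_test(
    seq: SequenceRecord,
    m: int = DEFAULT_M,
    j: int = DEFAULT_J,
    r: int = DEFAULT_R,
    rng: RngLike = 0,
    mode: str = "max_n",
    threshold: float = DEFAULT_THRESHOLD_F,
) -> FluffyResult:
    """Full fluffy-tail test of one sequence."""
    if r < 2:
        raise ValueError(f"need at least 2 shuffles, got r={r}")
    if mode not in L_MODES:
        raise ValueError(f"unknown tail-statistic mode {mode!r}")
    gen = _as_rng(rng)
    L0 = tail_statistic_L(seq, m, j, mode=mode)
    Ls = np.array([tail_statistic_L(shuffle_sequence(seq, gen), m, j, mode=mode) for _ in range(r)], dtype=float)
    s_r = float(Ls.std(ddof=1))
    try:
        F = fluffiness_F(L0, Ls)
        label: Optional[str] = classify_fluffy(F, threshold)
    except UndefinedStatisticError:
        F = None
        label = None
    return FluffyResult(
        id=seq.id, L0=float(L0), r=r, shuffle_Ls=tuple(Ls), s_r=s_r, F_coef=F, label=label, mode=mode
    )
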