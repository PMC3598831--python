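"""The thin-tail test: Z-score profiles, kurtosis, and thinness coefficients E and T_r.

For each seed-word the overrepresentation of its similar-word set relative to
a composition-matched Bernoulli sequence is

    Z = (n - E(W_m)) / sqrt(V(W_m))

The shape of the per-seed Z distribution carries the signal: cis-regulatory
modules tend to have thin-tailed (platykurtic) Z distributions. Excess
kurtosis is computed as

    k = sum_i (Z_i - mu)^4 / ((M - 1) sigma^4) - 3

with mu the sample mean and sigma the sample standard deviation (ddof = 1)
over the M seed-words. Two coefficients rescale k:

    E   = (k0 + 2 eps) / (4 eps),   eps = sqrt(c / M)   (c = 26 by default)
    T_r = (k0 - mean(k_shuffles)) / sd(k_shuffles)

E maps the 95% confidence band [-2 eps, 2 eps] of k under normality onto
[0, 1] without any shuffling; T_r compares the original sequence against r
composition-preserving shuffles. Decision rule: CRM if (E < 0.6 and T_r < 0),
NCNR if (E > 0.6 and T_r > 0), otherwise indeterminate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from . import word_stats
from .bernoulli_model import VARIANCE_FLOOR, batch_moments
from .sequence_io import CompositionModel, RngLike, SequenceRecord, _as_rng, composition, shuffle_sequence

logger = logging.getLogger(__name__)

#: minimum number of defined-Z seeds for the kurtosis to make sense
MIN_SEEDS_FOR_KURTOSIS = 4

DEFAULT_M = 5
DEFAULT_J = 1
DEFAULT_R = 50
DEFAULT_EPSILON_CONSTANT = 26.0
DEFAULT_THRESHOLD_E = 0.6
DEFAULT_THRESHOLD_T = 0.0

LABEL_CRM = "CRM"
LABEL_NCNR = "NCNR"
LABEL_INDETERMINATE = "indeterminate"


class UndefinedStatisticError(ValueError):
    """A statistic's preconditions are violated (zero variance, too few seeds...)."""


@dataclasses.dataclass(frozen=True)
class ZProfile:
    """Per-seed statistics (seed, n, E, V, Z) for one sequence."""

    seeds: tuple[str, ...]
    n: np.ndarray
    expectation: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    m: int
    j: int
    L: int
    dropped_seeds: int = 0  # seeds excluded for undefined Z (variance ~ 0)

    @property
    def M(self) -> int:
        return len(self.seeds)

    def histogram(self, bin_width: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """f(Z): counts of seed-words per Z bin; bins of ``bin_width`` centered at 0."""
        if self.M == 0:
            return np.array([0.0]), np.array([], dtype=int)
        lo = np.floor(self.z.min() / bin_width - 0.5)
        hi = np.ceil(self.z.max() / bin_width + 0.5)
        edges = (np.arange(lo, hi + 1) + 0.5) * bin_width - bin_width / 2
        counts, _ = np.histogram(self.z, bins=edges)
        return edges, counts


@dataclasses.dataclass(frozen=True)
class ThinTailResult:
    """Thin-tail coefficients and classification for one sequence."""

    id: str
    L: int
    M: int
    k0: float
    epsilon: float
    E_coef: float
    r: int
    shuffle_kurtoses: tuple[float, ...]
    T_coef: Optional[float]
    label_E: str
    label_T: Optional[str]
    label: str
    dropped_seeds: int = 0


def z_score(n: float, expectation: float, variance: float) -> float:
    """Z = (n - E) / sqrt(V); undefined when V <= 0."""
    if variance <= 0:
        raise UndefinedStatisticError(f"Z-score undefined for variance {variance!r}")
    return (n - expectation) / np.sqrt(variance)


def z_profile(
    seq: SequenceRecord,
    m: int = DEFAULT_M,
    j: int = DEFAULT_J,
    comp: Optional[CompositionModel] = None,
    counting_mode: str = "occurrences",
    include_cross: bool = True,
) -> ZProfile:
    """Z-scores of every seed-word's similar-word set in one sequence.

    The Bernoulli null composition defaults to the sequence's own; seeds with
    numerically zero variance are dropped (count reported).
    """
    if comp is None:
        comp = composition(seq)
    index, seed_letters, n = word_stats.family_counts(seq, m, j, mode=counting_mode)
    members = word_stats.ball_codes(seed_letters, j)
    E, V = batch_moments(members, comp.as_array(), seq.length, include_cross=include_cross)
    ok = V > VARIANCE_FLOOR
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: dropped %d seeds with undefined Z (zero variance)", seq.id, dropped)
    z = (n[ok] - E[ok]) / np.sqrt(V[ok])
    seeds = tuple(s for s, keep in zip(index.seeds, ok) if keep)
    return ZProfile(
        seeds=seeds,
        n=n[ok],
        expectation=E[ok],
        variance=V[ok],
        z=z,
        m=m,
        j=j,
        L=seq.length,
        dropped_seeds=dropped,
    )


def excess_kurtosis(values: Sequence[float]) -> float:
    """k = sum (z - mu)^4 / ((M - 1) sigma^4) - 3 with sample sd (ddof=1)."""
    z = np.asarray(values, dtype=float)
    M = z.size
    if M < MIN_SEEDS_FOR_KURTOSIS:
        raise UndefinedStatisticError(f"kurtosis needs at least {MIN_SEEDS_FOR_KURTOSIS} values, got {M}")
    mu = z.mean()
    sigma = z.std(ddof=1)
    if sigma == 0:
        raise UndefinedStatisticError("kurtosis undefined for constant values")
    return float(((z - mu) ** 4).sum() / ((M - 1) * sigma**4) - 3.0)


def kurtosis_standard_error(M: int, c: float = DEFAULT_EPSILON_CONSTANT) -> float:
    """eps = sqrt(c / M); c = 26 by default, 24 for the classical normal-theory value."""
    if M <= 0:
        raise ValueError(f"M must be positive, got {M}")
    return float(np.sqrt(c / M))


def thinness_E(k0: float, epsilon: float) -> float:
    """First thinness coefficient: (k0 + 2 eps) / (4 eps), the CI mapped to [0, 1]."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return (k0 + 2.0 * epsilon) / (4.0 * epsilon)


def shuffle_kurtoses(
    seq: SequenceRecord,
    m: int = DEFAULT_M,
    j: int = DEFAULT_J,
    r: int = DEFAULT_R,
    rng: RngLike = 0,
    counting_mode: str = "occurrences",
    include_cross: bool = True,
    max_retries_per_shuffle: int = 10,
) -> np.ndarray:
    """Kurtoses of r independently shuffled versions of ``seq``.

    Shuffling preserves mononucleotide composition, so the Bernoulli null of
    each shuffle equals the original's. Degenerate shuffles (too few seeds or
    constant Z) are redrawn a bounded number of times.
    """
    if r < 2:
        raise ValueError(f"need at least 2 shuffles, got r={r}")
    gen = _as_rng(rng)
    comp = composition(seq)
    out = np.empty(r)
    for i in range(r):
        for attempt in range(max_retries_per_shuffle):
            shuffled = shuffle_sequence(seq, gen)
            try:
                prof = z_profile(
                    shuffled, m, j, comp=comp, counting_mode=counting_mode, include_cross=include_cross
                )
                out[i] = excess_kurtosis(prof.z)
                break
            except UndefinedStatisticError:
                logger.warning("%s: degenerate shuffle (attempt %d), redrawing", seq.id, attempt + 1)
        else:
            raise UndefinedStatisticError(
                f"{seq.id}: {max_retries_per_shuffle} degenerate shuffles in a row"
            )
    return out


def thinness_T(k0: float, shuffle_ks: Sequence[float]) -> float:
    """Second thinness coefficient: (k0 - mean(ks)) / sd(ks), sample sd (ddof=1)."""
    ks = np.asarray(shuffle_ks, dtype=float)
    if ks.size < 2:
        raise ValueError(f"need at least 2 shuffle kurtoses, got {ks.size}")
    sd = ks.std(ddof=1)
    if sd == 0 or np.all(ks == ks[0]):
        raise UndefinedStatisticError("T undefined: shuffle kurtoses are constant")
    return float((k0 - ks.mean()) / sd)


def classify_thin(
    E_coef: float,
    T_coef: float,
    tE: float = DEFAULT_THRESHOLD_E,
    tT: float = DEFAULT_THRESHOLD_T,
) -> str:
    """CRM iff (E < tE and T < tT); NCNR iff (E > tE and T > tT); else indeterminate.

    Strict inequalities on both sides: boundary ties are indeterminate.
    """
    if E_coef < tE and T_coef < tT:
        return LABEL_CRM
    if E_coef > tE and T_coef > tT:
        return LABEL_NCNR
    return LABEL_INDETERMINATE


def thin_tail_test(
    seq: SequenceRecord,
    m: int = DEFAULT_M,
    j: int = DEFAULT_J,
    r: int = DEFAULT_R,
    rng: RngLike = 0,
    epsilon_constant: float = DEFAULT_EPSILON_CONSTANT,
    tE: float = DEFAULT_THRESHOLD_E,
    tT: float = DEFAULT_THRESHOLD_T,
    counting_mode: str = "occurrences",
    include_cross: bool = True,
) -> ThinTailResult:
    """Full thin-tail test of one sequence: k0, eps, E, r shuffles, T and the label."""
    prof = z_profile(seq, m, j, counting_mode=counting_mode, include_cross=include_cross)
    k0 = excess_kurtosis(prof.z)
    eps = kurtosis_standard_error(prof.M, c=epsilon_constant)
    E_coef = thinness_E(k0, eps)
    ks = shuffle_kurtoses(
        seq, m, j, r=r, rng=rng, counting_mode=counting_mode, include_cross=include_cross
    )
    try:
        T_coef: Optional[float] = thinness_T(k0, ks)
    except UndefinedStatisticError:
        T_coef = None
    label_E = LABEL_CRM if E_coef < tE else (LABEL_NCNR if E_coef > tE else LABEL_INDETERMINATE)
    if T_coef is None:
        label_T = None
        label = LABEL_INDETERMINATE
    else:
        label_T = LABEL_CRM if T_coef < tT else (LABEL_NCNR if T_coef > tT else LABEL_INDETERMINATE)
        label = classify_thin(E_coef, T_coef, tE=tE, tT=tT)
    return ThinTailResult(
        id=seq.id,
        L=seq.length,
        M=prof.M,
        k0=k0,
        epsilon=eps,
        E_coef=E_coef,
        r=r,
        shuffle_kurtoses=tuple(ks),
        T_coef=T_coef,
        label_E=label_E,
        label_T=label_T,
        label=label,
        dropped_seeds=prof.dropped_seeds,
    )
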