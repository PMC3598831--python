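"""Batch orchestration: run both tests over records, sharing shuffle profiles.

The thin-tail kurtosis and the fluffy-tail statistic both derive from the
per-seed family counts of each shuffled sequence, so one shuffle pass feeds
both tests.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from . import fluffy_tail, thin_tail
from .sequence_io import RngLike, SequenceRecord, _as_rng, composition

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SequenceAnalysis:
    """Everything both tests computed for one sequence (None where undefined)."""

    id: str
    L: int
    M: int
    k0: Optional[float] = None
    epsilon: Optional[float] = None
    E_coef: Optional[float] = None
    r: int = 0
    T_coef: Optional[float] = None
    label_E: Optional[str] = None
    label_T: Optional[str] = None
    label_combined: Optional[str] = None
    L0: Optional[float] = None
    F_coef: Optional[float] = None
    label_F: Optional[str] = None
    fluffy_mode: Optional[str] = None
    dropped_seeds: int = 0
    error: Optional[str] = None


def analyze_sequence(
    seq: SequenceRecord,
    m: int = thin_tail.DEFAULT_M,
    j: int = thin_tail.DEFAULT_J,
    r: int = thin_tail.DEFAULT_R,
    rng: RngLike = 0,
    which: str = "both",
    epsilon_constant: float = thin_tail.DEFAULT_EPSILON_CONSTANT,
    tE: float = thin_tail.DEFAULT_THRESHOLD_E,
    tT: float = thin_tail.DEFAULT_THRESHOLD_T,
    tF: float = fluffy_tail.DEFAULT_THRESHOLD_F,
    counting_mode: str = "occurrences",
    include_cross: bool = True,
    fluffy_mode: str = "max_n",
    keep_profile: bool = False,
) -> tuple[SequenceAnalysis, Optional[thin_tail.ZProfile]]:
    """Run the requested tests on one sequence with a single shuffle pass."""
    if which not in ("thin", "fluffy", "both"):
        raise ValueError(f"unknown test selection {which!r}")
    gen = _as_rng(rng)
    comp = composition(seq)
    prof = thin_tail.z_profile(seq, m, j, comp=comp, counting_mode=counting_mode, include_cross=include_cross)
    out = SequenceAnalysis(id=seq.id, L=seq.length, M=prof.M, r=r, dropped_seeds=prof.dropped_seeds)

    run_thin = which in ("thin", "both")
    run_fluffy = which in ("fluffy", "both")
    if run_thin:
        out.k0 = thin_tail.excess_kurtosis(prof.z)
        out.epsilon = thin_tail.kurtosis_standard_error(prof.M, c=epsilon_constant)
        out.E_coef = thin_tail.thinness_E(out.k0, out.epsilon)
        out.label_E = (
            thin_tail.LABEL_CRM
            if out.E_coef < tE
            else (thin_tail.LABEL_NCNR if out.E_coef > tE else thin_tail.LABEL_INDETERMINATE)
        )
    if run_fluffy:
        out.fluffy_mode = fluffy_mode
        out.L0 = float(fluffy_tail._L_from_counts(prof.n, fluffy_mode))

    # one shuffle pass for both statistics
    ks = np.empty(r)
    Ls = np.empty(r)
    from .sequence_io import shuffle_sequence

    i = 0
    attempts = 0
    while i < r:
        attempts += 1
        if attempts > 10 * r:
            raise thin_tail.UndefinedStatisticError(f"{seq.id}: repeated degenerate shuffles")
        shuffled = shuffle_sequence(seq, gen)
        sprof = thin_tail.z_profile(
            shuffled, m, j, comp=comp, counting_mode=counting_mode, include_cross=include_cross
        )
        try:
            k = thin_tail.excess_kurtosis(sprof.z) if run_thin else 0.0
        except thin_tail.UndefinedStatisticError:
            logger.warning("%s: degenerate shuffle, redrawing", seq.id)
            continue
        ks[i] = k
        Ls[i] = fluffy_tail._L_from_counts(sprof.n, fluffy_mode) if run_fluffy else 0.0
        i += 1
    if attempts > r:
        logger.info("%s: %d shuffle redraws", seq.id, attempts - r)

    if run_thin:
        try:
            out.T_coef = thin_tail.thinness_T(out.k0, ks)
            out.label_T = (
                thin_tail.LABEL_CRM
                if out.T_coef < tT
                else (thin_tail.LABEL_NCNR if out.T_coef > tT else thin_tail.LABEL_INDETERMINATE)
            )
            out.label_combined = thin_tail.classify_thin(out.E_coef, out.T_coef, tE=tE, tT=tT)
        except thin_tail.UndefinedStatisticError as exc:
            logger.warning("%s: %s", seq.id, exc)
            out.label_combined = thin_tail.LABEL_INDETERMINATE
    if run_fluffy:
        try:
            F = fluffy_tail.fluffiness_F(out.L0, Ls)
            out.F_coef = F
            out.label_F = fluffy_tail.classify_fluffy(F, tF)
        except thin_tail.UndefinedStatisticError as exc:
            logger.warning("%s: %s", seq.id, exc)
    return out, (prof if keep_profile else None)


def analyze_records(
    records: Sequence[SequenceRecord],
    rng: RngLike = 0,
    **kwargs,
) -> list[SequenceAnalysis]:
    """Analyze records independently; per-record failures are logged, not fatal.

    Each record gets its own child seed from ``rng`` so results do not depend
    on batch order of successful records.
    """
    gen = _as_rng(rng)
    results = []
    for rec in records:
        child = int(gen.integers(0, 2**31 - 1))
        try:
            analysis, _ = analyze_sequence(rec, rng=child, **kwargs)
        except (ValueError, thin_tail.UndefinedStatisticError) as exc:
            logger.error("%s: analysis failed: %s", rec.id, exc)
            analysis = SequenceAnalysis(id=rec.id, L=rec.length, M=0, error=str(exc))
        results.append(analysis)
    return results
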