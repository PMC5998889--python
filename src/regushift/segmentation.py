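"""Penalized segmentation of the time axis into periods of constant activity.

The optimization target is

    Score(Act) = sum_ij M_ij * Act_ij  -  c * |B| * ln(|G| * |T|)

where each row of the binary activity matrix ``Act`` must be constant within
every period induced by the break set, and ``B`` is the set of penalized
breaks.  The BIC-style penalty coefficient ``c`` defaults to 2 (the value the
search pseudocode charges per break); ``c = 1`` gives the score function in
its plain form.

Two search strategies are provided: :func:`search_exhaustive` enumerates all
break sets of each size k (with the optional early-stop rule that quits once
the score stops improving from k-1 to k), and :func:`search_dp` solves the
same problem by dynamic programming over segment gains, which is exact and
fast because the per-gene optimal activity decomposes over periods:
the best raw score for a fixed break set is

    sum_genes sum_periods max(0, sum of the gene's intensities in the period).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .model import (
    ActivityModel,
    IntensityMatrix,
    KBest,
    SegmentationResult,
    ValidationError,
    periods_from_breaks,
    validate_breaks,
)

__all__ = [
    "CandidateActivitySet",
    "derive_transitions",
    "score_model",
    "best_row_activity",
    "evaluate_segmentation",
    "search_exhaustive",
    "search_dp",
]

DEFAULT_PENALTY_FACTOR = 2.0


def _as_matrix(M) -> tuple[np.ndarray, tuple | None, tuple | None]:
    if isinstance(M, IntensityMatrix):
        return M.values, M.gene_ids, M.time_points
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"intensity matrix must be 2-D, got shape {arr.shape}")
    return arr, None, None


def _check_binary(act: np.ndarray) -> np.ndarray:
    act = np.asarray(act)
    if act.ndim != 2 or not np.isin(act, (0, 1)).all():
        raise ValidationError("activity matrix must be 2-D with entries in {0, 1}")
    return act.astype(np.int8)


class CandidateActivitySet:
    """The set V of binary vectors of length |T| constant on each period.

    With p periods there are 2**p candidates (the direct product of
    {zero, one} over the periods); the all-zero and all-one vectors are
    always members.  Used as the enumeration oracle for the per-period
    sign rule in :func:`best_row_activity`.
    """

    def __init__(self, tra, n_times: int) -> None:
        self.tra = validate_breaks(tra, n_times)
        self.n_times = n_times
        self.periods = periods_from_breaks(self.tra, n_times)

    @property
    def vectors(self) -> list[np.ndarray]:
        out = []
        for bits in itertools.product((0, 1), repeat=len(self.periods)):
            v = np.empty(self.n_times, dtype=np.int8)
            for bit, (a, b) in zip(bits, self.periods):
                v[a : b + 1] = bit
            out.append(v)
        return out

    def __len__(self) -> int:
        return 2 ** len(self.periods)


def derive_transitions(act) -> tuple[int, ...]:
    """Breaks realized by an activity matrix.

    A 1-based index j is a transition iff some row differs between the j-th
    and (j+1)-th columns.
    """
    act = _check_binary(act)
    changed = (act[:, 1:] != act[:, :-1]).any(axis=0)
    return tuple(int(j) + 1 for j in np.flatnonzero(changed))


def _penalty(n_breaks: int, n_genes: int, n_times: int, factor: float) -> float:
    return factor * n_breaks * math.log(n_genes * n_times)


def score_model(
    M,
    act,
    penalty_factor: float = DEFAULT_PENALTY_FACTOR,
    penalty_mode: str = "effective",
    tra=None,
    penalty_genes: int | None = None,
) -> tuple[float, float]:
    """Raw and penalized score of an activity matrix against M.

    Returns ``(raw_score, score)`` with ``raw = sum_ij M_ij * act_ij`` and
    ``score = raw - penalty_factor * |B| * ln(|G|*|T|)``.  In effective mode
    B is derived from ``act``; in declared mode the caller supplies ``tra``.
    ``|G|`` is the number of rows of M unless ``penalty_genes`` overrides it.
    """
    values, _, _ = _as_matrix(M)
    act = _check_binary(act)
    if act.shape != values.shape:
        raise ValidationError(f"act shape {act.shape} != M shape {values.shape}")
    if penalty_factor < 0:
        raise ValidationError("penalty_factor must be >= 0")
    if penalty_mode == "effective":
        breaks = derive_transitions(act)
    elif penalty_mode == "declared":
        if tra is None:
            raise ValidationError("declared penalty mode requires tra")
        breaks = validate_breaks(tra, values.shape[1])
    else:
        raise ValidationError(f"unknown penalty_mode {penalty_mode!r}")
    n_genes = penalty_genes if penalty_genes is not None else values.shape[0]
    raw = float((values * act).sum())
    return raw, raw - _penalty(len(breaks), n_genes, values.shape[1], penalty_factor)


def best_row_activity(m_row, tra) -> tuple[np.ndarray, float]:
    """Optimal period-constant activity vector for one gene.

    Equivalent to enumerating :class:`CandidateActivitySet` and maximizing
    the inner product with ``m_row``: a period is set active iff its
    intensity sum is strictly positive (an exact-zero sum stays inactive,
    preferring the sparser model), so the row's contribution is
    ``sum_periods max(0, period sum)``.
    """
    m_row = np.asarray(m_row, dtype=float)
    if m_row.ndim != 1:
        raise ValidationError("m_row must be 1-D")
    periods = periods_from_breaks(tra, m_row.size)
    v = np.zeros(m_row.size, dtype=np.int8)
    row_raw = 0.0
    for a, b in periods:
        s = float(m_row[a : b + 1].sum())
        if s > 0:
            v[a : b + 1] = 1
            row_raw += s
    return v, row_raw


def _segment_sums(prefix: np.ndarray, tra: tuple[int, ...]) -> np.ndarray:
    """Per-gene sums over the periods induced by tra (genes x periods)."""
    n_times = prefix.shape[1] - 1
    bounds = np.array((0, *tra, n_times))
    return prefix[:, bounds[1:]] - prefix[:, bounds[:-1]]


def _act_from_segments(seg_sums: np.ndarray, tra: tuple[int, ...], n_times: int) -> np.ndarray:
    bounds = (0, *tra, n_times)
    lengths = np.diff(bounds)
    return np.repeat((seg_sums > 0).astype(np.int8), lengths, axis=1)


def evaluate_segmentation(
    M,
    tra,
    penalty_factor: float = DEFAULT_PENALTY_FACTOR,
    penalty_mode: str = "declared",
    penalty_genes: int | None = None,
) -> ActivityModel:
    """Best activity model for a fixed break set.

    Each gene independently takes the candidate vector maximizing its inner
    product with its intensity row.  In effective mode the model is
    canonicalized: its break set is reset to the transitions its activity
    actually realizes.
    """
    values, _, _ = _as_matrix(M)
    tra = validate_breaks(tra, values.shape[1])
    prefix = np.concatenate(
        [np.zeros((values.shape[0], 1)), np.cumsum(values, axis=1)], axis=1
    )
    seg = _segment_sums(prefix, tra)
    raw = float(np.maximum(seg, 0.0).sum())
    act = _act_from_segments(seg, tra, values.shape[1])
    n_genes = penalty_genes if penalty_genes is not None else values.shape[0]
    if penalty_mode == "declared":
        used = tra
    elif penalty_mode == "effective":
        used = derive_transitions(act)
        tra = used
    else:
        raise ValidationError(f"unknown penalty_mode {penalty_mode!r}")
    score = raw - _penalty(len(used), n_genes, values.shape[1], penalty_factor)
    return ActivityModel(
        act=act,
        tra=tra,
        raw_score=raw,
        penalty_factor=penalty_factor,
        penalty_mode=penalty_mode,
        score=score,
    )


def _model_from_kbest(kb: KBest, penalty_factor: float, penalty_mode: str) -> ActivityModel:
    return ActivityModel(
        act=kb.act,
        tra=kb.tra,
        raw_score=kb.raw_score,
        penalty_factor=penalty_factor,
        penalty_mode=penalty_mode,
        score=kb.score,
    )


def search_exhaustive(
    M,
    penalty_factor: float = DEFAULT_PENALTY_FACTOR,
    penalty_mode: str = "declared",
    max_breaks: int | None = None,
    early_stop: bool = True,
    reference_extra: int = 2,
    penalty_genes: int | None = None,
) -> SegmentationResult:
    """Brute-force search over break sets of increasing size k.

    For each k every break set of that size is scored (each gene taking its
    optimal period-constant vector) and the best kept; ties prefer the
    lexicographically smallest break set.  With ``early_stop`` the k-loop
    terminates as soon as score_k fails to improve on score_{k-1}; further
    break counts up to ``best_k + reference_extra`` are still tabulated in
    ``result.reference`` for score-vs-period reporting, but never change the
    returned optimum.  The overall best is the highest-scoring evaluated k
    (ties prefer the smallest k).
    """
    values, gene_ids, time_points = _as_matrix(M)
    n_genes_m, n_times = values.shape
    if n_genes_m == 0 or n_times == 0:
        raise ValidationError("empty intensity matrix")
    if max_breaks is None:
        max_breaks = n_times - 1
    if max_breaks > n_times - 1:
        raise ValidationError(f"max_breaks {max_breaks} > |T|-1 = {n_times - 1}")
    n_pen = penalty_genes if penalty_genes is not None else n_genes_m
    prefix = np.concatenate(
        [np.zeros((n_genes_m, 1)), np.cumsum(values, axis=1)], axis=1
    )

    def eval_k(k: int) -> KBest:
        best = None
        for tra in itertools.combinations(range(1, n_times), k):
            seg = _segment_sums(prefix, tra)
            raw = float(np.maximum(seg, 0.0).sum())
            if penalty_mode == "declared":
                act = None
                score = raw - _penalty(k, n_pen, n_times, penalty_factor)
            else:
                act = _act_from_segments(seg, tra, n_times)
                eff = derive_transitions(act)
                score = raw - _penalty(len(eff), n_pen, n_times, penalty_factor)
            if best is None or score > best[0]:
                best = (score, raw, tra, act, seg)
        score, raw, tra, act, seg = best
        if act is None:
            act = _act_from_segments(seg, tra, n_times)
        if penalty_mode == "effective":
            tra = derive_transitions(act)
        return KBest(k=k, tra=tuple(tra), act=act, raw_score=raw, score=score)

    per_k: list[KBest] = []
    stopped_early = False
    for k in range(0, max_breaks + 1):
        kb = eval_k(k)
        per_k.append(kb)
        if early_stop and k >= 1 and kb.score <= per_k[-2].score:
            stopped_early = True
            break

    best_kb = max(per_k, key=lambda kb: (kb.score, -kb.k))
    reference: list[KBest] = []
    if stopped_early:
        upto = min(max_breaks, best_kb.k + reference_extra)
        for k in range(per_k[-1].k + 1, upto + 1):
            reference.append(eval_k(k))

    return SegmentationResult(
        per_k=tuple(per_k),
        best=_model_from_kbest(best_kb, penalty_factor, penalty_mode),
        search_mode="brute",
        stopped_early=stopped_early,
        penalty_factor=penalty_factor,
        penalty_mode=penalty_mode,
        max_breaks=max_breaks,
        reference=tuple(reference),
        gene_ids=gene_ids,
        time_points=time_points,
        penalty_genes=penalty_genes,
    )


def search_dp(
    M,
    penalty_factor: float = DEFAULT_PENALTY_FACTOR,
    max_breaks: int | None = None,
    penalty_genes: int | None = None,
) -> SegmentationResult:
    """Exact segmentation by dynamic programming over segment gains.

    ``gain(a, b) = sum_genes max(0, sum of intensities over columns a..b)``
    is precomputed from per-gene prefix sums (the memoized gene-and-period
    sub-scores).  ``S(m, a)`` -- the best total gain covering columns
    ``a..|T|-1`` with m segments -- satisfies

        S(m, a) = max_e gain(a, e) + S(m-1, e+1),

    so ``score_k = S(k+1, 0) - penalty_factor * k * ln(|G|*|T|)``, matching
    :func:`search_exhaustive` in declared mode on every instance (the
    declared-k penalty is constant within each k).  Backtracking takes the
    smallest optimal segment end first, which recovers the lexicographically
    smallest optimal break set.  Penalty counting is declared-mode; at the
    optimum every break is realized by some gene, so the effective-mode
    optimum coincides.
    """
    values, gene_ids, time_points = _as_matrix(M)
    n_genes_m, n_times = values.shape
    if n_genes_m == 0 or n_times == 0:
        raise ValidationError("empty intensity matrix")
    if max_breaks is None:
        max_breaks = n_times - 1
    if max_breaks > n_times - 1:
        raise ValidationError(f"max_breaks {max_breaks} > |T|-1 = {n_times - 1}")
    n_pen = penalty_genes if penalty_genes is not None else n_genes_m

    prefix = np.concatenate(
        [np.zeros((n_genes_m, 1)), np.cumsum(values, axis=1)], axis=1
    )
    # gains[a, e] = sum_i max(0, sum over columns a..e), e >= a
    gains = np.zeros((n_times, n_times))
    for a in range(n_times):
        seg = prefix[:, a + 1 :] - prefix[:, a : a + 1]
        gains[a, a:] = np.maximum(seg, 0.0).sum(axis=0)

    max_segments = max_breaks + 1
    # S[m, a]: best gain covering columns a..n_times-1 with m segments
    S = np.full((max_segments + 1, n_times + 1), -np.inf)
    S[0, n_times] = 0.0
    for m in range(1, max_segments + 1):
        for a in range(n_times - m, -1, -1):
            # last feasible segment end leaves m-1 columns for m-1 segments
            e_hi = n_times - m  # inclusive
            cand = gains[a, a : e_hi + 1] + S[m - 1, a + 1 : e_hi + 2]
            S[m, a] = cand.max()

    def backtrack(m: int) -> tuple[int, ...]:
        breaks = []
        a = 0
        while m > 1:
            e_hi = n_times - m
            cand = gains[a, a : e_hi + 1] + S[m - 1, a + 1 : e_hi + 2]
            e = a + int(np.argmax(cand))  # first max -> smallest break
            breaks.append(e + 1)  # break index: boundary after 1-based point e+1
            a = e + 1
            m -= 1
        return tuple(breaks)

    per_k: list[KBest] = []
    for k in range(0, max_breaks + 1):
        tra = backtrack(k + 1)
        seg = _segment_sums(prefix, tra)
        raw = float(S[k + 1, 0])
        act = _act_from_segments(seg, tra, n_times)
        score = raw - _penalty(k, n_pen, n_times, penalty_factor)
        per_k.append(KBest(k=k, tra=tra, act=act, raw_score=raw, score=score))

    best_kb = max(per_k, key=lambda kb: (kb.score, -kb.k))
    return SegmentationResult(
        per_k=tuple(per_k),
        best=_model_from_kbest(best_kb, penalty_factor, "declared"),
        search_mode="dp",
        stopped_early=False,
        penalty_factor=penalty_factor,
        penalty_mode="declared",
        max_breaks=max_breaks,
        gene_ids=gene_ids,
        time_points=time_points,
        penalty_genes=penalty_genes,
    )
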