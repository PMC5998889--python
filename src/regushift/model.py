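"""Domain types for transition analysis of gene-regulation activity.

A time-course experiment is viewed as |G| genes observed at |T| ordered time
points.  A regulation-intensity matrix ``M`` (genes x time points) scores, per
regulated gene and time point, the signed evidence that the gene's expression
is controlled by its upstream regulators at that time (positive = controlled).
The dynamic model is a binary activity matrix ``Act`` together with a set of
breaks ``Tra`` that partitions the time axis into periods on which every row
of ``Act`` is constant.

Break convention: break indices are 1-based, a break at index ``j`` means one
period ends at the j-th time point and the next starts at the (j+1)-th.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "TimePoint",
    "Edge",
    "ExpressionProfile",
    "RegulatoryNetwork",
    "IntensityMatrix",
    "ActivityModel",
    "KBest",
    "SegmentationResult",
    "periods_from_breaks",
    "validate_breaks",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message carries row/column location."""


@dataclass(frozen=True)
class TimePoint:
    """One observation time: original label, numeric value, optional unit."""

    label: str
    value: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(f"time point {self.label!r} has non-finite value")


def _as_time_points(time_points: Sequence) -> tuple[TimePoint, ...]:
    out = []
    for tp in time_points:
        if isinstance(tp, TimePoint):
            out.append(tp)
        else:
            v = float(tp)
            out.append(TimePoint(label=str(tp), value=v))
    return tuple(out)


def _check_times_increasing(time_points: Sequence[TimePoint]) -> None:
    values = [tp.value for tp in time_points]
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValidationError(f"time points not increasing: {values}")


class ExpressionProfile:
    """Genes x time points expression table (``Exp`` over gene set G, times T).

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    time_points
        Strictly increasing time points (``TimePoint`` or numbers).
    values
        Real matrix of shape ``(len(gene_ids), len(time_points))``; all
        entries must be finite.
    """

    def __init__(self, gene_ids: Sequence[str], time_points: Sequence, values) -> None:
        self.gene_ids: tuple[str, ...] = tuple(str(g) for g in gene_ids)
        self.time_points: tuple[TimePoint, ...] = _as_time_points(time_points)
        self.values: np.ndarray = np.asarray(values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dup}")
        _check_times_increasing(self.time_points)
        expected = (len(self.gene_ids), len(self.time_points))
        if self.values.shape != expected:
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"|G|x|T| = {expected}"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.gene_ids[i]!r} "
                f"at time {self.time_points[j].label!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def __repr__(self) -> str:
        return f"ExpressionProfile(|G|={self.n_genes}, |T|={self.n_times})"


@dataclass(frozen=True)
class Edge:
    """Directed regulation: regulator -> target; sign +1, -1 or 0 (unknown)."""

    regulator: str
    target: str
    sign: int = 0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValidationError(f"edge sign must be -1, 0 or +1, got {self.sign}")


class RegulatoryNetwork:
    """Directed gene regulatory network defining each gene's parent set.

    Edge signs (activation/repression) are carried as metadata only; the
    scoring model never uses them.  Self-loops are allowed but a gene's own
    expression is never part of its parent design, so a gene whose only
    regulator is itself counts as unregulated.
    """

    def __init__(self, edges: Iterable[Edge]) -> None:
        edges = tuple(edges)
        seen: dict[tuple[str, str], Edge] = {}
        for e in edges:
            key = (e.regulator, e.target)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen[key] = e
        self.edges: tuple[Edge, ...] = edges

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in (e.regulator, e.target))

    def parents(self, gene: str, exclude_self: bool = True) -> tuple[str, ...]:
        """Regulators of ``gene`` in sorted order (self excluded by default)."""
        ps = {e.regulator for e in self.edges if e.target == gene}
        if exclude_self:
            ps.discard(gene)
        return tuple(sorted(ps))

    @property
    def regulated_genes(self) -> tuple[str, ...]:
        """Genes with at least one parent other than themselves, sorted."""
        return tuple(sorted(g for g in self.node_ids if self.parents(g)))

    @property
    def unregulated_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g in self.node_ids if not self.parents(g)))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:
        return f"RegulatoryNetwork({len(self.node_ids)} genes, {self.n_edges} edges)"


class IntensityMatrix:
    """Regulation-intensity matrix ``M`` (regulated genes x time points).

    ``M[i, j] > 0`` is evidence that gene i's regulation is active at time j.
    """

    def __init__(self, gene_ids: Sequence[str], time_points: Sequence, values) -> None:
        self.gene_ids: tuple[str, ...] = tuple(str(g) for g in gene_ids)
        self.time_points: tuple[TimePoint, ...] = _as_time_points(time_points)
        self.values: np.ndarray = np.asarray(values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in intensity matrix")
        _check_times_increasing(self.time_points)
        expected = (len(self.gene_ids), len(self.time_points))
        if self.values.shape != expected:
            raise ValidationError(
                f"intensity shape {self.values.shape} != {expected}"
            )
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite intensity for gene {self.gene_ids[i]!r} "
                f"at time {self.time_points[j].label!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def __repr__(self) -> str:
        return f"IntensityMatrix(|G|={self.n_genes}, |T|={self.n_times})"


def validate_breaks(tra: Iterable[int], n_times: int) -> tuple[int, ...]:
    """Normalize a break set to a sorted tuple and range-check it."""
    tra = tuple(sorted(int(j) for j in set(tra)))
    for j in tra:
        if not 1 <= j <= n_times - 1:
            raise ValidationError(
                f"break index {j} out of range 1..{n_times - 1}"
            )
    return tra

def periods_from_breaks(tra: Iterable[int], n_times: int) -> list[tuple[int, int]]:
    """Periods induced by a break set, as 0-based inclusive column ranges.

    ``tra = (2,)`` with 4 time points yields ``[(0, 1), (2, 3)]``: the first
    period ends at the 2nd time point, the second starts at the 3rd.
    """
    tra = validate_breaks(tra, n_times)
    bounds = (0, *tra, n_times)
    return [(a, b - 1) for a, b in zip(bounds, bounds[1:])]


@dataclass
class ActivityModel:
    """A scored dynamic model: activity matrix, breaks, raw and penalized score.

    ``penalty_mode`` controls which breaks the BIC-style term counts:
    ``"effective"`` counts the transitions actually realized by ``act``
    (the score-function definition, where Tra is derived from Act), while
    ``"declared"`` counts the supplied break set even if some break is unused
    (the search pseudocode, which charges the current k).
    """

    act: np.ndarray
    tra: tuple[int, ...]
    raw_score: float
    penalty_factor: float
    penalty_mode: str
    score: float

    def __post_init__(self) -> None:
        self.act = np.asarray(self.act)
        self.tra = tuple(int(j) for j in self.tra)
        if self.penalty_mode not in ("effective", "declared"):
            raise ValidationError(f"unknown penalty_mode {self.penalty_mode!r}")

    @property
    def n_genes(self) -> int:
        return self.act.shape[0]

    @property
    def n_times(self) -> int:
        return self.act.shape[1]

    @property
    def n_periods(self) -> int:
        return len(self.tra) + 1

    def validate(self) -> None:
        """Check structural invariants (rows period-constant, breaks in range)."""
        from .segmentation import derive_transitions  # cycle-free at call time

        validate_breaks(self.tra, self.n_times)
        eff = derive_transitions(self.act)
        if not set(eff) <= set(self.tra):
            raise ValidationError(
                f"activity changes at {set(eff) - set(self.tra)} outside tra"
            )
        if self.penalty_mode == "effective" and eff != self.tra:
            raise ValidationError("effective-mode model is not canonical")


@dataclass(frozen=True)
class KBest:
    """Best model found for a fixed break count k."""

    k: int
    tra: tuple[int, ...]
    act: np.ndarray
    raw_score: float
    score: float


@dataclass
class SegmentationResult:
    """Outcome of a segmentation search.

    ``per_k`` holds one entry per break count the search rule evaluated;
    ``reference`` holds further break counts computed only for reporting
    (score-vs-period tables customarily show a few rows past the optimum).
    """

    per_k: tuple[KBest, ...]
    best: ActivityModel
    search_mode: str
    stopped_early: bool
    penalty_factor: float
    penalty_mode: str
    max_breaks: int
    reference: tuple[KBest, ...] = ()
    gene_ids: tuple[str, ...] | None = None
    time_points: tuple[TimePoint, ...] | None = None
    penalty_genes: int | None = None

    @property
    def best_k(self) -> int:
        return len(self.best.tra)

    def __repr__(self) -> str:
        return (
            f"SegmentationResult(best_k={self.best_k}, score={self.best.score:.4f}, "
            f"mode={self.search_mode}, stopped_early={self.stopped_early})"
        )
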