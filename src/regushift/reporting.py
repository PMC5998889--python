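"""Human-readable summaries: score-vs-period tables, period activity calls.

A gene is called "controlled" in a period when the mean of its intensity over
the period's time points is strictly positive.  Because every period mean is
the period sum divided by a positive length, this call agrees with the
optimal activity matrix of the segmentation whenever no period sum is
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    IntensityMatrix,
    SegmentationResult,
    ValidationError,
    periods_from_breaks,
)

__all__ = ["PeriodReport", "classify_period_activity", "score_table", "breakpoint_table"]


@dataclass
class PeriodReport:
    """Per-period classification of every regulated gene."""

    gene_ids: tuple[str, ...]
    periods: list[dict]
    mean_intensity: np.ndarray  # genes x periods
    controlled: np.ndarray      # genes x periods, bool

    @property
    def per_gene(self) -> dict[str, list[str]]:
        return {
            g: ["controlled" if c else "not_controlled" for c in row]
            for g, row in zip(self.gene_ids, self.controlled)
        }

    def to_frame(self) -> pd.DataFrame:
        cols = [f"period_{p['index'] + 1}" for p in self.periods]
        return pd.DataFrame(
            np.where(self.controlled, "controlled", "not_controlled"),
            index=pd.Index(self.gene_ids, name="gene"),
            columns=cols,
        )


def classify_period_activity(M, tra) -> PeriodReport:
    """Classify each gene as controlled or not in each period of ``tra``.

    The call is ``mean intensity over the period > 0`` (an exact-zero mean is
    "not controlled", matching the segmentation tie rule).
    """
    if isinstance(M, IntensityMatrix):
        values, gene_ids, tps = M.values, M.gene_ids, M.time_points
    else:
        values = np.asarray(M, dtype=float)
        if values.ndim != 2:
            raise ValidationError("intensity matrix must be 2-D")
        gene_ids = tuple(f"g{i + 1}" for i in range(values.shape[0]))
        tps = None
    spans = periods_from_breaks(tra, values.shape[1])
    means = np.column_stack(
        [values[:, a : b + 1].mean(axis=1) for a, b in spans]
    )
    periods = []
    for idx, (a, b) in enumerate(spans):
        rec: dict = {"index": idx, "start_col": a, "end_col": b}
        if tps is not None:
            rec["start_time"] = tps[a].value
            rec["end_time"] = tps[b].value
        periods.append(rec)
    return PeriodReport(
        gene_ids=tuple(gene_ids),
        periods=periods,
        mean_intensity=means,
        controlled=means > 0,
    )


def score_table(result: SegmentationResult) -> pd.DataFrame:
    """Score-vs-period-count table, one row per evaluated break count.

    Period count is k + 1; the optimal row is flagged ``best`` and rows
    computed past an early stop purely for reporting are flagged
    ``reference``.
    """
    rows = []
    for kb in result.per_k:
        rows.append(
            {"n_periods": kb.k + 1, "k": kb.k, "score": kb.score,
             "raw_score": kb.raw_score,
             "best": kb.k == result.best_k and kb.score == result.best.score,
             "reference": False}
        )
    for kb in result.reference:
        rows.append(
            {"n_periods": kb.k + 1, "k": kb.k, "score": kb.score,
             "raw_score": kb.raw_score, "best": False, "reference": True}
        )
    return pd.DataFrame(rows)


def breakpoint_table(result: SegmentationResult) -> pd.DataFrame:
    """Breakpoints of the best model with their reported time labels.

    The reported label is the time of the last point of the earlier period;
    both flanking time values are included.
    """
    tps = result.time_points
    rows = []
    for j in result.best.tra:
        row: dict = {"index": j}
        if tps is not None:
            row["time_label"] = tps[j - 1].label
            row["end_of_period_time"] = tps[j - 1].value
            row["start_of_next_time"] = tps[j].value
        rows.append(row)
    return pd.DataFrame(rows)
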