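"""Readers and writers for expression tables, networks, intensities, results.

Tabular formats are plain TSV (CSV via ``dialect="csv"``): first row = time
labels (numeric, optional ``min``/``h`` style unit suffix), first column =
gene ids.  Networks are 2-3 column edge lists or SIF.  Results are JSON plus
flat TSV exports (see :mod:`regushift.reporting`).

Readers reject malformed input with located errors rather than coercing;
replicate expression columns that share a time label are averaged at load.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np

from .model import (
    Edge,
    ExpressionProfile,
    IntensityMatrix,
    ParseError,
    RegulatoryNetwork,
    SegmentationResult,
    TimePoint,
    ValidationError,
    periods_from_breaks,
)

__all__ = [
    "parse_time_label",
    "read_expression",
    "read_network",
    "read_intensity",
    "write_intensity",
    "write_result",
    "read_result",
]

logger = logging.getLogger(__name__)

_TIME_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*"
    r"(min|mins|minutes?|h|hr|hrs|hours?|s|sec|d|days?)?\s*$"
)

_UNIT_CANON = {
    "min": "min", "mins": "min", "minute": "min", "minutes": "min",
    "h": "h", "hr": "h", "hrs": "h", "hour": "h", "hours": "h",
    "s": "s", "sec": "s",
    "d": "d", "day": "d", "days": "d",
}


def parse_time_label(label: str) -> tuple[float, str]:
    """Parse ``"780"``, ``"780min"`` or ``"2 h"`` into (value, canonical unit)."""
    m = _TIME_RE.match(label)
    if m is None:
        raise ParseError(f"cannot parse time label {label!r}")
    value = float(m.group(1))
    unit = _UNIT_CANON.get((m.group(2) or "").lower(), "")
    return value, unit


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_table(path, sep: str) -> tuple[list[str], list[str], np.ndarray]:
    """Read a gene x time table: (time labels, gene ids, float values)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: file is empty")
    header = lines[0].split(sep)
    time_labels = [c.strip() for c in header[1:]]
    if not time_labels:
        raise ParseError(f"{path}: header has no time columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != len(time_labels) + 1:
            raise ParseError(
                f"{path}: line {r} has {len(cells)} fields, "
                f"expected {len(time_labels) + 1}"
            )
        gene_ids.append(cells[0].strip())
        row = []
        for c, cell in enumerate(cells[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at line {r}, column {c}"
                ) from None
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}: non-finite value {cell!r} at line {r}, column {c}"
                )
            row.append(v)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return time_labels, gene_ids, np.array(rows, dtype=float)


def read_expression(path, dialect: str = "tsv") -> ExpressionProfile:
    """Load an expression profile; replicate columns (equal time) are averaged.

    Time labels must be nondecreasing; repeated labels are treated as
    replicate measurements and averaged (arithmetic mean, order-independent)
    into a single column.
    """
    sep = _sep(dialect)
    time_labels, gene_ids, values = _read_table(path, sep)
    parsed = [parse_time_label(lab) for lab in time_labels]
    units = {u for _, u in parsed if u}
    if len(units) > 1:
        raise ParseError(f"{path}: mixed time units {sorted(units)}")
    unit = units.pop() if units else ""
    tvals = [v for v, _ in parsed]
    if any(b < a for a, b in zip(tvals, tvals[1:])):
        raise ValidationError(f"{path}: time points not increasing: {tvals}")
    # group replicate columns by time value
    uniq: list[float] = []
    groups: dict[float, list[int]] = {}
    for j, v in enumerate(tvals):
        if v not in groups:
            uniq.append(v)
            groups[v] = []
        groups[v].append(j)
    averaged = np.column_stack([values[:, groups[v]].mean(axis=1) for v in uniq])
    n_rep = sum(len(g) > 1 for g in groups.values())
    if n_rep:
        logger.info("%s: averaged replicate columns at %d time value(s)", path, n_rep)
    tps = [TimePoint(label=f"{v:g}" + (unit and f" {unit}"), value=v, unit=unit)
           for v in uniq]
    return ExpressionProfile(gene_ids, tps, averaged)


_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "activation": 1, "activates": 1, "up": 1,
    "-": -1, "-1": -1, "repression": -1, "represses": -1, "inhibits": -1, "down": -1,
    "": 0, "?": 0, "unknown": 0, "0": 0,
}


def read_network(path, format: str = "tsv_edges") -> RegulatoryNetwork:
    """Load a directed regulatory network from an edge list or SIF file.

    ``tsv_edges``: whitespace/tab separated ``regulator target [sign]`` lines;
    ``sif``: ``source relation target [target...]`` lines (relation mapped to
    sign ``unknown``).  Duplicate (regulator, target) pairs collapse to one
    edge; self-loops are kept but logged as warnings.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty network file")
    edges: dict[tuple[str, str], Edge] = {}

    def add(reg: str, tgt: str, sign: int, lineno: int) -> None:
        key = (reg, tgt)
        prev = edges.get(key)
        if prev is not None:
            if prev.sign != sign and 0 not in (prev.sign, sign):
                raise ValidationError(
                    f"{path}: line {lineno}: conflicting signs for edge {key}"
                )
            if prev.sign == 0 and sign != 0:
                edges[key] = Edge(reg, tgt, sign)
            return
        if reg == tgt:
            logger.warning("%s: line %d: self-loop on %r", path, lineno, reg)
        edges[key] = Edge(reg, tgt, sign)

    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if format == "tsv_edges":
            if len(fields) < 2 or len(fields) > 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2-3 fields, got {len(fields)}"
                )
            sign_tok = fields[2].lower() if len(fields) == 3 else ""
            if sign_tok not in _SIGN_TOKENS:
                raise ParseError(
                    f"{path}: line {lineno}: unknown sign token {fields[2]!r}"
                )
            add(fields[0], fields[1], _SIGN_TOKENS[sign_tok], lineno)
        elif format == "sif":
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: SIF needs 'source relation target'"
                )
            for tgt in fields[2:]:
                add(fields[0], tgt, 0, lineno)
        else:
            raise ValueError(f"unknown network format {format!r}")
    return RegulatoryNetwork(edges.values())


def read_intensity(path, dialect: str = "tsv") -> IntensityMatrix:
    """Load an intensity matrix M (rows = regulated genes, columns = times)."""
    sep = _sep(dialect)
    time_labels, gene_ids, values = _read_table(path, sep)
    tps = []
    for lab in time_labels:
        v, u = parse_time_label(lab)
        tps.append(TimePoint(label=lab, value=v, unit=u))
    return IntensityMatrix(gene_ids, tps, values)


def write_intensity(M: IntensityMatrix, path, dialect: str = "tsv") -> None:
    """Write M as TSV with full-precision (round-trippable) floats."""
    sep = _sep(dialect)
    with open(path, "w") as fh:
        fh.write("gene" + sep + sep.join(tp.label for tp in M.time_points) + "\n")
        for gid, row in zip(M.gene_ids, M.values):
            fh.write(gid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def _break_records(result: SegmentationResult) -> list[dict]:
    """Breakpoint records: reported label = time of the last point of the
    earlier period; the index and both flanking time values are included."""
    tps = result.time_points
    recs = []
    for j in result.best.tra:
        rec: dict = {"index": j}
        if tps is not None:
            rec["time_label"] = tps[j - 1].label
            rec["end_of_period_time"] = tps[j - 1].value
            rec["start_of_next_time"] = tps[j].value
        recs.append(rec)
    return recs


def write_result(result: SegmentationResult, path, seed: int | None = None) -> None:
    """Serialize a segmentation result to JSON with a stable key order.

    Keys: ``breaks``, ``periods``, ``activity``, ``score_table``,
    ``settings``.  Scores survive a JSON round trip at full double precision.
    """
    n_times = result.best.n_times
    tps = result.time_points
    gene_ids = result.gene_ids or tuple(
        f"g{i + 1}" for i in range(result.best.n_genes)
    )
    period_cols = periods_from_breaks(result.best.tra, n_times)
    periods = []
    for idx, (a, b) in enumerate(period_cols):
        rec: dict = {"index": idx, "start_col": a, "end_col": b}
        if tps is not None:
            rec["start_time"] = tps[a].value
            rec["end_time"] = tps[b].value
        periods.append(rec)
    activity = {
        gid: [int(result.best.act[i, a]) for a, _ in period_cols]
        for i, gid in enumerate(gene_ids)
    }
    score_table = [
        {"k": kb.k, "n_periods": kb.k + 1, "score": kb.score,
         "raw_score": kb.raw_score, "breaks": list(kb.tra),
         "best": kb.k == result.best_k and kb.score == result.best.score,
         "reference": False}
        for kb in result.per_k
    ] + [
        {"k": kb.k, "n_periods": kb.k + 1, "score": kb.score,
         "raw_score": kb.raw_score, "breaks": list(kb.tra),
         "best": False, "reference": True}
        for kb in result.reference
    ]
    payload = {
        "breaks": _break_records(result),
        "periods": periods,
        "activity": activity,
        "score_table": score_table,
        "score": result.best.score,
        "raw_score": result.best.raw_score,
        "settings": {
            "penalty_factor": result.penalty_factor,
            "penalty_mode": result.penalty_mode,
            "penalty_genes": result.penalty_genes,
            "search_mode": result.search_mode,
            "max_breaks": result.max_breaks,
            "stopped_early": result.stopped_early,
            "seed": seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_result(path) -> dict:
    """Load a result JSON written by :func:`write_result`."""
    with open(path) as fh:
        return json.load(fh)
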