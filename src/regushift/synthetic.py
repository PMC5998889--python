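"""Synthetic inputs with planted period structure.

Generators for (a) intensity matrices whose rows switch between an "active"
and an "inactive" mean at planted breaks, (b) random acyclic regulatory
networks, and (c) expression profiles in which each regulated gene tracks a
linear combination of its parents during its active periods and an
independent signal otherwise.  Every generator is driven by a single integer
seed and is reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import (
    ExpressionProfile,
    IntensityMatrix,
    RegulatoryNetwork,
    Edge,
    ValidationError,
    periods_from_breaks,
    validate_breaks,
)

__all__ = [
    "PlantedTruth",
    "planted_truth",
    "generate_intensity",
    "generate_network",
    "generate_expression",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted instance.

    tra_true
        Planted break set (1-based, sorted).
    activity_plan
        Binary genes x periods matrix: 1 = regulation active in that period.
    mu_act, mu_inact
        Mean intensity when active (> 0) / inactive (< 0).
    sigma
        Intensity noise standard deviation (> 0).
    seed
        Integer driving all random draws.
    """

    tra_true: tuple[int, ...]
    activity_plan: np.ndarray
    mu_act: float = 1.0
    mu_inact: float = -1.0
    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tra_true", tuple(int(j) for j in self.tra_true))
        plan = np.asarray(self.activity_plan, dtype=np.int8)
        object.__setattr__(self, "activity_plan", plan)
        if not (self.mu_act > 0 > self.mu_inact):
            raise ValidationError("require mu_act > 0 > mu_inact")
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        if plan.ndim != 2 or not np.isin(plan, (0, 1)).all():
            raise ValidationError("activity_plan must be a binary 2-D matrix")
        if plan.shape[1] != len(self.tra_true) + 1:
            raise ValidationError(
                f"activity_plan has {plan.shape[1]} period columns, "
                f"expected {len(self.tra_true) + 1}"
            )

    @property
    def n_genes(self) -> int:
        return self.activity_plan.shape[0]

    @property
    def n_periods(self) -> int:
        return self.activity_plan.shape[1]


def planted_truth(
    n_genes: int,
    n_times: int,
    n_breaks: int,
    mu_act: float = 1.0,
    mu_inact: float = -1.0,
    sigma: float = 0.3,
    seed: int = 0,
    placement: str = "spread",
) -> PlantedTruth:
    """Draw a random break set and activity plan.

    ``placement="spread"`` (default) places breaks evenly along the time
    axis with +-1 jitter, so every planted period contains enough points to
    be resolvable against the model-complexity penalty — a break flanked by
    a one-point period carries almost no score support and is unidentifiable
    by design, not by noise.  ``placement="uniform"`` samples break indices
    uniformly without replacement instead.

    The activity plan is adjusted so every planted break flips at least one
    gene's activity; a break no gene flips would be unidentifiable by
    construction.
    """
    if n_breaks > n_times - 1:
        raise ValidationError(f"cannot place {n_breaks} breaks in {n_times} points")
    rng = np.random.default_rng(seed)
    if placement == "uniform":
        tra = tuple(
            sorted(rng.choice(np.arange(1, n_times), size=n_breaks, replace=False))
        )
    elif placement == "spread":
        base = [round((i + 1) * n_times / (n_breaks + 1)) for i in range(n_breaks)]
        jitter = rng.integers(-1, 2, size=n_breaks)
        pos = [int(np.clip(b + j, 1, n_times - 1)) for b, j in zip(base, jitter)]
        if len(set(pos)) < n_breaks:  # jitter collided; keep the even grid
            pos = [int(np.clip(b, 1, n_times - 1)) for b in base]
        tra = tuple(sorted(pos))
    else:
        raise ValidationError(f"unknown placement {placement!r}")
    plan = rng.integers(0, 2, size=(n_genes, n_breaks + 1)).astype(np.int8)
    # left-to-right fix-up: flipping column b+1 of one gene can only affect
    # the boundary being fixed and the one after it, which is checked next
    for b in range(n_breaks):
        if (plan[:, b] == plan[:, b + 1]).all():
            g = b % n_genes
            plan[g, b + 1] = 1 - plan[g, b]
    return PlantedTruth(
        tra_true=tra, activity_plan=plan,
        mu_act=mu_act, mu_inact=mu_inact, sigma=sigma, seed=seed,
    )


def generate_intensity(
    n_genes: int, n_times: int, truth: PlantedTruth
) -> tuple[IntensityMatrix, PlantedTruth]:
    """Gaussian intensity matrix around the planted activity plan.

    ``M[g, j] ~ Normal(mu_act, sigma)`` where the plan marks gene g active in
    the period containing j, else ``Normal(mu_inact, sigma)``.
    """
    if truth.n_genes != n_genes:
        raise ValidationError(
            f"plan has {truth.n_genes} genes, requested {n_genes}"
        )
    validate_breaks(truth.tra_true, n_times)
    rng = np.random.default_rng(truth.seed)
    periods = periods_from_breaks(truth.tra_true, n_times)
    lengths = [b - a + 1 for a, b in periods]
    mu = np.where(
        np.repeat(truth.activity_plan, lengths, axis=1) == 1,
        truth.mu_act, truth.mu_inact,
    )
    values = rng.normal(mu, truth.sigma)
    gene_ids = [f"g{i + 1:02d}" for i in range(n_genes)]
    M = IntensityMatrix(gene_ids, np.arange(n_times, dtype=float), values)
    return M, truth


def generate_network(n_genes: int, n_edges: int, seed: int = 0) -> RegulatoryNetwork:
    """Random acyclic network: n_edges distinct edges respecting a random
    topological order (so at most n_genes * (n_genes - 1) / 2 edges)."""
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges or n_edges < 0 or n_genes < 1:
        raise ValidationError(
            f"cannot place {n_edges} acyclic edges among {n_genes} genes "
            f"(max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    pairs = [(order[i], order[j]) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    gene_ids = [f"g{i + 1:02d}" for i in range(n_genes)]
    edges = [Edge(gene_ids[pairs[c][0]], gene_ids[pairs[c][1]]) for c in sorted(chosen)]
    return RegulatoryNetwork(edges)


def _signal(kind: str, n_times: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_times, dtype=float)
    if kind == "ramp":
        slope = rng.choice((-1.0, 1.0)) * rng.uniform(0.5, 1.5)
        return rng.normal(0.0, 1.0) + slope * (2.0 * scale / max(n_times - 1, 1)) * t
    if kind == "sine":
        # >= ~1.5 cycles over the course, so independently drawn signals
        # decorrelate within a period instead of looking collinear
        freq = rng.uniform(1.5, 4.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return scale * np.sin(2.0 * np.pi * freq * t / n_times + phase)
    if kind == "randomwalk":
        return np.cumsum(rng.normal(0.0, scale / np.sqrt(n_times), size=n_times))
    raise ValidationError(f"unknown parent_signal {kind!r}")


def generate_expression(
    network: RegulatoryNetwork,
    truth: PlantedTruth,
    n_times: int,
    parent_signal: str = "sine",
    sigma_expr: float | None = None,
    signal_scale: float = 3.0,
) -> tuple[ExpressionProfile, PlantedTruth]:
    """Expression profile in which regulation is active only in planted periods.

    Root (unregulated) genes follow an independent ``parent_signal`` draw.
    Each regulated gene equals the mean of its parents plus
    ``Normal(0, sigma_expr)`` noise within its active periods, and an
    independent signal draw plus noise within inactive periods.  Plan rows
    correspond to the network's regulated genes in sorted order.  The network
    must be acyclic (ignoring self-loops).

    ``sigma_expr`` defaults to ``truth.sigma``; ``signal_scale`` sets the
    amplitude of the driving signals, and its default 10:1 ratio to the
    default noise emulates a strongly regulated pathway.
    """
    regulated = network.regulated_genes
    if truth.n_genes != len(regulated):
        raise ValidationError(
            f"plan has {truth.n_genes} rows but network has "
            f"{len(regulated)} regulated genes"
        )
    validate_breaks(truth.tra_true, n_times)
    sigma_expr = truth.sigma if sigma_expr is None else sigma_expr
    dg = nx.DiGraph(
        (e.regulator, e.target) for e in network.edges if e.regulator != e.target
    )
    dg.add_nodes_from(network.node_ids)
    try:
        topo = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(dg)]
        raise ValidationError(f"network contains a cycle: {cycle}") from None

    rng = np.random.default_rng(truth.seed)
    periods = periods_from_breaks(truth.tra_true, n_times)
    plan_row = {g: truth.activity_plan[i] for i, g in enumerate(regulated)}
    values: dict[str, np.ndarray] = {}
    for g in sorted(network.node_ids):  # fixed draw order for reproducibility
        values[g] = _signal(parent_signal, n_times, signal_scale, rng)
        if g in plan_row:
            values[g] = values[g] + rng.normal(0.0, sigma_expr, size=n_times)
    # overwrite regulated genes in topological order so parents are final
    for g in topo:
        if g not in plan_row:
            continue
        parents = network.parents(g)
        combo = np.mean([values[p] for p in parents], axis=0)
        out = values[g].copy()  # inactive periods keep the independent draw
        for bit, (a, b) in zip(plan_row[g], periods):
            if bit:
                out[a : b + 1] = combo[a : b + 1] + rng.normal(
                    0.0, sigma_expr, size=b - a + 1
                )
        values[g] = out

    gene_ids = sorted(network.node_ids)
    profile = ExpressionProfile(
        gene_ids,
        np.arange(n_times, dtype=float),
        np.vstack([values[g] for g in gene_ids]),
    )
    return profile, truth
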