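"""Influential weights from total-influence matrices (DANP).

A factor's influential weight is the stationary distribution of the
row-normalised total-influence matrix: row-normalise T to T^alpha, transpose
it to the column-stochastic W^alpha, and raise to the limiting power.  The
limit's common column is the weight vector — equivalently the left
eigenvector pi with pi T^alpha = pi, sum(pi) = 1.  In the hierarchical mode
this is done once at the dimension level and once inside each dimension;
global criterion weights are the product of the criterion's local weight and
its dimension's weight.  The classic mode runs one full criterion-level
matrix instead and derives dimension weights afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dematel import (
    ConsistencyResult,
    InfluenceNetwork,
    TotalInfluenceResult,
    analyze_block,
    average_panel,
    build_inrm,
    consistency_index,
)
from .model import (
    DIMENSION_BLOCK,
    DecisionHierarchy,
    ExpertPanel,
    validate_hierarchy,
    validate_panel,
)


@dataclass(frozen=True)
class ConvergenceSettings:
    """Stopping rule for the limiting-power iteration."""

    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class Convergence:
    iterations: int
    residual: float


@dataclass(frozen=True)
class WeightSet:
    """Local and global weights of a hierarchical run.

    ``local_dimension_weights`` and each entry of ``local_criterion_weights``
    sum to one; ``global_criterion_weights`` (local criterion weight times
    its dimension's weight) therefore sum to one as well.
    """

    local_dimension_weights: dict[str, float]
    local_criterion_weights: dict[str, dict[str, float]]
    global_criterion_weights: dict[str, float]
    convergence: dict[str, Convergence] = field(default_factory=dict)


class ConsistencyWarning(UserWarning):
    """Raised as a warning when a panel's consensus index exceeds threshold."""


@dataclass(frozen=True)
class BlockAnalysis:
    """Everything computed for one block of the pipeline."""

    influence: TotalInfluenceResult
    network: InfluenceNetwork
    local_weights: dict[str, float]
    consistency: ConsistencyResult | None
    convergence: Convergence


@dataclass(frozen=True)
class HierarchicalRun:
    weights: WeightSet
    blocks: dict[str, BlockAnalysis]


def local_weights(
    result: TotalInfluenceResult,
    settings: ConvergenceSettings = ConvergenceSettings(),
) -> tuple[np.ndarray, Convergence]:
    """Stationary weights of one block's total-influence matrix.

    Power-iterates pi <- pi T^alpha from the uniform vector until successive
    iterates differ by less than ``settings.tolerance`` in max-abs norm, then
    cross-checks against a direct linear solve of the stationary equations.
    """
    T = result.T
    o = result.o
    if np.any(o <= 0):
        bad = [result.labels[i] for i in np.flatnonzero(o <= 0)]
        raise ValueError(f"factor exerts no influence; weights undefined: {', '.join(bad)}")
    P = T / o[:, None]  # row-stochastic T^alpha
    n = P.shape[0]
    pi = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, settings.max_iterations + 1):
        nxt = pi @ P
        nxt /= nxt.sum()
        residual = float(np.max(np.abs(nxt - pi)))
        pi = nxt
        if residual < settings.tolerance:
            break
    else:
        raise ValueError(
            f"weights did not converge within {settings.max_iterations} iterations "
            f"(residual {residual:.3e})"
        )
    direct = _stationary_solve(P)
    if np.max(np.abs(direct - pi)) > 1e-8:
        raise ValueError("power iteration and linear solve disagree on the stationary weights")
    return pi, Convergence(iterations=it, residual=residual)


def _stationary_solve(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by linear solve."""
    n = P.shape[0]
    M = np.vstack([P.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, b, rcond=None)
    return pi


def compose_global_weights(
    dim_weights: dict[str, float],
    crit_weights_per_dimension: dict[str, dict[str, float]],
    h: DecisionHierarchy,
    convergence: dict[str, Convergence] | None = None,
) -> WeightSet:
    """Multiply local criterion weights by their dimension's weight."""
    missing = [d for d in h.dimension_ids if d not in dim_weights]
    if missing:
        raise ValueError(f"missing dimension weights for: {', '.join(missing)}")
    missing = [d for d in h.dimension_ids if d not in crit_weights_per_dimension]
    if missing:
        raise ValueError(f"missing criterion-weight blocks for dimensions: {', '.join(missing)}")
    global_w: dict[str, float] = {}
    for d in h.dimension_ids:
        block = crit_weights_per_dimension[d]
        for c in h.criteria_of(d):
            if c not in block:
                raise ValueError(f"missing local weight for criterion {c!r} in dimension {d!r}")
            global_w[c] = dim_weights[d] * block[c]
    return WeightSet(
        local_dimension_weights=dict(dim_weights),
        local_criterion_weights={d: dict(v) for d, v in crit_weights_per_dimension.items()},
        global_criterion_weights=global_w,
        convergence=dict(convergence or {}),
    )


def _analyze_panel_block(
    panel: ExpertPanel,
    labels: tuple[str, ...],
    settings: ConvergenceSettings,
    consistency_threshold: float,
    consistency_policy: str,
) -> BlockAnalysis:
    cons: ConsistencyResult | None = None
    if panel.H >= 2:
        cons = consistency_index(panel, threshold=consistency_threshold)
        if not cons.passed:
            msg = (
                f"block {panel.block!r}: consistency {cons.value:.3f}% exceeds "
                f"threshold {cons.threshold:.3f}%"
            )
            if consistency_policy == "abort":
                raise ValueError(msg)
            warnings.warn(msg, ConsistencyWarning, stacklevel=3)
    A = average_panel(panel, labels)
    influence = analyze_block(A)
    w, conv = local_weights(influence, settings)
    return BlockAnalysis(
        influence=influence,
        network=build_inrm(influence),
        local_weights=dict(zip(labels, map(float, w))),
        consistency=cons,
        convergence=conv,
    )


def run_hierarchical(
    panels: dict[str, ExpertPanel],
    h: DecisionHierarchy,
    settings: ConvergenceSettings = ConvergenceSettings(),
    consistency_threshold: float = 5.0,
    consistency_policy: str = "warn",
) -> HierarchicalRun:
    """Full hierarchical pipeline over one dimension block plus one block per dimension.

    Each block runs averaging, consensus check, normalisation, total
    influence, indices, INRM and local weights; the local vectors are then
    composed into global criterion weights.
    """
    if consistency_policy not in ("warn", "abort"):
        raise ValueError("consistency_policy must be 'warn' or 'abort'")
    hv = validate_hierarchy(h)
    if hv:
        raise ValueError("invalid hierarchy: " + "; ".join(map(str, hv)))
    required = h.blocks
    missing = [b for b in required if b not in panels]
    if missing:
        raise ValueError(f"missing panels for blocks: {', '.join(missing)}")
    for b in required:
        pv = validate_panel(panels[b], h)
        if pv:
            raise ValueError(f"invalid panel for block {b!r}: " + "; ".join(map(str, pv)))

    blocks: dict[str, BlockAnalysis] = {}
    for b in required:
        blocks[b] = _analyze_panel_block(
            panels[b], tuple(h.block_labels(b)), settings,
            consistency_threshold, consistency_policy,
        )
    dim_w = blocks[DIMENSION_BLOCK].local_weights
    crit_w = {d: blocks[d].local_weights for d in h.dimension_ids}
    conv = {b: blocks[b].convergence for b in required}
    ws = compose_global_weights(dim_w, crit_w, h, conv)
    return HierarchicalRun(weights=ws, blocks=blocks)


def run_classic(
    full_panel: ExpertPanel,
    h: DecisionHierarchy,
    settings: ConvergenceSettings = ConvergenceSettings(),
) -> WeightSet:
    """Single full-matrix pipeline: global weights first, locals derived.

    The panel covers all criteria at once.  Dimension weights are the
    within-dimension sums of the global weights; local criterion weights are
    the globals renormalised within each dimension.
    """
    crit_ids = h.criterion_ids
    n = len(crit_ids)
    if full_panel.n != n:
        raise ValueError(
            f"classic mode needs a {n}x{n} panel over all criteria, got order {full_panel.n}"
        )
    A = average_panel(full_panel, tuple(crit_ids))
    influence = analyze_block(A)
    w, conv = local_weights(influence, settings)
    global_w = dict(zip(crit_ids, map(float, w)))
    dim_w: dict[str, float] = {}
    local_w: dict[str, dict[str, float]] = {}
    for d in h.dimension_ids:
        crits = h.criteria_of(d)
        s = sum(global_w[c] for c in crits)
        dim_w[d] = s
        local_w[d] = {c: global_w[c] / s for c in crits}
    return WeightSet(
        local_dimension_weights=dim_w,
        local_criterion_weights=local_w,
        global_criterion_weights=global_w,
        convergence={"full": conv},
    )


def questionnaire_item_count(h: DecisionHierarchy, mode: str) -> int:
    """Pairwise-comparison item count of the influence questionnaire.

    Classic mode compares every ordered pair of criteria: n(n-1).  The
    hierarchical design compares dimensions among themselves and criteria
    only within their dimension: D(D-1) + sum_d n_d(n_d - 1).
    """
    if mode == "classic":
        n = len(h.criteria)
        return n * (n - 1)
    if mode == "hierarchical":
        D = len(h.dimensions)
        return D * (D - 1) + sum(
            len(h.criteria_of(d)) * (len(h.criteria_of(d)) - 1) for d in h.dimension_ids
        )
    raise ValueError("mode must be 'classic' or 'hierarchical'")
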