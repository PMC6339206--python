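"""DEMATEL: from averaged pairwise influence judgments to total influence.

The chain is: average the expert matrices, check panel consensus, normalise
the average matrix so its Neumann series converges, sum the series in closed
form T = N(I-N)^{-1}, and summarise each factor by the influence it exerts
(row sum o) and receives (column sum r).  Prominence o+r measures how
engaged a factor is in the system; relation o-r separates net causes
(positive) from net receivers (negative).  The influential network relation
map (INRM) plots factors at (o+r, o-r) with arrows pointing from the
stronger to the weaker direction of each mutual influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DirectInfluenceMatrix, ExpertPanel

#: |o - r| below this is reported as neither cause nor receiver.
NEUTRAL_EPS = 1e-12


@dataclass(frozen=True)
class TotalInfluenceResult:
    """Total influence matrix of one block with its row/column summaries."""

    block: str
    labels: tuple[str, ...]
    u: float                # normalization factor of the direct matrix
    N: np.ndarray           # normalized direct influence, u * A
    T: np.ndarray           # total (direct + indirect) influence
    o: np.ndarray           # row sums: influence exerted
    r: np.ndarray           # column sums: influence received
    prominence: np.ndarray  # o + r
    relation: np.ndarray    # o - r


@dataclass(frozen=True)
class InrmNode:
    factor: str
    x: float      # prominence o + r
    y: float      # relation o - r
    role: str     # "cause" | "receiver" | "neutral"


@dataclass(frozen=True)
class InrmEdge:
    source: str
    target: str
    forward: float   # t(source -> target)
    backward: float  # t(target -> source)
    bidirectional: bool = False


@dataclass(frozen=True)
class InfluenceNetwork:
    level: str
    nodes: tuple[InrmNode, ...]
    edges: tuple[InrmEdge, ...]


@dataclass(frozen=True)
class ConsistencyResult:
    """Panel-consensus index in percent, with its threshold verdict."""

    value: float
    threshold: float
    passed: bool


def average_panel(p: ExpertPanel, labels: tuple[str, ...] | None = None) -> DirectInfluenceMatrix:
    """Elementwise mean of the H expert matrices."""
    if p.H == 0:
        raise ValueError("no expert matrices")
    A = np.mean(np.stack(p.matrices), axis=0)
    return DirectInfluenceMatrix(p.block, A, labels or tuple(str(i) for i in range(p.n)))


def consistency_index(p: ExpertPanel, threshold: float = 5.0) -> ConsistencyResult:
    """Average relative shift of the panel mean when the last expert joins.

    Compares the mean over all H experts with the mean over the first H-1
    (input order), entrywise, relative to the full mean; entries whose full
    mean is zero contribute nothing, but the denominator stays n(n-1).
    Returned in percent; small values mean the panel has converged on a
    consensus (conventional threshold 5%).
    """
    if p.H < 2:
        raise ValueError("consistency needs >= 2 experts")
    n = p.n
    stack = np.stack(p.matrices)
    a_full = stack.mean(axis=0)
    a_prev = stack[:-1].mean(axis=0)
    off = ~np.eye(n, dtype=bool)
    num = np.abs(a_full - a_prev)
    rel = np.zeros_like(a_full)
    nz = off & (a_full != 0)
    rel[nz] = num[nz] / a_full[nz]
    value = rel[off].sum() / (n * (n - 1)) * 100.0
    return ConsistencyResult(value=float(value), threshold=threshold, passed=bool(value < threshold))


def normalize_direct_matrix(A: DirectInfluenceMatrix) -> tuple[float, np.ndarray]:
    """Scale A by u = min(1/max row sum, 1/max column sum).

    Every row and column sum of the result is <= 1, which bounds the spectral
    radius and makes the total-influence series summable.
    """
    vals = A.values
    if not np.any(vals):
        raise ValueError("degenerate matrix: no influence recorded")
    u = min(1.0 / vals.sum(axis=1).max(), 1.0 / vals.sum(axis=0).max())
    return float(u), u * vals


def total_influence(N: np.ndarray) -> np.ndarray:
    """Closed form of the influence series N + N^2 + ... = N(I-N)^{-1}.

    Computed by a linear solve against (I - N) rather than explicit
    inversion.  Requires spectral radius of N strictly below 1.
    """
    N = np.asarray(N, dtype=float)
    n = N.shape[0]
    rho = max(abs(np.linalg.eigvals(N))) if n else 0.0
    if rho >= 1.0 - 1e-12:
        raise ValueError("non-convergent influence series (spectral radius >= 1)")
    # T(I-N) = N  =>  (I-N)' T' = N'
    T = np.linalg.solve((np.eye(n) - N).T, N.T).T
    return T


def influence_indices(T: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row sums o, column sums r, prominence o+r, relation o-r."""
    T = np.asarray(T, dtype=float)
    o = T.sum(axis=1)
    r = T.sum(axis=0)
    return o, r, o + r, o - r


def analyze_block(A: DirectInfluenceMatrix) -> TotalInfluenceResult:
    """Run normalisation, total influence and indices on one averaged block."""
    u, N = normalize_direct_matrix(A)
    T = total_influence(N)
    o, r, prom, rel = influence_indices(T)
    return TotalInfluenceResult(
        block=A.block, labels=tuple(A.labels), u=u, N=N, T=T,
        o=o, r=r, prominence=prom, relation=rel,
    )


def _role(rel: float) -> str:
    if abs(rel) < NEUTRAL_EPS:
        return "neutral"
    return "cause" if rel > 0 else "receiver"


def build_inrm(result: TotalInfluenceResult) -> InfluenceNetwork:
    """Nodes at (o+r, o-r); one arrow per pair from the stronger direction.

    When t_ij exceeds t_ji the single edge runs i -> j; exact ties yield a
    bidirectional edge (both directions recorded on one edge object).
    """
    labels = result.labels
    nodes = tuple(
        InrmNode(factor=labels[i], x=float(result.prominence[i]),
                 y=float(result.relation[i]), role=_role(result.relation[i]))
        for i in range(len(labels))
    )
    edges: list[InrmEdge] = []
    T = result.T
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            tij, tji = float(T[i, j]), float(T[j, i])
            if tij > tji:
                edges.append(InrmEdge(labels[i], labels[j], tij, tji))
            elif tji > tij:
                edges.append(InrmEdge(labels[j], labels[i], tji, tij))
            else:
                edges.append(InrmEdge(labels[i], labels[j], tij, tji, bidirectional=True))
    return InfluenceNetwork(level=result.block, nodes=nodes, edges=tuple(edges))
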