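"""Domain types for a hierarchical multi-criteria decision model.

A decision problem is organised as a two-level hierarchy: a small set of
*dimensions*, each owning two or more *criteria*.  Expert panels judge the
pairwise direct influence between factors on a bounded integer scale
(default 0-4, "no influence" to "very high influence"), one matrix block
for the dimension level and one block per dimension.  Alternatives are
scored per criterion on a bounded performance scale whose upper bound is
the aspiration level and whose lower bound is the worst level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DIMENSION_BLOCK = "dimensions"


@dataclass(frozen=True)
class Violation:
    """A single validation failure: the field at fault and the rule broken."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


@dataclass(frozen=True)
class DecisionHierarchy:
    """Two-level decision structure with its measurement scales.

    Parameters
    ----------
    dimensions
        Ordered ``(id, label)`` pairs. Declaration order is preserved in
        every matrix and report.
    criteria
        Ordered ``(id, label, dimension_id)`` triples.
    influence_scale
        Integer bounds of the pairwise direct-influence questionnaire.
    performance_scale
        Real bounds of the satisfaction/performance survey.
    f_aspired, f_worst
        Aspiration (best) and worst levels used by the gap analysis;
        conventionally the upper and lower bound of the semantic scale.
    """

    dimensions: tuple[tuple[str, str], ...]
    criteria: tuple[tuple[str, str, str], ...]
    influence_scale: tuple[int, int] = (0, 4)
    performance_scale: tuple[float, float] = (0.0, 10.0)
    f_aspired: float = 10.0
    f_worst: float = 0.0

    def __init__(
        self,
        dimensions: Sequence[Sequence[str]],
        criteria: Sequence[Sequence[str]],
        influence_scale: Sequence[int] = (0, 4),
        performance_scale: Sequence[float] = (0.0, 10.0),
        f_aspired: float = 10.0,
        f_worst: float = 0.0,
    ) -> None:
        object.__setattr__(self, "dimensions", tuple((str(a), str(b)) for a, b in dimensions))
        object.__setattr__(
            self, "criteria", tuple((str(a), str(b), str(c)) for a, b, c in criteria)
        )
        object.__setattr__(self, "influence_scale", (int(influence_scale[0]), int(influence_scale[1])))
        object.__setattr__(
            self, "performance_scale", (float(performance_scale[0]), float(performance_scale[1]))
        )
        object.__setattr__(self, "f_aspired", float(f_aspired))
        object.__setattr__(self, "f_worst", float(f_worst))

    @property
    def dimension_ids(self) -> list[str]:
        return [d for d, _ in self.dimensions]

    @property
    def criterion_ids(self) -> list[str]:
        return [c for c, _, _ in self.criteria]

    def criteria_of(self, dimension_id: str) -> list[str]:
        return [c for c, _, d in self.criteria if d == dimension_id]

    def dimension_of(self, criterion_id: str) -> str:
        for c, _, d in self.criteria:
            if c == criterion_id:
                return d
        raise KeyError(f"unknown criterion {criterion_id!r}")

    @property
    def block_sizes(self) -> dict[str, int]:
        """Matrix order per block: D for the dimension block, n_d per dimension."""
        sizes = {DIMENSION_BLOCK: len(self.dimensions)}
        for d in self.dimension_ids:
            sizes[d] = len(self.criteria_of(d))
        return sizes

    def block_labels(self, block: str) -> list[str]:
        """Factor ids of one block, in declaration order."""
        if block == DIMENSION_BLOCK:
            return self.dimension_ids
        if block not in self.dimension_ids:
            raise KeyError(f"unknown block {block!r}")
        return self.criteria_of(block)

    @property
    def blocks(self) -> list[str]:
        return [DIMENSION_BLOCK, *self.dimension_ids]

    def label_of(self, factor_id: str) -> str:
        for i, lab in self.dimensions:
            if i == factor_id:
                return lab
        for i, lab, _ in self.criteria:
            if i == factor_id:
                return lab
        raise KeyError(f"unknown factor {factor_id!r}")


@dataclass(frozen=True)
class ExpertPanel:
    """One block's raw survey: H square integer matrices, one per expert."""

    block: str
    matrices: tuple[np.ndarray, ...]

    def __init__(self, block: str, matrices: Sequence[np.ndarray]) -> None:
        mats = tuple(np.asarray(m, dtype=float) for m in matrices)
        object.__setattr__(self, "block", str(block))
        object.__setattr__(self, "matrices", mats)

    @property
    def H(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return 0 if not self.matrices else self.matrices[0].shape[0]


@dataclass(frozen=True)
class DirectInfluenceMatrix:
    """Panel-averaged direct influence A = [a_ij], zero diagonal, scale-bounded."""

    block: str
    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __init__(self, block: str, values: np.ndarray, labels: Sequence[str] = ()) -> None:
        A = np.asarray(values, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("direct-influence matrix must be square")
        object.__setattr__(self, "block", str(block))
        object.__setattr__(self, "values", A)
        object.__setattr__(self, "labels", tuple(labels) if labels else tuple(str(i) for i in range(len(A))))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PerformanceSurvey:
    """Per-alternative, per-criterion performance scores f_kj."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    scores: np.ndarray  # shape (K, J)

    def __init__(
        self,
        alternatives: Sequence[str],
        criteria: Sequence[str],
        scores: np.ndarray,
    ) -> None:
        S = np.asarray(scores, dtype=float)
        if S.ndim == 1:
            S = S[None, :]
        if S.shape != (len(alternatives), len(criteria)):
            raise ValueError(
                f"score array shape {S.shape} does not match "
                f"{len(alternatives)} alternatives x {len(criteria)} criteria"
            )
        object.__setattr__(self, "alternatives", tuple(str(a) for a in alternatives))
        object.__setattr__(self, "criteria", tuple(str(c) for c in criteria))
        object.__setattr__(self, "scores", S)

    def score(self, alternative: str, criterion: str) -> float:
        k = self.alternatives.index(alternative)
        j = self.criteria.index(criterion)
        return float(self.scores[k, j])


def validate_hierarchy(h: DecisionHierarchy) -> list[Violation]:
    """Check structural invariants; returns an empty list when all hold."""
    out: list[Violation] = []
    dim_ids = h.dimension_ids
    crit_ids = h.criterion_ids
    if len(set(dim_ids)) != len(dim_ids):
        out.append(Violation("dimensions", "dimension ids must be unique"))
    if len(set(crit_ids)) != len(crit_ids):
        out.append(Violation("criteria", "criterion ids must be unique"))
    if set(dim_ids) & set(crit_ids):
        out.append(Violation("criteria", "criterion ids must not collide with dimension ids"))
    if len(dim_ids) < 2:
        out.append(Violation("dimensions", "at least 2 dimensions required"))
    for d in dim_ids:
        n_d = len(h.criteria_of(d))
        if n_d < 2:
            out.append(
                Violation(f"dimensions[{d}]", f"dimension owns {n_d} criteria; pairwise comparison needs >= 2")
            )
    for c, _, d in h.criteria:
        if d not in dim_ids:
            out.append(Violation(f"criteria[{c}]", f"parent dimension {d!r} not declared"))
    lo, hi = h.influence_scale
    if not lo < hi:
        out.append(Violation("influence_scale", "lower bound must be below upper bound"))
    plo, phi = h.performance_scale
    if not plo < phi:
        out.append(Violation("performance_scale", "lower bound must be below upper bound"))
    if not h.f_worst < h.f_aspired:
        out.append(Violation("f_aspired", "aspiration level must exceed worst level"))
    return out


def validate_panel(p: ExpertPanel, h: DecisionHierarchy) -> list[Violation]:
    """Check one expert panel against the hierarchy's block sizes and scale."""
    out: list[Violation] = []
    sizes = h.block_sizes
    if p.block not in sizes:
        out.append(Violation("block", f"unknown block {p.block!r}"))
        return out
    n = sizes[p.block]
    lo, hi = h.influence_scale
    if p.H == 0:
        out.append(Violation("matrices", "panel holds no expert matrices"))
    for idx, E in enumerate(p.matrices):
        tag = f"matrices[{idx}]"
        if E.ndim != 2 or E.shape != (n, n):
            out.append(Violation(tag, f"expected {n}x{n} matrix for block {p.block!r}, got {E.shape}"))
            continue
        if np.any(np.diagonal(E) != 0):
            out.append(Violation(tag, "diagonal entries must be exactly 0"))
        off = E[~np.eye(n, dtype=bool)]
        if np.any(off < lo) or np.any(off > hi):
            out.append(Violation(tag, f"entries must lie within the influence scale [{lo}, {hi}]"))
    return out


def validate_survey(s: PerformanceSurvey, h: DecisionHierarchy) -> list[Violation]:
    """Check that a survey covers every criterion and stays on scale."""
    out: list[Violation] = []
    missing = [c for c in h.criterion_ids if c not in s.criteria]
    if missing:
        out.append(Violation("criteria", f"missing scores for criteria: {', '.join(missing)}"))
    extra = [c for c in s.criteria if c not in h.criterion_ids]
    if extra:
        out.append(Violation("criteria", f"scores for undeclared criteria: {', '.join(extra)}"))
    lo, hi = h.performance_scale
    if np.any(s.scores < lo) or np.any(s.scores > hi):
        out.append(Violation("scores", f"scores must lie within the performance scale [{lo}, {hi}]"))
    return out
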