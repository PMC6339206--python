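"""Aspiration-gap analysis (modified VIKOR, mean group utility only).

Instead of ranking against the best alternative, every score is measured
against a fixed aspiration level — typically the top of the survey scale —
so even a lone alternative gets a meaningful gap.  Two gap dialects exist:

``raw``
    The plain aspiration distance f_aspired - f_kj, in the survey's units.
``normalized``
    |f_aspired - f_kj| / |f_aspired - f_worst|, a dimensionless value in
    [0, 1].

The mean group utility S_k of alternative k is the weighted sum of its
per-criterion gaps; smaller is better.  The report also rolls performance
and gaps up the hierarchy: dimension level with local criterion weights,
overall with local dimension weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DecisionHierarchy, PerformanceSurvey, validate_survey
from .weights import WeightSet

DIALECTS = ("raw", "normalized")


@dataclass(frozen=True)
class CriterionRow:
    criterion: str
    dimension: str
    local_weight: float
    global_weight: float
    performance: float
    gap: float


@dataclass(frozen=True)
class DimensionRow:
    dimension: str
    local_weight: float
    performance: float
    gap: float


@dataclass(frozen=True)
class AlternativeReport:
    alternative: str
    criterion_rows: tuple[CriterionRow, ...]
    dimension_rows: tuple[DimensionRow, ...]
    overall_performance: float
    overall_gap: float
    mean_group_utility: float


@dataclass(frozen=True)
class GapReport:
    dialect: str
    f_aspired: float
    f_worst: float
    alternatives: tuple[AlternativeReport, ...]

    @property
    def ranking(self) -> tuple[str, ...]:
        """Alternatives ordered by mean group utility, best (smallest) first."""
        return tuple(
            a.alternative
            for a in sorted(self.alternatives, key=lambda a: a.mean_group_utility)
        )


def normalized_gap(f_kj: float, f_aspired: float, f_worst: float) -> float:
    """Distance to aspiration as a fraction of the full scale span."""
    if f_aspired == f_worst:
        raise ValueError("degenerate scale: aspiration and worst levels coincide")
    return abs(f_aspired - f_kj) / abs(f_aspired - f_worst)


def aspiration_distance(f_kj: float, f_aspired: float) -> float:
    """Plain signed distance to the aspiration level, in survey units."""
    return f_aspired - f_kj


def mean_group_utility(weights: dict[str, float], gaps: dict[str, float]) -> float:
    """Weighted sum of per-criterion gaps for one alternative."""
    missing = sorted(set(weights) - set(gaps))
    if missing:
        raise ValueError(f"gaps missing for criteria: {', '.join(missing)}")
    missing = sorted(set(gaps) - set(weights))
    if missing:
        raise ValueError(f"weights missing for criteria: {', '.join(missing)}")
    return float(sum(weights[c] * gaps[c] for c in weights))


def _gap(f: float, h: DecisionHierarchy, dialect: str) -> float:
    if dialect == "raw":
        return aspiration_distance(f, h.f_aspired)
    return normalized_gap(f, h.f_aspired, h.f_worst)


def aggregate_report(
    ws: WeightSet,
    survey: PerformanceSurvey,
    h: DecisionHierarchy,
    dialect: str = "normalized",
) -> GapReport:
    """Roll criterion scores and gaps up to dimension and overall levels.

    Dimension performance is the local-criterion-weighted mean of its
    criteria's scores; overall performance is the local-dimension-weighted
    mean of dimension performances.  Gaps are computed the same way in the
    requested dialect, and S_k over global weights is reported alongside.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown gap dialect {dialect!r}; expected one of {DIALECTS}")
    sv = validate_survey(survey, h)
    if sv:
        raise ValueError("invalid survey: " + "; ".join(map(str, sv)))

    alt_reports: list[AlternativeReport] = []
    for k, alt in enumerate(survey.alternatives):
        crit_rows: list[CriterionRow] = []
        dim_rows: list[DimensionRow] = []
        overall_perf = 0.0
        overall_gap = 0.0
        gaps_by_crit: dict[str, float] = {}
        for d in h.dimension_ids:
            wl_d = ws.local_dimension_weights[d]
            dim_perf = 0.0
            dim_gap = 0.0
            for c in h.criteria_of(d):
                f = survey.score(alt, c)
                g = _gap(f, h, dialect)
                gaps_by_crit[c] = g
                wl_c = ws.local_criterion_weights[d][c]
                crit_rows.append(
                    CriterionRow(
                        criterion=c, dimension=d,
                        local_weight=wl_c,
                        global_weight=ws.global_criterion_weights[c],
                        performance=f, gap=g,
                    )
                )
                dim_perf += wl_c * f
                dim_gap += wl_c * g
            dim_rows.append(DimensionRow(dimension=d, local_weight=wl_d,
                                         performance=dim_perf, gap=dim_gap))
            overall_perf += wl_d * dim_perf
            overall_gap += wl_d * dim_gap
        s_k = mean_group_utility(ws.global_criterion_weights, gaps_by_crit)
        alt_reports.append(
            AlternativeReport(
                alternative=alt,
                criterion_rows=tuple(crit_rows),
                dimension_rows=tuple(dim_rows),
                overall_performance=float(overall_perf),
                overall_gap=float(overall_gap),
                mean_group_utility=s_k,
            )
        )
    return GapReport(
        dialect=dialect, f_aspired=h.f_aspired, f_worst=h.f_worst,
        alternatives=tuple(alt_reports),
    )
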