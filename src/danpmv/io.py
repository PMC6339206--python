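"""Readers, writers and the bundled case-study fixture.

Matrices travel as labeled CSV: the first row and first column carry factor
ids, cells are "."-decimal numbers.  Hierarchies are declared in JSON or
YAML.  Influence networks export to GraphML and DOT with prominence,
relation and role as node attributes; reports export as CSV mirroring the
factor / local weight / global weight / performance / gap layout and as a
full-precision JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dematel import InfluenceNetwork, TotalInfluenceResult
from .model import (
    DIMENSION_BLOCK,
    DecisionHierarchy,
    DirectInfluenceMatrix,
    ExpertPanel,
    PerformanceSurvey,
)
from .vikor import GapReport
from .weights import WeightSet


class MatrixParseError(ValueError):
    """Raised when a labeled-CSV matrix file is malformed."""


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labeled square matrix; returns (labels, values)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise MatrixParseError(f"{path}: {exc}") from exc
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols):
        raise MatrixParseError(
            f"{path}: matrix is not square ({len(rows)} rows x {len(cols)} columns)"
        )
    if rows != cols:
        raise MatrixParseError(f"{path}: row labels {rows} do not match column labels {cols}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for r in rows:
            for c in cols:
                try:
                    float(df.loc[r, c])
                except (TypeError, ValueError):
                    raise MatrixParseError(
                        f"{path}: non-numeric cell at row {r!r}, column {c!r}: {df.loc[r, c]!r}"
                    ) from exc
        raise MatrixParseError(f"{path}: {exc}") from exc
    if np.any(np.isnan(values)):
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise MatrixParseError(f"{path}: missing value at row {rows[i]!r}, column {cols[j]!r}")
    return rows, values


def write_matrix_csv(path: str | Path, labels: list[str], values: np.ndarray, decimals: int | None = None) -> None:
    """Write a labeled square matrix; inverse of :func:`read_matrix_csv`."""
    values = np.asarray(values, dtype=float)
    if decimals is not None:
        values = np.round(values, decimals)
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(Path(path), float_format=None)


def load_hierarchy(path: str | Path) -> DecisionHierarchy:
    """Load a hierarchy declaration from a JSON or YAML document."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return hierarchy_from_dict(doc)


def hierarchy_from_dict(doc: dict) -> DecisionHierarchy:
    return DecisionHierarchy(
        dimensions=[(d[0], d[1]) for d in doc["dimensions"]],
        criteria=[(c[0], c[1], c[2]) for c in doc["criteria"]],
        influence_scale=tuple(doc.get("influence_scale", (0, 4))),
        performance_scale=tuple(doc.get("performance_scale", (0.0, 10.0))),
        f_aspired=doc.get("f_aspired", doc.get("performance_scale", (0.0, 10.0))[1]),
        f_worst=doc.get("f_worst", doc.get("performance_scale", (0.0, 10.0))[0]),
    )


def read_survey_csv(path: str | Path) -> PerformanceSurvey:
    """Read a long-format survey: alternative, criterion, score columns."""
    df = pd.read_csv(Path(path))
    required = {"alternative", "criterion", "score"}
    if not required.issubset(df.columns):
        raise MatrixParseError(
            f"{path}: survey needs columns {sorted(required)}, found {list(df.columns)}"
        )
    wide = df.pivot(index="alternative", columns="criterion", values="score")
    return PerformanceSurvey(
        alternatives=[str(a) for a in wide.index],
        criteria=[str(c) for c in wide.columns],
        scores=wide.to_numpy(dtype=float),
    )


def write_survey_csv(path: str | Path, survey: PerformanceSurvey) -> None:
    records = [
        {"alternative": a, "criterion": c, "score": survey.score(a, c)}
        for a in survey.alternatives
        for c in survey.criteria
    ]
    pd.DataFrame.from_records(records).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Bundled case fixture

FIXTURES = ("xingshisi",)


def load_case_fixture(name: str = "xingshisi") -> tuple[DecisionHierarchy, dict[str, ExpertPanel], PerformanceSurvey]:
    """Bundled rural quality-of-life case study.

    A 4-dimension / 26-criterion WHOQOL-BREF-derived hierarchy, the five
    published panel-averaged direct-influence matrices (represented as H=1
    panels with real-valued entries), and the single-village satisfaction
    survey on a 7-point Likert scale with aspiration level 7.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    root = resources.files("danpmv") / "fixtures" / name
    with resources.as_file(root / "hierarchy.json") as p:
        hierarchy = load_hierarchy(p)
    panels: dict[str, ExpertPanel] = {}
    for block in hierarchy.blocks:
        fname = "dimensions.csv" if block == DIMENSION_BLOCK else f"{block}.csv"
        with resources.as_file(root / fname) as p:
            labels, values = read_matrix_csv(p)
        expected = hierarchy.block_labels(block)
        if labels != expected:
            raise MatrixParseError(f"fixture block {block!r}: labels {labels} != {expected}")
        panels[block] = ExpertPanel(block, [values])
    with resources.as_file(root / "survey.csv") as p:
        survey = read_survey_csv(p)
    # align survey columns to hierarchy order
    order = [survey.criteria.index(c) for c in hierarchy.criterion_ids]
    survey = PerformanceSurvey(
        survey.alternatives, hierarchy.criterion_ids, survey.scores[:, order]
    )
    return hierarchy, panels, survey


# ---------------------------------------------------------------------------
# Exports

def inrm_to_graph(network: InfluenceNetwork) -> nx.DiGraph:
    """Directed graph with (x, y, role) on nodes and strengths on edges."""
    G = nx.DiGraph(level=network.level)
    for node in network.nodes:
        G.add_node(node.factor, x=node.x, y=node.y, role=node.role)
    for e in network.edges:
        G.add_edge(e.source, e.target, forward=e.forward, backward=e.backward)
        if e.bidirectional:
            G.add_edge(e.target, e.source, forward=e.backward, backward=e.forward)
    return G


def write_inrm(network: InfluenceNetwork, basepath: str | Path) -> list[Path]:
    """Export an influence network as GraphML, DOT and a node-coordinate CSV."""
    base = Path(basepath)
    G = inrm_to_graph(network)
    paths = []
    graphml = base.with_suffix(".graphml")
    nx.write_graphml(G, graphml)
    paths.append(graphml)
    dot = base.with_suffix(".dot")
    _write_dot(G, dot)
    paths.append(dot)
    coords = base.with_suffix(".csv")
    pd.DataFrame(
        [{"factor": n.factor, "prominence": n.x, "relation": n.y, "role": n.role}
         for n in network.nodes]
    ).to_csv(coords, index=False)
    paths.append(coords)
    return paths


def _write_dot(G: nx.DiGraph, path: Path) -> None:
    # plain-text DOT writer; avoids the optional pygraphviz/pydot dependency
    lines = [f'digraph "{G.graph.get("level", "inrm")}" {{']
    for n, d in G.nodes(data=True):
        lines.append(
            f'  "{n}" [x="{d["x"]:.6f}", y="{d["y"]:.6f}", role="{d["role"]}"];'
        )
    for u, v, d in G.edges(data=True):
        lines.append(
            f'  "{u}" -> "{v}" [forward="{d["forward"]:.6f}", backward="{d["backward"]:.6f}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def weights_to_frame(ws: WeightSet, h: DecisionHierarchy) -> pd.DataFrame:
    """Tabulate local and global weights, one row per dimension or criterion."""
    rows = []
    for d in h.dimension_ids:
        rows.append({"factor": d, "label": h.label_of(d), "level": "dimension",
                     "local_weight": ws.local_dimension_weights[d], "global_weight": None})
        for c in h.criteria_of(d):
            rows.append({"factor": c, "label": h.label_of(c), "level": "criterion",
                         "local_weight": ws.local_criterion_weights[d][c],
                         "global_weight": ws.global_criterion_weights[c]})
    return pd.DataFrame(rows)


def report_to_frame(report: GapReport, h: DecisionHierarchy, alternative: str | None = None) -> pd.DataFrame:
    """Tabulate one alternative's report in the published table layout."""
    alts = {a.alternative: a for a in report.alternatives}
    if alternative is None:
        alternative = report.alternatives[0].alternative
    alt = alts[alternative]
    dim_rows = {d.dimension: d for d in alt.dimension_rows}
    rows = []
    for d in h.dimension_ids:
        dr = dim_rows[d]
        rows.append({"factor": d, "label": h.label_of(d), "local_weight": dr.local_weight,
                     "global_weight": None, "performance": dr.performance, "gap": dr.gap})
        for cr in alt.criterion_rows:
            if cr.dimension == d:
                rows.append({"factor": cr.criterion, "label": h.label_of(cr.criterion),
                             "local_weight": cr.local_weight, "global_weight": cr.global_weight,
                             "performance": cr.performance, "gap": cr.gap})
    rows.append({"factor": "TOTAL", "label": "Overall", "local_weight": None,
                 "global_weight": None, "performance": alt.overall_performance,
                 "gap": alt.overall_gap})
    return pd.DataFrame(rows)


def report_to_dict(report: GapReport) -> dict:
    """Full-precision JSON-ready summary of a gap report."""
    return {
        "dialect": report.dialect,
        "f_aspired": report.f_aspired,
        "f_worst": report.f_worst,
        "ranking": list(report.ranking),
        "alternatives": [asdict(a) for a in report.alternatives],
    }
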