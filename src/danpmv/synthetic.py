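"""Synthetic expert panels and satisfaction surveys.

Real studies of this kind rest on two small surveys: a handful of experts
scoring pairwise influence on an integer 0-4 scale, and a few dozen
residents scoring satisfaction on a bounded Likert scale.  Neither survey's
raw data is ever published, so this module fabricates statistically similar
ones: each simulated expert is the ground-truth influence matrix rounded to
the integer scale, with every off-diagonal entry independently bumped up or
down by a small step with some probability, then clipped back into scale.
Simulated residents add Gaussian noise to true criterion scores, and the
reported survey value is the respondent mean, clipped.

A shared seed expands into independent per-block substreams keyed by a
stable hash of the block id, so adding or removing a block never reshuffles
the others.  The weight-recovery experiment quantifies how fast panel noise
washes out of the influential weights as the panel grows.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .model import (
    DecisionHierarchy,
    DirectInfluenceMatrix,
    ExpertPanel,
    PerformanceSurvey,
)
from .weights import ConvergenceSettings, run_hierarchical


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for simulating one expert panel per block."""

    hierarchy: DecisionHierarchy
    base_matrices: dict[str, np.ndarray]   # ground-truth A per block
    H: int = 10
    flip_probability: float = 0.3
    max_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.H < 1:
            raise ValueError("H must be >= 1")
        if self.max_step < 1:
            raise ValueError("max_step must be >= 1")
        lo, hi = self.hierarchy.influence_scale
        for block, A in self.base_matrices.items():
            A = np.asarray(A, dtype=float)
            if np.any(np.diagonal(A) != 0):
                raise ValueError(f"base matrix for block {block!r} has nonzero diagonal")
            if np.any(A < lo) or np.any(A > hi):
                raise ValueError(f"base matrix for block {block!r} exceeds the influence scale")


@dataclass(frozen=True)
class SurveySpec:
    """Recipe for simulating a bounded-Likert satisfaction survey."""

    hierarchy: DecisionHierarchy
    true_scores: dict[str, dict[str, float]]  # alternative -> criterion -> score
    respondents: int = 50
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.respondents < 1:
            raise ValueError("respondent count must be >= 1")
        lo, hi = self.hierarchy.performance_scale
        for alt, scores in self.true_scores.items():
            for c, v in scores.items():
                if not lo <= v <= hi:
                    raise ValueError(
                        f"true score {v} for ({alt!r}, {c!r}) outside performance scale [{lo}, {hi}]"
                    )


def _block_rng(seed: int, block: str, salt: str = "") -> np.random.Generator:
    """Independent substream per block via a stable hash of its id."""
    digest = hashlib.sha256(f"{seed}:{salt}:{block}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def generate_panel(spec: PanelSpec) -> dict[str, ExpertPanel]:
    """Simulate H integer expert matrices per block around the ground truth."""
    lo, hi = spec.hierarchy.influence_scale
    panels: dict[str, ExpertPanel] = {}
    for block in spec.hierarchy.blocks:
        if block not in spec.base_matrices:
            raise ValueError(f"no base matrix for block {block!r}")
        base = np.rint(np.asarray(spec.base_matrices[block], dtype=float))
        n = base.shape[0]
        rng = _block_rng(spec.seed, block, salt="panel")
        off = ~np.eye(n, dtype=bool)
        mats = []
        for _ in range(spec.H):
            E = base.copy()
            flips = rng.random((n, n)) < spec.flip_probability
            steps = rng.integers(1, spec.max_step + 1, size=(n, n))
            signs = rng.choice([-1.0, 1.0], size=(n, n))
            E[off & flips] += (signs * steps)[off & flips]
            E = np.clip(E, lo, hi)
            np.fill_diagonal(E, 0.0)
            mats.append(E)
        panels[block] = ExpertPanel(block, mats)
    return panels


def generate_survey(spec: SurveySpec) -> PerformanceSurvey:
    """Simulate the respondent-mean satisfaction score per criterion."""
    h = spec.hierarchy
    lo, hi = h.performance_scale
    alternatives = sorted(spec.true_scores)
    crit_ids = h.criterion_ids
    scores = np.empty((len(alternatives), len(crit_ids)))
    for k, alt in enumerate(alternatives):
        rng = _block_rng(spec.seed, alt, salt="survey")
        for j, c in enumerate(crit_ids):
            true = spec.true_scores[alt][c]
            draws = np.clip(true + rng.normal(0.0, spec.noise_sd, spec.respondents), lo, hi)
            scores[k, j] = draws.mean()
    return PerformanceSurvey(alternatives, crit_ids, scores)


def _weights_from_bases(
    h: DecisionHierarchy,
    base_matrices: dict[str, np.ndarray],
    settings: ConvergenceSettings,
) -> "np.ndarray":
    """Global weight vector computed from noiseless base matrices (H=1 panels)."""
    panels = {b: ExpertPanel(b, [np.asarray(base_matrices[b], dtype=float)]) for b in h.blocks}
    run = run_hierarchical(panels, h, settings)
    return np.array([run.weights.global_criterion_weights[c] for c in h.criterion_ids])


@dataclass(frozen=True)
class RecoveryResult:
    """Deviation of noisy-panel weights from ground-truth weights."""

    H: int
    flip_probability: float
    seed: int
    dimension_deviation: float  # max abs over local dimension weights
    global_deviation: float     # max abs over global criterion weights
    block_deviation: dict[str, float] = field(default_factory=dict)


def recovery_experiment(
    spec: PanelSpec,
    settings: ConvergenceSettings = ConvergenceSettings(),
    H_grid: tuple[int, ...] | None = None,
    flip_grid: tuple[float, ...] | None = None,
    replicates: int = 1,
) -> list[RecoveryResult]:
    """Measure weight-recovery error over a grid of panel sizes and noise levels.

    For every (H, flip_probability, replicate) cell, a fresh panel is drawn
    around the spec's base matrices, the full hierarchical pipeline is run on
    it (consistency warnings suppressed by policy), and the resulting weights
    are compared against the noiseless ground-truth weights.
    """
    h = spec.hierarchy
    truth_panels = {
        b: ExpertPanel(b, [np.rint(np.asarray(spec.base_matrices[b], dtype=float))])
        for b in h.blocks
    }
    truth = run_hierarchical(truth_panels, h, settings)
    truth_dim = np.array([truth.weights.local_dimension_weights[d] for d in h.dimension_ids])
    truth_glob = np.array([truth.weights.global_criterion_weights[c] for c in h.criterion_ids])

    H_values = H_grid or (spec.H,)
    flip_values = flip_grid or (spec.flip_probability,)
    results: list[RecoveryResult] = []
    for H in H_values:
        for fp in flip_values:
            for rep in range(replicates):
                seed = (spec.seed + 1_000_003 * rep + 7 * H + int(fp * 1009)) % (2**31)
                sub = PanelSpec(
                    hierarchy=h, base_matrices=spec.base_matrices,
                    H=H, flip_probability=fp, max_step=spec.max_step, seed=seed,
                )
                panels = generate_panel(sub)
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    run = run_hierarchical(panels, h, settings)
                dim = np.array(
                    [run.weights.local_dimension_weights[d] for d in h.dimension_ids]
                )
                glob = np.array(
                    [run.weights.global_criterion_weights[c] for c in h.criterion_ids]
                )
                block_dev = {}
                for b in h.blocks:
                    w_t = np.array(list(truth.blocks[b].local_weights.values()))
                    w_n = np.array(list(run.blocks[b].local_weights.values()))
                    block_dev[b] = float(np.max(np.abs(w_t - w_n)))
                results.append(
                    RecoveryResult(
                        H=H, flip_probability=fp, seed=seed,
                        dimension_deviation=float(np.max(np.abs(dim - truth_dim))),
                        global_deviation=float(np.max(np.abs(glob - truth_glob))),
                        block_deviation=block_dev,
                    )
                )
    return results
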