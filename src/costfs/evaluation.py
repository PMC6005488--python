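"""Selection-quality factors and the repeated-cost-draw harness.

A heuristic selector is judged against the *optimal reduct* ``R'`` — the
decision-relative reduct of minimal total test cost — under many random
cost settings.  For one run with selected subset ``R``:

* below factor   ``bf(R) = (c*(R') - c*(R)) / c*(R')`` — the relative
  saving when the selection undercuts the optimal reduct (possible
  because a selection need not be a reduct);
* exceeding factor ``ef(R) = (c*(R) - c*(R')) / c*(R')`` — the relative
  excess when it does not.

Over ``K`` runs, ``K1`` is the number of strictly-below runs and
``K2 = K - K1`` the rest (equal-cost runs land in ``K2`` with
``ef = 0``).  The aggregates are MBF (max below factor over all runs),
ABF (mean bf over the ``K1`` below runs; not applicable when ``K1 = 0``),
AEF (mean ef over the ``K2`` runs), and the finding-optimal factor
FOF — the fraction of runs whose selected cost does not exceed the
optimal reduct's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cost_model import CostDistributionSpec, generate_costs
from .decision_system import DecisionSystem
from .laplacian_score import GraphConfig, build_affinity, laplacian_score_feature
from .rough_core import NeighborhoodConfig, core, min_cost_reduct
from .selector import select

__all__ = [
    "RunRecord",
    "MetricsReport",
    "below_factor",
    "exceeding_factor",
    "aggregate",
    "run_experiment",
    "ExperimentResult",
]


def below_factor(cost_R: float, cost_opt: float) -> float:
    """Relative saving of the selected subset versus the optimal reduct."""
    if cost_opt <= 0:
        raise ValueError("optimal-reduct cost must be > 0")
    return (cost_opt - cost_R) / cost_opt


def exceeding_factor(cost_R: float, cost_opt: float) -> float:
    """Relative excess of the selected subset versus the optimal reduct."""
    if cost_opt <= 0:
        raise ValueError("optimal-reduct cost must be > 0")
    return (cost_R - cost_opt) / cost_opt


@dataclass(frozen=True)
class RunRecord:
    """One simulation run: a cost draw, a selection, and the baseline."""

    run: int
    cost_seed: int
    alpha: float
    cost_selected: float
    cost_optimal: float

    def __post_init__(self) -> None:
        if self.cost_selected <= 0 or self.cost_optimal <= 0:
            raise ValueError("run costs must be > 0")

    @property
    def below(self) -> bool:
        return self.cost_selected < self.cost_optimal

    @property
    def bf(self) -> float:
        return below_factor(self.cost_selected, self.cost_optimal)

    @property
    def ef(self) -> float:
        return exceeding_factor(self.cost_selected, self.cost_optimal)


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate factors over K runs at one (distribution, alpha) setting."""

    K: int
    K1: int
    K2: int
    fof: float
    mbf: float
    abf: float | None
    aef: float

    def as_dict(self) -> dict:
        return {"K": self.K, "K1": self.K1, "K2": self.K2, "FOF": self.fof,
                "MBF": self.mbf, "ABF": self.abf, "AEF": self.aef}


def aggregate(records: Sequence[RunRecord]) -> MetricsReport:
    """Aggregate run records into MBF / ABF / AEF / FOF.

    ABF averages only the strictly-below runs and is reported as ``None``
    ("not applicable") when there are none — a run never below is not the
    same as one below by zero.  AEF averages the non-below runs, where
    equal-cost runs contribute ``ef = 0``.
    """
    if not records:
        raise ValueError("need at least one run record")
    bfs = np.array([r.bf for r in records])
    efs = np.array([r.ef for r in records])
    below = bfs > 0
    K = len(records)
    K1 = int(below.sum())
    K2 = K - K1
    fof = float(np.mean([r.cost_selected <= r.cost_optimal for r in records]))
    abf = float(bfs[below].mean()) if K1 else None
    aef = float(efs[~below].mean()) if K2 else 0.0
    return MetricsReport(K=K, K1=K1, K2=K2, fof=fof,
                         mbf=float(bfs.max()), abf=abf, aef=aef)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-alpha reports plus the raw run log."""

    reports: Mapping[float, MetricsReport]
    records: tuple[RunRecord, ...]
    family: str
    d: int | None

    def best_alpha(self) -> float:
        """Alpha with the highest finding-optimal factor (ties: the
        alpha closest to 0, i.e. the least cost-aggressive)."""
        return max(self.reports, key=lambda a: (self.reports[a].fof, a))


DEFAULT_ALPHA_GRID = (0.0, -0.25, -0.5, -0.75, -1.0, -1.25, -1.5, -1.75, -2.0)


def run_experiment(system: DecisionSystem,
                   dist_spec: CostDistributionSpec,
                   K: int = 100,
                   alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                   d: int | None = None,
                   nbr_cfg: NeighborhoodConfig | None = None,
                   graph_cfg: GraphConfig | None = None,
                   master_seed: int = 0,
                   max_features_guard: int = 20) -> ExperimentResult:
    """Run the K-draw, alpha-sweep simulation on one system.

    Each run draws a fresh cost vector (seeded as ``master_seed`` plus a
    run counter, so single runs are re-extractable), finds the exact
    minimal-cost reduct as the baseline, and evaluates the selector at
    every alpha on that same draw.  ``d`` fixes the selection size; when
    ``None`` it matches the optimal reduct's size run by run, so the
    cost comparison is at equal panel size.  Fully reproducible under
    ``master_seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if nbr_cfg is None:
        nbr_cfg = NeighborhoodConfig.for_system(system)
    if graph_cfg is None:
        graph_cfg = GraphConfig()
    # core and raw LS depend on the system only, not the cost draw
    core_feats = core(system, nbr_cfg)
    graph = build_affinity(system, graph_cfg)
    raw_ls = {a: laplacian_score_feature(system.column(a), graph)
              for a in system.features}
    records: list[RunRecord] = []
    per_alpha: dict[float, list[RunRecord]] = {a: [] for a in alpha_grid}
    for i in range(K):
        cost_seed = int((master_seed + 1) * 100_003 + i) % (2**31)
        spec_i = CostDistributionSpec(
            family=dist_spec.family, low=dist_spec.low, high=dist_spec.high,
            normal_mean=dist_spec.normal_mean, normal_sd=dist_spec.normal_sd,
            pareto_shape=dist_spec.pareto_shape,
            integer_costs=dist_spec.integer_costs, seed=cost_seed)
        costs = generate_costs(spec_i, system.features)
        opt_subset, opt_cost = min_cost_reduct(
            system, costs, nbr_cfg, max_features_guard=max_features_guard)
        d_run = d if d is not None else max(len(opt_subset), 1)
        for alpha in alpha_grid:
            result = select(system, costs, d=d_run, alpha=alpha,
                            graph_cfg=graph_cfg, nbr_cfg=nbr_cfg,
                            core_override=core_feats, ls_override=raw_ls)
            rec = RunRecord(run=i, cost_seed=cost_seed, alpha=alpha,
                            cost_selected=result.total_cost,
                            cost_optimal=opt_cost)
            records.append(rec)
            per_alpha[alpha].append(rec)
    reports = {a: aggregate(recs) for a, recs in per_alpha.items()}
    return ExperimentResult(reports=reports, records=tuple(records),
                            family=dist_spec.family, d=d)
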