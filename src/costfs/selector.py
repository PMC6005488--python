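"""Core-first, score-ranked cost-sensitive feature selection.

The selection procedure has two stages.  First the decision-relative
core — every feature whose removal from the full set shrinks the
positive region — is added unconditionally: those features are in every
reduct, so omitting any of them loses classification-relevant
information.  Second, the remaining features are ranked by the
cost-weighted Laplacian score ``LS(a) * c(a)**alpha`` and appended in
descending order until ``d`` features are selected in total.

Compared with heuristics that add features one at a time re-evaluating a
criterion at each step, this computes all scores once on the affinity
graph, so the ranking stage is linear in the number of features and
captures between-instance structure through the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .decision_system import DecisionSystem, TestCostVector, subset_cost
from .laplacian_score import FeatureScore, GraphConfig, score_all
from .rough_core import NeighborhoodConfig, core

__all__ = ["SelectionResult", "select", "rank_remaining"]


@dataclass(frozen=True)
class SelectionResult:
    """Output of one selection run.

    ``selected`` is ordered: core features (file order) first, then
    ranked features in descending weighted-score order.
    """

    selected: tuple[str, ...]
    core_part: tuple[str, ...]
    ranked_part: tuple[str, ...]
    total_cost: float
    scores: FeatureScore
    d: int
    alpha: float


def rank_remaining(scores: FeatureScore, exclude: Iterable[str],
                   costs: TestCostVector | None = None,
                   feature_order: Sequence[str] | None = None) -> list[str]:
    """Candidates ordered by descending weighted score.

    Ties break toward the cheaper feature (cost is the objective being
    minimized), then toward earlier file order.
    """
    exclude = set(exclude)
    names = list(feature_order) if feature_order is not None else list(scores.ls)
    pos = {a: r for r, a in enumerate(names)}

    def key(a: str):
        cost = costs[a] if costs is not None else 0.0
        return (-scores.weighted[a], cost, pos[a])

    return sorted((a for a in names if a not in exclude), key=key)


def select(system: DecisionSystem, costs: TestCostVector, d: int,
           alpha: float = -1.0,
           graph_cfg: GraphConfig | None = None,
           nbr_cfg: NeighborhoodConfig | None = None,
           labels: Sequence | None = None,
           core_override: Iterable[str] | None = None,
           ls_override: Mapping[str, float] | None = None,
           strict_core: bool = False) -> SelectionResult:
    """Select ``d`` features: the core plus the best-scoring remainder.

    ``d`` is the total output size.  If the core alone exceeds ``d`` the
    default policy returns the full core with a warning — truncating the
    core would break the positive-region guarantee — while
    ``strict_core=True`` raises instead.  ``core_override`` and
    ``ls_override`` substitute an externally supplied core or raw-score
    vector (used e.g. to replay published worked examples).
    """
    if not 1 <= d <= system.n_features:
        raise ValueError(f"d={d} must be in [1, {system.n_features}]")
    if alpha > 0:
        raise ValueError("alpha must be <= 0")
    if nbr_cfg is None:
        nbr_cfg = NeighborhoodConfig.for_system(system)
    if core_override is not None:
        core_feats = tuple(core_override)
    else:
        core_feats = core(system, nbr_cfg)
    if len(core_feats) > d:
        if strict_core:
            raise ValueError(
                f"core has {len(core_feats)} features but d={d}; "
                "raise d or drop strict_core")
        warnings.warn(
            f"core has {len(core_feats)} features, exceeding d={d}; "
            "returning the full core", stacklevel=2)
    scores = score_all(system, costs, alpha, cfg=graph_cfg, labels=labels,
                       ls_override=ls_override)
    ranked_order = rank_remaining(scores, exclude=core_feats, costs=costs,
                                  feature_order=system.features)
    ranked_part = tuple(ranked_order[:max(0, d - len(core_feats))])
    selected = core_feats + ranked_part
    return SelectionResult(
        selected=selected,
        core_part=core_feats,
        ranked_part=ranked_part,
        total_cost=subset_cost(selected, costs),
        scores=scores,
        d=d,
        alpha=alpha,
    )
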