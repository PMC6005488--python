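"""kNN affinity graphs and the cost-weighted Laplacian score.

The Laplacian score measures a feature's locality-preserving power: on a
k-nearest-neighbor graph of the instances, a feature that varies little
across strongly connected pairs (relative to its overall variance) scores
well.  With the graph weight matrix ``S``, degree matrix ``D = diag(S 1)``
and Laplacian ``L = D - S``, the score of feature column ``f`` is the
Rayleigh quotient

    LS(f) = f~' L f~ / f~' D f~,   f~ = f - (f' D 1 / 1' D 1) 1.

Cost sensitivity enters through an exponential weighting

    LS(a, c) = LS(a) * c(a)**alpha,   alpha <= 0,

which trades importance against test cost; at ``alpha = 0`` the ranking
reduces to the plain score.

Two conventions are configurable because both appear in practice:

* kernel — ``squared_exponential`` ``exp(-d^2/t)`` (the textbook heat
  kernel) or ``exponential_distance`` ``exp(-d/t)`` (the worked-example
  convention reproduced in the tests);
* neighbor rule — ``or_rule`` (undirected union kNN; symmetric ``S``,
  positive-semidefinite ``L``) or ``directed_rows`` (each row keeps its
  own k nearest, possibly asymmetric).

``k`` counts the instance itself, so ``k = 3`` keeps two nearest others
per row.  Larger scores are treated as more important here, following
the cost-weighting convention above; note this inverts the original
Laplacian-score literature, where small scores are preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .decision_system import DecisionSystem, TestCostVector

__all__ = [
    "GraphConfig",
    "AffinityGraph",
    "FeatureScore",
    "build_affinity",
    "laplacian_score_feature",
    "cost_weighted_score",
    "score_all",
]

KERNELS = ("squared_exponential", "exponential_distance")
SYMMETRIZE = ("or_rule", "directed_rows")


@dataclass(frozen=True)
class GraphConfig:
    """Affinity-graph construction options.

    ``k`` includes the instance itself (default 3); ``t`` is the kernel
    bandwidth (default 1).  ``supervised`` restricts edges to same-label
    pairs when labels are supplied.
    """

    k: int = 3
    t: float = 1.0
    kernel: str = "squared_exponential"
    symmetrize: str = "or_rule"
    supervised: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.symmetrize not in SYMMETRIZE:
            raise ValueError(f"symmetrize must be one of {SYMMETRIZE}")

    @classmethod
    def worked_example(cls) -> "GraphConfig":
        """Convention that reproduces the printed liver-panel matrix."""
        return cls(k=3, t=1.0, kernel="exponential_distance",
                   symmetrize="directed_rows")


@dataclass(frozen=True)
class AffinityGraph:
    """Weight matrix ``S``, degrees ``D = diag(S 1)``, Laplacian ``L = D - S``."""

    S: np.ndarray

    @property
    def degrees(self) -> np.ndarray:
        return self.S.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.S


def _kernel_weights(dist: np.ndarray, cfg: GraphConfig) -> np.ndarray:
    if cfg.kernel == "squared_exponential":
        return np.exp(-(dist ** 2) / cfg.t)
    return np.exp(-dist / cfg.t)


def build_affinity(system: DecisionSystem, cfg: GraphConfig,
                   labels: Sequence | None = None) -> AffinityGraph:
    """Build the kNN affinity graph over all conditional features.

    Each row keeps its ``k`` nearest instances (self included; Euclidean
    distance, index order breaking ties); under ``or_rule`` the edge set
    is the symmetric union of the per-row choices.  Kept edges are
    weighted by the configured kernel, others are 0, and ``S_ii = 1``
    always (kernel at distance zero).  With ``supervised`` and labels,
    edges between differently-labeled instances are removed (self-loops
    stay).
    """
    m = system.n_instances
    if cfg.k >= m:
        raise ValueError(f"k={cfg.k} must be below the number of instances ({m})")
    dist = squareform(pdist(system.values))
    if cfg.supervised and labels is None:
        labels = system.decisions
    # argsort is stable, so equal distances resolve by instance order
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :cfg.k]
    keep = np.zeros((m, m), dtype=bool)
    np.put_along_axis(keep, nearest, True, axis=1)
    if cfg.symmetrize == "or_rule":
        keep |= keep.T
    if cfg.supervised and labels is not None:
        lab = np.asarray(labels, dtype=object)
        same = lab[:, None] == lab[None, :]
        keep &= same
    np.fill_diagonal(keep, True)
    S = np.where(keep, _kernel_weights(dist, cfg), 0.0)
    return AffinityGraph(S=S)


def laplacian_score_feature(f: Sequence[float], graph: AffinityGraph) -> float:
    """Rayleigh-quotient Laplacian score of one feature column.

    Constant columns return 0 by convention: degree-weighted centering
    annihilates them, and a constant feature has no locality-preserving
    power to measure.
    """
    f = np.asarray(f, dtype=float)
    d = graph.degrees
    total = d.sum()
    f_tilde = f - (f @ d) / total
    denom = f_tilde @ (d * f_tilde)
    if denom <= 1e-15 * max(1.0, float(np.abs(f).max()) ** 2):
        return 0.0
    num = f_tilde @ graph.laplacian @ f_tilde
    return float(num / denom)


def cost_weighted_score(ls: float, cost: float, alpha: float) -> float:
    """Exponentially cost-weighted importance ``ls * cost**alpha``.

    ``alpha`` must be non-positive; at 0 the score is returned unchanged.
    """
    if alpha > 0:
        raise ValueError("alpha must be <= 0")
    if cost <= 0:
        raise ValueError("cost must be > 0")
    return float(ls * cost ** alpha)


@dataclass(frozen=True)
class FeatureScore:
    """Raw and cost-weighted scores for every feature."""

    ls: Mapping[str, float]
    weighted: Mapping[str, float]
    alpha: float

    def ranking(self) -> list[str]:
        """Features by descending weighted score."""
        return sorted(self.ls, key=lambda a: -self.weighted[a])


def score_all(system: DecisionSystem, costs: TestCostVector, alpha: float,
              cfg: GraphConfig | None = None,
              labels: Sequence | None = None,
              ls_override: Mapping[str, float] | None = None) -> FeatureScore:
    """Score every feature: graph build, Laplacian score, cost weighting.

    ``ls_override`` substitutes externally supplied raw scores (e.g. a
    published importance vector) for the graph computation; the cost
    weighting is applied either way.
    """
    if cfg is None:
        cfg = GraphConfig()
    if ls_override is not None:
        ls = {a: float(ls_override[a]) for a in system.features}
    else:
        graph = build_affinity(system, cfg, labels=labels)
        ls = {a: laplacian_score_feature(system.column(a), graph)
              for a in system.features}
    weighted = {a: cost_weighted_score(ls[a], costs[a], alpha)
                for a in system.features}
    return FeatureScore(ls=ls, weighted=weighted, alpha=alpha)
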