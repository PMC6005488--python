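"""Neighborhood rough-set machinery for numeric decision systems.

Classical rough sets partition the universe by exact value equality,
which is useless for continuous measurements.  Here two instances are
*indiscernible* on a feature subset ``B`` when every per-feature gap is
within a threshold derived from that feature's measurement-error range:
``|a(x) - a(y)| <= lambda * e(a)``.  The default multiplier ``lambda=2``
reflects that two noisy readings of one true value can differ by up to
twice the error half-width; ``lambda=1`` is also supported.  With all
error ranges zero the relation collapses to classical equality-based
indiscernibility.

On top of the relation sit the standard constructs: the positive region
(instances whose whole neighborhood shares their label), decision-relative
reducts (minimal subsets preserving the full positive region), the core
(features in every reduct, equivalently those whose removal shrinks the
positive region), and an exact branch-and-bound search for the reduct of
minimal total test cost — the evaluation baseline for heuristic
selectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .decision_system import DecisionSystem, ErrorRangeVector, TestCostVector, error_ranges, subset_cost

__all__ = [
    "NeighborhoodConfig",
    "PositiveRegion",
    "indiscernible",
    "positive_region",
    "core",
    "is_reduct",
    "all_reducts",
    "min_cost_reduct",
]


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Indiscernibility thresholds: ``lambda * e(a)`` per feature."""

    e: ErrorRangeVector
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")

    @classmethod
    def for_system(cls, system: DecisionSystem, multiplier: float = 2.0,
                   delta: float = 0.1) -> "NeighborhoodConfig":
        return cls(e=error_ranges(system, delta=delta), multiplier=multiplier)

    def thresholds(self, features: Sequence[str]) -> np.ndarray:
        return np.array([self.multiplier * self.e[a] for a in features])


@dataclass(frozen=True)
class PositiveRegion:
    """Instances consistently classified by conditioning subset ``B``."""

    members: frozenset
    subset: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other) -> bool:
        if isinstance(other, PositiveRegion):
            return self.members == other.members
        if isinstance(other, (set, frozenset)):
            return self.members == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.members)


def indiscernible(system: DecisionSystem, i: int, j: int,
                  B: Iterable[str], cfg: NeighborhoodConfig) -> bool:
    """True iff instances ``i`` and ``j`` are within threshold on every
    feature of ``B``.  Empty ``B`` makes all pairs indiscernible.
    Reflexive and symmetric by construction."""
    B = list(B)
    if not B:
        return True
    cols = [system.feature_index(a) for a in B]
    gaps = np.abs(system.values[i, cols] - system.values[j, cols])
    return bool(np.all(gaps <= cfg.thresholds(B)))


def _neighbor_matrix(system: DecisionSystem, B: Sequence[str],
                     cfg: NeighborhoodConfig) -> np.ndarray:
    """Boolean |U|x|U| matrix of the indiscernibility relation on B."""
    m = system.n_instances
    if not B:
        return np.ones((m, m), dtype=bool)
    cols = [system.feature_index(a) for a in B]
    X = system.values[:, cols]
    thr = cfg.thresholds(B)
    rel = np.ones((m, m), dtype=bool)
    for c in range(X.shape[1]):
        col = X[:, c]
        rel &= np.abs(col[:, None] - col[None, :]) <= thr[c]
    return rel


def positive_region(system: DecisionSystem, B: Iterable[str],
                    cfg: NeighborhoodConfig) -> PositiveRegion:
    """Lower approximation of the decision: ``x`` belongs iff every
    instance indiscernible from ``x`` on ``B`` shares its label.

    Monotone nondecreasing in ``B`` (shrinking neighborhoods can only
    add consistent instances)."""
    B = tuple(B)
    rel = _neighbor_matrix(system, B, cfg)
    labels = np.asarray(system.decisions, dtype=object)
    same = labels[:, None] == labels[None, :]
    consistent = ~np.any(rel & ~same, axis=1)
    members = frozenset(np.flatnonzero(consistent).tolist())
    return PositiveRegion(members=members, subset=B)


def core(system: DecisionSystem, cfg: NeighborhoodConfig) -> tuple[str, ...]:
    """Features whose removal from the full set shrinks the positive
    region — equivalently (for monotone POS) the intersection of all
    decision-relative reducts."""
    C = system.features
    full = positive_region(system, C, cfg)
    out = []
    for a in C:
        rest = tuple(b for b in C if b != a)
        if positive_region(system, rest, cfg) != full:
            out.append(a)
    return tuple(out)


def is_reduct(system: DecisionSystem, B: Iterable[str],
              cfg: NeighborhoodConfig) -> bool:
    """True iff ``B`` preserves the full positive region and contains no
    superfluous feature."""
    B = tuple(B)
    full = positive_region(system, system.features, cfg)
    pos_B = positive_region(system, B, cfg)
    if pos_B != full:
        return False
    for a in B:
        rest = tuple(b for b in B if b != a)
        if positive_region(system, rest, cfg) == pos_B:
            return False
    return True


def all_reducts(system: DecisionSystem, cfg: NeighborhoodConfig,
                max_features_guard: int = 20) -> list[tuple[str, ...]]:
    """Enumerate every decision-relative reduct (exponential; guarded)."""
    C = system.features
    if len(C) > max_features_guard:
        raise ValueError(
            f"{len(C)} features exceeds the exhaustive-search guard "
            f"({max_features_guard}); raise max_features_guard knowingly")
    from itertools import combinations

    full = positive_region(system, C, cfg)
    covering: list[tuple[str, ...]] = []
    for r in range(len(C) + 1):
        for B in combinations(C, r):
            if positive_region(system, B, cfg) == full:
                covering.append(B)
    cov_sets = [frozenset(B) for B in covering]
    reducts = []
    for B, Bs in zip(covering, cov_sets):
        if not any(other < Bs for other in cov_sets):
            reducts.append(B)
    return reducts


def min_cost_reduct(system: DecisionSystem, costs: TestCostVector,
                    cfg: NeighborhoodConfig,
                    max_features_guard: int = 20,
                    ) -> tuple[tuple[str, ...], float]:
    """Exact minimal-test-cost reduct by depth-first branch and bound.

    Searches feature-inclusion space in file order, pruning any branch
    whose partial cost already reaches the incumbent (admissible because
    all costs are positive).  Ties are broken by fewer features, then by
    feature order.  Refuses systems wider than ``max_features_guard``.
    """
    C = system.features
    n = len(C)
    if n > max_features_guard:
        raise ValueError(
            f"{n} features exceeds the exhaustive-search guard "
            f"({max_features_guard}); raise max_features_guard knowingly")
    full = positive_region(system, C, cfg)
    order = {a: r for r, a in enumerate(C)}

    best: dict = {"cost": np.inf, "subset": None, "key": None}

    def sort_key(subset: tuple[str, ...], cost: float):
        return (cost, len(subset), tuple(order[a] for a in subset))

    def visit(idx: int, chosen: list[str], cost: float) -> None:
        if cost > best["cost"]:
            return
        if positive_region(system, chosen, cfg) == full:
            key = sort_key(tuple(chosen), cost)
            if best["key"] is None or key < best["key"]:
                best["cost"] = cost
                best["subset"] = tuple(chosen)
                best["key"] = key
            return  # supersets only cost more
        if cost == best["cost"] or idx == n:
            return  # any extension strictly exceeds the incumbent
        a = C[idx]
        chosen.append(a)
        visit(idx + 1, chosen, cost + costs[a])
        chosen.pop()
        visit(idx + 1, chosen, cost)

    visit(0, [], 0.0)
    subset = best["subset"]
    # positive costs make the cheapest covering subset inclusion-minimal,
    # hence a reduct (dropping a member would lower cost while covering)
    return subset, subset_cost(subset, costs)
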