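"""Test-cost-sensitive decision systems.

A *decision system* is a table of instances described by numeric
conditional features together with one categorical decision (class)
label per instance.  In cost-sensitive settings every conditional
feature additionally carries a *test cost* — the money or time paid to
measure its value for one instance — and, for numeric measurements, an
*error range* ``e(a)``: the half-width of the measurement uncertainty,
taken here as a fixed fraction ``delta`` of the feature's mean value.

This module holds the data model (:class:`DecisionSystem`,
:class:`TestCostVector`, :class:`ErrorRangeVector`), CSV/JSON I/O,
min-max normalization, subset-cost arithmetic, the packaged liver-panel
fixture, and a synthetic-system generator used throughout the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionSystem",
    "TestCostVector",
    "ErrorRangeVector",
    "normalize",
    "error_ranges",
    "subset_cost",
    "read_system",
    "write_system",
    "read_costs",
    "write_costs",
    "fixture_liver_subtable",
    "fixture_liver_importance",
    "synthetic_system",
]


class ParseError(ValueError):
    """Raised when a decision-system file is malformed."""


@dataclass(frozen=True)
class DecisionSystem:
    """Instances × numeric conditional features plus decision labels.

    Parameters
    ----------
    instance_ids : sequence of str
        Ordered identifiers of the universe ``U``.
    features : sequence of str
        Ordered conditional-feature names ``C``.  File/generator order is
        preserved and acts as the global tie-breaking order downstream.
    values : (|U|, |C|) ndarray of float
        The information function: ``values[i, r]`` is feature ``r`` on
        instance ``i``.  No missing entries.
    decisions : sequence
        One categorical label per instance.
    name : str
        Free-text description.
    """

    instance_ids: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray
    decisions: tuple
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "instance_ids", tuple(self.instance_ids))
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "decisions", tuple(self.decisions))
        m, n = values.shape if values.ndim == 2 else (0, 0)
        if values.ndim != 2 or m < 1 or n < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if len(self.instance_ids) != m:
            raise ValueError("instance_ids length must match value rows")
        if len(self.features) != n:
            raise ValueError("features length must match value columns")
        if len(self.decisions) != m:
            raise ValueError("decisions length must match value rows")
        if not np.isfinite(values).all():
            raise ValueError("values must be finite with no missing entries")

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def column(self, feature: str) -> np.ndarray:
        """Return one feature's value column."""
        return self.values[:, self.feature_index(feature)]

    def feature_index(self, feature: str) -> int:
        try:
            return self.features.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def to_frame(self, decision_column: str = "decision") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.features),
                          index=list(self.instance_ids))
        df[decision_column] = list(self.decisions)
        return df


@dataclass(frozen=True)
class TestCostVector:
    """Per-feature positive test cost; subset cost is additive."""

    cost: Mapping[str, float]

    def __post_init__(self) -> None:
        cost = {str(k): float(v) for k, v in dict(self.cost).items()}
        if any(v <= 0 for v in cost.values()):
            raise ValueError("all test costs must be > 0")
        object.__setattr__(self, "cost", cost)

    def __getitem__(self, feature: str) -> float:
        try:
            return self.cost[feature]
        except KeyError:
            raise KeyError(f"no cost for feature {feature!r}") from None

    def features(self) -> tuple[str, ...]:
        return tuple(self.cost)


@dataclass(frozen=True)
class ErrorRangeVector:
    """Per-feature measurement-error half-widths ``e(a)``.

    ``e(a) = delta * mean_i a(x_i)``, kept at full precision; round only
    for display.
    """

    e: Mapping[str, float]
    delta: float = 0.1

    def __post_init__(self) -> None:
        e = {str(k): float(v) for k, v in dict(self.e).items()}
        if any(v < 0 for v in e.values()):
            raise ValueError("error ranges must be non-negative")
        object.__setattr__(self, "e", e)

    def __getitem__(self, feature: str) -> float:
        return self.e[feature]

    def displayed(self, decimals: int = 2) -> dict[str, float]:
        """Rounded copy for tabular display."""
        return {a: round(v, decimals) for a, v in self.e.items()}


def normalize(system: DecisionSystem) -> DecisionSystem:
    """Min-max scale every feature column to [0, 1].

    Each column is mapped ``y = (x - min) / (max - min)``.  A constant
    column (``max == min``) maps to all zeros: the value range collapses
    and the feature carries no discriminating information.  Idempotent.
    """
    values = system.values
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(values)
    nonconst = span > 0
    out[:, nonconst] = (values[:, nonconst] - lo[nonconst]) / span[nonconst]
    return replace(system, values=out)


def error_ranges(system: DecisionSystem, delta: float = 0.1) -> ErrorRangeVector:
    """Compute ``e(a) = delta * column mean`` for every feature.

    Assumes the system has already been min-max normalized, so the means
    (hence error ranges) live on the [0, 1] scale.
    """
    means = system.values.mean(axis=0)
    return ErrorRangeVector(
        e={a: delta * m for a, m in zip(system.features, means)},
        delta=delta,
    )


def subset_cost(subset: Iterable[str], costs: TestCostVector) -> float:
    """Total test cost of a feature subset; the empty set costs 0."""
    return float(sum(costs[a] for a in set(subset)))


def read_system(path, decision_column: str | None = None,
                name: str | None = None) -> DecisionSystem:
    """Read a decision system from a headered CSV.

    The first column is taken as the instance identifier when it is
    non-numeric; ``decision_column`` defaults to the last column.
    Missing or non-numeric conditional cells raise :class:`ParseError`
    naming the offending row and column.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least one feature and a decision column")
    first = df.columns[0]
    if not pd.api.types.is_numeric_dtype(df[first]):
        ids = [str(v) for v in df[first]]
        df = df.drop(columns=[first])
    else:
        ids = [str(i) for i in range(len(df))]
    if decision_column is None:
        decision_column = df.columns[-1]
    if decision_column not in df.columns:
        raise ParseError(f"{path}: decision column {decision_column!r} not found")
    decisions = tuple(df[decision_column])
    cond = df.drop(columns=[decision_column])
    for col in cond.columns:
        bad = cond[col].isna()
        if bad.any():
            row = ids[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        if not pd.api.types.is_numeric_dtype(cond[col]):
            coerced = pd.to_numeric(cond[col], errors="coerce")
            bad = coerced.isna()
            row = ids[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    return DecisionSystem(
        instance_ids=ids,
        features=tuple(cond.columns),
        values=cond.to_numpy(dtype=float),
        decisions=decisions,
        name=name or str(path),
    )


def write_system(system: DecisionSystem, path,
                 decision_column: str = "decision") -> None:
    """Write a decision system as CSV (instance id column first)."""
    df = system.to_frame(decision_column=decision_column)
    df.index.name = "id"
    df.to_csv(path)


def read_costs(path) -> TestCostVector:
    """Read a cost vector from two-column CSV (feature,cost) or JSON."""
    text = open(path).read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return TestCostVector(cost=json.loads(text))
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: cost CSV must have exactly two columns")
    return TestCostVector(cost=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1])))


def write_costs(costs: TestCostVector, path) -> None:
    pd.DataFrame({"feature": costs.features(),
                  "cost": [costs[a] for a in costs.features()]}
                 ).to_csv(path, index=False)


def _data_path(filename: str):
    return resources.files("costfs.data").joinpath(filename)


def fixture_liver_subtable() -> tuple[DecisionSystem, TestCostVector]:
    """The packaged 6-instance liver-panel subtable and its cost vector.

    Five blood-test features (Mcv, Alkphos, Sgpt, Sgot, Gammagt), already
    min-max normalized, with whole-dollar test costs (16, 20, 45, 28, 33)
    and binary disorder labels.
    """
    with resources.as_file(_data_path("liver_subtable.csv")) as p:
        system = read_system(p, decision_column="Selector", name="liver-subtable")
    with resources.as_file(_data_path("liver_costs.csv")) as p:
        costs = read_costs(p)
    return system, costs


def fixture_liver_importance() -> dict[str, float]:
    """Reference Laplacian-score importance vector for the liver panel.

    These published per-feature scores accompany the worked example and
    are shipped as *given inputs* for the downstream cost-weighting and
    selection examples; they are not an oracle for the affinity-graph
    pipeline on the 6-row subtable.
    """
    with resources.as_file(_data_path("liver_importance.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["feature"], df["ls"].astype(float)))


def synthetic_system(
    n_instances: int = 50,
    n_features: int = 10,
    n_classes: int = 2,
    n_informative: int = 4,
    n_redundant: int = 2,
    noise_sd: float = 0.05,
    seed: int | None = None,
    class_sep: float = 1.0,
    name: str = "synthetic",
) -> DecisionSystem:
    """Generate a normalized synthetic decision system.

    Informative features take class-dependent means (classes spread by
    ``class_sep``) plus Gaussian noise of scale ``noise_sd``; redundant
    features are near-copies of cycling informative ones (noise at a
    tenth of ``noise_sd``, floored at 1e-3 so copies are not byte-exact);
    the remaining features are pure uniform noise.  All columns are
    min-max normalized at the end, so values lie in [0, 1].  Deterministic
    under ``seed``.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative feature")
    if n_informative + n_redundant > n_features:
        raise ValueError(
            "n_informative + n_redundant must not exceed n_features "
            f"({n_informative} + {n_redundant} > {n_features})")
    if n_classes < 1:
        raise ValueError("need at least one class")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n_instances)
    values = np.empty((n_instances, n_features))
    for r in range(n_informative):
        centers = rng.permutation(n_classes) * class_sep
        values[:, r] = centers[labels] + rng.normal(0.0, noise_sd, n_instances)
    for j in range(n_redundant):
        src = j % n_informative
        copy_sd = max(noise_sd / 10.0, 1e-3)
        values[:, n_informative + j] = (
            values[:, src] + rng.normal(0.0, copy_sd, n_instances))
    n_noise = n_features - n_informative - n_redundant
    if n_noise:
        values[:, n_informative + n_redundant:] = rng.uniform(
            0.0, 1.0, (n_instances, n_noise))
    feats = (
        [f"inf{r}" for r in range(n_informative)]
        + [f"red{j}" for j in range(n_redundant)]
        + [f"noise{j}" for j in range(n_noise)]
    )
    system = DecisionSystem(
        instance_ids=tuple(f"x{i}" for i in range(n_instances)),
        features=tuple(feats),
        values=values,
        decisions=tuple(int(v) for v in labels),
        name=name,
    )
    return normalize(system)
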