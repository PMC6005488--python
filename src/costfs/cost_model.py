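"""Random test-cost generation for simulation experiments.

Real benchmark tables rarely ship test costs, so simulation studies draw
them at random, conventionally on [1, 100], from one of three families:

* ``uniform`` — every price equally likely;
* ``normal`` — prices cluster around the midpoint (few cheap tests);
* ``pareto`` — many cheap tests and a few expensive ones (heavy right
  skew), the regime where cost-aware selection pays off most.

Out-of-range draws are resampled rather than clipped, so no probability
mass piles up at the bounds.  Costs default to whole units (integer
dollars), matching how published cost vectors are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decision_system import TestCostVector

__all__ = ["CostDistributionSpec", "generate_costs"]

FAMILIES = ("uniform", "normal", "pareto")


@dataclass(frozen=True)
class CostDistributionSpec:
    """Configuration for one random cost draw.

    ``normal_mean``/``normal_sd`` default to ``(m+M)/2`` and ``(M-m)/6``
    so ~99.7% of the untruncated mass already falls inside [m, M];
    ``pareto_shape`` defaults to 2 with scale ``m``, giving the heavy
    right skew of a classic Pareto law.  All are overridable.
    """

    family: str = "uniform"
    low: float = 1.0
    high: float = 100.0
    normal_mean: float | None = None
    normal_sd: float | None = None
    pareto_shape: float = 2.0
    integer_costs: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not (0 < self.low <= self.high):
            raise ValueError("bounds must satisfy 0 < low <= high")
        if self.normal_sd is not None and self.normal_sd <= 0:
            raise ValueError("normal_sd must be > 0")
        if self.pareto_shape <= 0:
            raise ValueError("pareto_shape must be > 0")

    @property
    def mean(self) -> float:
        return self.normal_mean if self.normal_mean is not None else (self.low + self.high) / 2.0

    @property
    def sd(self) -> float:
        if self.normal_sd is not None:
            return self.normal_sd
        return max((self.high - self.low) / 6.0, 1e-12)


def _draw(rng: np.random.Generator, spec: CostDistributionSpec, size: int) -> np.ndarray:
    if spec.family == "uniform":
        return rng.uniform(spec.low, spec.high, size)
    if spec.family == "normal":
        return rng.normal(spec.mean, spec.sd, size)
    # classic Pareto with scale = low: X = low * (1 + pareto(shape))
    return spec.low * (1.0 + rng.pareto(spec.pareto_shape, size))


def generate_costs(spec: CostDistributionSpec,
                   features: Sequence[str],
                   rng: np.random.Generator | None = None) -> TestCostVector:
    """Draw one test cost per feature under ``spec``.

    Every cost lies in ``[low, high]``; out-of-range draws are resampled.
    With ``integer_costs`` the accepted draws are rounded to the nearest
    integer and re-clamped to the bounds.  Reproducible via ``spec.seed``
    (or an explicitly supplied generator, which takes precedence).
    """
    features = list(features)
    if not features:
        raise ValueError("feature list must be non-empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = len(features)
    out = np.empty(n)
    filled = 0
    if spec.low == spec.high:
        out[:] = spec.low
        filled = n
    while filled < n:
        draws = _draw(rng, spec, 2 * (n - filled))
        ok = draws[(draws >= spec.low) & (draws <= spec.high)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    if spec.integer_costs:
        out = np.clip(np.rint(out), np.ceil(spec.low), np.floor(spec.high))
    return TestCostVector(cost=dict(zip(features, out)))
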