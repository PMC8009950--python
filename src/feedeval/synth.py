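"""Synthetic-data generators emulating the study's data structures.

Three generators with known ground truth make every pipeline stage testable
without measured data:

* replicate nutrient panels — additive normal within-substrate noise
  truncated at zero, with per-analyte quantification limits emitting "<x"
  entries (composition replicates are well approximated as normal at the
  reported noise levels);
* juvenile growth series — a power law with multiplicative lognormal noise
  per replicate group (weights stay positive and variance grows with size);
* expert judgment matrices — log-normal jitter around the consistent matrix
  of a known priority vector, symmetrized to preserve reciprocity and
  clipped to the 1-9 judgment scale.

All randomness flows through a single integer seed per spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ahp import SCALE_MAX, SCALE_MIN, PairwiseMatrix, PriorityVector
from .growth import GrowthSeries
from .panels import AnalyteSeries, Censor, Measurement, NutrientPanel


@dataclass
class PanelSpec:
    """Ground truth for replicate composition panels.

    ``true_means``: substrate -> analyte -> mean; ``sds``: analyte -> within-
    substrate standard deviation; ``limits``: analyte -> quantification limit
    (draws below it are emitted as below-limit).  The default replicate count
    is the study design of triplicate measurements.
    """

    true_means: Mapping[str, Mapping[str, float]]
    sds: Mapping[str, float]
    n_replicates: int = 3
    limits: Mapping[str, float] = field(default_factory=dict)
    category: str = "amino_acid"
    unit: str = "g/100g"
    basis: str = "dry_weight"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need n >= 2 replicates")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("standard deviations must be non-negative")


def gen_panel(spec: PanelSpec) -> dict[str, NutrientPanel]:
    """Draw replicate panels: values ~ Normal(mean, sd) truncated at 0."""
    rng = np.random.default_rng(spec.seed)
    panels: dict[str, NutrientPanel] = {}
    for substrate, means in spec.true_means.items():
        panel = NutrientPanel(substrate=substrate, category=spec.category,
                              unit=spec.unit, basis=spec.basis)
        for analyte, mu in means.items():
            sd = spec.sds.get(analyte, 0.0)
            draws = np.clip(rng.normal(mu, sd, size=spec.n_replicates), 0.0, None)
            limit = spec.limits.get(analyte)
            reps = []
            for x in draws:
                if limit is not None and x < limit:
                    reps.append(Measurement(limit, Censor.BELOW_LIMIT, limit=limit))
                else:
                    reps.append(Measurement(float(x)))
            panel.analytes[analyte] = AnalyteSeries(reps, unit=spec.unit)
        panels[substrate] = panel
    return panels


@dataclass
class GrowthSpec:
    """Ground truth for power-law growth: BW(t) = a * t**b * exp(eps)."""

    a: float = 0.1479
    b: float = 1.8022
    times: Sequence[float] = tuple(range(5, 75, 5))
    n_groups: int = 3
    sigma: float = 0.1  # sd of the lognormal noise on the log scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def gen_growth(spec: GrowthSpec) -> GrowthSeries:
    """Simulate group-mean body weights with multiplicative lognormal noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    clean = spec.a * t**spec.b
    eps = rng.normal(0.0, spec.sigma, size=(t.size, spec.n_groups))
    return GrowthSeries(time=t, group_weights=clean[:, None] * np.exp(eps))


def gen_expert_matrices(
    true_weights: PriorityVector,
    jitter: float,
    n_experts: int,
    seed: int = 0,
) -> list[PairwiseMatrix]:
    """Near-consistent reciprocal matrices around a known priority vector.

    Upper-triangle entries are (w_j / w_k) * exp(delta) with
    delta ~ Normal(0, jitter^2); the lower triangle is filled with exact
    reciprocals and everything is clipped to the 1-9 scale.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    w = true_weights.weights
    n = w.size
    out = []
    for _ in range(n_experts):
        A = np.ones((n, n))
        for j in range(n):
            for k in range(j + 1, n):
                val = (w[j] / w[k]) * np.exp(rng.normal(0.0, jitter))
                val = float(np.clip(val, SCALE_MIN, SCALE_MAX))
                A[j, k] = val
                A[k, j] = 1.0 / val
        out.append(PairwiseMatrix(true_weights.items, A))
    return out
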