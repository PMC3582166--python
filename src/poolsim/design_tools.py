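"""Depth planning and pooled-vs-individual cost comparison.

Exome depth of a pool is planned from sequencer output:

    average depth = lanes * reads_per_lane * capture_efficiency / n_exons

Defaults describe an Illumina HiSeq 2000-class platform: ~120 million reads
per lane, ~50% of reads captured on target in practice (kits advertise 70%+),
and ~180,000 targeted exons.  One lane then yields 120e6 * 0.5 / 180,000 =
333.3x overall exome depth; note vendor rules of thumb often round this
towards 400x.

The cost model is linear: a per-lane sequencing price, a fixed library-prep
charge for the single pooled library, and a small per-sample charge for DNA
normalisation, versus a full per-sample library+sequencing price for
individual sequencing.  Default coefficients (2013 list prices, USD) are
1500/lane + 250 fixed + 2/pooled sample, and 625/individually-prepped sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PlatformModel",
    "CostModel",
    "average_depth",
    "per_sample_depth",
    "lanes_required",
    "pooled_cost",
    "individual_cost",
    "savings_percent",
]


@dataclass(frozen=True)
class PlatformModel:
    """Sequencer/capture characteristics used for depth arithmetic."""

    reads_per_lane: float = 120e6
    capture_efficiency: float = 0.5
    n_exons: int = 180_000

    def __post_init__(self) -> None:
        if self.reads_per_lane <= 0:
            raise ValueError("reads_per_lane must be positive")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must lie in (0, 1]")
        if self.n_exons <= 0:
            raise ValueError("n_exons must be positive")


@dataclass(frozen=True)
class CostModel:
    """Linear pricing of pooled versus individual sequencing (USD)."""

    per_lane_cost: float = 1500.0
    fixed_cost: float = 250.0
    per_pooled_sample_cost: float = 2.0
    per_individual_sample_cost: float = 625.0

    def __post_init__(self) -> None:
        for name in ("per_lane_cost", "fixed_cost", "per_pooled_sample_cost",
                     "per_individual_sample_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def average_depth(lanes: int, platform: PlatformModel = PlatformModel()) -> float:
    """Overall mean exome depth delivered by ``lanes`` sequencer lanes."""
    if lanes < 1:
        raise ValueError("lanes must be >= 1")
    return lanes * platform.reads_per_lane * platform.capture_efficiency / platform.n_exons


def per_sample_depth(mean_depth: float, n_samples: int) -> float:
    """Mean depth per pooled sample, lambda_ps = lambda_D / N_s."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    return mean_depth / n_samples


def lanes_required(
    target_per_sample_depth: float,
    n_samples: int,
    platform: PlatformModel = PlatformModel(),
) -> int:
    """Smallest lane count giving at least the target per-sample depth.

    Guidance for pooled designs: keep per-sample depth at 10x minimum, or
    20x when rare variants matter.
    """
    if target_per_sample_depth <= 0:
        raise ValueError("target_per_sample_depth must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    per_lane = average_depth(1, platform) / n_samples
    lanes = max(1, math.ceil(target_per_sample_depth / per_lane - 1e-12))
    while average_depth(lanes, platform) / n_samples < target_per_sample_depth:
        lanes += 1  # guard against float round-down
    return lanes


def pooled_cost(lanes: int, n_samples: int, model: CostModel = CostModel()) -> float:
    """Total price of sequencing one pooled library on ``lanes`` lanes."""
    if lanes < 1:
        raise ValueError("lanes must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return (
        model.per_lane_cost * lanes
        + model.fixed_cost
        + model.per_pooled_sample_cost * n_samples
    )


def individual_cost(n_samples: int, model: CostModel = CostModel()) -> float:
    """Total price of library prep + sequencing for each sample separately."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return model.per_individual_sample_cost * n_samples


def savings_percent(
    lanes: int, n_samples: int, model: CostModel = CostModel()
) -> float:
    """Individual cost as a percentage of the pooled cost (100 = parity)."""
    pooled = pooled_cost(lanes, n_samples, model)
    if pooled <= 0:
        raise ValueError("pooled cost must be positive")
    return 100.0 * individual_cost(n_samples, model) / pooled
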