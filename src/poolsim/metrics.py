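"""Accuracy metrics for pooled allele-frequency estimates.

The headline statistic is the *relative RMSE*: the root-mean-square error of
the pooled estimate F_hat over replicate simulations, divided by the target
frequency F.  Division by F puts frequencies from 0.5% to 50% on one scale —
an absolute error of 0.005 is trivial at F = 0.5 and catastrophic at
F = 0.005.  Simulated exome-wide datasets are scored instead with a per-SNP
symmetric error rate |F_hat - F| / ((F_hat + F) / 2).

`analytic_relative_rmse` is the closed form for the ideal model (equal
contributions, no bias, exact-F genotypes), under which
alt_reads | D ~ Binomial(D, F) and hence
Var(F_hat | D > 0) = F (1 - F) E[1/D | D > 0] with D ~ Poisson(lambda_D).
It serves as an independent oracle for the Monte-Carlo machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pool_model import SnpSimBatch

__all__ = [
    "EstimateSet",
    "SummaryStats",
    "relative_rmse",
    "symmetric_error_rate",
    "summarize_estimates",
    "analytic_relative_rmse",
    "mean_inverse_depth",
]


@dataclass(frozen=True)
class EstimateSet:
    """Replicate frequency estimates for one target frequency.

    Zero-depth replicates (undefined estimates) are removed before any metric
    is computed; their count is retained in ``n_excluded``.
    """

    estimates: np.ndarray
    target_frequency: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        object.__setattr__(self, "estimates", est)
        if np.isnan(est).any():
            raise ValueError("estimates must not contain NaN; use from_batch")
        if est.size and ((est < 0).any() or (est > 1).any()):
            raise ValueError("estimates must lie in [0, 1]")
        if self.n_excluded < 0:
            raise ValueError("n_excluded must be non-negative")

    @classmethod
    def from_batch(cls, batch: SnpSimBatch, target_frequency: Optional[float] = None):
        """Collect defined estimates from a simulation batch."""
        est = batch.estimated_frequencies
        keep = ~np.isnan(est)
        if target_frequency is None:
            targets = np.unique(batch.target_frequencies)
            if targets.size != 1:
                raise ValueError("batch holds multiple target frequencies")
            target_frequency = float(targets[0])
        return cls(
            estimates=est[keep],
            target_frequency=target_frequency,
            n_excluded=int((~keep).sum()),
        )

    @property
    def n(self) -> int:
        return int(self.estimates.size)


@dataclass(frozen=True)
class SummaryStats:
    """Five-number summary plus mean, sample variance and relative RMSE of a
    replicate set — the per-frequency row of a simulation report."""

    minimum: float
    q1: float
    median: float
    mean: float
    q3: float
    maximum: float
    variance: float
    relative_rmse: float

    FIELDS = ("minimum", "q1", "median", "mean", "q3", "maximum",
              "variance", "relative_rmse")

    def as_tuple(self):
        return tuple(getattr(self, f) for f in self.FIELDS)


def relative_rmse(est_set: EstimateSet) -> float:
    """sqrt(mean((F_hat_i - F)^2)) / F over the retained estimates."""
    if est_set.n == 0:
        raise ValueError("cannot compute relative RMSE of an empty set")
    f = est_set.target_frequency
    if f <= 0:
        raise ValueError("relative RMSE undefined at target frequency 0")
    rmse = math.sqrt(np.mean((est_set.estimates - f) ** 2))
    return rmse / f


def symmetric_error_rate(estimate, target):
    """|F_hat - F| / ((F_hat + F) / 2), the per-SNP accuracy of a single
    pooled measurement; 0 by convention when both arguments are 0.

    Symmetric in its arguments and bounded by 2.  Accepts arrays.
    """
    est = np.asarray(estimate, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if (est < 0).any() or (tgt < 0).any():
        raise ValueError("estimate and target must be non-negative")
    denom = (est + tgt) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, np.abs(est - tgt) / denom, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def summarize_estimates(est_set: EstimateSet) -> SummaryStats:
    """Order statistics (linear-interpolation quartiles), mean, sample
    variance (n-1 denominator) and relative RMSE of a replicate set."""
    if est_set.n == 0:
        raise ValueError("cannot summarise an empty estimate set")
    e = est_set.estimates
    q1, med, q3 = np.percentile(e, [25, 50, 75])
    return SummaryStats(
        minimum=float(e.min()),
        q1=float(q1),
        median=float(med),
        mean=float(e.mean()),
        q3=float(q3),
        maximum=float(e.max()),
        variance=float(e.var(ddof=1)) if est_set.n > 1 else 0.0,
        relative_rmse=relative_rmse(est_set),
    )


def mean_inverse_depth(mean_depth: float, tail_mass: float = 1e-12) -> float:
    """E[1/D | D > 0] for D ~ Poisson(mean_depth), by direct pmf summation
    truncated once the accumulated mass reaches 1 - ``tail_mass``."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    hi = int(mean_depth + 40 * math.sqrt(mean_depth) + 50)
    p_pos = 1.0 - math.exp(-mean_depth)
    while True:
        d = np.arange(1, hi + 1)
        pmf = stats.poisson.pmf(d, mean_depth)
        # float accumulation error over d terms bounds achievable closure
        slack = max(tail_mass, d.size * 1e-15)
        if pmf.sum() >= p_pos - slack:
            return float((pmf / d).sum() / p_pos)
        hi *= 2


def analytic_relative_rmse(frequency: float, mean_depth: float) -> float:
    """Closed-form relative RMSE of the ideal pooled estimator:
    sqrt(F (1-F) E[1/D | D>0]) / F."""
    if not 0.0 < frequency < 1.0:
        raise ValueError("frequency must lie strictly in (0, 1)")
    inv = mean_inverse_depth(mean_depth)
    return math.sqrt(frequency * (1.0 - frequency) * inv) / frequency
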