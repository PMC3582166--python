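"""Drivers for the three pooled-sequencing simulation studies.

* Study 1 (`run_sim1`): how pooling error variance sigma^2 and pool size
  affect the relative RMSE of the frequency estimate, at a fixed overall
  depth shared by all pool sizes.
* Study 2 (`run_sim2`): how mean depth *per pooled sample* (lambda_ps =
  lambda_D / N_s) trades off against pool size, under ideal pooling.
* Study 3 (`run_sim3`): exome-scale performance — each SNP is measured once,
  with its minor-allele frequency drawn from an empirical MAF distribution,
  and accuracy is scored by the per-dataset median symmetric error rate as a
  function of sequencer lane count.

Each grid cell gets its own child RNG stream derived from the master seed and
the cell's parameters, so results are reproducible cell-by-cell regardless of
grid composition or evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design_tools
from .metrics import EstimateSet, summarize_estimates, symmetric_error_rate
from .pool_model import (
    BiasModel,
    Composition,
    PoolDesign,
    SequencingDesign,
    simulate_snps,
)

__all__ = [
    "MafDistribution",
    "GRID_COLUMNS",
    "load_maf_distribution",
    "synthetic_maf_distribution",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "write_grid_tsv",
    "DEFAULT_POOL_SIZES",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_SIGMA2_VALUES",
    "DEFAULT_PER_SAMPLE_DEPTHS",
]

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = (200, 400, 800, 1600)
DEFAULT_FREQUENCIES = (0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
#: sigma^2 = 1e-5 is the "ideal pooling" setting; 1, 2, 4 correspond to
#: contribution standard deviations of 10%, 20% and 40% of the mean c = 10.
DEFAULT_SIGMA2_VALUES = (1e-5, 1.0, 2.0, 4.0)
DEFAULT_PER_SAMPLE_DEPTHS = (0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20)

GRID_COLUMNS = [
    "pool_size", "maf", "sigma2", "per_sample_depth", "mean_depth",
    "replicates", "n_excluded", "min", "q1", "median", "mean", "q3", "max",
    "var", "relative_rmse", "seed",
]


@dataclass(frozen=True)
class MafDistribution:
    """Discrete minor-allele-frequency distribution with sampling support."""

    frequencies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "weights", w)
        if f.size == 0 or f.size != w.size:
            raise ValueError("frequencies and weights must be non-empty and equal-length")
        if (f <= 0).any() or (f > 0.5).any():
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` frequencies with replacement."""
        return rng.choice(self.frequencies, size=n, p=self.weights)


def load_maf_distribution(path) -> MafDistribution:
    """Read a plain-text MAF table: one frequency per line, optional
    whitespace-separated weight, ``#`` comments.

    Frequencies above 0.5 are folded to the minor allele (f -> 1 - f);
    zero-frequency records are dropped (their count is logged) and the
    remaining weights renormalised.
    """
    freqs, weights = [], []
    n_zero = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            try:
                f = float(parts[0])
                w = float(parts[1]) if len(parts) > 1 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}: cannot parse line {lineno}: {raw!r}") from exc
            if not 0.0 <= f <= 1.0 or w < 0:
                raise ValueError(
                    f"{path}: line {lineno}: frequency must be in [0,1] and "
                    f"weight non-negative, got {raw!r}"
                )
            if f > 0.5:
                f = 1.0 - f
            if f == 0.0:
                n_zero += 1
                continue
            freqs.append(f)
            weights.append(w)
    if n_zero:
        logger.info("dropped %d zero-frequency records from %s", n_zero, path)
    if not freqs:
        raise ValueError(f"{path}: no usable frequency records")
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{path}: weights sum to zero")
    # collapse duplicate support points so weights describe a distribution
    df = pd.DataFrame({"f": freqs, "w": w / total}).groupby("f", as_index=False).sum()
    return MafDistribution(frequencies=df["f"].to_numpy(), weights=df["w"].to_numpy())


def synthetic_maf_distribution(
    n_points: int = 2000,
    shape_a: float = 0.3,
    shape_b: float = 2.5,
    seed: int = 0,
) -> MafDistribution:
    """A rare-allele-heavy stand-in for an empirical population MAF spectrum.

    Support points are Beta(shape_a, shape_b) draws folded to (0, 0.5], with
    equal weights.  The defaults concentrate most mass below 5% MAF, the
    qualitative shape of site-frequency spectra in large resequencing panels.
    Deterministic for a given seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if shape_a <= 0 or shape_b <= 0:
        raise ValueError("shape parameters must be positive")
    rng = np.random.default_rng(seed)
    draws = np.empty(0)
    while draws.size < n_points:
        batch = rng.beta(shape_a, shape_b, 2 * n_points)
        batch = np.minimum(batch, 1.0 - batch)
        batch = batch[batch > 0.0]
        draws = np.concatenate([draws, batch])
    f = np.sort(draws[:n_points])
    w = np.full(n_points, 1.0 / n_points)
    return MafDistribution(frequencies=f, weights=w)


def _cell_rng(seed: int, *key: float) -> np.random.Generator:
    """Child generator for one grid cell, independent of grid order."""
    entropy = [int(seed)] + [int(round(k * 1e9)) for k in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _grid_row(pool, seq, frequency, sigma2, replicates, rng, seed,
              bias=None, composition: Composition = "hardy_weinberg"):
    batch = simulate_snps(pool, seq, frequency, bias=bias,
                          composition=composition, replicates=replicates,
                          rng=rng)
    est = EstimateSet.from_batch(batch)
    s = summarize_estimates(est)
    lam = seq.mean_depth_for(pool.n_samples)
    return {
        "pool_size": pool.n_samples,
        "maf": frequency,
        "sigma2": sigma2,
        "per_sample_depth": lam / pool.n_samples,
        "mean_depth": lam,
        "replicates": replicates,
        "n_excluded": est.n_excluded,
        "min": s.minimum, "q1": s.q1, "median": s.median, "mean": s.mean,
        "q3": s.q3, "max": s.maximum, "var": s.variance,
        "relative_rmse": s.relative_rmse,
        "seed": seed,
    }


def run_sim1(
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    sigma2_values: Sequence[float] = DEFAULT_SIGMA2_VALUES,
    mean_depth: float = 2500.0,
    replicates: int = 10_000,
    seed: int = 0,
    composition: Composition = "hardy_weinberg",
) -> pd.DataFrame:
    """Pooling-error study: relative RMSE over a (pool size, MAF, sigma^2)
    grid at one overall mean depth shared by all pool sizes.

    The overall depth is a free parameter of the study design; 2500x is the
    default at which the ideal-pooling cells agree with the closed-form
    oracle across the MAF range.  Bias is disabled: this study isolates
    pooling and sampling variance.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for ns in pool_sizes:
        for sigma2 in sigma2_values:
            pool = PoolDesign(ns, contribution_mean=10.0, contribution_var=sigma2)
            seq = SequencingDesign(mean_depth=mean_depth)
            for f in frequencies:
                rng = _cell_rng(seed, 1, ns, f, sigma2, mean_depth)
                rows.append(_grid_row(pool, seq, f, sigma2, replicates, rng,
                                      seed, composition=composition))
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def run_sim2(
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    per_sample_depths: Sequence[float] = DEFAULT_PER_SAMPLE_DEPTHS,
    replicates: int = 10_000,
    seed: int = 0,
    composition: Composition = "hardy_weinberg",
) -> pd.DataFrame:
    """Depth study: relative RMSE over a (pool size, MAF, per-sample depth)
    grid under ideal pooling (sigma^2 = 1e-5) and no bias; the overall depth
    of each cell is lambda_ps * N_s."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sigma2 = 1e-5
    rows = []
    for ns in pool_sizes:
        pool = PoolDesign(ns, contribution_mean=10.0, contribution_var=sigma2)
        for lam_ps in per_sample_depths:
            seq = SequencingDesign(per_sample_depth=lam_ps)
            for f in frequencies:
                rng = _cell_rng(seed, 2, ns, f, lam_ps)
                rows.append(_grid_row(pool, seq, f, sigma2, replicates, rng,
                                      seed, composition=composition))
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def run_sim3(
    dist: MafDistribution,
    pool_size: int = 1092,
    lanes_list: Sequence[int] = (2, 4, 6, 8, 10, 12, 14, 16),
    n_snps: int = 10_000,
    repetitions: int = 1000,
    seed: int = 0,
    platform: design_tools.PlatformModel = design_tools.PlatformModel(),
    sigma2: float = 1e-5,
    bias: Optional[BiasModel] = None,
    composition: Composition = "hardy_weinberg",
) -> pd.DataFrame:
    """Exome-scale study: per-lane-count distribution of the per-dataset
    error rate when every SNP is measured once.

    For each lane count, each repetition draws ``n_snps`` target frequencies
    from ``dist``, simulates one pooled measurement per SNP at the depth the
    lanes deliver, and scores the dataset by the median (and mean) symmetric
    error rate across its SNPs.  Reported per lane count: the median and
    quartiles of the per-repetition medians, and the median of the
    per-repetition means.
    """
    if dist.frequencies.size == 0:
        raise ValueError("empty MAF distribution")
    if n_snps < 1 or repetitions < 1:
        raise ValueError("n_snps and repetitions must be >= 1")
    pool = PoolDesign(pool_size, contribution_mean=10.0, contribution_var=sigma2)
    rows = []
    for lanes in lanes_list:
        lam = design_tools.average_depth(lanes, platform)
        seq = SequencingDesign(mean_depth=lam)
        rep_medians = np.empty(repetitions)
        rep_means = np.empty(repetitions)
        for rep in range(repetitions):
            rng = _cell_rng(seed, 3, lanes, rep)
            freqs = dist.sample(n_snps, rng)
            batch = simulate_snps(pool, seq, freqs, bias=bias,
                                  composition=composition, rng=rng)
            keep = ~np.isnan(batch.estimated_frequencies)
            err = symmetric_error_rate(
                batch.estimated_frequencies[keep], batch.target_frequencies[keep]
            )
            rep_medians[rep] = np.median(err)
            rep_means[rep] = err.mean()
        q1, med, q3 = np.percentile(rep_medians, [25, 50, 75])
        rows.append({
            "lanes": lanes,
            "mean_depth": lam,
            "per_sample_depth": lam / pool_size,
            "pool_size": pool_size,
            "n_snps": n_snps,
            "repetitions": repetitions,
            "median_error": med,
            "q1_error": q1,
            "q3_error": q3,
            "median_of_mean_error": float(np.median(rep_means)),
            "seed": seed,
        })
    return pd.DataFrame(rows)


def write_grid_tsv(df: pd.DataFrame, path) -> None:
    """Serialise a result grid as TSV (deterministic formatting, so identical
    seeds give byte-identical files)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
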