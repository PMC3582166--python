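"""Generative model of one pooled-sequencing measurement of a SNP.

A pool mixes DNA from ``n_samples`` individuals without barcodes, so a read
cannot be assigned to its sample and the alternative-allele frequency must be
estimated from the pooled read ratio.  The measurement chain modelled here:

1. Each sample contributes an amount of DNA ``c + eps_i`` with
   ``eps_i ~ Normal(0, sigma^2)`` (pipetting / library-prep error).
2. The probability a read originates from sample *i* is its contribution
   share ``p_i = (c + eps_i) / sum_j (c + eps_j)``.
3. Sequencing depth at the SNP is ``D ~ Poisson(lambda_D)`` where ``lambda_D``
   is the mean exome depth of the pool.
4. Reads are allocated to samples ``(R_1..R_Ns) ~ Multinomial(D, p)``.
5. A homozygous-alt sample turns all its reads into alt reads; a heterozygote
   turns each of its reads into an alt read with probability *P*, the per-SNP
   allele balance.  Absent mapping bias *P* = 0.5; with reference-allele
   preferential bias ``P ~ Normal(mu_P, sigma_P^2)`` clamped to [0, 1], drawn
   once per SNP and shared by all heterozygous carriers.
6. The estimator is the raw ratio ``F_hat = alt_reads / D``.

`simulate_snp` composes these steps literally, one SNP at a time.
`simulate_snps` is a vectorised replicate driver that exploits two exact
distributional identities (the sum of multinomial counts over a fixed subset
of categories is binomial with the summed probability, and a sum of binomials
sharing one success probability is binomial) to run tens of thousands of
replicates in a few numpy calls.  The two paths sample the same law; tests
verify this against brute-force lattice enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

__all__ = [
    "PoolingError",
    "PoolDesign",
    "SequencingDesign",
    "BiasModel",
    "GenotypeVector",
    "SnpSimResult",
    "SnpSimBatch",
    "DEFAULT_MEAN_BALANCE",
    "DEFAULT_BALANCE_VAR",
    "draw_contributions",
    "contribution_probabilities",
    "assign_genotypes",
    "draw_depth",
    "allocate_reads",
    "draw_alt_reads",
    "estimate_frequency",
    "simulate_snp",
    "simulate_snps",
]

#: Mean heterozygote allele balance observed in exome DNA sequencing data;
#: the shortfall below 0.5 reflects reference-allele preferential mapping.
DEFAULT_MEAN_BALANCE = 0.483
#: Between-sample variance of the per-sample mean balances (33 exome samples
#: across three capture platforms), used as the default spread of P.
DEFAULT_BALANCE_VAR = 1.3027e-4

Composition = Literal["hardy_weinberg", "all_het_preferred"]


class PoolingError(ValueError):
    """Raised when a pool configuration or realisation is unusable."""


@dataclass(frozen=True)
class PoolDesign:
    """Pool composition: size, ideal per-sample DNA contribution, and the
    variance of the per-sample pooling error.

    Parameters
    ----------
    n_samples:
        Number of individuals mixed into the pool (N_s).
    contribution_mean:
        Ideal DNA amount each sample adds (c), arbitrary units.  Only the
        ratio sigma/c matters for the read-share distribution.
    contribution_var:
        Variance sigma^2 of the additive pooling error.
    """

    n_samples: int
    contribution_mean: float = 10.0
    contribution_var: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise PoolingError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.contribution_mean <= 0:
            raise PoolingError("contribution_mean must be positive")
        if self.contribution_var < 0:
            raise PoolingError("contribution_var must be non-negative")


@dataclass(frozen=True)
class SequencingDesign:
    """Depth parameterisation: overall mean depth lambda_D or mean depth per
    pooled sample lambda_ps = lambda_D / N_s.  Exactly one may be given; the
    other is derived once the pool size is known."""

    mean_depth: Optional[float] = None
    per_sample_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean_depth is None and self.per_sample_depth is None:
            raise PoolingError("give mean_depth or per_sample_depth")
        for v, name in ((self.mean_depth, "mean_depth"),
                        (self.per_sample_depth, "per_sample_depth")):
            if v is not None and v <= 0:
                raise PoolingError(f"{name} must be positive, got {v}")

    def mean_depth_for(self, n_samples: int) -> float:
        """Overall Poisson mean depth lambda_D for a pool of ``n_samples``."""
        if self.mean_depth is not None:
            if self.per_sample_depth is not None:
                expect = self.per_sample_depth * n_samples
                if abs(self.mean_depth - expect) > 1e-9 * max(1.0, expect):
                    raise PoolingError(
                        "mean_depth and per_sample_depth disagree: "
                        f"{self.mean_depth} != {expect}"
                    )
            return float(self.mean_depth)
        return float(self.per_sample_depth * n_samples)


@dataclass(frozen=True)
class BiasModel:
    """Reference-allele preferential bias: the per-SNP heterozygote allele
    balance P is drawn from Normal(mean_balance, balance_var), clamped to
    [0, 1].  ``mean_balance`` below 0.5 biases frequency estimates downward."""

    mean_balance: float = DEFAULT_MEAN_BALANCE
    balance_var: float = DEFAULT_BALANCE_VAR

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_balance < 1.0:
            raise PoolingError("mean_balance must lie strictly in (0, 1)")
        if self.balance_var < 0:
            raise PoolingError("balance_var must be non-negative")

    def draw_balance(self, rng: np.random.Generator, size=None):
        """One clamped Normal draw of P per SNP."""
        p = rng.normal(self.mean_balance, math.sqrt(self.balance_var), size)
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class GenotypeVector:
    """Per-sample alternative-allele dosages (0, 1 or 2) realising a pool
    frequency, plus the target frequency they encode."""

    genotypes: np.ndarray
    target_frequency: float

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int64)
        object.__setattr__(self, "genotypes", g)
        if not 0.0 <= self.target_frequency <= 1.0:
            raise PoolingError("target_frequency must lie in [0, 1]")
        if g.size == 0 or not np.isin(g, (0, 1, 2)).all():
            raise PoolingError("genotypes must be a non-empty vector of {0,1,2}")
        expected = round(2 * g.size * self.target_frequency)
        if int(g.sum()) != expected:
            raise PoolingError(
                f"total dosage {int(g.sum())} != round(2*n*F) = {expected}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.size)

    @property
    def n_het(self) -> int:
        return int(np.count_nonzero(self.genotypes == 1))

    @property
    def n_hom_alt(self) -> int:
        return int(np.count_nonzero(self.genotypes == 2))


@dataclass(frozen=True)
class SnpSimResult:
    """One simulated pooled measurement of a SNP.

    ``estimated_frequency`` is ``alt_reads / depth``, or NaN when the Poisson
    depth came out zero (no reads, nothing to estimate)."""

    depth: int
    alt_reads: int
    estimated_frequency: float
    target_frequency: float

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise PoolingError("need 0 <= alt_reads <= depth")


@dataclass
class SnpSimBatch:
    """Vectorised replicate output: one entry per simulated SNP."""

    depths: np.ndarray
    alt_reads: np.ndarray
    estimated_frequencies: np.ndarray  # NaN where depth == 0
    target_frequencies: np.ndarray

    def __len__(self) -> int:
        return int(self.depths.size)

    @property
    def n_excluded(self) -> int:
        """Replicates with zero depth (estimate undefined)."""
        return int(np.count_nonzero(self.depths == 0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "depth": self.depths,
                "alt_reads": self.alt_reads,
                "est_freq": self.estimated_frequencies,
                "target_freq": self.target_frequencies,
            }
        )


# ---------------------------------------------------------------------------
# elementary operations


def draw_contributions(design: PoolDesign, rng: np.random.Generator) -> np.ndarray:
    """Realised DNA amounts c + eps_i, clamped below at zero.

    A sample cannot remove DNA from the pool, so negative Normal draws are
    clamped; for the regimes of interest (sigma <= 0.4 c) the clamp fires with
    probability below 1e-6 and normality is effectively preserved.
    """
    amounts = rng.normal(
        design.contribution_mean,
        math.sqrt(design.contribution_var),
        design.n_samples,
    )
    np.clip(amounts, 0.0, None, out=amounts)
    if not amounts.any():
        raise PoolingError(
            "all contributions clamped to zero; pooling variance is too large "
            "relative to the mean contribution"
        )
    return amounts


def contribution_probabilities(contributions: Sequence[float]) -> np.ndarray:
    """Read-origin probabilities p_i = amount_i / sum(amounts)."""
    amounts = np.asarray(contributions, dtype=float)
    if amounts.size == 0 or (amounts < 0).any():
        raise PoolingError("contributions must be non-negative and non-empty")
    total = amounts.sum()
    if total <= 0:
        raise PoolingError("contributions sum to zero; probabilities undefined")
    return amounts / total


def _genotype_counts(n_samples: int, frequency: float, composition: Composition):
    """(n_hom_alt, n_het, n_hom_ref) with exact total dosage round(2nF)."""
    if not 0.0 <= frequency <= 1.0:
        raise PoolingError(f"frequency must lie in [0, 1], got {frequency}")
    total = round(2 * n_samples * frequency)
    if composition == "all_het_preferred":
        # as many heterozygotes as the dosage total permits
        if total <= n_samples:
            n2, n1 = 0, total
        else:
            n2, n1 = total - n_samples, 2 * n_samples - total
    elif composition == "hardy_weinberg":
        n2 = round(n_samples * frequency**2)
        n1 = round(2 * n_samples * frequency * (1 - frequency))
        n1 = min(n1, n_samples - n2)
        # shift samples between adjacent dosage classes until exact
        d = total - (2 * n2 + n1)
        while d != 0:
            n0 = n_samples - n2 - n1
            if d > 0:
                if n0 > 0:
                    n1 += 1
                else:
                    n1 -= 1
                    n2 += 1
                d -= 1
            else:
                if n1 > 0:
                    n1 -= 1
                else:
                    n2 -= 1
                    n1 += 1
                d += 1
    else:
        raise PoolingError(f"unknown composition {composition!r}")
    n0 = n_samples - n2 - n1
    assert 2 * n2 + n1 == total and min(n0, n1, n2) >= 0
    return n2, n1, n0


def assign_genotypes(
    n_samples: int,
    frequency: float,
    composition: Composition = "hardy_weinberg",
) -> GenotypeVector:
    """Deterministically assign per-sample genotypes realising ``frequency``.

    The total alt dosage is exactly ``round(2 * n_samples * frequency)`` —
    the pool frequency is a fixed property of the cohort, not a random draw.
    ``hardy_weinberg`` rounds the HWE class expectations n F^2 / 2n F(1-F) /
    n (1-F)^2 and shifts samples between adjacent classes to hit the dosage
    exactly; ``all_het_preferred`` maximises the heterozygote count.
    """
    n2, n1, n0 = _genotype_counts(n_samples, frequency, composition)
    genotypes = np.concatenate(
        [np.full(n2, 2), np.full(n1, 1), np.zeros(n0, dtype=np.int64)]
    ).astype(np.int64)
    return GenotypeVector(genotypes=genotypes, target_frequency=frequency)


def draw_depth(seq: SequencingDesign, rng: np.random.Generator,
               n_samples: Optional[int] = None) -> int:
    """One Poisson(lambda_D) draw of the SNP depth."""
    lam = seq.mean_depth if seq.mean_depth is not None else seq.mean_depth_for(n_samples)
    return int(rng.poisson(lam))


def allocate_reads(
    depth: int, probs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Multinomial(depth, p) allocation of reads to samples."""
    p = np.asarray(probs, dtype=float)
    if depth < 0:
        raise PoolingError("depth must be non-negative")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise PoolingError("probs must be a probability vector")
    return rng.multinomial(depth, p)


def draw_alt_reads(
    allocation: Sequence[int],
    genotypes: GenotypeVector,
    bias: Optional[BiasModel],
    rng: np.random.Generator,
) -> int:
    """Alternative-allele reads given per-sample read counts and genotypes.

    Homozygous-ref samples contribute none of their reads; homozygous-alt
    contribute all; each heterozygote contributes Binomial(R_i, P) with one
    shared per-SNP balance P (0.5 exactly when ``bias`` is None).  There is
    no sequencing-error term: a sample with no alt allele never emits an alt
    read.
    """
    alloc = np.asarray(allocation, dtype=np.int64)
    g = genotypes.genotypes
    if alloc.size != g.size:
        raise PoolingError(
            f"allocation length {alloc.size} != n_samples {g.size}"
        )
    if (alloc < 0).any():
        raise PoolingError("allocation counts must be non-negative")
    balance = 0.5 if bias is None else float(bias.draw_balance(rng))
    alt = int(alloc[g == 2].sum())
    het_reads = int(alloc[g == 1].sum())
    if het_reads:
        alt += int(rng.binomial(het_reads, balance))
    return alt


def estimate_frequency(alt_reads: int, depth: int) -> float:
    """The pooled estimator F_hat = alt_reads / depth; NaN at zero depth."""
    if depth < 0 or alt_reads < 0 or alt_reads > depth:
        raise PoolingError("need 0 <= alt_reads <= depth")
    if depth == 0:
        return float("nan")
    return alt_reads / depth


def simulate_snp(
    pool: PoolDesign,
    seq: SequencingDesign,
    frequency: float,
    bias: Optional[BiasModel] = None,
    composition: Composition = "hardy_weinberg",
    rng: Optional[np.random.Generator] = None,
    contributions: Optional[np.ndarray] = None,
) -> SnpSimResult:
    """Simulate one pooled measurement by composing the elementary steps.

    Contributions and genotypes are drawn fresh per SNP (each replicate is an
    independent pooled experiment); pass ``contributions`` to reuse one fixed
    pool realisation across SNPs instead.
    """
    rng = np.random.default_rng() if rng is None else rng
    if contributions is None:
        contributions = draw_contributions(pool, rng)
    probs = contribution_probabilities(contributions)
    genotypes = assign_genotypes(pool.n_samples, frequency, composition)
    depth = draw_depth(seq, rng, pool.n_samples)
    allocation = allocate_reads(depth, probs, rng)
    alt = draw_alt_reads(allocation, genotypes, bias, rng)
    return SnpSimResult(
        depth=depth,
        alt_reads=alt,
        estimated_frequency=estimate_frequency(alt, depth),
        target_frequency=frequency,
    )


# ---------------------------------------------------------------------------
# vectorised replicate driver


def _subset_probability_sums(pool, n2, n1, n, rng):
    """Per-replicate read-share totals of the hom-alt and het sample classes.

    Contributions are iid, so "the first n2 samples are hom-alt, the next n1
    het" loses no generality; per-row prefix sums handle replicate-varying
    class sizes.  With zero pooling variance the shares are exact fractions
    and no draws are needed.
    """
    ns = pool.n_samples
    if pool.contribution_var == 0.0:
        return n2 / ns, n1 / ns
    amounts = rng.normal(
        pool.contribution_mean, math.sqrt(pool.contribution_var), (n, ns)
    )
    np.clip(amounts, 0.0, None, out=amounts)
    cs = np.cumsum(amounts, axis=1)
    totals = cs[:, -1]
    if not totals.all():
        raise PoolingError("a replicate drew an all-zero contribution vector")
    rows = np.arange(n)
    s2 = np.where(n2 > 0, cs[rows, np.maximum(n2 - 1, 0)], 0.0)
    s12 = np.where(n2 + n1 > 0, cs[rows, np.maximum(n2 + n1 - 1, 0)], 0.0)
    return s2 / totals, (s12 - s2) / totals


def simulate_snps(
    pool: PoolDesign,
    seq: SequencingDesign,
    frequencies: Union[float, Sequence[float]],
    bias: Optional[BiasModel] = None,
    composition: Composition = "hardy_weinberg",
    replicates: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SnpSimBatch:
    """Simulate many independent pooled SNP measurements at once.

    ``frequencies`` is either a scalar (with ``replicates`` copies simulated)
    or one target frequency per SNP.  Same law as `simulate_snp`: the alt-read
    total decomposes exactly as R_homalt + Binomial(R_het_total, P) where
    (R_homalt, R_het_total) are the multinomial class totals, themselves a
    binomial chain given the depth.
    """
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.ndim == 0:
        if replicates is None or replicates < 1:
            raise PoolingError("scalar frequency requires replicates >= 1")
        freqs = np.full(replicates, float(freqs))
    elif replicates is not None and replicates != freqs.size:
        raise PoolingError("replicates disagrees with frequencies length")
    n = freqs.size

    # genotype class counts per SNP (deterministic given F)
    n2 = np.empty(n, dtype=np.int64)
    n1 = np.empty(n, dtype=np.int64)
    for f in np.unique(freqs):
        c2, c1, _ = _genotype_counts(pool.n_samples, float(f), composition)
        mask = freqs == f
        n2[mask] = c2
        n1[mask] = c1

    p2, p1 = _subset_probability_sums(pool, n2, n1, n, rng)

    lam = seq.mean_depth_for(pool.n_samples)
    depths = rng.poisson(lam, n)

    r2 = rng.binomial(depths, p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(p2 < 1.0, p1 / (1.0 - p2), 0.0)
    r1 = rng.binomial(depths - r2, np.clip(q, 0.0, 1.0))

    if bias is None:
        balance = 0.5
    else:
        balance = bias.draw_balance(rng, n)
    alt = r2 + rng.binomial(r1, balance)

    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(depths > 0, alt / depths, np.nan)
    return SnpSimBatch(
        depths=depths,
        alt_reads=alt,
        estimated_frequencies=est,
        target_frequencies=freqs,
    )
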