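"""Heterozygote allele balance from VCF genotype + allelic-depth data.

Allele balance at a heterozygous site is the fraction of reads supporting the
alternative allele, alt / (ref + alt).  Free of artefacts it should average
0.5; in real DNA sequencing it sits slightly below (reference-allele
preferential mapping: reads carrying the alternative allele are harder to
align to the reference).  This module measures per-sample balance from any
VCF with GT and AD fields, summarises it per sample, and fits the
`BiasModel` the pool simulator consumes (mean and between-sample variance of
the per-sample mean balances).

Balances are taken from the AD annotation as called, not recomputed from
reads.  Only biallelic SNVs contribute; multiallelic and indel records are
skipped and counted.  `generate_vcf_fixture` writes a synthetic VCF with a
known true balance so the whole chain is testable without external data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .pool_model import BiasModel

__all__ = [
    "BalanceRecord",
    "BalanceSummary",
    "het_allele_balances",
    "summarize_balance",
    "fit_bias_model",
    "generate_vcf_fixture",
    "save_bias_model",
    "load_bias_model",
]

logger = logging.getLogger(__name__)


@dataclass
class BalanceRecord:
    """Per-sample allele balances, one per contributing heterozygous site."""

    sample_id: str
    balances: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.balances, dtype=float)
        self.balances = b
        if b.size and ((b < 0).any() or (b > 1).any()):
            raise ValueError("balances must lie in [0, 1]")


@dataclass(frozen=True)
class BalanceSummary:
    """Quantiles, mean and 95% normal-approximation CI of the mean of one
    sample's heterozygote allele balances."""

    sample_id: str
    minimum: float
    q1: float
    median: float
    mean: float
    q3: float
    maximum: float
    ci_low: float
    ci_high: float
    n_sites: int


def _is_het(gt) -> bool:
    if gt is None:
        return False
    alleles = [a for a in gt if a is not None]
    return sorted(alleles) == [0, 1]


def het_allele_balances(vcf_path, min_total_depth: int = 1):
    """Measure alt/(ref+alt) at heterozygous biallelic SNVs, per sample.

    Sites contribute when the genotype is 0/1 (any phasing) and the summed
    allelic depth is at least ``min_total_depth`` (default 1, i.e. no depth
    filter beyond having reads).  Multiallelic and indel records are skipped
    with a logged count.  A missing AD annotation raises, naming the record.
    """
    import pysam

    balances: dict[str, list] = {}
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        balances = {s: [] for s in samples}
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in "ACGT"
                or alts[0] not in "ACGT"
            ):
                n_skipped += 1
                continue
            for s in samples:
                call = rec.samples[s]
                if not _is_het(call.get("GT")):
                    continue
                ad = call.get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
                    raise ValueError(
                        f"missing AD annotation for sample {s} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                ref_d, alt_d = int(ad[0]), int(ad[1])
                total = ref_d + alt_d
                if total >= max(min_total_depth, 1):
                    balances[s].append(alt_d / total)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records in %s", n_skipped, vcf_path)
    return [
        BalanceRecord(sample_id=s, balances=np.asarray(balances[s]))
        for s in samples
    ]


def summarize_balance(record: BalanceRecord) -> BalanceSummary:
    """Per-sample summary: linear-interpolation quantiles and the 95% CI of
    the mean (mean +/- 1.96 sd / sqrt(n)).  Requires at least 2 sites."""
    b = record.balances
    if b.size < 2:
        raise ValueError(
            f"sample {record.sample_id}: need >= 2 heterozygous sites, have {b.size}"
        )
    q1, med, q3 = np.percentile(b, [25, 50, 75])
    mean = float(b.mean())
    half = 1.96 * float(b.std(ddof=1)) / math.sqrt(b.size)
    return BalanceSummary(
        sample_id=record.sample_id,
        minimum=float(b.min()),
        q1=float(q1),
        median=float(med),
        mean=mean,
        q3=float(q3),
        maximum=float(b.max()),
        ci_low=mean - half,
        ci_high=mean + half,
        n_sites=int(b.size),
    )


def fit_bias_model(summaries: Sequence[BalanceSummary]) -> BiasModel:
    """Fit the reference-bias parameters from per-sample summaries:
    mean_balance = mean of the per-sample means (unweighted), balance_var =
    their sample variance (n-1).  Requires at least 2 samples."""
    if len(summaries) < 2:
        raise ValueError("need >= 2 per-sample summaries to fit a bias model")
    means = np.asarray([s.mean for s in summaries], dtype=float)
    return BiasModel(
        mean_balance=float(means.mean()),
        balance_var=float(means.var(ddof=1)),
    )


_BASES = ("A", "C", "G", "T")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=poolsim-synthetic-fixture
##contig=<ID=1,length=249250621>
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def generate_vcf_fixture(
    n_samples: int,
    n_sites: int,
    true_balance: Union[float, Sequence[float]],
    depth_mean: float = 60.0,
    seed: int = 0,
    out_path="fixture.vcf",
    het_fraction: float = 0.6,
):
    """Write a synthetic VCFv4.2 with a known heterozygote allele balance.

    Every nominal site is a biallelic SNV; per sample the genotype is het
    with probability ``het_fraction`` (alt depth ~ Binomial(total,
    true_balance), total ~ Poisson(depth_mean)), otherwise hom-ref or
    hom-alt.  Indel and multiallelic decoy records (one per ~25 SNV sites)
    are appended to exercise the record filters.  ``true_balance`` may be a
    scalar or one value per sample.

    Returns a dict with the path, record counts, and the per-sample number
    of heterozygous sites with at least one read (the sites a
    ``min_total_depth=1`` measurement must recover).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    balance = np.broadcast_to(
        np.asarray(true_balance, dtype=float), (n_samples,)
    ).copy()
    if ((balance <= 0) | (balance >= 1)).any():
        raise ValueError("true_balance must lie strictly in (0, 1)")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    het_pass_counts = dict.fromkeys(sample_ids, 0)
    n_decoys = n_sites // 25

    lines = [_VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(sample_ids)]
    pos = 1000
    for i in range(n_sites):
        pos += int(rng.integers(10, 500))
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        fields = [f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP"]
        u = rng.random(n_samples)
        totals = rng.poisson(depth_mean, n_samples)
        for j, sid in enumerate(sample_ids):
            d = int(totals[j])
            if u[j] < het_fraction:
                alt_d = int(rng.binomial(d, balance[j]))
                gt, ad = "0/1", (d - alt_d, alt_d)
                if d >= 1:
                    het_pass_counts[sid] += 1
            elif u[j] < het_fraction + (1 - het_fraction) / 2:
                gt, ad = "0/0", (d, 0)
            else:
                gt, ad = "1/1", (0, d)
            fields.append(f"{gt}:{ad[0]},{ad[1]}:{d}")
        lines.append("\t".join(fields))
    # decoy records the measurement must skip
    for k in range(n_decoys):
        pos += int(rng.integers(10, 500))
        decoy_calls = "\t".join(["0/1:10,10:20"] * n_samples)
        if k % 2 == 0:  # indel
            lines.append(f"1\t{pos}\t.\tAT\tA\t.\tPASS\t.\tGT:AD:DP\t{decoy_calls}")
        else:  # multiallelic SNV
            calls = "\t".join(["0/1:10,5,5:20"] * n_samples)
            lines.append(f"1\t{pos}\t.\tA\tC,G\t.\tPASS\t.\tGT:AD:DP\t{calls}")
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {
        "path": str(out_path),
        "n_snv_records": n_sites,
        "n_decoy_records": n_decoys,
        "het_pass_counts": het_pass_counts,
    }


def save_bias_model(bias: BiasModel, path) -> None:
    """Serialise a fitted bias model as JSON."""
    with open(path, "w") as fh:
        json.dump(
            {"mean_balance": bias.mean_balance, "balance_var": bias.balance_var},
            fh,
            indent=2,
        )


def load_bias_model(path) -> BiasModel:
    with open(path) as fh:
        d = json.load(fh)
    return BiasModel(mean_balance=d["mean_balance"], balance_var=d["balance_var"])
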