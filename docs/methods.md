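# Methods

## The measurement model

`poolsim` treats one pooled SNP measurement as a four-stage stochastic chain:
pooling → depth → read allocation → allele sampling.

**Pooling.** Sample *i* contributes c + ε_i units of DNA, ε_i ~ N(0, σ²) iid.
The constant c (default 10, arbitrary units) only sets the scale; accuracy
depends on σ/c, the coefficient of variation of the contribution. Draws are
clamped below at zero (a sample cannot subtract DNA); for the regimes studied
(σ² ≤ 4 at c = 10, i.e. CV ≤ 40%) the clamp fires with probability < 1e-6,
so the Normal shape is effectively intact. If a replicate nevertheless draws
an all-zero vector, the pool is unusable and the code raises rather than
silently renormalising.

**Genotypes.** The pool's true frequency F is a fixed property of the
cohort, so genotypes are assigned *deterministically* with total alt dosage
exactly round(2·N_s·F). Two compositions are offered: `hardy_weinberg`
(default) rounds the HWE class expectations N_s·F², 2N_s·F(1−F), N_s·(1−F)²
and shifts samples between adjacent dosage classes until the dosage is
exact; `all_het_preferred` maximises the heterozygote count. Sampling
genotypes binomially instead would add cohort-sampling variance on top of
measurement variance (≈ +20% RMSE at F = 0.5, N_s = 200, 1x/sample) and is
deliberately not what the estimator-accuracy studies measure.

**Depth and allocation.** D ~ Poisson(λ_D); reads are split across samples
as Multinomial(D, p) with p_i the contribution shares. λ_D can be given
directly, per pooled sample (λ_ps = λ_D/N_s), or derived from sequencer
lanes via depth = lanes · reads_per_lane · capture_efficiency / n_exons
(defaults 120e6 reads/lane, 0.5 efficiency, 180,000 exons, i.e. 333.3x per
lane — note that platform marketing often rounds this figure up towards
400x; the code returns the formula's value).

**Allele sampling.** Dosage-2 samples convert all their reads to alt reads;
each heterozygote converts reads with probability P, the per-SNP allele
balance. P = 0.5 exactly when bias is disabled. With bias enabled,
P ~ N(µ_P, σ_P²) clamped to [0, 1] is drawn **once per SNP and shared by all
heterozygous carriers** — allele balance is a per-site alignment property,
which is also how it is measured from VCFs (per site, then aggregated per
sample). Defaults µ_P = 0.483, σ_P² = 1.30e-4 come from the mean and
between-sample variance of per-sample mean heterozygote balances in 33
exome-sequenced samples spanning three capture platforms. There is no
sequencing-error term: a pool with no alt allele never yields an alt read,
matching a model whose focus is pooling and sampling variance, not base
calling.

**Estimator.** F̂ = alt/D. When the Poisson depth is 0 the estimate is
undefined (NaN); such replicates are excluded from all metrics and their
count is reported (`n_excluded`). At the depths of interest (≥ 100x) the
event is vanishingly rare.

## Metrics

Relative RMSE √(Σ(F̂_i − F)²/n)/F puts MAFs from 0.5% to 50% on one scale.
Quartiles use linear interpolation between order statistics (numpy default);
variance uses the n−1 denominator. The per-SNP symmetric error rate
|F̂ − F|/((F̂+F)/2) is bounded by 2 and defined as 0 when both arguments are
0. The closed form for the ideal model, √(F(1−F)·E[1/D | D>0])/F, evaluates
E[1/D | D>0] by direct Poisson-pmf summation over a window of λ ± 40√λ
(doubled until the captured mass is within max(1e-12, n·1e-15) of P(D>0);
the floor accounts for float accumulation across the summed terms).

## Vectorised engine

`simulate_snp` composes the chain literally, one SNP at a time.
`simulate_snps` runs many replicates at once using two exact identities:
the multinomial counts summed over a fixed subset of categories are
Binomial(D, Σp_i), and a sum of binomials sharing one success probability is
binomial. The alt count therefore reduces to
R_homalt + Binomial(R_het, P) with (R_homalt, R_het) a conditional binomial
chain given D. Because contributions are iid, "the first n₂ samples are
hom-alt" loses no generality, and per-replicate prefix sums of the
contribution matrix give the class shares. The reduction is validated two
ways in the suite: a two-sample KS test against the literal op-composition
path, and a χ² test against exact enumeration of the
Poisson × multinomial × binomial lattice for a 2-sample pool (depth mass
truncated at 1 − 1e-9, states pooled below expectation 5, α = 0.001).

## The three studies

- **Pooling-error study** (`run_sim1`): grid over pool size
  {200, 400, 800, 1600} × MAF {0.5…50%} × σ² {1e-5, 1, 2, 4} at one overall
  depth shared by all pool sizes; 10,000 replicates per cell. The overall
  depth is a free design parameter, default 2500x — the value at which the
  ideal-pooling (σ² = 1e-5) cells agree with the closed-form oracle across
  the MAF range. Bias is disabled in this and the depth study, which
  isolate pooling/sampling variance.
- **Depth study** (`run_sim2`): grid over per-sample depth
  {0.5 … 20} × pool size × MAF under ideal pooling; λ_D = λ_ps · N_s.
- **Exome-scale study** (`run_sim3`): each SNP is measured *once*. Per
  repetition, n_snps target MAFs are drawn from an empirical MAF
  distribution, one pooled measurement is simulated per SNP at the depth a
  given lane count delivers, and the dataset is scored by the median
  symmetric error rate over its SNPs (the median, not the mean, because
  rare-MAF-dominated means are unstable; the per-repetition mean is emitted
  alongside). Reported per lane count: median and quartiles of the
  per-repetition medians. Defaults: pool 1092, 10,000 SNPs, 1000
  repetitions, ideal pooling, no bias.

Seeding: a master seed plus the cell's parameters feed a
`numpy.random.SeedSequence`, so every grid cell has its own stream and
reproduces byte-identically regardless of which other cells run.

## Synthetic inputs

**MAF spectrum.** `load_maf_distribution` consumes any plain-text frequency
table (optional weights, `#` comments, major-allele folding, zero-frequency
records dropped and logged). When no table is supplied,
`synthetic_maf_distribution` provides a stand-in: Beta(0.3, 2.5) draws
folded to (0, 0.5], equal weights — a rare-heavy spectrum with most mass
below 5% MAF, qualitatively like the site-frequency spectrum of a large
resequencing panel. It is *not* calibrated to any real panel, so
exome-study error levels under it are indicative only; orderings (more
lanes → lower error) are the claims the tests assert. With a real
panel-derived table the 2-lane/16-lane medians land near 30%/5%.

**VCF fixtures.** `generate_vcf_fixture` writes a plain VCFv4.2 with GT/AD/DP
fields and known true balance (het alt depth ~ Binomial(total, balance),
total ~ Poisson(depth_mean)), plus indel and multiallelic decoy records that
the measurement must skip. It emulates called genotypes with clean AD
annotations; it does not emulate genotyping error, depth-dependent balance,
or multi-chromosome structure, so passing round-trip tests demonstrates the
measurement/fitting chain, not robustness to miscalled sites.

## Allele-balance measurement

Heterozygous (0/1, any phasing), biallelic SNV records contribute
alt/(ref+alt) per sample, taken from the AD annotation as called. The depth
filter defaults to 1 (no filter beyond having reads). Per-sample summaries
use linear-interpolation quantiles and a Normal 95% CI of the mean;
`fit_bias_model` sets µ_P to the unweighted mean of per-sample means and
σ_P² to their n−1 variance. Unweighted (rather than site-count-weighted)
means keep each sample's capture platform equally represented.

## Problem sizes and runtime

Replicate counts follow the studies: 10,000 per grid cell for the RMSE
studies and the acceptance script. The exome-scale acceptance check runs a
reduced design — 1000 SNPs × 50 repetitions × lanes {2, 4, 8, 16} at pool
1092 — which bounds the Monte-Carlo noise of each per-repetition median
well below the lane-to-lane differences it asserts; the full 10,000 × 1000
design is available through `run_sim3`/the CLI. The whole test suite runs
in well under a minute on one CPU.

## Known limitations

- No read-level simulation: no base-call errors, no mapping-quality
  filtering, no FASTQ/variant calling. The estimator is the raw read ratio.
- The cost model is a linear interpolant of 2013 list prices (1500/lane,
  250 fixed, 2 per pooled sample, 625 per individually prepped sample);
  treat the defaults as placeholders for current quotes.
- One ambiguity is resolved as an option: contributions are redrawn for
  every simulated SNP (each replicate an independent pooled experiment);
  passing `contributions=` to `simulate_snp` freezes one pool realisation
  instead. The fixed-pool mode makes no claim of correspondence to the
  published studies.
- The printed ideal-case series the 2500x default reproduces contains one
  internally inconsistent entry (MAF 40%, printed 0.030 where the closed
  form and every consistent depth give ≈ 0.0245); comparisons skip it.
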