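# poolsim

Error simulation and design planning for **pooled (non-barcoded) DNA
sequencing** studies.

Sequencing one library made from the mixed DNA of hundreds of individuals is
far cheaper than sequencing them separately, but the reads cannot be assigned
to individuals: a SNP's alternative-allele frequency must be estimated from
the pooled read ratio. `poolsim` quantifies how accurate that estimate is as
a function of pool size, sequencing depth, pooling error, and reference-allele
mapping bias — and converts lane counts into depth and study cost so designs
can be planned before any DNA is pooled.

## Model

For a pool of N<sub>s</sub> samples, one SNP measurement is generated as:

- per-sample DNA contribution c + ε<sub>i</sub>, with ε<sub>i</sub> ~
  N(0, σ²); the read-origin probabilities are
  p<sub>i</sub> = (c + ε<sub>i</sub>) / Σ<sub>j</sub>(c + ε<sub>j</sub>)
- depth D ~ Poisson(λ<sub>D</sub>), with λ<sub>D</sub> planned from sequencer
  lanes: depth = lanes × reads/lane × capture efficiency / #exons
- read allocation (R<sub>1</sub>, …, R<sub>N<sub>s</sub></sub>) ~
  Multinomial(D, p)
- a homozygous-alt carrier turns all of its reads into alt reads; each
  heterozygote contributes Binomial(R<sub>i</sub>, P) alt reads, where P is
  the per-SNP allele balance — 0.5 absent bias, or drawn from
  N(µ<sub>P</sub>, σ<sub>P</sub>²) to model the reference-allele preferential
  mapping observed in real exome data (mean balance 0.483 across 33 samples
  from three capture platforms)
- the estimator is F̂ = alt reads / D

Accuracy is scored by the **relative RMSE**
√(Σ(F̂<sub>i</sub> − F)²/n) / F over replicate simulations, and — for
simulated exome datasets where each SNP is measured once — by the per-SNP
symmetric error rate |F̂ − F| / ((F̂ + F)/2). Under ideal pooling the
relative RMSE has the closed form √(F(1−F)·E[1/D | D>0]) / F, which the
package uses as an independent oracle for its Monte-Carlo engine.

## Worked example

```python
import numpy as np
from poolsim import (PoolDesign, SequencingDesign, simulate_snps,
                     EstimateSet, relative_rmse, analytic_relative_rmse,
                     lanes_required, pooled_cost, individual_cost, savings_percent)

pool = PoolDesign(n_samples=200, contribution_mean=10.0, contribution_var=1e-5)
seq = SequencingDesign(per_sample_depth=1.0)          # 200x overall
rng = np.random.default_rng(1)
batch = simulate_snps(pool, seq, frequencies=0.5, replicates=10_000, rng=rng)
est = EstimateSet.from_batch(batch)
print(f"simulated relative RMSE : {relative_rmse(est):.4f}")
print(f"closed-form prediction  : {analytic_relative_rmse(0.5, 200):.4f}")

lanes = lanes_required(10.0, 1000)
print(f"lanes for 10x/sample    : {lanes}")
print(f"pooled cost (16 lanes)  : ${pooled_cost(16, 1000):,.0f}")
print(f"individual cost         : ${individual_cost(1000):,.0f}")
print(f"savings                 : {savings_percent(16, 1000):.0f}%")
```

prints

```
simulated relative RMSE : 0.0710
closed-form prediction  : 0.0709
lanes for 10x/sample    : 30
pooled cost (16 lanes)  : $26,250
individual cost         : $625,000
savings                 : 2381%
```

A pool of 200 people sequenced at only 1x per sample estimates a common
(F = 0.5) allele to about ±7% relative error; a rare allele at the same depth
is several times worse (run the grid: `poolsim sim2`). The planning tools say
a 1000-sample pool needs 30 HiSeq-class lanes to reach the recommended 10x
per sample, and that pooling the library costs ~24x less than individually
prepping the same cohort.

The same machinery is scriptable from the shell: `poolsim sim1|sim2|sim3`
emit TSV result grids, `poolsim plan`/`cost` do the design arithmetic, and
`poolsim allele-balance`/`make-fixture` measure heterozygote allele balance
from a VCF (GT+AD fields) and fit the bias model the simulator consumes.

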