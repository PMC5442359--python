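# hicsig

Significant chromatin-interaction calling from Hi-C contact matrices with a
**hurdle zero-truncated negative binomial (ZTNB) null model**.

## The problem

Hi-C counts the paired-end reads joining every pair of genomic intervals.
Most of those counts come from random polymer ligation — which decays with
genomic distance and is biased by GC content, mappability and restriction
site density — not from specific chromatin loops.  Calling an interaction
therefore means asking: *is this bin pair's count larger than the background
predicts?*  Hi-C counts are both overdispersed (variance ≫ mean) and
zero-inflated (library drop-out), and models that ignore either property
(binomial, Poisson, plain NB) inflate significance and flood the results
with false positives.

`hicsig` is for computational genomicists who want calibrated per-bin-pair
P values at sub-TAD resolution, without pre-normalizing the matrix.

## The model

For interaction bin (i, j) with count y_ij, distance d_ij and bias
covariates x_ij:

```
P(y = 0)      = pi0_ij                    pi0_ij = logit^-1(gamma' x_ij)
P(y | y > 0)  = ZTNB(mu_ij, alpha)        log mu_ij = beta' x_ij
x_ij          = [ B_1(d_ij) … B_6(d_ij),  z(log gc_i·gc_j),  z(log map_i·map_j) ]
```

where B_1..B_6 is an order-3 B-spline basis on [0, 2 Mb] with inner knots at
the 25/50/75% distance quantiles, alpha is one NB2 dispersion per chromosome
(variance mu + alpha·mu²), and z(·) is a per-chromosome z-score over all
enumerated records.  Fitting is two-pass: fit on a random sample of records,
drop records in the P < 0.025 upper tail of their fitted law as candidate
true interactions, refit.  Each record then gets the upper-tail P value
`P(Y >= y_ij)` and a genome-wide Benjamini–Hochberg q value; O/E
normalization divides y by the fitted hurdle mean.

Downstream analyses: hotspot tracks (per-bin max −log10 P), genomic and
epigenomic bin annotation with distance-band Fisher enrichment and rank-sum
pooling, A/B compartment calls from PC1 of the contact correlation matrix,
without-replacement downsampling with precision–recall evaluation, and
long-range promoter–promoter network extraction.  A synthetic-data module
generates toy genomes and ground-truth hurdle counts so the whole pipeline
is testable offline.  See `docs/methods.md` for assumptions and numerics.

## Worked example

```python
from hicsig import synthetic, hurdle_model

# a seeded toy world: 800 kb chromosome, ~50k interaction records,
# counts drawn from a known hurdle-ZTNB law with 1% spiked interactions
scen = synthetic.SimulationScenario(seed=1)
sim = synthetic.simulate_scenario(scen, spikes=True)
records = sim["records"]

fit = hurdle_model.estimate_null(records, sample_frac=1.0, seed=1,
                                 max_distance=scen.max_distance)
scored = hurdle_model.score_records(records, fit)
called = hurdle_model.call_significant(scored, fdr=0.01)
print(f"alpha = {fit.alpha:.3f}  (truth {scen.alpha})")
print(f"significant at 1% FDR: {int(called['significant'].sum())} "
      f"of {len(called)} records ({len(sim['truth'])} spiked)")
```

prints (seed 1):

```
alpha = 0.249  (truth 0.3)
significant at 1% FDR: 96 of 50530 records (442 spiked)
```

The fitted dispersion is close to (slightly below) the generating value —
the outlier-trimming pass deliberately shaves the upper tail — and the 96
calls at 1% FDR recover a subset of the 442 planted spikes (many spikes at
large distance have tiny means and are genuinely undetectable; on unspiked
null data the same pipeline calls essentially nothing).

The same pipeline from the shell:

```bash
hicsig simulate --seed 1 --out sim/
hicsig call --fasta sim/genome.fa --pairs sim/pairs.tsv \
            --sample-frac 1.0 --seed 1 --fdr 0.01 --out run
hicsig enrich --records run.records.tsv --bins run.bins.tsv --out enr
```

`call` writes `run.bins.tsv`, `run.records.tsv` (one row per interaction
bin: d, y, mu, pi0, p, q, oe), `run.significant.bedpe`,
`run.hotspots.bedgraph`, per-chromosome fit JSONs and a run summary.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on a seeded
synthetic world — toy genome, covariates, two-pass null fit, P values, FDR
calls, hotspot and downsampling checks — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
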