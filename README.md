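# lumispan

Survival-curve inference and 96-well plate normalization for *C. elegans*
lifespan and bioluminescent-biosensor assays.

## The problem

Lifespan assays in liquid culture score ~100 nematodes alive or dead at
regular timepoints; the quantity of interest is the **median lifespan**,
the time at which 50% of the population is still alive, with a confidence
interval that honestly reflects both sampling noise and any
extra-binomial variability of the counts. In parallel, bioluminescent
biosensor strains report metabolic status through per-well light output in
96-well plates, where well-to-well variation in worm number forces
averaging over groups of wells and expressing results relative to a
solvent control.

`lumispan` implements both pipelines as a tested library:

* **Survival model.** Alive counts `y_i ~ Binomial(n_i, p(t_i))` with
  `logit p(t) = β₀ + β₁t + … + β_d t^d`, degree `d ∈ {1, 3}` (linear or
  cubic), fitted by iteratively reweighted least squares. A Pearson
  overdispersion parameter `φ = χ²/df`, floored at 1, scales the
  coefficient covariance so that counts noisier than binomial widen — and
  never narrow — the intervals.
* **Median inversion.** The median lifespan is the descending root of
  `η(t) = Σ β_k t^k = 0` (survival falling through 50%), located by a
  dense grid scan plus bisection to 10⁻⁹ days.
* **Percentile bootstrap.** Alive counts are resampled per timepoint from
  `Binomial(n_i, p̂_i)` at the *observed* proportions, the model refitted,
  and the 2.5th/97.5th percentiles of the bootstrap medians taken as the
  95% interval.
* **Plate reduction.** Background subtraction, aggregation of ≥5-well
  groups into technical replicates (mean ± SEM), and percent-of-control
  normalization against the solvent arm.
* **Synthetic data.** Seeded generators for both designs: beta-binomial
  lifespan counts under a known logit-polynomial survival curve, and
  plate wells with truncated-normal worm counts (mean 30, range 17–45)
  and log-normal luminescence noise.

## Worked example

The numbered scripts under `analysis/` run the full loop on synthetic
data. `analysis/01_simulate_lifespan.py` draws three arms from known
cubic-logit curves; `03_median_bootstrap.py` then prints:

```
    arm  median           95% CI  truth
 medium   20.95 ( 20.35,  21.56)  20.62
   DMSO   18.72 ( 18.13,  19.33)  19.07
    SSE   15.05 ( 14.42,  15.60)  15.79
```

Each row is the estimated median lifespan in days from a cubic fit to one
simulated assay (100 worms scored every 2 days, days 2–34), the
percentile-bootstrap interval (B = 1000), and the generating curve's true
median. Estimates track the truth to within a day; a 95% interval that
misses its target (as the SSE arm's does here) is exactly what a 5% miss
rate looks like in a three-arm snapshot. `04_coverage_study.py` checks
the miss rate systematically (50 replicates, coverage 98% at nominal
95%), and `05_plate_normalization.py` closes the plate loop: a simulated
0.55× metabolic effect is read back as

```
 DMSO @ 4 h:  100.0% of control (SEM 6.3, n=3 replicates)
  SSE @ 4 h:   55.4% of control (SEM 1.8, n=3 replicates)
```

The same operations are scriptable via the `lumispan` CLI
(`simulate-lifespan`, `simulate-plate`, `fit`, `median`, `coverage`,
`normalize`), with every stochastic command requiring an explicit
`--seed` and every output JSON embedding the resolved configuration.

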