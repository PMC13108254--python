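# herbdamage

Ancient-DNA damage and decay analysis for herbarium and museum specimens.

DNA in preserved specimens degrades through two dominant post-mortem
processes: depurination-driven fragmentation of the backbone and cytosine
deamination at fragment ends. `herbdamage` quantifies both from shotgun
sequencing data of historical collections (merged single-end alignments or
pre-tallied damage tables) and models how damage accumulates with specimen
age and the climate at the collection site. It is written for researchers
screening herbarium or museum libraries for genuine degraded DNA and for
studies of DNA preservation itself.

## What it computes

Per library:

- **endogenous fraction** `e = mapped / total reads`;
- **fragment-length summary**: lognormal fit (log-mean, log-SD) and the
  empirical median of merged-read lengths;
- **damage fraction per site** `λ`: surviving fragment lengths under random
  per-bond breakage are exponentially distributed, so `λ` is minus the
  slope of `ln(count_L)` on length `L` (fit accepted when R² > 0.95 and
  P < 0.05);
- **terminal deamination**: the first-base 5′ C>T frequency `f_CT(1)`
  (mirrored 3′ G>A), authenticated by fitting
  `f(p) = A·e^(−r(p−1)) + c` over the first 20 positions (sample kept when
  R² > 0.5 and the one-sided amplitude test gives P < 0.05);
- **divergence correction**: `d_corr = max(0, f_CT(1) − b)` where `b` is
  the mean frequency of the ten non-deamination substitution types.

Per cohort (after applying the >5,000-read, λ and authentication gates):

- the **decay rate** `k` (per site per year) as the slope of `λ` on age,
  following `λ = k·age`, per genus and overall;
- **ANCOVA** (`metric ~ age × genus`, sequential sums of squares) with a
  nested-model F-test deciding whether damage accumulates at different
  rates in different genera;
- **variance partitioning** of each metric over up to four blocks
  (temperature, precipitation, age, genus) on the adjusted-R² scale, with
  unique-fraction significance from Freedman–Lane residual permutation.

A synthetic-cohort generator (`herbdamage.simulate`) reproduces the
statistical structure these analyses assume — geometric fragment lengths
with `λ = k·age`, exponentially decaying terminal C>T over a uniform
divergence baseline, genus-structured climate covariates, age-independent
endogenous fractions — with full ground truth recorded, so the whole
pipeline is testable without any sequencing data.

## Worked example

Estimating the decay rate from a simulated 200-sample cohort built with
`k = 2.08e-4` (`python examples/decay_rate.py`):

```
true k    : 2.080e-04 per site per year
fitted k  : 2.075e-04  (95% CI 2.060e-04 .. 2.090e-04)
R2 = 0.998, P = 2e-267, n = 200
```

Each library's λ comes from its own length-spectrum fit; regressing those
200 λ values on specimen age recovers the planted per-site, per-year
breakage rate, with a heteroscedasticity-robust confidence interval
covering the truth. The other scripts in `examples/` walk through
per-sample profiling and gating, authentication of damage profiles, and
the cohort-level ANCOVA/variance-partition analyses.

The same pipeline is scriptable from the shell:

```bash
herbdamage simulate --seed 1 --out cohort/
herbdamage profile cohort/SYN* --metadata cohort/metadata.tsv --out prof/
herbdamage cohort prof/sample_metrics.tsv --out stats/
```

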