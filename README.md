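# survscan

Optimal-cutpoint survival stratification with an honest permutation p-value,
univariate Cox hazard ratios per 2-fold expression change, a joint
two-variable threshold search, signed Monte-Carlo overlap tests for
differentially-expressed gene sets, and the TMM / log2(FPKM+1) expression
preparation these analyses consume.

The package is aimed at translational bioinformaticians who relate the
expression of a gene or splice isoform — e.g. the variant-exon-containing
vs standard CD44 isoforms in colorectal cancer cohorts — to overall or
progression-free survival, and who need the statistics of that workflow to
be explicit, seeded and testable rather than buried in a notebook.

## The statistics at the core

**Cutpoint scan.** For a cohort with covariate x (log2 expression), every
quantile level q ∈ {0.10, 0.11, …, 0.90} defines a threshold c_q; patients
with x > c_q form the high group and the two-group log-rank statistic
χ²(q) = (ΣO − ΣE)²/ΣV is computed over the distinct event times. The
optimal cutpoint maximizes χ²(q).

**Permutation correction.** Choosing the cutoff by maximizing the statistic
inflates the type-I error badly (the naive χ²₁ p of the winning split
rejects a true null ~40% of the time at nominal 5% in our simulations).
The permutation test shuffles (time, event) against the fixed expression
vector N = 10 000 times, re-optimizes the cutoff *within every
permutation*, and reports p = #{null max > observed max}/N (an add-one
variant is also reported).

**Cox model.** h(t|x) = h₀(t)·exp(βx), Newton-fitted on the Efron partial
likelihood; since x is log2 expression, HR = e^β is the hazard ratio per
2-fold expression increase, with CI e^(β±1.96·se).

**Universal threshold.** For two variables on a shared scale, the level
maximizing the average of the two log-rank statistics when both cohorts
are split at the same absolute value.

**Signed overlap.** Two DEG sets (FDR < 0.05, |FC| ≥ 1.5, each gene signed
by its direction of change) are compared by concordant / discordant /
total intersection counts against a Monte-Carlo null that redraws both
sets uniformly from the gene universe with random signs; in "shared" mode
the null is exactly hypergeometric.

**Expression prep.** TMM normalization (matches edgeR's
`calcNormFactors` to ~1e-10), TMM-scaled log2(FPKM+1), filterByExpr-style
background filtering, and linear-scale isoform ratios.

## Worked example

```python
import numpy as np
from survscan import CohortSpec, CutpointSurvival, simulate_cohort

cohort, truth = simulate_cohort(
    CohortSpec(n=400, hr_high=2.5, cut_quantile=0.5, seed=11)
)
print("planted:", truth)
res = CutpointSurvival(cohort).fit(n_permutations=2000, seed=11)
print(res.summary())
```

prints

```
planted: {'effect': 'step', 'threshold': 6.689, 'cut_quantile': 0.5,
          'hr_high': 2.5, 'event_fraction': 0.86}
Optimal-cutpoint survival stratification
----------------------------------------
n = 400, events = 344
grid: 0.10..0.90 (81 levels, 0 skipped)
optimal cutpoint: level 0.52 (threshold 6.7615), log-rank chi2 = 79.4710
permutation p (2000 perms, strict): 0  [strict 0, add-one 0.0004998]
naive chi2(1) p (no selection correction): 4.893e-19
Cox univariate (ties=efron): beta=0.2340 (se=0.0360), HR per 2-fold=1.264
[1.178, 1.356], Wald p=8.12e-11, n=400, events=344
```

Reading it: the generator planted a hazard step (HR 2.5) at the median of
the expression distribution (threshold 6.689 on the log2 scale); the scan
recovered quantile level 0.52 / threshold 6.76. None of the 2000
re-optimized permutation maxima exceeded the observed statistic of 79.5,
so the strict permutation p is 0 (add-one bound 1/2001 ≈ 5e-4). The Cox
HR of 1.26 per 2-fold increase is the log-linear summary of an effect that
is actually a step — the stratified and the regression views answer
different questions and both are reported. `res.km_curves()` returns the
low/high Kaplan-Meier coordinates, `res.scan.to_table()` the full scan.

The same machinery is scriptable:

```bash
survscan simdata cohort --seed 2 --out sim/           # cohort + ground truth
survscan surv cutscan --survival sim/cohort.tsv --expr expr.tsv \
    --gene GENE1 --n-perm 10000 --seed 1 --out out/
survscan overlap test --a de_a.tsv --b de_b.tsv --universe 19000 \
    --mode concordant --n-iter 10000 --seed 1 --out out/
survscan pipeline run --config config.yaml            # end-to-end, one report
```

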