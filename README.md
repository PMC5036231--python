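# limbertail

Tools for cohort-based case-control analysis of **limber tail** (acute
self-resolving flaccidity of the canine tail, also called cold tail,
swimmer's tail or frozen tail) from owner-reported data, built around
the design used with the UK Dogslife Labrador Retriever cohort: most
episodes never reach a veterinary practice, so disease burden and risk
factors have to be estimated from what owners report online.

The package is aimed at veterinary epidemiologists working with
owner-reported cohort data. It implements the full pipeline:

1. **Synthetic cohort generation** (`limbertail.synthetic`) — a
   single-generation sire/dam pedigree with Dirichlet-multinomial
   offspring allocation, owner covariates, a logistic disease model
   with a sire-level random effect, free-text illness reports and tail
   questionnaires, all seeded and with ground truth exposed for testing.
2. **Keyword screening** (`limbertail.screening`) — candidate incidents
   are texts containing "tail" plus one of thirteen keyword stems
   (`cold, dead, droopy, drop, limb, limber, limp, rudder, staved,
   stiff, stride, swim, swimmers`); "tail" without a keyword goes to a
   manual-review queue driven by a reproducible overrides file.
3. **Case/control classification** (`limbertail.classify`) — the case
   definition is *some degree of tail flaccidity with no alternative
   cause reported*; provisional cases without limpness are excluded,
   provisional controls with unexplained limpness are promoted.
4. **Exact inference** (`limbertail.epi` / `limbertail.exact2x2`) —
   Clopper-Pearson binomial intervals for incidences; for 2×2 exposure
   tables the conditional maximum-likelihood odds ratio (the maximiser
   of the noncentral hypergeometric likelihood given both margins),
   exact conditional confidence intervals (minimum-likelihood ordering
   by default, Blaker and central available) and Fisher's exact test;
   logistic regression for latitude/longitude risk with Wald intervals.
5. **Pedigree permutation test** (`limbertail.permutation`) — do case
   dogs share sires (or dams) more than random same-size samples from
   the cohort? The contribution statistic for a sample grouped by
   parent with counts c₁..c_k is Σcᵢ²/Σcᵢ (offspring-weighted; the
   plain mean n/k is also reported), compared against a Monte-Carlo
   null with upper-tail p = (1 + #{null ≥ observed})/(n_perm + 1).
   An exhaustive-enumeration oracle is included.

## Worked example

The swimming exposure table — 36 of 38 cases swam against 68 of 86
controls — and the working-dog table (6 working cases, 32 non-working
cases, 3 working controls, 83 non-working controls):

```python
>>> from limbertail import ContingencyTable2x2, exact_or_estimate, clopper_pearson_ci
>>> swim = exact_or_estimate(ContingencyTable2x2(36, 2, 68, 18))
>>> round(swim.or_point, 1), round(swim.ci_low, 1), round(swim.ci_high, 1), round(swim.p_value, 2)
(4.7, 1.1, 30.0, 0.03)
>>> work = exact_or_estimate(ContingencyTable2x2(6, 32, 3, 83))
>>> round(work.or_point, 1), round(work.ci_low, 1), round(work.ci_high, 1), round(work.p_value, 2)
(5.1, 1.1, 24.9, 0.02)
>>> est = clopper_pearson_ci(9, 93)   # unexplained limpness among 93 sampled controls
>>> [round(v, 1) for v in est.percent]
[9.7, 4.5, 17.6]
```

So a case had 4.7 times the odds of being a swimmer (95% CI 1.1 to
30.0) and 5.1 times the odds of being a working dog (1.1 to 24.9),
both nominally significant by Fisher's exact test, and 9.7% (4.5 to
17.6%) of randomly questionnaired dogs turned out to have had
unexplained tail limpness.

A complete synthetic run, from pedigree to permutation test:

```sh
limbertail run-all --seed 1 --out demo
```

which ends its `demo/report.md` with (seed 1, 2000 dogs):

```
## Pedigree permutation test

- observed sire contribution statistic 2.850 (beyond the null 97.5th centile 2.514)
- upper-tail p = 0.001499 (2000 permutations)
```

i.e. the simulated familial effect is correctly detected: case dogs
concentrate on fewer sires than 97.5% of random same-size samples.
The individual stages are also exposed as `limbertail simulate`,
`screen`, `classify`, `analyse`, `permtest` and `validate`.

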