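# Methods

## Problem setting

Limber tail is an acute, painful, self-resolving flaccidity of the
canine tail seen mostly in larger working breeds. Because affected
dogs usually recover without veterinary care, practice records
undercount the condition severely (the "symptom iceberg"); owner
reports collected by an online cohort are the only practical source.
The analysis chain implemented here is: screen free-text owner reports
for candidate incidents, verify case/control status with a tail-sign
questionnaire, estimate incidence and exposure odds ratios with exact
small-sample methods, model latitude risk with logistic regression,
and test for familial clustering with a pedigree permutation test.

## Exact 2×2 inference

Conditioning a 2×2 exposure-by-status table on both margins leaves one
free cell distributed as Fisher's noncentral hypergeometric with
noncentrality ψ, the odds ratio. All inference derives from that
distribution, evaluated in log space over the conditional support.

- **Point estimate**: the conditional MLE solves E_ψ[A] = a; the
  conditional mean is strictly increasing in log ψ, so a bracketed
  Brent search on the log scale (xtol 1e-12) is robust. A count on the
  support boundary (zero cell) yields 0 or ∞ with a `boundary` flag.
- **Confidence intervals**: three orderings are implemented. The
  default inverts the two-sided *minimum-likelihood* test (the p-value
  that sums all tables as or less probable than the one observed, tie
  tolerance 1+1e-7) — this is the companion of the two-sided Fisher p
  and the default of the standard exact-2×2 R tooling, and it
  reproduces the published bounds for both headline tables. Blaker's
  combined-tails ordering and the classical central interval (two
  one-sided tests at α/2; matches `scipy.stats.contingency.odds_ratio`)
  are available via `method=`. Endpoints are found by outward walk from
  the MLE plus Brent root search; two-sided p-curves are piecewise
  smooth in ψ between tie-set changes, and the outermost α-crossing is
  taken.
- **Fisher's exact test**: minimum-likelihood two-sided rule; one-sided
  alternatives are plain tail sums.
- Duality holds within each ordering: the CI excludes 1 exactly when
  the matching two-sided p is below α (tested exhaustively on small
  margins, knife-edge attainable levels excepted).

Cross-checks: conditional MLE and Fisher p agree with the independent
scipy implementations to <1e-6 over every non-degenerate table with
all margins ≤ 12 (5,238 tables), and with a grid-refinement likelihood
maximiser on small tables.

## Binomial and descriptive machinery

Incidence proportions use Clopper-Pearson central exact intervals via
the beta-quantile characterisation; k=0 and k=n pin the corresponding
bound. `cumulative_incidence` adds an explicit non-responder
sensitivity bound (k/(n+m), treating all m non-responders as
unaffected). Continuous summaries (episode duration, pain and
quality-of-life scores) use means with symmetric t-intervals and the
sample Pearson correlation. Duration categories are recoded as: "a few
hours" → 0.125 d, "a few days" → 3 d, "a week or more" → 8 d, explicit
counts pass through; unrecognised categories are warned about and
excluded rather than guessed.

Logistic regression is a thin wrapper over `statsmodels.Logit` (Wald
intervals, both log-odds and OR scales). Non-convergence and
separation are flagged on the result object; separated fits are never
reported silently. Latitude and longitude are fitted as separate
single-predictor models by default: the source description of the
geographic model is ambiguous about predictor/response roles, and with
case-control sampling the single-predictor fit of status on latitude is
the defensible reading; a joint fit is a one-liner with the same API.

## Pedigree permutation test

The contribution statistic for a dog sample grouped by sire (or dam)
with counts c₁..c_k over k contributing parents is Σcᵢ²/Σcᵢ — each
parent weighted by its contribution, equivalently the mean sibship
size experienced by a sampled dog. The unweighted alternative n/k is
implemented and reported alongside, because the original formula sits
in a figure that survives only as text; the offspring-weighted form is
the default as the only reading consistent with "dogs contributing
more than one offspring were weighted". Both equal 1 iff all parents
are distinct and n iff a single parent contributed every dog.

The null is built from simple random samples (without replacement) of
the case-set size drawn from the full cohort table, not from cases ∪
controls only. The upper-tail p uses the add-one rule
p = (1 + #{null ≥ observed})/(n_perm + 1), so min p = 1/(n_perm+1);
"significant familial clustering" is additionally reported as the
observed statistic exceeding the null's 97.5th centile. Dogs with an
unknown parent on the tested axis are dropped (and counted), never
imputed. An exhaustive enumeration oracle (`exhaustive_null`, bounded
at 10⁶ subsets) provides exact tail probabilities for small cohorts.

With a discrete statistic the add-one rule counts full tie blocks and
is therefore conservative (super-uniform under the null). That is the
right behaviour for reporting, but it is a nuisance when *checking*
sampler calibration, so `tie_break="random"` places the observed value
at a uniformly random rank within its tie block — for a correct
sampler this makes the null distribution of p exactly uniform on the
add-one grid. Calibration studies use the randomised form; reported
p-values use the conservative default.

**Calibration protocol.** 500 replicate cohorts of 600 dogs (60 sires,
80 dams, Dirichlet concentration 1.0 — skewed, popular-sire-like
families) are simulated with the sire effect switched off; the
Kolmogorov-Smirnov test of the resulting p-values against uniform must
not reject at the 1% level. The cohort shape was fixed from a
granularity argument: a 60-case sample moves the statistic on a 1/60
grid, and skewed families spread the null over many attainable values
(largest point mass ≈ 3%), so tie effects cannot mask a genuine
sampler bias. Power rises monotonically with the sire-effect SD
(≈0.2 / 0.55 / 0.86 at SD 0.5 / 1.0 / 1.5 with ~40 cases from a
400-dog cohort) and exceeds 0.5 at the case counts typical of the
study design with SD ≥ 1.

## Synthetic cohort generator

The generator emulates the three study tables with known truth:

- **Pedigree**: one generation; offspring allocated to `n_sires` sires
  (independently, dams) by a multinomial over Dirichlet(γ) weights.
  γ → ∞ approaches uniform contributions; small γ lets a few popular
  sires dominate, spanning contribution patterns like
  {3, 2, 2, 1×31}. No real litter-size distribution is published, so
  γ = 1 is the default: visibly skewed without being degenerate.
- **Covariates**: i.i.d. across dogs, matched to the published control
  marginals — swimming prevalence 68/86 ≈ 0.79, purpose ≈ 95%
  household pets / 3.5% working, UK latitudes clipped to [49, 61]
  (generated directly in degrees; postcode geocoding is out of scope).
- **Disease model**: logit P(affected) = β₀ + β_swim·swims +
  β_work·working + β_lat·(lat − 52.8) + u_sire, u_sire ~ N(0, σ_s²),
  with "working" including gundog-and-pet dogs. Defaults use the
  published effect sizes (log 4.7, log 5.1, log 1.47), σ_s = 0.9 for a
  moderate familial effect, and β₀ = −4.14, solved by numerical
  integration so the marginal incidence under the default covariate mix
  is the observed 9.7%. Latent sire effects and linear predictors are
  returned for test introspection.
- **Free text**: every affected dog emits ≥1 report from template
  classes — keyword-bearing phrasings built from the observed owner
  vocabulary, keyword-free "tail" phrasings (10%, the manual-review
  channel), and non-tail distractors emitted by any dog at a
  configurable rate. Per-incident vet-visit probability defaults to
  the observed 11/53. Template-class labels are ground truth and go to
  the sidecar JSON, not the reports CSV.
- **Questionnaires**: one per dog (repeat submissions collapsed; the
  case-control analysis is per dog). Affected dogs report limp-at-end
  with probability 0.85 and limp-along-length with 0.5, so ~7.5% of
  affected dogs lack limpness signs and exercise the provisional-case
  exclusion path (2 of 31 published); 5% attribute the signs to an
  alternative cause. Unaffected dogs carry a sign profile at rate 5/93,
  split 60/40 between anal-gland attributions and signs-without-
  limpness — the published non-promotable control profiles. Promotable
  limpness among provisional controls arises mechanistically, from
  truly affected dogs whose reports the keyword screen missed. Pain
  and quality-of-life scores are integer-rounded clipped bivariate
  normals (means 6.0 and 4.1); the latent correlation is inflated for
  rounding attenuation so the sample Pearson r matches the configured
  0.72. Duration categories are drawn with weights chosen to put the
  recoded mean near the observed 3.5 days.

What the generator does **not** emulate: under-reporting of whole
incidents (every affected dog reports, so the synthetic incidence among
provisional controls is far below the published 9.7% — that figure is
exercised through the printed counts instead), multigenerational
kinship, litter structure, longitudinal questionnaire schedules,
recall bias, and real UK geography. Passing tests therefore validate
the statistical machinery, not the ecological realism of any particular
synthetic dataset.

## Parameter-recovery protocols

Logistic recovery runs 100 replicate cohorts of 20,000 dogs at the
published effect sizes with σ_s = 0 and requires each true beta inside
its 95% Wald CI in ≥ 90 replicates. The sire effect is switched off
deliberately: with a random intercept present, a marginal logistic fit
estimates attenuated population-averaged betas, so Wald coverage of
the conditional betas would fail for a reason that is not a defect of
the fitting machinery. Problem sizes throughout the suite (cohorts of
400-20,000, 99-10,000 permutations, 100-500 replicates) were chosen to
give the assertions comfortable statistical margins at interactive
runtimes.

## Numerical and interface choices

- All generators take explicit integer seeds; there is no global
  random state, and identical (seed, config) reproduce outputs byte
  for byte, including the pipeline's hashed output manifest.
- CSV outputs are UTF-8 with ISO-8601 dates; unknown parents are empty
  fields; ground truth lives in a separate sidecar JSON.
- Screening matches case-insensitive substrings ("limb" matches
  "limber" and would match "climbing"; "tail" matches "tailbase") —
  the stems only make sense as substrings, and the review queue plus
  overrides absorb false positives. Same-dog matched reports merge
  into one incident only when they share a report date; the schema
  carries a single report date, so date-range overlap cannot be
  evaluated.
- "Unsure" on a limpness sign counts as "no" (the case definition
  requires positive flaccidity); any concrete attribution vetoes case
  status even with limpness reported. Pain-question inconsistencies
  (no/unsure answers with non-zero pain scores) are counted and
  reported, never corrected.
- Rounding for report output is 1 decimal for percentages and odds
  ratios. Unrounded values are always retained in `results.json`.

## Known limitations

- Mixed-effects models of height/weight/exercise with a dog-level
  random effect are deliberately not implemented (routine null
  comparisons needing repeated-measures data the pipeline does not
  model); the report notes them as such.
- The minimum-likelihood CI can be non-monotone in pathological
  tables; the implementation takes the outermost α-crossing, which for
  very sparse tables can differ from acceptance-region constructions
  by tie handling.
- The exhaustive permutation oracle is limited to 10⁶ subsets.
- Survival/person-time modelling and multiple-testing correction are
  out of scope, matching the design being reproduced.
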