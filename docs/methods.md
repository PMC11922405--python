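# Methods

This note records the statistical model, the synthetic-data design, the
numerical conventions, and the open design choices made in `painpro`,
in enough detail to reproduce or audit any number the package emits.

## Composite scores

The pain composite score is a time-weighted convex combination of the
two intensity ratings over the first postoperative day:

    PCS = worst · t + least · (1 − t),  t ∈ [0, 1]

with `worst`, `least` integer NRS 0–10 items and `t` the fraction of
time in severe pain (recorded on a 10 % grid). Consequences used as
test invariants: the PCS is bounded by min/max of the two ratings,
reduces to `least` at `t = 0` and `worst` at `t = 1`, and is monotone in
each argument (in `t` when `worst ≥ least`).

PITS, EIS and AES are arithmetic means of their item blocks (three
physical-interference items; anxiety and helplessness; four
adverse-event items). Item schemas are configuration, not constants
(`scores.ItemSchema`), because instruments differ in exactly which
items they field; the defaults match the granularity of the published
summary grids (thirds / halves / quarters). By default a score is
missing unless *all* its items are present (`min_items=None`),
consistent with the strict no-imputation, complete-case policy; the
PRO-Score is the unweighted mean of PCS, PITS, EIS and AES and is
missing if any component is (weights are configurable but default to
equal, since no weighting is established).

## Rescaling a bounded score for beta regression

Beta regression needs the outcome strictly inside (0, 1). Scores are
divided by 10 and then compressed with the standard
proportion-compression `y → (y(n−1) + 0.5)/n`, `n` = effective sample
size of the fitted model (the compression vanishes as `n → ∞`, and its
inverse is applied when predictions are mapped back to NRS units). An
epsilon-clamp strategy is available as an alternative
(`rescale_to_open_unit(..., strategy="epsilon")`). The forward and
inverse transforms round-trip to 1e-12, which the suite asserts.

## Primary model: beta regression with marginal means

The rescaled PCS is modelled with a beta likelihood in mean–precision
parameterisation (`α = μφ`, `β = (1−μ)φ`), logit link for `μ`, constant
precision `φ` with a log link, fitted by maximum likelihood
(statsmodels `BetaModel`). Covariates: anesthesia subgroup (six levels,
ordered `GA-o, GA&PNBc, GA&PNBs, SA-o, SA&PNBc, SA&PNBs`), sex, age,
weight, enrolment period (three categories), pre/intra- and
postoperative non-opioid use, PACU and ward opioid use as two separate
indicators, O&S status, and country-income stratum.

With only two income strata a genuine random intercept is weakly
identified, so the stratum enters as a fixed intercept by default;
`income_mode="penalized"` instead shrinks the stratum coefficient with
an L2 penalty (a ridge approximation to a random intercept) for
sensitivity analyses.

**Estimated marginal means.** The reference grid crosses all factor
covariates with equal weight and holds continuous covariates at their
sample means. Linear predictors are averaged on the link scale within
each level of the target factor, then back-transformed through the
inverse logit and the inverse compression, so EMMs live on NRS 0–10 and
respect its bounds. CIs are delta-method on the link scale and
back-transformed. The suite checks this machinery against a brute-force
oracle (explicit per-grid-row prediction averaging) to 1e-6 on the link
scale.

**Pairwise contrasts.** All k(k−1)/2 pairs are formed; the test
statistic is the link-scale t ratio, referred to the studentized-range
distribution with residual degrees of freedom `n − p` (Tukey), or to
the t distribution when unadjusted. Point estimates and CIs are
reported on the NRS response scale (delta-method SE; simultaneous
half-width `q/√2 · SE` under Tukey). The O&S split uses a single model
with a subgroup×O&S interaction and treats the 12 cell means as one
EMM family (66 contrasts); empty cells raise an error naming the cell.

## Opioid-use model

Opioid use (any PACU or ward administration; event-based, so a
zero-dose record still counts) is modelled by multivariable logistic
regression with the same covariates minus the PACU/ward indicators
(they are components of the outcome), reference level `GA-o`. Odds
ratios carry Wald CIs. Adjusted percentage-point differences come from
g-computation: every record is counterfactually assigned each subgroup,
predicted probabilities are averaged, and marginal probabilities are
differenced (×100). In a covariate-free model this reproduces raw
proportion differences exactly, which the suite asserts. CIs are a
seeded nonparametric bootstrap over records (default B = 1000) or
delta-method; the method tag is always emitted. Because catheter groups
run near 100 % use, (quasi-)separation is expected rather than
exceptional: the fit detects it (solver failure, non-convergence, or
coefficients beyond ±15 on the logit scale) and switches to a
ridge-penalised likelihood (unpenalised intercept, penalised Newton
iterations, covariance from the penalised information), with a warning
and a `logit-ridge` method tag. Multiplicity is not adjusted by default
(the Tukey adjustment is specified for the primary endpoint only); a
Bonferroni option exists.

## Morphine equivalents

Conversion factors differ between references, so the table is explicit
and versioned; every pipeline manifest records the version. Defaults
(`painpro-default-1.0`, mg oral morphine per mg): oral morphine 1.0
(fixed by definition), iv morphine 3.0, oral oxycodone 1.5, iv
piritramide 2.0 (chained through its iv-morphine equivalence), oral
tramadol 0.1, oral tapentadol 0.3, iv fentanyl 300 per mg, oral
hydromorphone 5.0. Subcutaneous routes fall back to the iv factor
unless the table overrides. Unknown (drug, route) pairs yield a
*missing* ME — never zero — and poison the patient's 24-h total
(complete-case propagation). Totals cover PACU + ward administrations;
intraoperative opioids are out of scope of the 24-h total by default.

## Descriptive tables

Quartiles use linear interpolation (numpy default, R type 7) — pinned
because published [Q1; Q3] values are convention-dependent. Categorical
summaries use the non-missing denominator and every row reports its N.
Dispatch: two groups → Mann–Whitney U, more → Kruskal–Wallis,
categorical → Pearson chi-square with Yates continuity correction on
2×2 tables (the correction reproduces the published 2×2 p-values and
matches the default of standard R `chisq.test`); one-way ANOVA is
available per variable.

## Synthetic registry

The generator is the package's test bed, not a model of any real
hospital. Design:

- **Cohort structure** (paper-like defaults): n = 4328; six subgroups
  with income-dependent mixes taken from the published per-stratum
  counts, high-income share 0.748; continuous catheters nearly absent
  in the middle/low-income stratum; O&S prevalence 9.5 %; enrolment
  periods 25/45/30 %.
- **Latent outcome**: PCS* = 10 · Beta(μφ, (1−μ)φ) with
  `logit(μ) = η` built from per-subgroup baseline logits, an O&S shift
  (+0.4), and small covariate effects (age/weight per 10 units centred
  at 67 y / 80 kg). Defaults: baseline logits chosen so subgroup means
  sit at NRS 3.0–3.7 (the published adjusted range), φ = 2.5 chosen so
  the marginal PCS quartiles match the published 2.8 [1.0; 5.0].
- **Observable encoding**: a compatible integer pair
  `least ≤ PCS* ≤ worst` is drawn uniformly and the time fraction
  `t = (PCS* − least)/(worst − least)` is snapped to the 10 % grid
  (degenerate `worst = least` → t = 0). Snapped triples that would
  collapse onto an exact 0 or 10 are re-expressed as the nearest
  achievable *interior* triple (e.g. `worst = round(10·PCS*)`,
  `least = 0`, `t = 0.1`): the latent beta family has no boundary mass,
  and boundary-exact artifacts would be compressed to `0.5/n` where
  their log-likelihood contributions systematically distort the beta
  fit — with the repair, the discretisation round-trip error is ≤ 0.5
  NRS (median ≈ 0.1) and large-sample EMM contrasts are recovered to
  better than 0.04 NRS.
- **Secondary items**: thresholded Gaussian copula tied to the latent
  PCS through its probability-integral transform (correlation 0.6),
  with per-family marginal shapes giving realistic medians; this
  induces a plausible joint structure but does *not* reproduce any real
  instrument's item-level correlations.
- **Opioid use**: Bernoulli per subgroup with the published per-subgroup
  rates as defaults; users' 24-h ME totals are lognormal
  (meanlog 2.7, sdlog 0.9, matching the published median ≈ 15 mg and
  right skew) split across 1–3 administrations of common opioids.
- **Missingness**: independent per-field Bernoulli masks; primary
  outcome fields are complete by default (the cohort is defined by
  complete primary outcomes).
- **Reproducibility**: one top-level seed; every variable family draws
  from a named substream, so adding or reordering generation code does
  not silently shift other streams.

Ground truth (`GroundTruth.true_emm`) is computed from the same
equal-weight covariate grid the EMMs use, with age/weight at their
centres — so parameter-recovery checks compare like with like.

What passing tests show — and what they do not: recovery, coverage and
familywise-error results certify the *estimation machinery* under the
generator's assumptions (correct mean structure, beta-like outcome,
independent records, missingness unrelated to outcome). They cannot
certify behaviour under real-registry features the generator omits:
hospital clustering, informative missingness, item-level response
styles, or selection into anesthesia technique.

## Monte Carlo problem sizes

The shipped checks use: 50 registries of n = 200 for the EMM oracle; 50
registries of n = 4000 for contrast bias/coverage; 200 registries of
n = 1200 for familywise error (the acceptance script uses 30/150
replicates at the same sizes); n = 20 000 for the g-computation gap
recovery. These sizes put Monte Carlo noise comfortably below the
thresholds being checked while keeping the default suite fast.

## Numerical conventions and edge cases

- Factor levels are coded from ordered categoricals (subgroups in the
  fixed publication order, others lexicographic), so designs are
  invariant to row order.
- Degenerate strata (a factor level with < 2 complete cases) raise an
  error naming the level rather than producing unstable fits.
- Residual df for the studentized range: `n_used − p` (mean-model
  parameters). At registry scale the df choice is immaterial but it is
  pinned for reproducibility.
- `α = 0.05`, two-sided, throughout.
- Percent-vs-fraction confusion is refused loudly: `pcs()` errors on
  `t > 1` with the instruction to divide by 100.
- Plausibility filtering is total and conservative: age < 18 or
  weight < 34 kg removes the record; an implausible single
  administration removes only that administration. Exclusion logs are
  exhaustive (kept + excluded = input), asserted in tests.

## Known limitations

- The composite scores are used as defined, not psychometrically
  validated; no factor analysis or reliability assessment is included.
- The g-computation contrasts are associational standardisation, not
  causal effect estimates; no propensity or IPW machinery is provided.
- The ridge fallback's CIs are approximate (penalised information);
  they are tagged so downstream consumers can treat them with care.
- The penalized income mode is a ridge approximation, not REML.
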