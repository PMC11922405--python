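# painpro

Multidimensional analysis of acute postoperative pain after total knee
arthroplasty (TKA), built as a reusable, tested pipeline around
registry-style patient-reported outcomes (PROs).

Large pain registries (PAIN OUT-style) record, for the first
postoperative day, numeric-rating-scale (NRS 0–10) pain items, the
percentage of time in severe pain, pain-related interference and
adverse-event items, and every analgesic administration. `painpro`
implements the full analysis chain for comparing anesthesia strategies —
general (GA) or spinal (SA) anesthesia, each alone (`GA-o`, `SA-o`) or
combined with a single-injection (`&PNBs`) or continuous catheter
(`&PNBc`) peripheral nerve block:

1. **Composite scores.** The pain composite score blends intensity and
   time burden,

   `PCS = worst · t + least · (1 − t)`,  `t` = fraction of time in severe pain,

   so `min(worst, least) ≤ PCS ≤ max(worst, least)`. Item means give the
   physical-interference (PITS), emotional-interference (EIS: anxiety,
   helplessness) and adverse-events (AES) scores; the PRO-Score is the
   unweighted mean of all four. No imputation anywhere: analyses are
   complete-case and report the N they used.
2. **Morphine equivalents.** Postoperative opioid administrations are
   converted to mg oral morphine with an explicit, versioned (drug,
   route) factor table, plus a dichotomous opioid-use endpoint.
3. **Adjusted primary analysis.** The PCS is rescaled into (0, 1)
   (`y → 0.1·PCS`, then the boundary compression `(y(n−1)+0.5)/n`) and
   modelled by beta regression in mean–precision form: `y ~ Beta(μφ,
   (1−μ)φ)`, `logit(μ) = η` with anesthesia subgroup, sex, age, weight,
   enrolment period, non-opioid/opioid co-medication indicators,
   preoperative opioid/substance (O&S) status and an income-stratum
   intercept. Group effects are reported as estimated marginal means
   (EMMs) on the NRS scale with all 15 pairwise contrasts adjusted by
   the Tukey (studentized-range) test; an O&S-split (6 × 2 grid, 66
   contrasts) uses a subgroup×O&S interaction.
4. **Opioid-use model.** A multivariable logistic model (reference
   `GA-o`) reports odds ratios and — via g-computation (marginal
   standardisation) — adjusted percentage-point differences in opioid
   use, with bootstrap or delta-method CIs. Separation (subgroups with
   ≈100 % use) automatically falls back to a ridge-penalised likelihood,
   tagged in every output.
5. **Descriptives.** Publication-style tables: median [Q1; Q3] (type-7
   quartiles) or n (%), with Mann–Whitney U / Kruskal–Wallis /
   chi-square (Yates on 2×2) tests.
6. **Synthetic registry.** Because registries of this kind are not
   public, a generator draws latent PCS values from the beta model with
   configurable subgroup effects and reverse-engineers questionnaire
   triples (integer worst/least, 10 %-grid time) that reproduce them,
   along with correlated ordinal items, opioid administrations and
   configurable missingness — giving every downstream stage a ground
   truth to recover.

## Worked example

```python
from painpro import simulate, registry, scores, morphine, beta_model, logit_model

cfg = simulate.default_paperlike_config(n=2000, seed=1)
records, admin, truth = simulate.generate(cfg)
records["subgroup"] = registry.allocate_subgroup(records)
sc = scores.score_registry(records)
sc["opioid_use"] = morphine.opioid_use_flag(sc, admin).to_numpy()

fit = beta_model.fit_beta(sc)
mm = beta_model.emmeans(fit)
print(mm.table[["subgroup", "estimate", "ci_low", "ci_high"]].round(2))
```

```
subgroup  estimate  ci_low  ci_high
    GA-o      4.06    3.68     4.47
 GA&PNBc      4.29    3.89     4.70
 GA&PNBs      3.88    3.48     4.29
    SA-o      3.61    3.28     3.94
 SA&PNBc      3.87    3.45     4.29
 SA&PNBs      3.89    3.54     4.25
```

These are covariate-adjusted mean PCS values per anesthesia subgroup on
the NRS 0–10 scale (equal-weight reference grid, continuous covariates
at their means), with delta-method 95 % CIs back-transformed through the
logit link. Tukey-adjusted pairwise contrasts and the opioid-use model
follow the same pattern:

```
GA&PNBc vs GA&PNBs:  +0.41 NRS [-0.19, 1.00], Tukey p = 0.367
opioid use, GA&PNBc vs GA&PNBs:  +10.9 pp [6.7, 15.2]   (g-computation)
```

i.e. in this simulated cohort the catheter group reports, if anything,
slightly *more* pain than the single-injection group and ~11 percentage
points more opioid use — the qualitative pattern the generator's
defaults encode.

The same chain is available from the shell:

```bash
painpro simulate --n 2000 --seed 1 --out registry.csv --administrations adm.csv
painpro filter   --registry registry.csv --administrations adm.csv --out filtered.csv
painpro score    --registry filtered.csv --administrations adm.csv --out scored.csv
painpro fit-pcs  --scored scored.csv --out-prefix pcs
painpro fit-opioid-use --scored scored.csv --out-prefix opioid
painpro run      --config config.yaml --outdir out/   # all-in-one + manifest
```

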