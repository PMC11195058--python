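# organclock

Organ-specific biological age from blood plasma proteomics.

Large cohort studies show that human organs age at different rates, and
that the plasma proteome carries organ-resolved aging signal: proteins
whose genes are expressed predominantly in one tissue report on that
tissue's physiological state. `organclock` implements the full analysis
stack for this idea — for computational biologists and biomarker
researchers who want to train, audit, or stress-test organ aging clocks
without access-restricted cohort data.

## What it computes

1. **Organ panels.** A gene is *organ-enriched* when its expression in
   one organ is at least 4× its expression in any other organ of a
   bulk-tissue atlas; the proteins of enriched genes form one panel per
   organ, plus an *organismal* panel (everything else on the assay) and a
   *conventional* panel (the whole assay).
2. **Aging clocks.** Per panel, a LASSO regression of chronological age
   on protein levels. The penalty λ is chosen by 5-fold cross-validation
   and then backed off to the largest λ whose mean CV R² still reaches
   95% of the optimum, trading a sliver of accuracy for sparsity.
   Preprocessing follows a strict train-anchored contract: split by
   collection center, drop proteins missing in >10% of samples, KNN-impute
   with k = √n_train neighbors, z-score by training means/SDs.
3. **Age gaps.** For clock prediction ŷ and age y, the *age gap* is the
   residual of ŷ regressed on y (OLS fitted on training samples), then
   z-scored by the training gap mean/SD:
   `z = (ŷ − (a + b·y) − μ_gap) / σ_gap`. A z-gap of +1.5 means the organ
   looks ~1.5 SD biologically older than same-aged peers.
4. **Ageotypes.** Samples with any |z| ≥ 1.5 are extreme agers —
   single-organ, multi-organ (2–4 / 5–7 / 8+ organs, same sign), or
   ambiguous (both signs); cross-visit transition statistics quantify
   their longitudinal stability.
5. **Associations.** Cox proportional-hazards per-SD hazard ratios of
   z-gaps against incident disease and mortality (age and sex adjusted,
   Benjamini–Hochberg corrected per analysis family), Gini dispersion of
   per-organ log HRs (high = organ-specific disease, low = systemic),
   penalized-Cox concordance comparison of biomarker sets, and
   Kaplan–Meier curves.
6. **FIBA** (permutation Feature Importance for Biological Aging): the
   loss in a gap–outcome effect size after permuting one clock protein's
   values, with predictions, residualizer, and z-scale held fixed.
7. **Synthetic cohorts.** A generator plants the structure the analysis
   assumes — equicorrelated standard-normal latent organ gaps (ρ = 0.21),
   AR(1) persistence across visits (r = 0.6), a linear proteome emission
   model, exponential-baseline proportional-hazards events with 17-year
   administrative censoring, collection centers, and MCAR missingness —
   with full ground truth retained, so every stage is testable by
   parameter recovery.

## Worked example

```python
import numpy as np
import pandas as pd
from organclock import SimulationConfig, simulate_cohort, fit_clock, cox_association

cfg = SimulationConfig(n_subjects=1500, seed=7)
cohort = simulate_cohort(cfg)

X, ages = cohort.proteomes[0].fillna(cohort.proteomes[0].mean()), cohort.ages(0)
train, test = X.iloc[:1000], X.iloc[1000:]

clock = fit_clock(train, ages.iloc[:1000],
                  panel=cohort.ground_truth["panels"]["brain"], name="brain")
gaps = clock.age_gaps(test, ages.iloc[1000:])
r = np.corrcoef(clock.predict(test), ages.iloc[1000:])[0, 1]
print(f"brain clock: {len(clock.nonzero_proteins_)} proteins, test r = {r:.3f}")

recovery = np.corrcoef(gaps["z_gap"], cohort.gap_wide(0)["brain"].iloc[1000:])[0, 1]
print(f"held-out corr(z-gap, true latent gap) = {recovery:.3f}")

surv = cohort.events["mortality"].set_index("subject_id")[["time", "event"]]
z = clock.age_gaps(X, ages)["z_gap"].rename("brain")
cov = pd.DataFrame({"age": ages, "sex": cohort.subjects.set_index("subject_id")["sex"]})
res = cox_association(z, surv, cov)
print(f"mortality per-SD HR = {res.hazard_ratio:.2f} "
      f"(95% CI {np.exp(res.ci_low):.2f}-{np.exp(res.ci_high):.2f}, p = {res.p:.1e})")
```

Output:

```
brain clock: 11 proteins, test r = 0.809
held-out corr(z-gap, true latent gap) = 0.912
mortality per-SD HR = 1.97 (95% CI 1.79-2.17, p = 3.2e-44)
```

The clock keeps 11 of 20 panel proteins and predicts age at r = 0.81 on
held-out samples; its z-gap tracks the planted latent brain gap at
r = 0.91. The marginal mortality hazard ratio (1.97 per SD) exceeds the
planted brain-specific effect (1.58) because organ gaps are correlated
(ρ = 0.21) and the other gaps also carry risk — the same inflation a
marginal Cox fit shows on real cohorts.

The end-to-end pipeline, and every stage individually, is also available
from the shell:

```bash
organclock run --out results/ --seed 1
organclock simulate --out cohort/ --seed 1 --n 2000
organclock panels --atlas atlas.tsv --assay proteins.txt --out panels.json
```

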