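# freeil18

Serum free interleukin-18 (IL-18) as a prognostic marker for severe
infection in patients starting dialysis — as a tested, reusable analysis
pipeline.

Incident-dialysis patients are at high risk of severe infection. IL-18 is a
proinflammatory cytokine whose activity is neutralized by its binding
protein (IL-18BP); only the unbound ("free") fraction can engage the IL-18
receptor, so free IL-18 — not the total — is the biologically meaningful
exposure. ELISA panels measure *total* IL-18 and *total* IL-18BP; `freeil18`
derives the free concentration, selects a prognostic cutoff, and runs the
dichotomized survival analysis of infection-hospitalization events, for
epidemiologists and nephrology researchers working with cohort assay data.

## The model

At equilibrium the three species obey the law of mass action with
dissociation constant $K_d$ (default 0.4 nM = 400 pmol/l):

$$K_d = \frac{[\mathrm{free\ IL\text{-}18}]\,[\mathrm{free\ IL\text{-}18BP}]}{[\mathrm{complex}]},\qquad
[\mathrm{IL\text{-}18}] = [\mathrm{free\ IL\text{-}18}] + [\mathrm{complex}],\quad
[\mathrm{IL\text{-}18BP}] = [\mathrm{free\ IL\text{-}18BP}] + [\mathrm{complex}]$$

which gives the closed form (with $T$ total IL-18, $B$ total IL-18BP)

$$[\mathrm{free\ IL\text{-}18}] = \frac{-(B - T + K_d) + \sqrt{(B - T + K_d)^2 + 4 K_d T}}{2}.$$

Downstream, the marker is dichotomized at the threshold maximizing the
Youden index $J = \text{sensitivity} + \text{specificity} - 1$ on the ROC
curve (orientation: *low* free IL-18 predicts infection, strict `<`), the
groups are compared by Kaplan–Meier curves with the log-rank test, and the
adjusted effect is estimated by Cox proportional hazards regression
(Breslow ties, Wald intervals $\exp(\hat\beta \pm z_{0.975}\,\mathrm{se})$).
A seeded synthetic-cohort generator with correlated lognormal analytes and
exponential event/dropout hazards stands in for patient-level data.

## Worked example

```python
>>> from freeil18 import free_ligand, solve_equilibrium
>>> free_ligand(total_ligand=29.9, binding_protein=1034.0, kd=400.0)
8.46685588731813
>>> solve_equilibrium(29.9, 1034.0, 400.0)
EquilibriumState(free_ligand=8.46685588731813, free_bp=1012.5668558873181, complex=21.43314411268187)
```

For the cohort-mean inputs (total IL-18 29.9 pmol/l, IL-18BP 1034 pmol/l),
8.5 pmol/l of the cytokine is free, 21.4 pmol/l is sequestered in the
complex, and almost all binding protein remains unoccupied — the expected
regime when IL-18BP is in ~35-fold molar excess.

End-to-end on a simulated cohort, fixing the 6.0 pmol/l cutoff:

```python
>>> from freeil18 import default_idic_config, generate_cohort, run_pipeline, AnalysisConfig
>>> cohort = generate_cohort(default_idic_config(seed=1))
>>> report = run_pipeline(cohort, AnalysisConfig(cutoff=6.0))
>>> report["roc"]["display"]
{'auc': 0.59, 'sensitivity_pct': 56.5, 'specificity_pct': 64.3}
>>> report["survival"]["logrank"]
{'statistic': 4.3755614381384484, 'p': 0.036457817981035534, 'df': 1}
>>> [f for f in report["cox"]["fits"] if f["covariate"] == "low_free_il18"][0]["hr"]
2.3772...
```

In this replicate, 110 of 295 simulated subjects fall below 6.0 pmol/l;
their infection-hospitalization rate is 11.8% against 5.4% above the cutoff,
the log-rank test rejects equal event-time distributions at p = 0.036, and
low free IL-18 carries an adjusted hazard ratio of 2.4 (95% CI 1.0–5.5).
Numbers vary with the seed: a single n = 295 cohort estimates a fourfold
true hazard ratio with wide uncertainty.

The same analysis from the shell:

```bash
freeil18 simulate --seed 1 -o cohort.csv
freeil18 analyze cohort.csv --cutoff 6.0 -o report.json --tables-dir tables/
freeil18 free-il18 assays.csv --kd 400 -o free.csv   # batch equilibrium only
```

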