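# copdsem

Structural equation modeling of whether the systemic manifestations seen
in smokers — low bone density and muscle mass, arterial stiffness,
insulin resistance, reduced kidney function, short telomeres, systemic
inflammation — are direct effects of smoking or are mediated by the lung
dysfunction of COPD. The package is written for biostatisticians and
respiratory epidemiologists who want the full analysis to be runnable
and testable without access to clinical data: it pairs a from-scratch
SEM engine with a synthetic-cohort simulator whose generating truth is
the published standardized path structure.

## The model

For subject *i*, smoking exposure (pack-years, `PY`), lung function
(`FEV1`, `KCO`) and systemic outcomes `Yₖ` follow linear structural
equations with latent factors η (musculoskeletal: ASMMI, hip/lumbar BMD,
pinch, grip; cytokines: IL-6, IL-8, TNFα, MCP-1):

```
FEV1 = a₁·PY + c₁'·(age, gender) + ε
KCO  = a₂·PY + c₂'·(age, gender) + ε
Yₖ   = bₖ₁·FEV1 + bₖ₂·KCO + dₖ·PY + cₖ'·(age, gender) + εₖ
yⱼ   = λⱼ·η + εⱼ                      (measurement model)
```

The direct effect of smoking on outcome *k* is `dₖ`; the lung-mediated
(indirect) effect is `a₁bₖ₁ + a₂bₖ₂`. Estimation is full-information
maximum likelihood (FIML) on the multivariate-normal likelihood
evaluated per missingness pattern, so incomplete rows contribute their
observed subvectors. Coefficients are reported standardized (rescaled by
model-implied SDs, bounded by ±1 in proper solutions). Paths not
significant at p < 0.05 are removed by backward pruning (adjustment
paths exempt); model adequacy uses CFI and TLI (> 0.90 adequate) and
RMSEA (≤ 0.05 good, 0.05–0.08 adequate) with a noncentral-chi-square 90%
CI. See `docs/methods.md` for the estimation details and the generator's
calibration.

## Worked example

```sh
copdsem simulate --seed 1 --out cohort.csv      # 292 subjects, published missingness
copdsem fit --data cohort.csv --model 1 --out report.json
```

or equivalently run the numbered drivers: `python
analysis/01_simulate_cohort.py` then `02_fit_models.py`,
`03_descriptives.py`, `04_recovery.py` (outputs under `results/`).

The fit prints the pruned standardized coefficient table (`NS` = removed
by the p < 0.05 rule). With seed 1:

```
## Model 1 (n = 292)

| Outcome         | pack_years | fev1   | kco    |
|-----------------|------------|--------|--------|
| musculoskeletal | NS         | NS     | 0.371  |
| egfr            | NS         | NS     | NS     |
| homa_ir         | NS         | NS     | NS     |
| pwv             | NS         | NS     | -0.241 |
| telomere        | NS         | 0.329  | NS     |
| wbc             | 0.218      | -0.260 | NS     |
| crp             | 0.327      | -0.233 | 0.147  |
| cytokines       | NS         | -0.203 | NS     |

Goodness of fit: RMSEA = 0.000 (90% CI 0.000; 0.025), CFI = 1.000,
TLI = 1.000 [chi2(146) = 141.0]
```

Reading the table: direct smoking effects survive only for the
inflammation markers (WBC 0.218, CRP 0.327) — every other outcome is
reached through lung function, e.g. telomere length only via FEV1
(0.329). The effect decomposition quantifies this: smoking's total
standardized effect on telomere length here is −0.192, all of it
indirect (direct 0.000). This mirrors the generating truth, in which
only CRP, WBC and eGFR carry nonzero direct smoking paths; at n = 292
the weakest of them (eGFR, 0.15) usually lacks the power to survive
pruning. `analysis/04_recovery.py` shows the engine is unbiased where
power is not the issue: over 50 complete cohorts of n = 2000 every
printed generating path is recovered with |bias| ≤ 0.003 and 95% CI
coverage between 0.90 and 1.00.

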