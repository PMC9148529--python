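# ecarm — longitudinal missing data in external control arm studies

`ecarm` is a Python package for biostatisticians studying what happens when a
prospective observational cohort is used as the **external control arm** of a
single-arm clinical trial — specifically, how the handling of longitudinal
missing outcome data shapes the comparative result.

The motivating setting is rheumatoid arthritis treat-to-target care: a trial
cohort following a stringent strategy is compared with an observational cohort
following a pragmatic strategy.  The endpoint at the 6-, 12- and 24-month
visits is clinical remission by the Disease Activity Score in 28 joints,

    DAS28 = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·PGA,

with remission defined as DAS28 < 2.6.  Trial follow-up produces *monotone*
missingness (pure drop-out), while observational follow-up mixes three
missingness types per subject-visit: **missing outcome data at a recorded
visit** (≥ 1 DAS28 component absent), **intermittent missing visits** (a whole
visit skipped, with a later observed visit), and **drop-out** (everything from
some visit onward missing).

After emulating baseline randomization with propensity-score IPTW, the
package runs five approaches to this missingness and contrasts their
per-visit log odds ratios of remission (trial vs observational strategy):

| approach             | missing at visit | intermittent | drop-out |
|----------------------|------------------|--------------|----------|
| `complete_case`      | exclusion        | exclusion    | exclusion|
| `strict_censor_ipcw` | censor → IPCW    | censor → IPCW| IPCW     |
| `mi_censor_ipcw`     | MI               | censor → IPCW| IPCW     |
| `mi_ipcw`            | MI               | MI           | IPCW     |
| `mi_all`             | MI               | MI           | MI       |

IPCW is time-varying inverse probability of censoring weighting from
sequential per-visit logistic hazards (cumulative weight
`∏ 1/(1−ĥ(j))`, stabilized by default); MI is multiple imputation by chained
equations with predictive mean matching on the DAS28 components, pooled by
Rubin's rules with Barnard–Rubin degrees of freedom.

Because the real cohorts behind this design are not publicly available, the
package ships a first-class **synthetic two-cohort generator** with known
ground truth: shifted baseline covariate distributions, a configurable true
strategy log odds ratio, and labeled MCAR/MAR/MNAR missingness imposed at the
reported study rates (trial drop-out 1.6/6.4/10.1 %; observational drop-out
2.4/9.2/35.1 %, intermittent 7.3/11.3 %, partial visits 4.0/4.6/8.5 %).

## Worked example

```bash
ecarm run-all --seed 1 --out-dir demo_run
```

simulates the two cohorts (188 trial / 328 observational subjects), labels
the missingness patterns, estimates IPTW, runs all five approaches
(M = 10 imputations) and prints:

```
          approach  visit_month estimate    se odds_ratio p_value    95% CI
     complete_case            6    0.523 0.257       1.69   0.042 1.02-2.79
     complete_case           12    1.204 0.247       3.33 < 0.001 2.06-5.41
     complete_case           24    0.221 0.237       1.25   0.351 0.78-1.99
strict_censor_ipcw            6    0.304 0.211       1.36   0.148 0.90-2.05
strict_censor_ipcw           12    1.124 0.218       3.08 < 0.001 2.01-4.72
strict_censor_ipcw           24    0.219 0.238       1.24   0.358 0.78-1.98
    mi_censor_ipcw            6    0.336 0.209       1.40   0.108 0.93-2.11
    mi_censor_ipcw           12    1.076 0.212       2.93 < 0.001 1.94-4.45
    mi_censor_ipcw           24    0.322 0.224       1.38   0.152 0.89-2.14
           mi_ipcw            6    0.315 0.210       1.37   0.134 0.91-2.07
           mi_ipcw           12    1.005 0.205       2.73 < 0.001 1.83-4.08
           mi_ipcw           24    0.303 0.214       1.35   0.157 0.89-2.06
            mi_all            6    0.294 0.209       1.34   0.161 0.89-2.02
            mi_all           12    0.941 0.205       2.56 < 0.001 1.71-3.83
            mi_all           24    0.188 0.212       1.21   0.377 0.79-1.83
```

Each row is one approach at one visit: the log-OR `estimate` and its robust
(sandwich) `se`, the odds ratio of remission for the stringent (trial)
strategy versus the pragmatic (observational) strategy, and the Wald 95% CI.
In this seed's run the complete-case analysis gives the most optimistic
6/12-month effects — its exclusions select against well-doing observational
patients who attend less — while the four advanced approaches agree more
closely with each other; the generator's true marginal log ORs for this
configuration are 0.42/0.76/0.39 at 6/12/24 months.  The output directory
also receives the simulated panels, the label table, the SMD balance report,
per-arm estimated remission proportions per approach (the response-rate
figure analog), pattern summaries and a run manifest.

The same stages are available individually (`ecarm simulate`, `classify`,
`balance`, `analyze`, `report`) and as library functions
(`ecarm.generate_study`, `ecarm.compare_approaches`, ...).

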