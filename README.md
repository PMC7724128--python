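# listcount

Analysis tools for **double-list experiments** (item-count technique)
measuring sensitive health behaviours — behaviours such as condom use among
female sex workers or physical intimate partner violence, where direct
survey questions suffer from social desirability bias.

In a list experiment, control respondents are read J non-sensitive
statements, treated respondents the same statements plus the sensitive one,
and everyone reports only the *number* of statements they agree with. The
prevalence of the sensitive behaviour is the treatment effect in

```
Y_i = λ + β T_i + ε_i
```

i.e. β̂ = mean(Y | treated) − mean(Y | control). In the double-list design
two different non-sensitive lists share the sensitive item; every
respondent is treated on exactly one list (assigned by arrival parity), so
the pooled regression

```
Y_i = λ + β T_i + δ·1(List = A) + ε_i
```

with respondent-clustered standard errors uses each person once as
treatment and once as control, cutting the standard error by roughly 40%.

The package provides:

- a **synthetic cohort generator** (latent sensitive trait, per-item
  agreement probabilities, within-respondent agreement correlation,
  direct-question misreporting, and switchable assumption violations);
- **estimators**: per-list, pooled, and subgroup-interacted prevalence
  fits; Wald tests of misreporting (list vs direct question) and of
  internal consistency (list A vs list B);
- **diagnostics** for the three identifying assumptions: randomisation
  balance, the no-design-effect CDF inequalities with Bonferroni
  correction, and floor/ceiling proportions;
- **design tools**: the double-list SE-reduction accounting and the
  bias–variance minimum sample size — the N above which the unbiased but
  noisy list estimate beats a direct question with bias B, obtained from
  the break-even quadratic in x = N − 1, y = B:

  ```
  y²x² + ((2π* − 1)y − 4·Var[Y(0)])·x − C = 0,   C = π*(1 − π*) + 4·Var[Y(0)]
  ```

  with N_min = round(x) + 1;
- a **CLI** (`listcount`) and a pipeline that renders the four standard
  study tables.

## Worked example

```sh
listcount --quiet simulate --study burkina --n 1706 --seed 3 --out cohort.csv
listcount --quiet estimate cohort.csv --list pooled
```

prints

```
pooled: N=3412 prevalence=0.254 SE=0.023 CI95=[0.209; 0.298] direct=0.054 misreporting=0.200 p=0.000
```

The cohort was generated with a true prevalence of 0.24 and a direct
question that captures only ~0.05 of it: the pooled double-list estimate
recovers 0.254 ± 0.023, while the direct question yields 0.054 — a
misreporting gap of 0.200. The minimum sample size at which the list
experiment beats that (heavily biased) direct question in MSE:

```sh
listcount samplesize --pi 0.800 --var-y0 0.673 --bias 0.168
# quadratic 0.028224 x^2 + -2.591200 x + -2.852000 = 0, C=2.852000, root x=92.896, N_min=94
```

The numbered scripts under `analysis/` run the full narrative on two
synthetic cohorts (01 simulate → 02 prevalence/misreporting → 03 internal
consistency → 04 diagnostics → 05 efficiency/sample size) and write their
tables under `results/`.

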