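# Methods

## The design and its identification

A list experiment elicits a sensitive binary behaviour indirectly. Control
respondents hear J non-sensitive statements, treated respondents the same
J plus the sensitive statement; each reports only the count Y of statements
they agree with. If (i) treatment is randomised, (ii) adding the sensitive
item does not change answers to the non-sensitive items, and (iii) no
respondent loses answer privacy by sitting at the floor (agrees with
nothing) or the ceiling (agrees with everything), then

E[Y | T=1] − E[Y | T=0] = π,

the prevalence of the sensitive behaviour. The double-list variant uses two
non-sensitive lists A and B sharing the sensitive item; respondents with
odd arrival numbers are treated on A and control on B, even arrivals the
reverse. Every respondent therefore contributes one treated and one control
count, and the pooled estimator has roughly half the variance of a
single-list estimator on the same people.

## Estimators

All estimators are linear regressions (via statsmodels OLS) on the long
respondent × list table:

- **single list**: `Y ~ T`; the slope is exactly the difference in arm
  means. Default standard errors are heteroskedasticity-robust (HC1): the
  treated arm's count adds a Bernoulli(π) term, so arm variances differ by
  construction. Classical errors are available for comparison.
- **pooled**: `Y ~ T + 1(List=A)`, standard errors clustered at the
  respondent level using the standard sandwich with the
  G/(G−1)·(N−1)/(N−K) small-sample factor (G = respondents). With equal
  group sizes the pooled slope equals the mean of the two single-list
  slopes exactly; the test suite asserts this identity.
- **subgroup**: `Y ~ T * S` (plus the list flag and clustering when
  pooled); in the single-list case the model is saturated, so β is the
  S=0 difference in cell means and β+α the S=1 difference.
- Confidence intervals are β ± 1.96·SE throughout (large samples in the
  intended applications; no t-correction).

**Misreporting Wald test.** The contrast mean(direct) − β̂ is referred to a
normal distribution. The default variance treats the two estimates as
independent, SE² = SE(β̂)² + p̂(1−p̂)/n. Because the same respondents
answer both instruments this ignores a covariance term; a `stacked`
variant estimates it from per-respondent influence contributions
(ψ-aggregation of the OLS influence and the proportion's influence) and is
available as an option. The independent form is the default because it is
what can be computed from published summary tables alone.

**Internal-consistency Wald test.** β̂_A = β̂_B is tested by stacking both
lists with list-specific intercepts and treatment effects and clustering at
the respondent level, which accounts for the negative covariance induced by
each person serving opposite roles on the two lists. An independent-variance
variant exists for summary-only inputs. Contrasts smaller than 1e−12 are
treated as exact ties (p = 1) to avoid dividing round-off by round-off in
degenerate fixtures.

## Assumption diagnostics

- **Balance**: per-covariate two-sample z tests between the two arrival
  groups plus a joint F test from regressing the group indicator on all
  covariates. Constant covariates are skipped with a flag.
- **No design effect**: the identifying assumption implies the CDF
  inequalities F0(y) ≥ F1(y) for y = 0..J and F1(y) ≥ F0(y−1) for
  y = 1..J+1 (control counts on 0..J, treated on 0..J+1). Each inequality
  gets a one-sided z statistic on the difference of empirical CDF values
  with unpooled binomial variances; the family is summarised by the
  Bonferroni-corrected minimum p over all 2(J+1) inequalities. The top
  inequality of the second family (y = J+1) is vacuous — both CDFs equal
  1 — and is reported with p = 1 but still counted in the multiplicity,
  keeping the correction conservative. Degenerate zero-variance cells map
  to p = 0 (violated) or p = 1 (satisfied). A continuity correction is not
  applied. This is a moment-based formulation of the printed inequalities;
  likelihood-based design-effect tests are out of scope.
- **Floor/ceiling**: the control-arm proportions at Y = 0 and Y = J, with
  warning flags above 5% (floor) and 10% (ceiling) by default; both
  thresholds are arguments.

## Synthetic cohorts

The generator draws, per respondent: a latent trait Z ~ Bernoulli(π)
(optionally shifted by binary covariates and clamped to [0,1]); agreement
indicators for each non-sensitive item; counts Y = Σ agreements (+Z on the
treated list); and a direct report equal to Z distorted by the misreporting
model — over-reporting flips 0→1 with probability q
(E[direct] = π + q(1−π)), under-reporting flips 1→0
(E[direct] = π(1−q)). Group assignment is deterministic arrival parity.
Fixed seed ⇒ byte-identical output.

**Item profile.** Both lists default to agreement probabilities
(0.9, 0.5, 0.1): one item most respondents agree with and one most
disagree with, the standard recipe against ceiling/floor pressure, plus a
middling item. A `guideline_compliant` flag marks profiles with
max ≥ 0.8 and min ≤ 0.2.

**Within-respondent agreement correlation.** Real respondents have a
persistent propensity to agree, which shows up in two published regularities
this generator is meant to emulate: control-count variances well above the
independent-items value (≈0.67 vs 0.43 for this profile), and double-list
SE reductions near 40%, beyond the 1 − 1/√2 ≈ 29.3% bound that independent
items imply (the negative covariance between β̂_A and β̂_B needs positively
correlated counts within a person). Item agreements are therefore drawn from
a Gaussian copula: latent = √ρ·v_i + √(1−ρ)·w_ij thresholded at Φ⁻¹(p_j),
which preserves every marginal agreement rate exactly. The exchangeable
correlation ρ defaults to 0 in the generic configuration (keeping the
Poisson-binomial marginal-count property exact) and to 0.3 in the two study
configurations, the value at which the closed-form SE-reduction expression
(bivariate-normal pair covariances) gives ≈40% in both designs. With ρ = 0.3
the joint-disagreement (floor) probability rises to ≈6–7%, so the floor
flag can fire on null cohorts; this is a property of correlated agreement,
not a generator defect.

**Study configurations.** `senegal_config`: n = 495, π = 0.80,
over-reporting q = 0.84 so E[direct] = 0.968. `burkina_config`: n = 1706,
π = 0.24, under-reporting q = 0.775 so E[direct] = 0.054. Both carry two
independent binary covariates at realistic frequencies. These constants
come from the closed forms above and were fixed once.

**Controllable violations.** `design_effect_shift` adds a constant to the
treated item probabilities (clamped to [0,1], clamping logged) — negative
shifts emulate treated respondents concealing agreement and violate the
first inequality family; `liar_mode="deflate_at_ceiling"` makes a treated
trait-holder report J instead of J+1, biasing β̂ down by
π·Pr(all items agreed).

**What the generator does not model**, and hence what passing tests cannot
show about field data: interviewer/enumerator effects, non-response,
counting errors in the marble mechanics, misreporting that leaks into the
list answers themselves, and covariate-dependent misreporting. Tests
demonstrate internal correctness of the estimators and diagnostics under
the stated data-generating process, not external validity of any survey.

## Efficiency and minimum sample size

`se_reduction(se_double, se_single)` = (SE_double − SE_single)/SE_single
(×100 for percent).

The bias–variance break-even compares MSE_direct(N) = B² + p(1−p)/N, with
p = π* − B, against MSE_list(N) = C/(N−1), C = π*(1−π*) + 4·Var[Y(0)].
Setting them equal in x = N−1, y = B gives

y²x² + ((2π*−1)y − 4·Var[Y(0)])x − C = 0,

solved in closed form; the negative root is discarded and
N_min = round(x) + 1 (nearest integer). Coefficients are formed at full
precision — no intermediate rounding. Conventions worth noting:

- the direct-question variance uses p = π* − B regardless of the direction
  of misreporting; the formula is applied verbatim also to over-reported
  behaviours, where p = π* + B would be the literal direct-question rate.
- with published inputs rounded to 3 decimals the recovered N_min can
  differ by a respondent or so from values computed on unrounded data; the
  nearest-integer convention is the one consistent with the worked
  reference values, and floor/ceiling conventions each contradict at least
  one of them.
- zero bias has no finite solution (the direct question wins at every N)
  and raises a dedicated error.

A brute-force cross-check (`mse_crossover_bruteforce`) scans N directly
over the two MSE curves; the test suite requires agreement within one
respondent over a 100-point parameter grid.

## Problem sizes used in the test suite

Monte-Carlo checks run at the study scale where the property demands it:
parameter recovery and CI coverage use 500 replicates at n = 1706;
design-effect size (500 null replicates) and power (200 replicates under a
−0.15 shift); the efficiency band uses 200 replicates; size checks of the
consistency Wald test use 400 replicates at n = 400. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands while
keeping the default suite in the tens of seconds.

## Known limitations

- Maximum-likelihood and nonlinear least-squares list-experiment
  estimators are deliberately absent; estimation is difference-in-means
  regression throughout.
- Survey weights and stratification are not modelled; the group flag is
  the only design variable.
- The subgroup model handles one binary moderator at a time; categorical
  covariates are expanded to indicators (reference = most frequent level)
  before analysis.
- Listwise deletion is the only missing-data policy, with a logged count.
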