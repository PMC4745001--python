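# Methods

## Setting and model

A two-stage seamless phase II/III trial compares `k` experimental arms with a
shared control. Each patient contributes a long-term (primary) response `Y`
and a short-term response `W`, jointly bivariate normal within patient,

    (Y, W) ~ N((mu_y, mu_w), [[sigma^2, rho sigma sigma0], [rho sigma sigma0, sigma0^2]]),

independent across patients. At the interim look, `n1` patients per arm have
both endpoints and a further `N1 - n1` have only the short-term endpoint; one
experimental arm is selected and, together with the control, reaches `n2`
patients with primary data at the final analysis. The hypotheses are
one-sided, `H_i: theta_i <= 0`, where `theta_i` is the long-term mean
difference vs control. The final statistic is the sum of within-pair
differences `S_i = sum_{j<=n2} (Y_ij - Y_0j)`, reported as the familiar
z statistic `Z = S_i / sqrt(V2)` with `V2 = 2 n2 sigma^2`.

## Selection statistics

Three interim estimates of `theta_i` are implemented (`flexselect.estimators`):

* `theta_breve`: the first-cohort mean difference of primary responses —
  the only option when no short-term data are used.
* `theta_hat`: `theta_breve` corrected by the scaled excess of the
  first-cohort short-term difference over its all-interim-patients estimate.
  The correction has mean zero, so `theta_hat` is unbiased and its law does
  not depend on the true short-term effects.
* `theta_tilde`: `theta_breve` plus the scaled second-cohort short-term
  residuals relative to *assumed known* short-term effects, divided by `n1`.
  This is the conditional mean (up to affine rescaling) of `S_i` given the
  interim data; selecting its argmax maximises the conditional probability of
  rejection, i.e. the conditional type I error.

The scale factor in both corrections is `rho sigma / sigma0`, the regression
slope of `Y` on `W`. Substituting the estimated short-term effects into
`theta_tilde` reproduces `theta_hat` exactly; this identity is tested.

## Joint law and the selected statistic's distribution

For every variant, the k selection statistics and the k final statistics are
jointly normal with a Kronecker covariance `[[V1, rho_e sqrt(V1 V2)],
[rho_e sqrt(V1 V2), V2]] ⊗ Sigma`, where `Sigma` is equicorrelated with
off-diagonal 1/2 (the shared control arm), and

| variant | V1 | rho_e^2 |
|---|---|---|
| breve | 2 sigma^2 / n1 | n1 / n2 |
| tilde | 2 sigma^2 (n1 + rho^2 (N1 - n1)) / n1^2 | (n1 + rho^2 (N1 - n1)) / n2 |
| hat | (2 sigma^2 / n1)(1 - rho^2 (N1 - n1)/N1) | n1 / (n2 (1 - rho^2 (N1 - n1)/N1)) |

These follow from elementary covariance algebra; `rho_e` is a correlation and
always lies in (0, 1) for a valid design (`N1 <= n2` guarantees it), and
`rho_e(tilde) >= rho_e(hat) >= rho_e(breve)` with equality at `rho = 0`.

On standardised scales each statistic splits into an arm component and a
common control component, `Z_i = m_i + (eps_i + delta)/sqrt(2)`, with the
arm/control component pairs across the two layers correlated `rho_e`.
Because pairwise differences cancel the control component, the selection
event depends only on the arm components, and the integral over the control
component is Gaussian and closes analytically. The CDF of the selected final
statistic therefore reduces to one one-dimensional integral per arm:

    P(S_{T*} <= s) = sum_i ∫ phi(t) prod_{j != i} Phi(t + sqrt2 (m_i - m_j))
                     * Phi((sqrt2 (s~ - nu_i) - rho_e t) / sqrt(2 - rho_e^2)) dt

with `m_i = theta_i / sqrt(V1)`, `nu_i = n2 theta_i / sqrt(V2)`,
`s~ = s / sqrt(V2)`. Dropping the last factor gives the selection
probabilities (a Dunnett-type integral). An independent Monte-Carlo oracle —
10^6 draws from the explicit 2k-dimensional covariance — validates the
reduction in the tests.

## Numerics

* Quadrature: Gauss–Hermite on the remaining axis, 128 nodes refined to 192;
  if the two disagree by more than 1e-9 (absolute, on a probability) the
  term is re-evaluated with adaptive quadrature; persistent failure raises.
  The integrand (a product of normal CDFs times the normal density) is
  entire, so GH converges essentially to machine precision here.
* Calibration (`flexselect.calibration`): the critical value solves
  `1 - F(c~) = alpha` by Brent's method on the standardised scale, bracketed
  in [1, 5], xtol 1e-10; the attained level is reported and must match alpha
  to 1e-6. For `k = 1` the solution is the one-sided normal quantile.
* The standardised critical value depends on the nuisance parameters only
  through `rho` (sigma cancels). Simulation workflows that recalibrate from
  an estimated correlation therefore interpolate a monotone (PCHIP) cubic
  through a grid of solved values (step 0.01); interpolation error is below
  1e-4, well under the 5e-5-per-solve tolerance times the 2-dp reporting
  granularity. Estimated correlations outside the admissible range are
  clipped just inside the boundary.
* Ties in the argmax selection are broken toward the lowest arm index — a
  probability-zero event under the continuous model.

## Designs and error-rate control

Calibrating against the tilde (worst-case) rule gives the *flexible* design:
its critical value controls the familywise error rate strongly for **any**
selection rule based on the interim data, because no rule can exceed the
conditional error of the argmax-`theta_tilde` rule, and the familywise error
is maximised at the global null. Calibrating against `theta_hat` or
`theta_breve` reproduces the designs that pre-specify selection by the
adjusted estimate or by primary data only; the breve critical value does not
depend on `rho`. Evaluating a breve- or hat-calibrated critical value under
worst-case selection (`error_rate_given_c`) quantifies the inflation that
motivates the flexible calibration; at the base design (below) with
`rho = 0.9` the analytic inflation of the primary-only value 2.19 is about
0.030 versus the nominal 0.025.

## Simulator

`flexselect.simulator` offers two engines.

* *sufficient*: draws (selection statistics, final statistics) directly from
  the joint law via the shared-control decomposition; exact, vectorised, and
  used for 10^5-replicate operating characteristics in seconds. Requires
  known nuisance parameters.
* *individual*: simulates patient-level bivariate responses. Second-cohort
  primary responses are drawn jointly with their short-term responses, so
  the conditional structure that the worst-case statistic exploits is
  present. This engine supports the estimated-nuisance workflow: per
  replicate, (sigma, sigma0, rho) are estimated from the interim data
  (pooled within-arm moments by default; per-arm averaging optional), the
  scale factor is plugged into the selection statistic, and the critical
  value is looked up from the rho grid. With known nuisance parameters the
  final z uses the known sigma, matching the sufficient engine; the
  estimated-nuisance path uses the pooled sample SE.

Default study conditions mirror the base design used throughout:
`k = 3, n1 = 40, N1 = 100, n2 = 200, alpha = 0.025, sigma = sigma0 = 1`,
with the power scenario `theta_long = (1/3, 0, 0)` and 100 000 replicates.
Because the adjusted-estimate rule is invariant to a common shift of the
true short-term effects (the adjustment cancels them — an exact identity,
tested with matched seeds), power results do not depend on the unspecified
true short-term effects; they default to zero.

## Combination-test comparator

The inverse-normal comparator (`flexselect.combination`) splits by
recruitment time: stage 1 is the primary endpoint of the `N1` per-group
patients recruited before the interim look (analysed when observed, i.e. at
trial end), stage 2 the `n2 - N1` per-group patients recruited after
selection. The stage-1 p-value for the selected arm is adjusted by a
one-sided Dunnett-type correction over the k comparisons with shared
control (correlation 1/2); Bonferroni is available as a sensitivity option.
Weights are `w1 = sqrt(N1/n2)`, `w2 = sqrt((n2-N1)/n2)`. Both p-values are
p-clud for any selection rule (the stage-1 cohort is selection-free, and the
selected statistic is dominated by the maximum whose Dunnett p is uniform),
which is verified by simulation. A cohort-mean engine runs the flexible
design and the combination test on identical simulated trials for
head-to-head power comparisons; the combination test is slightly less
powerful at matched configurations, and its exact cells depend on
construction details (intersection test, weights) that admit several
conventions, so only the qualitative ordering is asserted.

## Worked-example fixture

`fixture_table1` generates a patient-level dataset whose per-arm cohort
means equal the printed interim summaries of the motivating Alzheimer's
(galantamine, ADAS-Cog) example exactly, by mean-shifting bivariate normal
draws with `rho = 0.77` and unit dispersions; the final-analysis arms are
rescaled so the estimated SE of the mean difference is exactly 0.525. Means
— and hence all three selection statistics and the final z = 6.59 — are
exact; dispersions are synthetic, since the source summaries do not report
them, so nuisance-estimate values from this fixture are only approximately
0.77.

## What the synthetic generators do and do not show

All generators draw from the same homoscedastic bivariate-normal,
equal-allocation model that underlies the calibration. Passing tests
demonstrate internal correctness (calibration, distribution theory,
estimators) and reproduce the published operating characteristics, but say
nothing about robustness to non-normal responses, unequal variances or
allocation, dropout, or drift between cohorts — all outside this model, as
are multi-stage extensions, early stopping, and selection of more than one
arm.

## Known limitations

* Small first stages (around `n1 = 10..20`) with estimated nuisance
  parameters show slight error inflation (a plug-in effect, no small-sample
  correction is applied); the method is not recommended at such sizes.
* The quadrature evaluates mixtures of at most moderate `k` (tested to
  `k = 3`; the cost is linear in `k`).
* Invalid-design guards on the conditional variance and `rho_e` are
  defensive: for structurally valid designs (`n1 < N1 <= n2`, `|rho| < 1`)
  those quantities are automatically in range.
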