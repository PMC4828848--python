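# Methods

## Generating model

Each simulated trial is a parallel two-group design with `n = 100`
participants per arm measured at `J = 4` occasions. Outcomes follow a
random-intercept model

    Y_ij = mu[g_i, j] + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_e^2),

with `g_i` the arm (0 control, 1 treatment). This induces a
compound-symmetric within-subject covariance
`Sigma = sigma_b^2 J + sigma_e^2 I`, so the within-subject correlation is
`rho = sigma_b^2 / (sigma_b^2 + sigma_e^2)`. Outcomes mimic SF-36
norm-based composite scores: both arms start at mean 50 and the total
variance is fixed at 110 (SD ~ 10.49). Variance scenarios are
`(sigma_b^2, sigma_e^2) in {(77, 33), (55, 55), (33, 77)}`, i.e.
`rho in {0.7, 0.5, 0.3}`. Values are continuous Gaussians at full floating
precision; item-level questionnaire structure, integer scoring and
floor/ceiling effects are deliberately not modelled.

The default (linear) trajectory holds the control arm flat at 50 and moves
the treatment arm linearly to 54.18, an end-of-study effect of 4.18 chosen
so the planned complete-data two-sample *t*-test has 80% power
(`theoretical_ttest_power(100, 4.18, sqrt(110)) = 0.801`, noncentral-t,
two-sided alpha 0.05). A second, attenuating-effect trajectory is shipped
as `make_nonlinear_trajectory()`; its cell means (control 50, 52, 51, 50;
treatment 50, 58, 56, 54.18) are illustrative defaults — any 2 x J grid
with equal baselines is accepted via `make_custom_trajectory`. Both arms'
end-of-study difference is what power and bias are measured against.

## Dropout mechanisms

Dropout is monotone (nobody returns) and baseline is always complete.
Targets are *cumulative* per-arm dropout proportions at the final visit;
they are spread over the J-1 post-baseline waves as a constant per-wave
hazard `d = 1 - (1 - target)^(1/(J-1))` — the least-informative schedule
given only a cumulative figure; other schedules would change how much
partial follow-up the MMRM can exploit, which is why the MMRM power values
(unlike the complete-case ones, which depend only on the final-visit count)
are schedule-dependent.

- **MCAR** — each still-observed subject drops with probability `d`,
  independent of outcomes.
- **MAR** — at wave j the dropout probability is
  `expit(alpha_{g,j} + s * g(Y_{i,j-1}))`: logistic in the *previous*,
  observed value.
- **MNAR** — identical but in the *current* value `Y_ij`, which is then
  deleted (retained internally with `observed = False` for diagnostics,
  never shown to estimators).

Two selection directions: `low_only`, `g(y) = -(y - 50)` (feeling poorly
-> staying home), and `both_tails`, `g(y) = |y - 50|` (poorly or
particularly well); deviations are measured from the population norm 50,
not arm-specific means, so a treated arm drifting upward naturally sheds
more "vacation" dropouts. The slope default is `s = 0.25` log-odds per
score unit — strong selection, roughly an odds ratio of 12 across one
10-point SD. The intercept `alpha_{g,j}` is recalibrated on every
replicate's at-risk subjects by bracketed root-finding (Brent, mean
probability matched to ~1e-12), so realized cumulative dropout matches the
target in expectation *regardless* of the slope. Power and bias magnitudes
under MAR/MNAR do depend on `s`: stronger selection means more bias in the
complete-case estimate. With `s = 0.25` the complete-case bias under
one-reason MAR at rho = 0.7 is far more negative than under weak
selection; only the signs and orderings (MMRM unbiased and more powerful
than the t-test under MAR) are slope-invariant, and only those are asserted.

Scenario registry: `complete`, `mcar_equal` (40/40), `mar_unequal_one`
(50 control / 30 treatment, low_only), `mar_unequal_two` (both_tails),
`mar_equal` (40/40 both_tails), and the three MNAR counterparts. A
`missing_scale` knob turns any scenario into a reduced-missingness variant
(e.g. 10-15%) without new code.

## Estimators

**Complete-case t-test.** Pooled-variance two-sample t-test among subjects
observed at the analysis occasion; df = n1 + n2 - 2. Welch's form is
available (`equal_var=False`) but the pooled form matches the design power
calculation and is the default.

**MMRM.** Saturated cell-means model (one mean per arm x occasion, no
trajectory assumption) with a single covariance matrix shared by both arms
— matching the generating model; arm-specific covariance is out of scope.
Subject i contributes the Gaussian log-density of its observed sub-vector.
Estimation is REML by default (ML available); the cell means are profiled
out by generalized least squares at every covariance evaluation, and the
covariance parameters are maximized by L-BFGS-B with the exact analytic
gradient of the profiled criterion:

    dF/dSigma = sum over patterns of  Vinv [n V - E - n P] Vinv

(V the pattern sub-matrix, E the residual cross-product sum, P the matching
block of the GLS information inverse; P enters under REML only), chained
through the parameterization. Structures:

- **CS**: `Sigma = sigma^2 [(1 - rho) I + rho J]`, parameters
  `(log sigma^2, scaled logistic z)` with `rho in (-1/(J-1), 1)` so Sigma
  stays positive definite;
- **UN**: log-Cholesky factors, `J(J+1)/2 = 10` free parameters at 4
  visits.

Subjects are grouped by missingness pattern x arm and the likelihood is
evaluated from per-group sufficient statistics (count, sum, outer-product
sum), so an objective evaluation costs a handful of <= 4x4 factorizations
independent of n — with monotone dropout there are at most 2J groups.
Start values come from the pooled complete-pairs covariance of within-cell
residuals, eigenvalue-clipped to SPD. Convergence is declared when the
optimizer succeeds or the final gradient's max-norm is below 1e-3 (the
L-BFGS line search occasionally halts "abnormally" when already at the
optimum); non-convergence is flagged on the fit, counted, and excluded
from Monte-Carlo summaries (observed failure rate ~0 at these sizes).
A cell (arm x occasion) with no observed data makes the saturated mean
non-estimable; the fit raises an error naming the cell.

**Contrast.** The treatment effect is the difference in fitted cell means
at the analysis occasion; its SE comes from `(sum_i X_i' V_i^-1 X_i)^-1`.
The t statistic uses df = (subjects in the fit) - 2. Kenward-Roger or
Satterthwaite corrections are not implemented: with ~100 subjects per arm
all candidate df rules agree to about three decimals of the p-value. On
complete data the MMRM contrast reproduces the t-test estimate exactly
(GLS = OLS under balance), and the UN fit's SE matches the pooled-t SE, a
property the tests assert to 1e-8.

The CS fit is cross-validated against an independent implementation
(statsmodels `MixedLM` random-intercept model, which is exactly the CS
model for rho >= 0): variance components and contrast agree to ~1e-3
relative on missing-data fits.

## Monte-Carlo evaluation

Per scenario: simulate -> impose dropout -> run the three analyses at the
final occasion -> aggregate. Power is `100 x #(p < alpha)/R` (strict
inequality), percent bias `100 x (mean estimate - 4.18)/4.18`, each with
the binomial MC standard error `100 sqrt(p(1-p)/R)` attached. One master
seed drives a `SeedSequence` spawn per replicate (separate streams for
simulation and dropout), so runs are reproducible and replicates are
order-independent. Per-replicate records (estimate, p, convergence,
realized dropout) are retained and written by the CLI so summaries can be
recomputed without re-simulation.

### Problem sizes

The packaged test suite runs scenario checks at 2,000 replicates (MC SE of
a power percentage ~1.1 points; tolerances in the tests are stated as
multiples of the replicate-level MC SE). `scripts/acceptance.py` runs the
MCAR power-gain experiment at the full 10,000 replicates (MC SE of the
paired power difference ~0.4 points, computed on the common replicates so
the methods' rejection indicators are correlated and the difference is
estimated more precisely than either power alone).

## What the generator does and does not emulate

Passing tests show that, under Gaussian compound-symmetric data with
logistic monotone dropout, the MMRM recovers the design power lost by
complete-case analysis and stays unbiased under MAR. Real trial data
deviate in ways the generator deliberately omits: bounded/discretized
scores, non-normal tails, intermittent (non-monotone) missingness,
covariate-dependent dropout, unequal randomization, and more than four
visits (where the UN structure's J(J+1)/2 parameters grow quickly and its
power cost need not stay negligible). The real-data reader accepts
non-monotone patterns — the observed-data likelihood does not need
monotonicity — but conclusions from the simulation grid transfer to such
data only qualitatively.

## Known limitations

- MNAR bias magnitudes are strongly slope-dependent; the package reports
  them but makes no claim they match any particular published magnitude.
- The t-test/MMRM df rule matters for very small trials; below ~30
  subjects per arm a Kenward-Roger-style correction (not implemented)
  would be preferable.
- `bias_pct` is undefined for a zero true effect by construction; null
  scenarios should assess type-I error via `power_pct` instead.
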