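# mmrmsim

Many longitudinal randomized controlled trials are ultimately judged by a
comparison of arms at one time point — usually the final visit. A common
analysis is a two-sample *t*-test restricted to participants still observed
at that visit, but longitudinal studies lose participants, and a
complete-case *t*-test both discards the partial follow-up of dropouts and
is only valid when missingness is completely at random. A mixed model for
repeated measures (MMRM) with a contrast at the target visit uses every
observed measurement and remains unbiased under missing-at-random dropout.

`mmrmsim` is a simulation pipeline for quantifying that trade-off. It is
aimed at trial statisticians and methodologists who want to reproduce,
extend or teach the comparison. It provides:

- a generator for two-arm longitudinal trials under a random-intercept model
  `Y_ij = mu[arm,j] + b_i + e_ij` with `b_i ~ N(0, sigma_b^2)` and
  `e_ij ~ N(0, sigma_e^2)`, giving compound-symmetric within-subject
  correlation `rho = sigma_b^2 / (sigma_b^2 + sigma_e^2)`; outcomes mimic
  SF-36 norm-based scores (mean 50, total variance 110, end-of-study
  treatment effect 4.18);
- monotone dropout mechanisms — MCAR, MAR (per-wave dropout logistic in the
  previous visit's value) and MNAR (logistic in the current, deleted value)
  — with intercepts calibrated per arm and wave so cumulative dropout hits
  specified targets (e.g. 40%/40% or 50%/30%);
- three analyses of each replicate: complete-case pooled *t*-test, MMRM
  with compound-symmetric (CS) covariance, and MMRM with unstructured (UN)
  covariance, each yielding the treatment contrast at the final visit. The
  MMRM is a saturated cell-means model fitted by profiled REML on the
  observed-data Gaussian likelihood;
- Monte-Carlo evaluation: power `100 x #(p < 0.05)/R` and percent bias
  `100 x (mean estimate - 4.18)/4.18`, with per-replicate records kept.

## Worked example

```python
import numpy as np
import mmrmsim as m

design = m.TrialDesign()                      # 100/arm, 4 visits, alpha 0.05
means = m.make_linear_trajectory(50, 4.18, 4) # control flat, treatment to 54.18
var = m.variance_components(110, rho=0.5)     # sigma_b^2 = sigma_e^2 = 55

print(round(m.theoretical_ttest_power(100, 4.18, np.sqrt(110)), 3))
# 0.801  -- the design's planned power

data = m.simulate_trial(design, means, var, seed=1)
data = m.apply_mcar(data, m.SCENARIOS["mcar_equal"], seed=2)   # 40%/40%
print(m.run_example(data).report())
# Treatment contrast at occasion 4
#   ttest   : estimate   4.09  SE  1.81  p 0.0260  (n = 63 + 56)
#   mmrm_cs : estimate   4.04  SE  1.72  p 0.0201  (n = 100 + 100)
#   mmrm_un : estimate   4.14  SE  1.67  p 0.0139  (n = 100 + 100)
```

On this replicate the *t*-test keeps only the 119 completers (SE 1.81)
while both MMRMs use all 200 participants and estimate the same contrast
with a smaller standard error — the mechanism behind the MMRM's power
advantage. Replicated scenarios aggregate this:

```python
cfg = m.ScenarioConfig(rho=0.7, dropout=m.SCENARIOS["mcar_equal"],
                       n_replicates=2000, master_seed=7)
s = m.run_scenario(cfg)
print({k: round(s[k].power_pct, 1) for k in ("ttest", "mmrm_cs", "mmrm_un")})
# {'ttest': 58.6, 'mmrm_cs': 70.5, 'mmrm_un': 70.6}
```

Under 40% MCAR dropout at rho = 0.7, complete-case power falls to ~58%
while the MMRM retains ~70% — and estimating ten covariance parameters (UN)
instead of two (CS) costs essentially nothing at four visits.

The same grid is available from a shell:

```sh
mmrmsim simulate --scenario mcar_equal --rho all --replicates 2000 \
                 --seed 7 --out results/
mmrmsim analyze results_trial.csv --method mmrm-cs --time 4
```

## Real data

`read_long_csv` maps any long-format CSV (subject, arm, time, value) onto
the package's containers; `HELP_MCS_MAP` is a ready-made column map for the
publicly downloadable HELP trial SF-36 mental composite score data
(https://www3.amherst.edu/~nhorton/r2/datasets.php — download `helpfull`,
keep columns id/treat/time/mcs). `run_example(data, time_index)` then
prints the three-way comparison at, e.g., the 24-month visit. The dataset
is not bundled; fetching it is a user step.

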