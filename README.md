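# partnest

Design and analysis of **partially nested trials with a binary outcome**.

Trials of group-administered treatments (group therapy, exercise classes) or
care-provider treatments compare a *clustered* arm — patients nested in
therapy groups or therapists, whose outcomes are correlated — with an
*un-clustered* control arm of independent patients. Standard cluster-trial
methodology assumes clustering in both arms and does not carry over directly.
`partnest` implements analysis, power/sample-size calculation and
Monte-Carlo evaluation for this design, for trial statisticians planning or
analysing such studies.

## The model

Clustered-arm outcomes follow a logistic-normal model: cluster *j* draws a
latent log-odds η*ⱼ* ~ N(η_G, σ²_U) and its members are Bernoulli(expit η*ⱼ*);
controls are independent Bernoulli(π_C). Scenarios are specified on the
*manifest* scale — the marginal event probability π_G and the intra-cluster
correlation of the binary outcome

ρ = (π₁₁ − π₁²) / (π₁(1 − π₁)),

with (η_G, σ_U) recovered by solving the normal-mixture integrals
numerically (`solve_latent`).

Analysis methods provided:

* **SMT / SATT** — summary-measures test of per-cluster proportions against
  individual control outcomes (normal reference, or t with Satterthwaite
  moment-matched df);
* **ATP** — adjusted test of proportions, with the clustered arm's variance
  inflated by a design effect D (equal, size or minimum-variance cluster
  weights) and the ICC estimated by one-way ANOVA;
* **LRI / LRC** — logistic random intercept / random coefficient models by
  Gauss–Hermite maximum likelihood, with Wald and likelihood-ratio tests.
  The LRC places the random effect only in the clustered arm and is
  *inconsistent* for a null effect on the proportion scale (`lrc_null_bias`
  computes its asymptotic bias); it is therefore gated behind a warning;
* **LGEE** — logistic GEE (independence or exchangeable working
  correlation) with robust sandwich errors for the marginal log-odds ratio.

Power and sample size use normal approximations on three scales — the
difference of proportions (PROP), the log-odds ratio (LOG-ODDS) and the
arc-sine transform γ = 2 arcsin √π (ARC-SINE) — each inflating the clustered
arm by DE = 1 + (m − 1)ρ, plus noncentral-t Satterthwaite variants,
allocation-ratio optimisation (λ_eq, λ_max) and a cluster-size-CV
adjustment to the design effect.

## Worked example

```python
from partnest import (LatentScenario, TrialDesign, simulate_trial,
                      summary_measures_test, fit_lri, lrt, wald_test)

scenario = LatentScenario.from_manifest(pi_g=0.15, pi_c=0.40, rho=0.05)
design = TrialDesign.equal(k=10, m=10, n_control=100)
data = simulate_trial(scenario, design, seed=77)

print(summary_measures_test(data))
lri = fit_lri(data)
print(lrt(lri, fit_lri(data, constrain_null=True)))
```

Running `python examples/analyze_trial.py` (which does the above for all six
methods) prints:

```
       smt: estimate -0.1800 (risk_difference), p_two 0.0090, p_lower 0.0045
      satt: estimate -0.1800 (risk_difference), p_two 0.0139, p_lower 0.0069
atp_minvar: estimate -0.1800 (risk_difference), p_two 0.0133, p_lower 0.0066
  lri_wald: estimate -1.1009 (logodds_cluster_specific), p_two 0.0169, p_lower 0.0084
   lri_lrt: estimate -1.1009 (logodds_cluster_specific), p_two 0.0271, p_lower 0.0136
 lgee_wald: estimate -0.9949 (logodds_marginal), p_two 0.0154, p_lower 0.0077
```

The three proportion-scale methods share the point estimate (−0.18 risk
difference) under equal cluster sizes but differ in how they reference the
statistic; the LRI estimates a cluster-specific log-odds ratio (−1.10),
attenuated to −0.99 on the marginal scale by GEE. All agree the group
treatment reduces the event rate at the 5% level.

The other example scripts cover power/sample size and allocation
(`power_and_samplesize.py`), the random-coefficient null bias
(`lrc_null_bias.py`) and Monte-Carlo test size and power
(`simulation_study.py`). A thin CLI mirrors the library:
`partnest analyze|power|samplesize|simulate|fixtures --help`.

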