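# Methods

## The design and its asymmetry

A partially nested trial compares a clustered arm — `k` therapy groups (or
therapists) of sizes `m_j`, total `N_G = Σ m_j` — with `N_C` independent
control subjects. The outcome is binary. Clustering exists in one arm only,
which breaks the between-arm symmetry that cluster-randomised methodology
relies on: variances differ by arm by construction, and the sampling
distribution of any between-arm contrast is asymmetric whenever the event
rate is away from 0.5. Two consequences run through the package: tests must
accommodate unequal variances (hence the Satterthwaite machinery), and
two-sided error probabilities can be very unevenly split between tails even
when their sum is near nominal — so every test reports `p_lower` and
`p_upper` separately, and the simulation harness tabulates per-tail
rejection rates.

## Population model and the latent/manifest link

Clustered-arm data are generated (and modelled) as logistic-normal: cluster
`j` draws `eta_j ~ N(eta_G, sigma_U^2)` once, members are
`Bernoulli(expit(eta_j))`. Controls are iid `Bernoulli(pi_C)`. Design inputs
live on the manifest scale: the marginal probability
`pi_1 = E[expit(eta + sigma_U Z)]` and the intra-cluster correlation
`rho = (pi_11 - pi_1^2) / (pi_1 (1 - pi_1))` with
`pi_11 = E[expit(eta + sigma_U Z)^2]`.

`solve_latent(pi, rho)` inverts this map by nested univariate Brent
root-finding: for a trial `sigma` the location `eta(sigma)` solves the
marginal equation (strictly monotone in `eta`); the outer equation matches
the manifest ICC, which is strictly increasing in `sigma`. The bracket is
`sigma ∈ [0, 5]` (a manifest ICC of 0.1 at `pi = 0.05` needs only
`sigma ≈ 1.4`; values beyond the cap correspond to ICCs far outside the
plausible 0–0.1 range for treatment-induced clustering and raise an
explicit error). Inner/outer tolerances are 1e-12/1e-10 with a residual
check at 1e-8; `rho = 0` returns `(logit(pi), 0)` exactly. Degenerate
requests (`pi ∈ {0, 1}`, `rho = 1`) are rejected, not clamped.

All mixing integrals use fixed-order Gauss–Hermite quadrature (probabilists'
weights, renormalised to the standard normal). The default order is 64 for
the scalar link integrals and 40 inside model likelihoods; tests verify
agreement with adaptive quadrature to ~1e-9 and insensitivity of fits
between 20 and 40 nodes. Fixed-order rules were chosen over adaptive ones
because the integrands are smooth, bounded and unimodal over the parameter
region in scope (`|eta| ≤ ~6`, `sigma ≤ ~2` for data generation; cluster
sizes ≤ 20 in fits), and a deterministic rule makes every result exactly
reproducible.

Plausible ICC defaults follow an effect-size argument: writing a
standardized effect `d` as a variance fraction `(d/2)^2 / (1 + (d/2)^2)`,
medium (0.5) and large (0.8) effects correspond to 5.9% and 13.8% of total
variance, motivating 0.05 and 0.1 as reference values of `rho`
(`cohen_variance_fraction`).

## Why the random-coefficient model is excluded from recommendations

Two mixed parameterisations differ only in where the random effect enters:
the random intercept (LRI) puts `u_j` in both arms (controls as singleton
clusters sharing `sigma_U`), the random coefficient (LRC) multiplies it by
the treatment indicator. For this design the *unconstrained* maximised
log-likelihoods coincide — the control block depends on the parameters only
through its implied marginal probability, so the two models are
reparameterisations of one another — but the null models (`delta = 0`)
differ. Under LRI a null `delta` implies equal marginal proportions; under
LRC the model compares a cluster-specific effect with a marginal control, so
a proportion-scale null forces
`delta -> eta_G - logit(pi)`, non-zero whenever `pi != 0.5` and
`sigma_U > 0`, antisymmetric about `pi = 0.5`, increasing in `rho`, and
independent of cluster size. `lrc_null_bias` computes this limit by
quadrature plus root-finding (at `pi = 0.1`, `rho = 0.1` it is −0.397);
`fit_lrc` emits a warning and the CLI requires an explicit flag.

## Estimation details

**Mixed logistic likelihood.** Outcomes are exchangeable within a cluster,
so a cluster's marginal likelihood depends only on (size, event count).
Clusters are aggregated into such patterns with multiplicities before
optimisation — for equal clusters of size `m` there are at most `m + 1`
clustered patterns plus two control patterns — making the fit cost
independent of the number of clusters (a 40 000-cluster fit costs the same
as a 10-cluster fit). Optimisation is L-BFGS-B on
`(alpha, delta, sigma_U ≥ 0)` with the analytic score (posterior-weighted
quadrature residuals), started from the control log-odds, the raw log-odds
difference, and the ANOVA ICC converted through the latent-scale ICC
`sigma^2 / (sigma^2 + pi^2/3)`. Convergence requires optimizer success or a
score norm below 1e-5 at tolerances `ftol = 1e-13`, `gtol = 1e-9`. The
search region is bounded (`|alpha| ≤ 20`, `|delta| ≤ 40`, `sigma_U ≤ 8`);
a solution pinned near a bound signals a degenerate likelihood ridge and is
reported as a non-convergence failure, as is an arm with observed event rate
0 or 1 (no information about a log-odds contrast). The covariance is the
inverse observed information, obtained lazily by central differences of the
analytic score; when `sigma_U` sits at the zero boundary its row/column is
dropped. The likelihood-ratio test keeps the chi-squared(1) reference —
`delta` is interior; the `sigma_U` boundary affects fits, not the `delta`
test — which makes the LRT conservative when the true ICC is 0, a property
the tests check. Per-tail attribution for the LRT follows the sign of the
fitted `delta`; an exact zero counts as no rejection in either direction.

**Proportion-scale tests.** The SMT uses equal cluster weights, the sample
variance of cluster proportions (ddof 1), and the moment (ddof 1) control
variance `p_C(1-p_C) N_C/(N_C-1)`, keeping estimation moment-based in both
arms; SATT refers the same statistic to a t distribution with the
moment-matched df. The ATP supports equal, size and minimum-variance cluster
weights with the matching design effects; the pooled proportion in the null
SE is total events over total subjects (the natural pooled estimator; the
alternatives differ only at higher order). Minimum-variance weights are
one-pass — ANOVA ICC first, then weights, no iteration. Negative ANOVA ICC
estimates are truncated to 0 (keeping `D ≥ 1`), with the raw value retained
in the result.

**GEE.** Logistic estimating equations with independence or exchangeable
working correlation and robust sandwich covariance are delegated to
statsmodels (scale fixed at 1; the exchangeable correlation uses
statsmodels' moment estimator; no small-sample df correction, matching
z-type inference). The mixed likelihoods above are authored here; the plain
logistic MLE serves only as an independent oracle in tests.

## Power and sample size

Three normal-approximation calculations share the structure
`power = Phi^{-1}-shifted` with arm variances `v_C/N_C + v_G·DE/N_G`,
`DE = 1 + (m-1)rho`: PROP (`v = pi(1-pi)` in the numerator of the effect
scale), LOG-ODDS (`v = 1/[pi(1-pi)]`), ARC-SINE (`v = 1`, the
variance-stabilised scale). The printed one-term power expression is the
default; the two-term version (adding the opposite-tail rejection
probability, relevant only near zero effect) is available via
`two_term=True`. Sample-size mode ceils `N_C`, takes `k = ceil(lambda N_C/m)`
whole clusters, sets `N_G = k·m`, and reports the achieved power recomputed
at the rounded sizes. Allocation: `lambda_eq` (same power as 1:1 at fixed
total size) and `lambda_max = sqrt(lambda_eq)` (optimal) per scale.

The Satterthwaite variant evaluates a noncentral-t at the two-sided critical
value of a central t whose df come from the *population* variances
(`v_1 = pi_G(1-pi_G)DE/m` over `k` cluster summaries vs `v_2 = pi_C(1-pi_C)`
over `N_C` controls; arcsine analogues drop the `pi(1-pi)` factors). This is
an approximation: the exact treatment integrates a noncentral F over the
distribution of the variance estimates, which is out of scope here; the
approximation converges to the normal-based power as `k` grows and
lower-bounds it for small `k` (both tested).

Cluster-size variation enters as `DE = 1 + ((1+cv^2)m - 1)rho`, the
relative-variance inflation appropriate for equal-weight analyses; a
variance parameterisation converts via `cv = sigma_m/m`. This specific form
is an interpretive choice — the literature states only that cv/variance
terms are added to the design effect — and matters little in scope, since
therapy-group cv is typically below ~0.25 where the adjustment is a few
percent.

## The simulation harness

Each replicate draws its own `numpy` Generator keyed by `(seed, replicate)`,
so reports are bit-for-bit reproducible and independent of execution order.
Per method the harness records the estimate, two-sided and per-tail
rejections at `alpha`, and the ICC estimate (ANOVA for ATP, the manifest
back-transform for LRI, the working correlation for GEE). Bias is measured
against each method's own estimand: `pi_G - pi_C` for proportion-scale
methods, the marginal log-odds ratio for GEE, and the cluster-specific
log-odds ratio `eta_G - eta_C` (with `eta_C` solving the control marginal
equation) for the mixed models. Failures — degenerate arms or
non-convergence — are excluded from denominators and reported, with an
option to count them as non-rejections for sensitivity. Monte-Carlo 95% CIs
use the normal approximation `rate ± 1.96 sqrt(rate(1-rate)/n)`; at 20 000
replicates the half-width stays below ±0.005 for rates up to 0.07.

Default replication is 2 000–5 000 per scenario (CIs of roughly ±1 to
±0.6 pp on a test size near 5%), with larger counts available by
configuration; the acceptance script uses 6 000 and 10 000 replicates for
its two stochastic quantities.

## What the generator does and does not emulate

The generator reproduces the study conditions of interest: equal cluster
sizes (5–20), manifest ICC 0–0.1, event rates 0.05–0.95, controls
un-clustered. It does not model varying or informative cluster sizes,
missing data, covariates, or non-normal random effects. Passing tests
therefore certify behaviour *under the logistic-normal mechanism*: in real
trials where the random-effect distribution is skewed, cluster sizes vary
grossly, or attendance is outcome-related, the small-sample test-size and
bias results here are indicative, not guaranteed. Because data generation
and the mixed-model analyses share the logistic-normal family, the
parameter-recovery results are within-family consistency checks, not
robustness evidence (the beta-binomial alternative was deliberately not
used, to avoid confounding model disagreement with small-sample behaviour).

## Known limitations

* No covariate adjustment (the `beta x_i` term in the linear predictors is
  not implemented).
* Satterthwaite power is the population-variance-df approximation, not the
  exact noncentral-F treatment.
* GEE working structures are limited to independence and exchangeable.
* Designs with clustering in both arms (fully nested) are out of scope.
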