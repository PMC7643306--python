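# Methods

## Model

Two parallel groups with a continuous endpoint, equal variances and
equal allocation: `X_i^I ~ N(mu_I, sigma^2)`, `X_i^C ~ N(mu_C, sigma^2)`,
`i = 1..n` per group, testing `H0: mu_I - mu_C <= 0` against the
one-sided superiority alternative. Everything is parameterised by the
standardized effect `Delta = (mu_I - mu_C)/sigma`; `sigma` never enters
on its own (only the patient-level simulator uses raw `mu` and `sigma`,
and validates that their ratio matches `Delta`).

The two-stage design observes `n1 < n` patients per group at interim.
The interim statistic is the pooled-SD z-type statistic
`T1 = (Xbar_1^I - Xbar_1^C)/S_pooled,1 * sqrt(n1/2)`; the final
analysis uses the inverse normal combination
`T_{1+2} = (w1*T1 + w2*T2)/sqrt(w1^2+w2^2)` of `T1` and the incremental
statistic `T2` built exclusively from second-stage data. All analytic
formulas treat the stage statistics as exactly normal (the known-
variance approximation); only the fixed-design sample size uses the
noncentral t, because that anchor is defined by a t-test.

With default weights `w_i = sqrt(n_i)`, the pair `(T1, T_{1+2})` is
bivariate normal with mean `(Delta*sqrt(n1/2), Delta*sqrt(n/2))`, unit
variances and correlation `rho = sqrt(n1/n)`. We deliberately implement
the covariance as *unit variances with off-diagonal `rho`*: a printed
source for this design family shows the matrix with `sqrt(n1/n)` on the
diagonal and 1 off it, which is not a valid correlation matrix and is
read here as a typographical transposition — the implemented law is the
only one consistent with `Cov(T1, T_{1+2}) = sqrt(n1/n)` and it
reproduces all published operating characteristics. The simulator's
empirical correlation test pins this down independently.

## Stopping rules and probabilities

Stop for efficacy iff `p1 <= alpha1`; stop for futility (non-binding)
iff `p1 > alpha0`; continue iff `alpha1 < p1 <= alpha0`; reject at the
final analysis iff `p_{1+2} <= alpha_{1+2}`. One-sided p-values are
`p = 1 - Phi(T)` throughout, so under any continuous law the boundary
convention (`>` vs `>=`) has probability zero; the non-strict
continuation convention above is what the simulator applies to ties.

* futility stop: `P(p1 > alpha0) = Phi(z_{1-alpha0} - Delta*sqrt(n1/2))`
  (equals `1 - alpha0` under the null);
* efficacy stop: `1 - Phi(z_{1-alpha1} - Delta*sqrt(n1/2))`;
* overall power: efficacy stop + the continuation rectangle
  `P(z_{1-alpha0} < T1 <= z_{1-alpha1}, T_{1+2} > z_{1-alpha_{1+2}})`.
  The continuation term is evaluated directly as a rectangle
  probability (non-negative by construction) rather than as a signed
  difference of orthant CDF values, whose sign convention is easy to
  get wrong.

Pocock local levels solve
`c + P(T1 < z_{1-c}, T_{1+2} >= z_{1-c}) = alpha` for the common level
`c = alpha1 = alpha_{1+2}` under the null law. Because the futility
rule is non-binding, it is *not* credited in this equation: type I
error control never relies on the stop being executed, and the actual
type I error with stopping applied is below `alpha`.

## The admissible conditions and the optimum

Given limits `pi_wrong` (probability of wrongly stopping under the
planning effect `Delta`) and `Pow_loss` (global power given up at
`Delta`), a boundary is admissible when both hold. Condition (i)
inverts in closed form, `alpha0 >= 1 - Phi(z_{pi_wrong} +
Delta*sqrt(n1/2))`. Condition (ii) is equivalent to the *lost power* —
the probability of stopping for futility in a replication where the
final analysis would have rejected,
`P(T1 <= z_{1-alpha0}, T_{1+2} > z_{1-alpha_{1+2}})` — being at most
`Pow_loss`; we solve this tail equation by Brent root finding rather
than differencing two near-equal powers, which preserves relative
accuracy when the admissible loss is tiny (down to ~1e-13, needed for
the round-trip identity between `implied_admissible_params` and the
optimizer to hold at 1e-6).

The reference power in (ii) is the group sequential power *without
futility stopping at the same N* (not the nominal planning power): the
design's maximal power is what a futility rule can erode, and this
reading reproduces the published tables.

Both conditions bound `alpha0` from below and the correct-stop
probability `P_{Delta_true}(p1 > alpha0)` for `Delta_true < Delta` is
decreasing in `alpha0`, so the optimum is
`alpha0_opt = max(bound_pi, bound_pow)`, floored at `alpha1` (an empty
continuation region cannot be undercut). The `binding` label names the
achieving bound; ties within 1e-8 are labelled `pi_wrong`, and
`efficacy_floor` marks the degenerate floor case. `pi_wrong = 0`
forces `alpha0 = 1` (never stop) and is permitted with a warning.

## Numerics

* Bivariate-normal rectangles: adaptive Gauss–Kronrod quadrature
  (`scipy.integrate.quad`, `epsabs 1e-12`) of the conditional
  decomposition `phi(x)[Phi(b(x)) - Phi(a(x))]`, truncated at ±9 SD
  (mass beyond < 1e-18). Deterministic, absolute error well below the
  1e-8 contract; cross-checked in tests against `dblquad` and scipy's
  multivariate normal CDF.
* Scalar roots (Pocock level, power-loss bound): Brent's method with
  validated brackets, `xtol <= 1e-12`; the Pocock bracket upper end is
  `alpha` itself, where the excess equals the non-negative continuation
  tail, so the root stays bracketed even as `n1/n -> 1`.
* Sample size: normal-approximation start
  `n ≈ 2((z_{1-alpha}+z_{power})/Delta)^2`, then exact noncentral-t
  stepping to the minimal integer.
* Rounding for display: published-style tables print 2 decimals
  (nearest); files carry 6 decimals so a written CSV re-parses to the
  computed values at 6 significant digits.

## Monte-Carlo oracle

`gsfutility.simulate` re-derives every operating characteristic without
the analytic machinery. `z_scale` mode draws `(T1, T2)` from their
normal laws and combines them; `patient_level` mode draws individual
observations, computes the pooled-SD interim statistic and a
second-stage-only `T2`, and converts to p-values by the normal
approximation. The generator emulates exactly the idealised model —
normal endpoints, common known-to-be-equal variances, equal
allocation, no dropout, no drift between stages — so agreement of the
two routes validates the algebra and the adequacy of the normal
approximation at the studied sample sizes (n1 >= 35 per group), not
robustness to real-data violations (non-normality, variance
heterogeneity, attrition).

Streams: a single master seed; the batch driver derives the stream for
effect index `i` as `SeedSequence((seed, i))`, so estimates for an
effect are invariant to the rest of the effect list. Default 1e5
replications (binomial SE <= 0.0016); 1e6 used where a type I error of
0.025 must be resolved to three standard errors.

## Problem sizes and defaults

The shipped example settings are the published study conditions:
`Delta = 0.5`, one-sided `alpha = 0.025`, interim at 50% information,
`N ∈ {140, 172, 188}` and admissible grids
`Pow_loss ∈ {0.01, 0.05}`, `pi_wrong ∈ {0.01, 0.05, 0.10}`. The test
suite runs the simulator at 1e4–1e6 replications depending on the
precision the check needs; the brute-force admissibility oracle scans
`alpha0` in steps of 1e-4.

## Limitations

Two stages only; equal allocation; Pocock levels (the level solver is
the single place an alternative spending rule would plug in); no
binding-futility re-optimization of local levels; no sample-size
recalculation at interim; continuous endpoints only. The optimality
notion is the minimum-admissible-boundary criterion — other defensible
criteria (conditional power, utility maximization, joint optimization
of boundary and interim timing) are out of scope.
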