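# gsfutility

Optimal futility stopping boundaries for two-stage group sequential
superiority trials with a continuous endpoint.

## The problem

A two-arm trial compares a continuous endpoint between an intervention
and a control, `X ~ N(mu_I, sigma^2)` vs `N(mu_C, sigma^2)`, testing
`H0: mu_I - mu_C <= 0` one-sided. A group sequential design adds an
interim analysis after `n1` of the `n` patients per arm: the trial stops
early for **efficacy** when the interim p-value satisfies `p1 <= alpha1`
and for **futility** (non-binding) when `p1 > alpha0`. Otherwise it
continues and rejects at the final analysis when `p_{1+2} <= alpha_{1+2}`,
where the final statistic is the inverse normal combination
`T_{1+2} = (w1*T1 + w2*T2)/sqrt(w1^2 + w2^2)` of the independent
stage-wise z-statistics. With the customary weights `w_i = sqrt(n_i)`,
`(T1, T_{1+2})` is bivariate normal with means
`(Delta*sqrt(n1/2), Delta*sqrt(n/2))`, unit variances and correlation
`sqrt(n1/n)`, where `Delta = (mu_I - mu_C)/sigma` is the standardized
effect — so every operating characteristic is an exact bivariate-normal
rectangle probability.

Efficacy boundaries are well studied (here: Pocock's constant local
levels `alpha1 = alpha_{1+2}`, solved so the global one-sided type I
error equals `alpha`); futility boundaries, in contrast, are often set
arbitrarily (a common convention is `alpha0 = 0.5`). This package
derives the boundary from two pre-specified performance limits:

* **(i) wrong stopping** — the probability of stopping for futility
  although the effect truly equals the planning effect `Delta` must not
  exceed `pi_wrong`:  `P_Delta(p1 > alpha0) <= pi_wrong`, equivalently
  `alpha0 >= 1 - Phi(z_{pi_wrong} + Delta*sqrt(n1/2))`;
* **(ii) power loss** — the global power given up by the futility rule
  must not exceed `Pow_loss`.

Both conditions are lower bounds on `alpha0`, while the probability of
*correctly* stopping (under no or a diluted effect) grows as `alpha0`
shrinks — so the optimal boundary is the **minimum admissible** one,
`alpha0_opt = max` of the two bounds. It is intended for trial
statisticians planning a two-stage design who want the futility rule's
consequences quantified, not guessed.

## Worked example

A quality-of-life trial plans to detect a 10-point score difference at a
common SD of 20 (`Delta = 0.5`) with one-sided `alpha = 0.025` and power
0.90, interim at 50% information, allowing at most 5 points of power
loss and a 5% wrong-stop chance (`examples/optimal_boundary.py`):

```
fixed-design t-test sample size: 86 per group, N = 172 total
Pocock local levels alpha1 = alpha12 = 0.0147 (interim at n1 = 43/group)
group sequential power without futility stopping: 0.88

optimal futility boundary alpha0 = 0.2503 (binding constraint: pi_wrong)
  wrong-stop bound 0.2503, power-loss bound 0.1362

actual power with the futility rule: 0.86
P(stop for futility | effect = 0.5):  0.05  (wrong stop)
P(stop for futility | effect = 0.25): 0.31  (correct stop)
P(stop for futility | effect = 0): 0.75  (correct stop)
```

Reading: the t-test needs 172 patients; run group-sequentially with
Pocock levels the same N gives power 0.88. The smallest futility
boundary whose wrong-stop probability stays below 5% is `p1 > 0.25`;
the power-loss condition would have allowed an even smaller one. With
that rule the trial keeps 0.86 power, stops a truly null treatment at
interim 75% of the time, and stops a genuinely effective one only 5% of
the time.

The same API exposes the other direction: `implied_admissible_params`
reports the power loss and wrong-stop probability an *arbitrary*
boundary (say the conventional 0.5) implies, and `sensitivity_grid`
tabulates `alpha0_opt` with full operating characteristics over a grid
of `(Pow_loss, pi_wrong)` choices (`examples/sensitivity_table.py`).
A Monte-Carlo simulator (`gsfutility.simulate`, z-scale or
patient-level with pooled-SD statistics) independently verifies every
analytic probability (`examples/monte_carlo_check.py`).

A thin CLI wraps the same functions:

```sh
gsfutility --delta 0.5 --alpha 0.025 --n-total 188 --n-total 140 \
    --pow-loss 0.01 --pow-loss 0.05 --pi-wrong 0.01 --pi-wrong 0.05 --pi-wrong 0.10 \
    --out table.csv --format csv
```

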