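"""Plan a two-stage trial and derive its optimal futility boundary.

The setting mirrors a quality-of-life superiority trial: a score
difference of 10 points at a common SD of 20 (standardized effect
delta = 0.5), one-sided alpha = 0.025, target power 0.90, and an
interim analysis after half the patients.
"""

from gsfutility import (
    AdmissibleParams,
    DesignSpec,
    fixed_design_sample_size,
    optimal_futility_boundary,
    overall_power,
    performance_profile,
)

delta, alpha = 0.5, 0.025

n = fixed_design_sample_size(delta, alpha, power=0.90)
print(f"fixed-design t-test sample size: {n} per group, N = {2 * n} total")

design = DesignSpec.from_total(delta, alpha, 2 * n, info_fraction=0.5)
print(
    f"Pocock local levels alpha1 = alpha12 = {design.alpha1:.4f} "
    f"(interim at n1 = {design.n1_per_group}/group)"
)
print(
    "group sequential power without futility stopping: "
    f"{overall_power(design, None, delta):.2f}"
)

# allow at most 5 points of power loss and at most a 5% chance of
# stopping for futility although the effect truly is delta
params = AdmissibleParams(pow_loss=0.05, pi_wrong=0.05)
result = optimal_futility_boundary(design, params)
print(
    f"\noptimal futility boundary alpha0 = {result.alpha0_opt:.4f} "
    f"(binding constraint: {result.binding})"
)
print(
    f"  wrong-stop bound {result.bound_pi:.4f}, "
    f"power-loss bound {result.bound_pow:.4f}"
)

oc = performance_profile(design, result.alpha0_opt)
print(f"\nactual power with the futility rule: {oc.actual_power:.2f}")
print(f"P(stop for futility | effect = {delta}):  {oc.p_wrong_stop:.2f}  (wrong stop)")
for effect, p in sorted(oc.p_correct_stop.items(), reverse=True):
    print(f"P(stop for futility | effect = {effect:g}): {p:.2f}  (correct stop)")
print(
    "\nThe trial stops at interim when the one-sided p-value exceeds the "
    "boundary; smaller boundaries stop ineffective treatments more often "
    "at the price of power."
)
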