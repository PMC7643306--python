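"""Optimal futility boundaries under admissible conditions.

A futility boundary ``alpha0`` (the trial stops at interim when the
one-sided interim p-value exceeds it) is *admissible* for the planning
effect ``delta`` when

(i)  the probability of wrongly stopping for futility under ``delta``
     is at most ``pi_wrong``:   P_delta(p1 > alpha0) <= pi_wrong, and
(ii) the global power lost by the futility rule is at most
     ``pow_loss``:  power(alpha0) >= power(no futility) - pow_loss.

Because the probability of *correctly* stopping for futility (under the
null or a non-relevant effect) increases as the boundary decreases, the
optimal boundary is the minimum admissible one, i.e. the larger of the
two constraint-specific lower bounds.  Condition (i) inverts in closed
form; condition (ii) is solved by root finding on the monotone power
curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .design import (
    DesignSpec,
    bvn_rectangle,
    futility_stop_probability,
    joint_law,
    overall_power,
)

__all__ = [
    "AdmissibleParams",
    "FutilityResult",
    "OperatingCharacteristics",
    "pi_wrong_bound",
    "pow_loss_bound",
    "optimal_futility_boundary",
    "performance_profile",
    "implied_admissible_params",
    "sensitivity_grid",
]

_TIE_TOL = 1e-8


@dataclass(frozen=True)
class AdmissibleParams:
    """The two admissibility parameters.

    ``pow_loss`` — admissible global power loss caused by the futility
    rule (probability units); must be below the design's power.
    ``pi_wrong`` — admissible probability of wrongly stopping for
    futility when the true effect equals the planning effect delta.
    """

    pow_loss: float
    pi_wrong: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pow_loss < 1.0:
            raise ValueError(f"pow_loss must be in [0, 1), got {self.pow_loss}")
        if not 0.0 <= self.pi_wrong <= 1.0:
            raise ValueError(f"pi_wrong must be in [0, 1], got {self.pi_wrong}")


@dataclass(frozen=True)
class FutilityResult:
    """Optimal boundary with the two constraint lower bounds.

    ``binding`` names the constraint that determines the optimum:
    ``"pi_wrong"`` (wrong-stop bound), ``"pow_loss"`` (power-loss
    bound) or ``"efficacy_floor"`` when both bounds fall at or below
    the efficacy boundary ``alpha1``.
    """

    alpha0_opt: float
    bound_pi: float
    bound_pow: float
    binding: str


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Design performance at a given futility boundary.

    ``actual_power`` — power including the futility rule, at the
    planning effect.  ``p_wrong_stop`` — futility-stop probability at
    the planning effect.  ``p_correct_stop`` — futility-stop
    probability at each requested (smaller) true effect.
    """

    actual_power: float
    p_wrong_stop: float
    p_correct_stop: Mapping[float, float]


def pi_wrong_bound(design: DesignSpec, pi_wrong: float) -> float:
    """Closed-form lower bound on alpha0 from the wrong-stop condition.

        alpha0 >= 1 - Phi( z_{pi_wrong} + delta * sqrt(n1/2) ).

    Decreasing in ``pi_wrong`` and in ``n1``.  The degenerate values
    ``pi_wrong = 0`` (never allow a wrong stop, boundary 1: never stop)
    and ``pi_wrong = 1`` (no constraint, boundary 0) return the limit
    with a warning.
    """
    if not 0.0 <= pi_wrong <= 1.0:
        raise ValueError(f"pi_wrong must be in [0, 1], got {pi_wrong}")
    if pi_wrong == 0.0 or pi_wrong == 1.0:
        warnings.warn(
            f"pi_wrong={pi_wrong} degenerates the wrong-stop bound to "
            f"{1.0 - pi_wrong}",
            stacklevel=2,
        )
        return 1.0 - pi_wrong
    drift = design.delta * math.sqrt(design.n1_per_group / 2.0)
    return float(1.0 - ndtr(ndtri(pi_wrong) + drift))


def pow_loss_bound(design: DesignSpec, pow_loss: float) -> float:
    """Lower bound on alpha0 from the power-loss condition.

    Smallest ``alpha0`` in ``(alpha1, 1]`` whose design power at the
    planning effect is within ``pow_loss`` of the no-futility power at
    the same sample size; found by root finding on the monotone power
    curve.  Returns ``alpha1`` when the constraint holds for every
    boundary (the admissible loss exceeds what even a maximally
    aggressive rule can cost).
    """
    if not 0.0 <= pow_loss < 1.0:
        raise ValueError(f"pow_loss must be in [0, 1), got {pow_loss}")
    # the power given up by the futility rule is exactly the probability of
    # stopping when the final analysis would have rejected; solving on this
    # tail keeps full relative accuracy even for tiny admissible losses
    law = joint_law(design, design.delta)
    z_final = ndtri(1.0 - design.alpha12)

    def lost(a0: float) -> float:
        return bvn_rectangle(-np.inf, ndtri(1.0 - a0), z_final, np.inf, law)

    a_lo = design.alpha1 * (1.0 + 1e-9) + 1e-15
    if lost(a_lo) <= pow_loss:
        return float(design.alpha1)
    # lost() decreases from the full continuation loss to 0 at a0 = 1
    return float(
        optimize.brentq(lambda a0: lost(a0) - pow_loss, a_lo, 1.0, xtol=1e-12)
    )


def optimal_futility_boundary(
    design: DesignSpec, params: AdmissibleParams
) -> FutilityResult:
    """Minimum admissible futility boundary.

    The optimum is ``max(pi_wrong_bound, pow_loss_bound)`` — both
    conditions impose lower bounds and every larger boundary is also
    admissible, while the probability of correctly stopping for
    futility shrinks as the boundary grows.  Ties (within 1e-8) are
    labelled ``pi_wrong``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b_pi = pi_wrong_bound(design, params.pi_wrong)
    b_pow = pow_loss_bound(design, params.pow_loss)

    alpha0 = max(b_pi, b_pow, design.alpha1)
    if alpha0 <= design.alpha1 + _TIE_TOL:
        binding = "efficacy_floor"
    elif b_pi >= b_pow - _TIE_TOL:
        binding = "pi_wrong"
    else:
        binding = "pow_loss"
    return FutilityResult(
        alpha0_opt=float(min(alpha0, 1.0)),
        bound_pi=float(b_pi),
        bound_pow=float(b_pow),
        binding=binding,
    )


def _default_effects(design: DesignSpec) -> tuple[float, ...]:
    # "correct stopping" is evaluated at half the planning effect and at 0
    return (design.delta / 2.0, 0.0)


def performance_profile(
    design: DesignSpec,
    alpha0: float,
    true_effects: Sequence[float] | None = None,
) -> OperatingCharacteristics:
    """Operating characteristics of the design at a futility boundary.

    Power (including the futility rule) and the wrong-stop probability
    are evaluated at the planning effect; futility-stop probabilities
    are reported for each requested true effect (default: half the
    planning effect and the null).
    """
    effects = _default_effects(design) if true_effects is None else tuple(true_effects)
    stop_at_1 = alpha0 >= 1.0
    power = overall_power(design, None if stop_at_1 else alpha0, design.delta)
    wrong = 0.0 if stop_at_1 else futility_stop_probability(
        design, alpha0, design.delta
    )
    correct = {
        float(e): (
            0.0 if stop_at_1 else futility_stop_probability(design, alpha0, e)
        )
        for e in effects
    }
    return OperatingCharacteristics(
        actual_power=float(power),
        p_wrong_stop=float(wrong),
        p_correct_stop=correct,
    )


def implied_admissible_params(
    design: DesignSpec, alpha0: float
) -> AdmissibleParams:
    """Admissibility parameters for which ``alpha0`` is exactly optimal.

    Useful to audit an arbitrarily chosen boundary (e.g. the
    conventional 0.5): reports the wrong-stop probability it implies at
    the planning effect and the power it gives up relative to the
    no-futility design.  Feeding the result back into
    :func:`optimal_futility_boundary` reproduces ``alpha0``.
    """
    if not design.alpha1 < alpha0 <= 1.0:
        raise ValueError(
            f"alpha0 must lie in (alpha1, 1], got {alpha0} with "
            f"alpha1={design.alpha1}"
        )
    if alpha0 >= 1.0:
        return AdmissibleParams(pow_loss=0.0, pi_wrong=0.0)
    pi = futility_stop_probability(design, alpha0, design.delta)
    # the exact power given up: stop for futility although the final
    # analysis would have rejected (full relative accuracy in the tail)
    loss = bvn_rectangle(
        -np.inf,
        ndtri(1.0 - alpha0),
        ndtri(1.0 - design.alpha12),
        np.inf,
        joint_law(design, design.delta),
    )
    return AdmissibleParams(pow_loss=float(loss), pi_wrong=float(pi))


def sensitivity_grid(
    designs: DesignSpec | Iterable[DesignSpec],
    pow_loss_values: Sequence[float],
    pi_wrong_values: Sequence[float],
    true_effects: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Optimal boundaries and operating characteristics over a grid.

    One row per ``(design, pow_loss, pi_wrong)`` combination, with
    ``pow_loss`` as the outer loop and ``pi_wrong`` as the inner loop.
    Columns: ``n_total``, ``pow_loss``, ``pi_wrong``, ``alpha0_opt``,
    ``binding``, ``actual_power``, ``p_wrong_stop`` and one
    ``p_stop_at_<effect>`` column per requested true effect.
    """
    if isinstance(designs, DesignSpec):
        designs = [designs]
    designs = list(designs)
    if not pow_loss_values or not pi_wrong_values:
        raise ValueError("pow_loss_values and pi_wrong_values must be non-empty")

    rows = []
    for design in designs:
        effects = (
            _default_effects(design) if true_effects is None else tuple(true_effects)
        )
        for pl in pow_loss_values:
            for piw in pi_wrong_values:
                res = optimal_futility_boundary(
                    design, AdmissibleParams(pow_loss=pl, pi_wrong=piw)
                )
                oc = performance_profile(design, res.alpha0_opt, effects)
                row = {
                    "n_total": design.n_total,
                    "pow_loss": pl,
                    "pi_wrong": piw,
                    "alpha0_opt": res.alpha0_opt,
                    "binding": res.binding,
                    "actual_power": oc.actual_power,
                    "p_wrong_stop": oc.p_wrong_stop,
                }
                for e in effects:
                    row[f"p_stop_at_{e:g}"] = oc.p_correct_stop[float(e)]
                rows.append(row)
    return pd.DataFrame(rows)
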