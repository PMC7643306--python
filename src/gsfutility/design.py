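"""Two-stage group sequential design with inverse normal combination.

The design compares a continuous endpoint between two equally sized
groups with a one-sided superiority hypothesis.  An interim analysis is
performed after ``n1`` patients per group; the final analysis combines
the stage-wise z-statistics with the inverse normal combination

    T_{1+2} = (w1*T1 + w2*T2) / sqrt(w1**2 + w2**2),

so that under a true standardized effect ``delta`` the pair
``(T1, T_{1+2})`` is bivariate normal with means
``(delta*sqrt(n1/2), delta*sqrt(n/2))``, unit variances and correlation
``sqrt(n1/n)`` (with the customary weights ``w_i = sqrt(n_i)``).  All
operating characteristics of the design — local significance levels,
efficacy and futility stopping probabilities, overall power — reduce to
rectangle probabilities of this bivariate normal law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.special import ndtr, ndtri
from scipy.stats import nct
from scipy.stats import t as t_dist

__all__ = [
    "DesignSpec",
    "JointLaw",
    "bvn_rectangle",
    "pocock_local_levels",
    "joint_law",
    "futility_stop_probability",
    "efficacy_stop_probability",
    "overall_power",
    "fixed_design_sample_size",
]

_PHI_TAIL = 9.0  # standard normal mass beyond 9 SD is < 1e-18


@dataclass(frozen=True)
class JointLaw:
    """Bivariate normal law of (T1, T_{1+2}) with unit variances.

    Parameters
    ----------
    mean
        Pair ``(E[T1], E[T_{1+2}])`` under the true standardized effect.
    correlation
        Correlation of the two statistics; ``sqrt(n1/n)`` for the
        default inverse-normal weights.
    """

    mean: tuple[float, float]
    correlation: float

    def __post_init__(self) -> None:
        m1, m2 = self.mean
        if not (math.isfinite(m1) and math.isfinite(m2)):
            raise ValueError("joint-law mean must be finite")
        if not abs(self.correlation) < 1.0:
            raise ValueError(
                f"|correlation| must be < 1, got {self.correlation!r}"
            )


@dataclass(frozen=True)
class DesignSpec:
    """Two-stage group sequential superiority design, equal allocation.

    Parameters
    ----------
    delta
        Standardized effect ``(mu_I - mu_C) / sigma`` the trial is
        powered for (dimensionless).
    alpha
        Global one-sided significance level.
    n_per_group
        Patients per arm at the final analysis (``N = 2*n``).
    n1_per_group
        Patients per arm at the interim analysis.
    alpha1, alpha12
        Local one-sided levels at interim and final analysis.  Use
        :func:`pocock_local_levels` (or :meth:`with_pocock`) to obtain
        constant local levels that exhaust ``alpha`` exactly.
    weights
        Inverse normal combination weights ``(w1, w2)``; default
        ``(sqrt(n1), sqrt(n2))``, which makes the correlation between
        T1 and T_{1+2} equal ``sqrt(n1/n)``.
    """

    delta: float
    alpha: float
    n_per_group: int
    n1_per_group: int
    alpha1: float
    alpha12: float
    weights: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (
            isinstance(self.n_per_group, (int, np.integer))
            and isinstance(self.n1_per_group, (int, np.integer))
        ):
            raise ValueError("per-group sample sizes must be integers")
        if not 0 < self.n1_per_group < self.n_per_group:
            raise ValueError(
                "need 0 < n1_per_group < n_per_group, got "
                f"n1={self.n1_per_group}, n={self.n_per_group}"
            )
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0 < self.alpha1 <= self.alpha:
            raise ValueError("alpha1 must satisfy 0 < alpha1 <= alpha")
        if not 0 < self.alpha12 < 0.5:
            raise ValueError("alpha12 must be in (0, 0.5)")
        if self.weights is None:
            object.__setattr__(
                self,
                "weights",
                (math.sqrt(self.n1_per_group), math.sqrt(self.n2_per_group)),
            )
        w1, w2 = self.weights
        if w1 <= 0 or w2 <= 0:
            raise ValueError("combination weights must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n2_per_group(self) -> int:
        return self.n_per_group - self.n1_per_group

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_group

    @property
    def info_fraction(self) -> float:
        return self.n1_per_group / self.n_per_group

    @property
    def correlation(self) -> float:
        """corr(T1, T_{1+2}) implied by the combination weights."""
        w1, w2 = self.weights
        return w1 / math.hypot(w1, w2)

    # -- constructors -------------------------------------------------------

    @classmethod
    def with_pocock(
        cls,
        delta: float,
        alpha: float,
        n_per_group: int,
        n1_per_group: int,
    ) -> "DesignSpec":
        """Design with constant (Pocock) local levels exhausting ``alpha``."""
        a1, a12 = pocock_local_levels(n1_per_group / n_per_group, alpha)
        return cls(
            delta=delta,
            alpha=alpha,
            n_per_group=n_per_group,
            n1_per_group=n1_per_group,
            alpha1=a1,
            alpha12=a12,
        )

    @classmethod
    def from_total(
        cls,
        delta: float,
        alpha: float,
        n_total: int,
        info_fraction: float = 0.5,
    ) -> "DesignSpec":
        """Pocock design from the total sample size ``N = 2*n``.

        ``info_fraction`` is the planned interim information fraction
        ``n1/n``; both stage sizes must come out as whole patients per
        group (equal allocation), otherwise a ``ValueError`` is raised.
        """
        if n_total % 2:
            raise ValueError("equal allocation requires an even total N")
        n = n_total // 2
        n1 = info_fraction * n
        if abs(n1 - round(n1)) > 1e-9:
            raise ValueError(
                f"interim fraction {info_fraction} of n={n} per group is not "
                "a whole number of patients"
            )
        return cls.with_pocock(delta, alpha, n, int(round(n1)))


# ---------------------------------------------------------------------------
# numerical kernel


def bvn_rectangle(
    lower1: float,
    upper1: float,
    lower2: float,
    upper2: float,
    law: JointLaw,
) -> float:
    """P(lower1 < Z1 <= upper1, lower2 < Z2 <= upper2) under ``law``.

    Unit-variance bivariate normal rectangle probability, computed by
    adaptive quadrature of the conditional decomposition

        integral over x of  phi(x - m1) * [Phi(b(x)) - Phi(a(x))] dx,

    which is deterministic and accurate to well below 1e-8 absolute.
    Infinite limits are admitted.
    """
    if lower1 > upper1 or lower2 > upper2:
        raise ValueError("rectangle limits must satisfy lower <= upper")
    m1, m2 = law.mean
    rho = law.correlation
    if lower1 == upper1 or lower2 == upper2:
        return 0.0

    if rho == 0.0:
        p1 = ndtr(upper1 - m1) - ndtr(lower1 - m1)
        p2 = ndtr(upper2 - m2) - ndtr(lower2 - m2)
        return float(np.clip(p1 * p2, 0.0, 1.0))

    s = math.sqrt(1.0 - rho * rho)
    lo = max(lower1, m1 - _PHI_TAIL)
    hi = min(upper1, m1 + _PHI_TAIL)
    if lo >= hi:
        return 0.0

    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)

    def integrand(x: float) -> float:
        cond_mean = m2 + rho * (x - m1)
        z = x - m1
        dens = inv_sqrt2pi * math.exp(-0.5 * z * z)
        return dens * (
            ndtr((upper2 - cond_mean) / s) - ndtr((lower2 - cond_mean) / s)
        )

    value, _ = integrate.quad(
        integrand, lo, hi, epsabs=1e-12, epsrel=1e-11, limit=200
    )
    return float(np.clip(value, 0.0, 1.0))


# ---------------------------------------------------------------------------
# local significance levels


def pocock_local_levels(
    info_fraction: float, alpha: float
) -> tuple[float, float]:
    """Constant local one-sided levels ``alpha1 = alpha12`` for two stages.

    Solves the type I error equation

        P_H0( p1 <= c  or  (p1 > c and p_{1+2} <= c) ) = alpha

    under the null joint law (zero means, correlation
    ``sqrt(info_fraction)``) for the common local level ``c``.

    Returns
    -------
    (alpha1, alpha12)
        Equal by construction; ``alpha1 < alpha``.
    """
    if not 0.0 < info_fraction < 1.0:
        raise ValueError(f"info_fraction must be in (0, 1), got {info_fraction}")
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")

    null_law = JointLaw(mean=(0.0, 0.0), correlation=math.sqrt(info_fraction))

    def type1_excess(c: float) -> float:
        z = ndtri(1.0 - c)
        # reject at interim (prob c) or continue and reject at final
        tail = bvn_rectangle(-np.inf, z, z, np.inf, null_law)
        return c + tail - alpha

    try:
        # type1_excess(alpha) equals the continuation tail >= 0, so the
        # root is bracketed even as info_fraction -> 1
        c = optimize.brentq(type1_excess, 1e-12, alpha, xtol=1e-13)
    except ValueError as exc:  # pragma: no cover - cannot occur for valid input
        raise RuntimeError("Pocock level root not bracketed in (0, alpha)") from exc
    return float(c), float(c)


# ---------------------------------------------------------------------------
# joint law and stopping probabilities


def _interim_drift(design: DesignSpec, delta_true: float) -> float:
    return delta_true * math.sqrt(design.n1_per_group / 2.0)


def joint_law(design: DesignSpec, delta_true: float) -> JointLaw:
    """Joint law of (T1, T_{1+2}) under the true standardized effect.

    With the default weights the mean is
    ``(delta*sqrt(n1/2), delta*sqrt(n/2))`` and the correlation
    ``sqrt(n1/n)``; for general weights both follow from the inverse
    normal combination of the independent stage statistics.
    """
    w1, w2 = design.weights
    norm = math.hypot(w1, w2)
    m1 = _interim_drift(design, delta_true)
    m_stage2 = delta_true * math.sqrt(design.n2_per_group / 2.0)
    m12 = (w1 * m1 + w2 * m_stage2) / norm
    return JointLaw(mean=(m1, m12), correlation=w1 / norm)


def futility_stop_probability(
    design: DesignSpec, alpha0: float, delta_true: float
) -> float:
    """P(p1 > alpha0): the trial stops for futility at interim.

    Under the null (``delta_true = 0``) the interim p-value is uniform,
    so this equals ``1 - alpha0``.  Strictly decreasing in ``alpha0``.
    """
    if not 0.0 < alpha0 < 1.0:
        raise ValueError(f"alpha0 must be in (0, 1), got {alpha0}")
    # p1 > alpha0  <=>  T1 < z_{1-alpha0}
    return float(ndtr(ndtri(1.0 - alpha0) - _interim_drift(design, delta_true)))


def efficacy_stop_probability(design: DesignSpec, delta_true: float) -> float:
    """P(p1 <= alpha1): the trial stops for efficacy at interim."""
    return float(
        1.0 - ndtr(ndtri(1.0 - design.alpha1) - _interim_drift(design, delta_true))
    )


def overall_power(
    design: DesignSpec,
    alpha0: float | None,
    delta_true: float,
) -> float:
    """Global rejection probability with a non-binding futility rule.

    The null hypothesis is rejected either at interim (``p1 <= alpha1``)
    or, after continuing (``alpha1 < p1 <= alpha0``), at the final
    analysis (``p_{1+2} <= alpha12``):

        P(p1 <= alpha1)
          + P( z_{1-alpha0} < T1 <= z_{1-alpha1},  T_{1+2} > z_{1-alpha12} ).

    ``alpha0=None`` means no futility rule (continuation region
    ``alpha1 < p1 <= 1``).  Non-decreasing in ``alpha0``.
    """
    if alpha0 is None or (isinstance(alpha0, str) and alpha0 == "none"):
        lower1 = -np.inf
    else:
        if alpha0 <= design.alpha1:
            raise ValueError(
                "futility boundary below efficacy boundary: "
                f"alpha0={alpha0} <= alpha1={design.alpha1}"
            )
        if alpha0 > 1.0:
            raise ValueError(f"alpha0 must be <= 1, got {alpha0}")
        lower1 = -np.inf if alpha0 == 1.0 else ndtri(1.0 - alpha0)

    law = joint_law(design, delta_true)
    continuation = bvn_rectangle(
        lower1,
        ndtri(1.0 - design.alpha1),
        ndtri(1.0 - design.alpha12),
        np.inf,
        law,
    )
    return float(efficacy_stop_probability(design, delta_true) + continuation)


# ---------------------------------------------------------------------------
# fixed-design anchor


def fixed_design_sample_size(delta: float, alpha: float, power: float) -> int:
    """Per-group n for a fixed-design two-sample t-test (equal variances).

    Smallest integer ``n`` per group such that the one-sided two-sample
    t-test at level ``alpha`` attains the target ``power`` for the
    standardized effect ``delta``, using the noncentral t distribution
    with ``2n - 2`` degrees of freedom and noncentrality
    ``delta*sqrt(n/2)``.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    if not alpha < power < 1.0:
        raise ValueError(f"power must be in (alpha, 1), got {power}")

    def attained(n: int) -> float:
        df = 2 * n - 2
        crit = t_dist.ppf(1.0 - alpha, df)
        return float(1.0 - nct.cdf(crit, df, delta * math.sqrt(n / 2.0)))

    # normal-approximation start, then walk to the exact noncentral-t answer
    z_a, z_b = ndtri(1.0 - alpha), ndtri(power)
    n = max(2, math.ceil(2.0 * ((z_a + z_b) / delta) ** 2))
    if n > 10_000_000:
        raise ValueError("required sample size unreasonably large")
    while n > 2 and attained(n - 1) >= power:
        n -= 1
    while attained(n) < power:
        n += 1
        if n > 10_000_000:
            raise ValueError("target power unattainable")
    return n
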