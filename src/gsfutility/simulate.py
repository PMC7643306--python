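"""Monte-Carlo oracle for the two-stage design.

Simulates the trial either on the z-statistic scale (stage statistics
drawn directly from their normal laws) or at the patient level
(individual normal observations, pooled-SD stage statistics), applies
the efficacy/futility stopping rules and estimates every operating
characteristic independently of the analytic formulas.  The patient
level mode computes the interim statistic

    T1 = (mean(X1_I) - mean(X1_C)) / S_pooled_1 * sqrt(n1/2)

and the incremental second-stage statistic T2 from second-stage data
only, then combines them with the inverse normal weights; p-values use
the normal approximation, p_i = 1 - Phi(T_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtri

from .design import DesignSpec

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate",
    "estimate_operating_characteristics",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    ``mode`` is ``"z_scale"`` (draw the stage statistics directly) or
    ``"patient_level"`` (draw individual observations with means
    ``mu_i``/``mu_c`` and common SD ``sigma``; their standardized
    difference must equal ``delta_true``).
    """

    delta_true: float
    n_reps: int = 100_000
    seed: int = 0
    mode: str = "z_scale"
    mu_i: float | None = None
    mu_c: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.mode not in ("z_scale", "patient_level"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "patient_level":
            mu_i = 0.0 if self.mu_i is None else self.mu_i
            mu_c = 0.0 if self.mu_c is None else self.mu_c
            sigma = 1.0 if self.sigma is None else self.sigma
            if self.mu_i is None and self.mu_c is None:
                mu_i = self.delta_true * sigma
            object.__setattr__(self, "mu_i", mu_i)
            object.__setattr__(self, "mu_c", mu_c)
            object.__setattr__(self, "sigma", sigma)
            if sigma <= 0:
                raise ValueError("sigma must be positive")
            if abs((mu_i - mu_c) / sigma - self.delta_true) > 1e-12:
                raise ValueError(
                    "(mu_i - mu_c)/sigma must equal delta_true"
                )


@dataclass(frozen=True)
class SimResult:
    """Monte-Carlo estimates with binomial standard errors.

    ``p_reject`` is the overall rejection probability (efficacy stop or
    continuation followed by final rejection); the four outcome
    probabilities efficacy-stop / futility-stop / continue-reject /
    continue-accept partition the replications.  ``corr_all`` is the
    empirical correlation of (T1, T_{1+2}) over all replications (no
    stopping applied); ``corr_continued`` restricts to continuing ones.
    """

    n_reps: int
    p_reject: float
    p_efficacy_stop: float
    p_futility_stop: float
    p_continue: float
    se: Mapping[str, float] = field(repr=False)
    corr_all: float = float("nan")
    corr_continued: float = float("nan")


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def _stage_statistics(
    design: DesignSpec, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (T1, T2) for every replication."""
    reps = config.n_reps
    if config.mode == "z_scale":
        m1 = config.delta_true * math.sqrt(design.n1_per_group / 2.0)
        m2 = config.delta_true * math.sqrt(design.n2_per_group / 2.0)
        t1 = rng.standard_normal(reps) + m1
        t2 = rng.standard_normal(reps) + m2
        return t1, t2

    n1, n2 = design.n1_per_group, design.n2_per_group
    if n1 < 2 or n2 < 2:
        raise ValueError("patient_level mode needs >= 2 patients per group per stage")
    mu_i, mu_c, sigma = config.mu_i, config.mu_c, config.sigma

    def pooled_t(n: int) -> np.ndarray:
        xi = rng.normal(mu_i, sigma, size=(reps, n))
        xc = rng.normal(mu_c, sigma, size=(reps, n))
        diff = xi.mean(axis=1) - xc.mean(axis=1)
        ss = xi.var(axis=1, ddof=1) + xc.var(axis=1, ddof=1)
        s_pooled = np.sqrt(ss / 2.0)  # equal n: pooled variance is the mean
        return diff / s_pooled * math.sqrt(n / 2.0)

    return pooled_t(n1), pooled_t(n2)


def simulate(
    design: DesignSpec, alpha0: float, config: SimConfig
) -> SimResult:
    """Simulate the two-stage trial and estimate its outcome probabilities.

    Stops for efficacy when ``p1 <= alpha1``, for futility when
    ``p1 > alpha0``; otherwise continues and rejects when
    ``p_{1+2} <= alpha12``.  Fully reproducible for a fixed seed.
    """
    if not design.alpha1 < alpha0 <= 1.0:
        raise ValueError(
            f"alpha0 must lie in (alpha1, 1], got {alpha0} with "
            f"alpha1={design.alpha1}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    t1, t2 = _stage_statistics(design, config, rng)
    w1, w2 = design.weights
    t12 = (w1 * t1 + w2 * t2) / math.hypot(w1, w2)

    # one-sided p-values via the normal approximation: p <= a <=> T >= z_{1-a}
    z_eff = ndtri(1.0 - design.alpha1)
    z_fut = ndtri(1.0 - alpha0)  # p1 > alpha0 <=> T1 < z_{1-alpha0}
    z_final = ndtri(1.0 - design.alpha12)

    eff = t1 >= z_eff
    fut = (~eff) & (t1 < z_fut)
    cont = ~(eff | fut)
    reject = eff | (cont & (t12 >= z_final))

    n = config.n_reps
    probs = {
        "p_reject": reject.mean(),
        "p_efficacy_stop": eff.mean(),
        "p_futility_stop": fut.mean(),
        "p_continue": cont.mean(),
    }
    se = {k: _binomial_se(v, n) for k, v in probs.items()}

    corr_all = float(np.corrcoef(t1, t12)[0, 1]) if n > 1 else float("nan")
    corr_cont = (
        float(np.corrcoef(t1[cont], t12[cont])[0, 1]) if cont.sum() > 1 else float("nan")
    )
    return SimResult(
        n_reps=n,
        se=se,
        corr_all=corr_all,
        corr_continued=corr_cont,
        **{k: float(v) for k, v in probs.items()},
    )


def estimate_operating_characteristics(
    design: DesignSpec,
    alpha0: float,
    effect_list: Sequence[float],
    config: SimConfig,
) -> dict[float, SimResult]:
    """One :func:`simulate` call per true effect.

    The random stream for effect ``i`` is seeded with
    ``SeedSequence((config.seed, i))``, so results for any effect are
    invariant to the rest of the list.
    """
    out: dict[float, SimResult] = {}
    for i, effect in enumerate(effect_list):
        sub_seed = np.random.SeedSequence((config.seed, i)).generate_state(1)[0]
        cfg = SimConfig(
            delta_true=float(effect),
            n_reps=config.n_reps,
            seed=int(sub_seed % (2**31)),
            mode=config.mode,
            sigma=config.sigma if config.mode == "patient_level" else None,
        )
        out[float(effect)] = simulate(design, alpha0, cfg)
    return out
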