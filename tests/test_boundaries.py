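"""Optimal-boundary layer: constraint bounds, optimum, grids.

The frozen two-decimal expectations below are the published operating
characteristics of the worked example (quality-of-life trial, delta=0.5,
one-sided alpha=0.025, interim at 50% information, N=188 and N=140).
"""

import math

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from gsfutility import (
    AdmissibleParams,
    DesignSpec,
    implied_admissible_params,
    optimal_futility_boundary,
    overall_power,
    performance_profile,
    pi_wrong_bound,
    pow_loss_bound,
    sensitivity_grid,
)

# (n_total, pow_loss, pi_wrong, alpha0_opt, power, wrong, stop@delta/2, stop@0)
TABLE_ROWS = [
    (188, 0.01, 0.01, 0.46, 0.90, 0.01, 0.13, 0.54),
    (188, 0.05, 0.01, 0.46, 0.90, 0.01, 0.13, 0.54),
    (188, 0.01, 0.05, 0.29, 0.89, 0.03, 0.26, 0.71),
    (188, 0.05, 0.05, 0.22, 0.89, 0.05, 0.33, 0.78),
    (188, 0.01, 0.10, 0.29, 0.89, 0.03, 0.26, 0.71),
    (188, 0.05, 0.10, 0.13, 0.85, 0.10, 0.47, 0.87),
    (140, 0.01, 0.01, 0.59, 0.80, 0.01, 0.10, 0.41),
    (140, 0.05, 0.01, 0.59, 0.80, 0.01, 0.10, 0.41),
    (140, 0.01, 0.05, 0.33, 0.79, 0.05, 0.27, 0.67),
    (140, 0.05, 0.05, 0.33, 0.79, 0.05, 0.27, 0.67),
    (140, 0.01, 0.10, 0.32, 0.79, 0.05, 0.28, 0.68),
    (140, 0.05, 0.10, 0.21, 0.77, 0.10, 0.41, 0.79),
]

# arbitrary conventional boundary 0.5, with its implied admissible params
ARBITRARY_ROWS = [
    (188, 0.0013, 0.008, 0.50, 0.90, 0.01, 0.11, 0.50),
    (140, 0.0018, 0.018, 0.50, 0.80, 0.02, 0.15, 0.50),
]


def _design(n_total, d188, d140):
    return {188: d188, 140: d140}[n_total]


class TestPiWrongBound:
    def test_closed_form_examples(self, d188, d140):
        assert round(pi_wrong_bound(d188, 0.05), 2) == 0.22
        assert round(pi_wrong_bound(d140, 0.01), 2) == 0.59

    def test_median_case(self, d188):
        expected = 1 - ndtr(0.5 * math.sqrt(47 / 2))
        assert pi_wrong_bound(d188, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing(self, d188, d140):
        grid = np.linspace(0.005, 0.5, 40)
        vals = [pi_wrong_bound(d188, q) for q in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # larger interim sample -> smaller bound at fixed pi_wrong
        assert pi_wrong_bound(d188, 0.05) < pi_wrong_bound(d140, 0.05)

    def test_degenerate_values_warn(self, d188):
        with pytest.warns(UserWarning):
            assert pi_wrong_bound(d188, 0.0) == 1.0
        with pytest.warns(UserWarning):
            assert pi_wrong_bound(d188, 1.0) == 0.0


class TestPowLossBound:
    def test_published_examples(self, d188, d140):
        assert round(pow_loss_bound(d188, 0.01), 2) == 0.29
        assert round(pow_loss_bound(d140, 0.01), 2) == 0.32

    def test_bound_achieves_exact_loss(self, d188):
        a0 = pow_loss_bound(d188, 0.02)
        ref = overall_power(d188, None, 0.5)
        assert overall_power(d188, a0, 0.5) == pytest.approx(ref - 0.02, abs=1e-8)

    def test_slack_constraint_returns_efficacy_floor(self, d188):
        # even stopping whenever p1 > alpha1 cannot lose this much power
        max_loss = overall_power(d188, None, 0.5) - overall_power(
            d188, d188.alpha1 * 1.001, 0.5
        )
        assert pow_loss_bound(d188, max_loss + 0.05) == d188.alpha1


class TestOptimalBoundary:
    def test_worked_example_boundaries(self, d188, d140):
        r188 = optimal_futility_boundary(d188, AdmissibleParams(0.05, 0.05))
        r140 = optimal_futility_boundary(d140, AdmissibleParams(0.05, 0.05))
        assert round(r188.alpha0_opt, 2) == 0.22
        assert round(r140.alpha0_opt, 2) == 0.33
        assert r188.binding == "pi_wrong"

    def test_small_admissible_params(self, d188, d140):
        assert round(
            optimal_futility_boundary(d188, AdmissibleParams(0.01, 0.01)).alpha0_opt, 2
        ) == 0.46
        assert round(
            optimal_futility_boundary(d140, AdmissibleParams(0.01, 0.01)).alpha0_opt, 2
        ) == 0.59

    def test_optimum_is_max_of_bounds(self, d188):
        res = optimal_futility_boundary(d188, AdmissibleParams(0.01, 0.10))
        assert res.alpha0_opt == pytest.approx(
            max(res.bound_pi, res.bound_pow), abs=1e-12
        )
        assert res.binding == "pow_loss"

    @pytest.mark.parametrize("row", TABLE_ROWS)
    def test_just_below_optimum_violates_a_condition(self, row, d188, d140):
        n_total, pl, piw, *_ = row
        design = _design(n_total, d188, d140)
        res = optimal_futility_boundary(design, AdmissibleParams(pl, piw))
        a0 = res.alpha0_opt
        ref = overall_power(design, None, design.delta)

        def admissible(a):
            wrong = ndtr(ndtri(1 - a) - design.delta * math.sqrt(design.n1_per_group / 2))
            power_ok = overall_power(design, a, design.delta) >= ref - pl - 1e-10
            return wrong <= piw + 1e-10 and power_ok

        assert admissible(a0)
        below = a0 - 1e-3
        if below > design.alpha1:
            assert not admissible(below)


def _brute_force_optimal(design, pow_loss, pi_wrong, step=1e-4):
    """Scan alpha0 candidates, checking both admissible conditions directly.

    Condition (ii) power is computed by an independent fixed-grid
    trapezoid integral of the continuation probability (cumulative in
    the lower T1 limit), not by the package's adaptive-quadrature path.
    """
    a1, a12 = design.alpha1, design.alpha12
    delta = design.delta
    m1 = delta * math.sqrt(design.n1_per_group / 2)
    m2 = delta * math.sqrt(design.n_per_group / 2)
    rho = math.sqrt(design.n1_per_group / design.n_per_group)
    s = math.sqrt(1 - rho * rho)

    xs = np.linspace(m1 - 9.5, ndtri(1 - a1), 60_001)
    integrand = (
        np.exp(-0.5 * (xs - m1) ** 2)
        / math.sqrt(2 * math.pi)
        * (1.0 - ndtr((ndtri(1 - a12) - m2 - rho * (xs - m1)) / s))
    )
    # cumulative continuation probability from each x to the efficacy limit
    rev = np.concatenate(
        [np.cumsum(((integrand[1:] + integrand[:-1]) / 2)[::-1])[::-1], [0.0]]
    ) * (xs[1] - xs[0])
    eff = 1 - ndtr(ndtri(1 - a1) - m1)
    power_none = eff + rev[0]

    candidates = np.arange(a1 + step, 1.0 + step / 2, step)
    z0 = ndtri(1 - np.clip(candidates, None, 1 - 1e-16))
    cont = np.interp(z0, xs, rev, left=rev[0], right=0.0)
    cond_power = eff + cont >= power_none - pow_loss - 1e-9
    cond_wrong = ndtr(z0 - m1) <= pi_wrong + 1e-9
    ok = cond_power & cond_wrong
    if not ok.any():
        return 1.0
    return float(candidates[np.argmax(ok)])


class TestBruteForceOracle:
    @pytest.mark.parametrize("row", TABLE_ROWS)
    def test_table_cells(self, row, d188, d140):
        n_total, pl, piw, *_ = row
        design = _design(n_total, d188, d140)
        res = optimal_futility_boundary(design, AdmissibleParams(pl, piw))
        brute = _brute_force_optimal(design, pl, piw)
        assert res.alpha0_opt == pytest.approx(brute, abs=2e-4)

    def test_randomized_designs(self):
        rng = np.random.default_rng(987654)
        checked = 0
        while checked < 20:
            n = int(rng.integers(30, 160))
            n1 = int(rng.integers(max(2, int(0.3 * n)), int(0.7 * n) + 1))
            delta = float(rng.uniform(0.2, 0.8))
            alpha = float(rng.choice([0.025, 0.05]))
            pl = float(rng.uniform(0.005, 0.08))
            piw = float(rng.uniform(0.01, 0.2))
            design = DesignSpec.with_pocock(delta, alpha, n, n1)
            res = optimal_futility_boundary(design, AdmissibleParams(pl, piw))
            brute = _brute_force_optimal(design, pl, piw)
            assert res.alpha0_opt == pytest.approx(brute, abs=2e-4), (
                n, n1, delta, alpha, pl, piw,
            )
            checked += 1

    def test_correct_stop_maximal_at_optimum(self, d188):
        """Among admissible boundaries the null stop probability 1-alpha0
        is maximised at the minimum admissible boundary."""
        res = optimal_futility_boundary(d188, AdmissibleParams(0.05, 0.05))
        admissible = np.arange(res.alpha0_opt, 1.0, 1e-3)
        null_stops = 1 - admissible
        assert null_stops.argmax() == 0


class TestPerformanceProfile:
    @pytest.mark.parametrize("row", TABLE_ROWS + ARBITRARY_ROWS)
    def test_published_operating_characteristics(self, row, d188, d140):
        n_total, pl, piw, a0, power, wrong, stop_half, stop_null = row
        design = _design(n_total, d188, d140)
        if (pl, piw, a0) in {(0.0013, 0.008, 0.50), (0.0018, 0.018, 0.50)}:
            alpha0 = 0.5
        else:
            alpha0 = optimal_futility_boundary(
                design, AdmissibleParams(pl, piw)
            ).alpha0_opt
            assert round(alpha0, 2) == a0
        oc = performance_profile(design, alpha0)
        assert round(oc.actual_power, 2) == power
        assert round(oc.p_wrong_stop, 2) == wrong
        assert round(oc.p_correct_stop[design.delta / 2], 2) == stop_half
        assert round(oc.p_correct_stop[0.0], 2) == stop_null

    def test_no_futility_boundary(self, d188):
        oc = performance_profile(d188, 1.0)
        assert oc.p_wrong_stop == 0.0
        assert oc.actual_power == pytest.approx(
            overall_power(d188, None, 0.5), abs=1e-12
        )

    def test_custom_effects(self, d188):
        oc = performance_profile(d188, 0.22, true_effects=[0.1])
        assert set(oc.p_correct_stop) == {0.1}


class TestImpliedParams:
    def test_arbitrary_half_boundary(self, d188, d140):
        p188 = implied_admissible_params(d188, 0.5)
        assert round(p188.pow_loss, 4) == 0.0013
        assert round(p188.pi_wrong, 3) == 0.008
        p140 = implied_admissible_params(d140, 0.5)
        assert round(p140.pi_wrong, 3) == 0.018

    @pytest.mark.parametrize("alpha0", [0.1, 0.22, 0.5, 0.8])
    def test_round_trip_through_optimizer(self, alpha0, d188):
        params = implied_admissible_params(d188, alpha0)
        res = optimal_futility_boundary(d188, params)
        assert res.alpha0_opt == pytest.approx(alpha0, abs=1e-6)

    def test_pi_bound_inverse_round_trip(self, d140):
        a0 = pi_wrong_bound(d140, 0.07)
        assert implied_admissible_params(d140, a0).pi_wrong == pytest.approx(
            0.07, abs=1e-8
        )


class TestSensitivityGrid:
    def test_reproduces_published_table(self, d188, d140):
        table = sensitivity_grid([d188, d140], [0.01, 0.05], [0.01, 0.05, 0.10])
        assert len(table) == 12
        by_key = {
            (row["n_total"], row["pow_loss"], row["pi_wrong"]): row
            for _, row in table.iterrows()
        }
        for n_total, pl, piw, a0, power, wrong, stop_half, stop_null in TABLE_ROWS:
            row = by_key[(n_total, pl, piw)]
            assert round(row["alpha0_opt"], 2) == a0
            assert round(row["actual_power"], 2) == power
            assert round(row["p_wrong_stop"], 2) == wrong
            assert round(row["p_stop_at_0.25"], 2) == stop_half
            assert round(row["p_stop_at_0"], 2) == stop_null

    def test_single_cell_matches_direct_calls(self, d140):
        table = sensitivity_grid(d140, [0.03], [0.07])
        res = optimal_futility_boundary(d140, AdmissibleParams(0.03, 0.07))
        oc = performance_profile(d140, res.alpha0_opt)
        row = table.iloc[0]
        assert row["alpha0_opt"] == pytest.approx(res.alpha0_opt, abs=1e-14)
        assert row["actual_power"] == pytest.approx(oc.actual_power, abs=1e-14)

    def test_ordering_and_monotonicity(self, d188):
        pls = [0.01, 0.03, 0.05]
        piws = [0.02, 0.05, 0.10, 0.15]
        table = sensitivity_grid(d188, pls, piws)
        # pow_loss outer, pi_wrong inner
        assert list(table["pow_loss"][:4]) == [0.01] * 4
        assert list(table["pi_wrong"][:4]) == piws
        for pl in pls:
            sub = table[table["pow_loss"] == pl]
            assert (np.diff(sub["alpha0_opt"]) <= 1e-12).all()
        for piw in piws:
            sub = table[table["pi_wrong"] == piw].sort_values("pow_loss")
            assert (np.diff(sub["alpha0_opt"]) <= 1e-12).all()

    def test_empty_grid_rejected(self, d188):
        with pytest.raises(ValueError):
            sensitivity_grid(d188, [], [0.05])


class TestAdmissibleParamsValidation:
    def test_ranges(self):
        with pytest.raises(ValueError):
            AdmissibleParams(pow_loss=-0.1, pi_wrong=0.05)
        with pytest.raises(ValueError):
            AdmissibleParams(pow_loss=0.05, pi_wrong=1.5)

    def test_zero_pi_wrong_forces_no_stopping(self, d188):
        res = optimal_futility_boundary(d188, AdmissibleParams(0.05, 0.0))
        assert res.alpha0_opt == 1.0
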