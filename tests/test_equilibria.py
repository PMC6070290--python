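"""Fixed-point enumeration, Jacobian stability, and regime classification."""

import numpy as np
import pytest

from commonsgame import (
    FixedPointFamily,
    GrowthClass,
    Outcome,
    Stability,
    SystemState,
    classify_regime,
    classify_stability,
    enumerate_fixed_points,
    jacobian,
    vector_field,
)
from commonsgame.equilibria import reports_to_json

from conftest import random_params


def by_family(reports):
    return {rep.family: rep for rep in reports}


# --- independent oracle: the specialized Jacobians at each equilibrium, as
# --- closed forms in the parameters (diagonal/triangular at the boundary)


def jac_origin(p):
    return np.array([
        [p.p_beta, 0.0],
        [0.0, p.r - p.b_m * p.N * (1 + p.alpha) / p.R_m],
    ])


def jac_coop_depleted(p):
    return np.array([
        [-p.p_beta, 0.0],
        [0.0, p.r - p.b_m * p.N / p.R_m],
    ])


def jac_defector_boundary(p):
    a, bm, rm, n, r = p.alpha, p.b_m, p.R_m, p.N, p.r
    return np.array([
        [p.p_beta + a * bm * ((1 + a) * bm * n - rm * r) / (rm * r), 0.0],
        [a * bm * n * (rm * r - (1 + a) * bm * n) / (rm * r),
         ((1 + a) * bm * n - rm * r) / rm],
    ])


def jac_coop_interior(p):
    a, bm, rm, n, r = p.alpha, p.b_m, p.R_m, p.N, p.r
    return np.array([
        [a * bm * (rm * r - bm * n) / (rm * r) - p.p_beta, 0.0],
        [a * bm * n * (rm * r - bm * n) / (rm * r), (bm * n - rm * r) / rm],
    ])


def jac_interior(p):
    a, bm, rm, n, r = p.alpha, p.b_m, p.R_m, p.N, p.r
    pb = p.p_beta
    x_star = 1 + 1 / a - rm * r / (a * bm * n) + pb * rm * r / (a**2 * bm**2 * n)
    off = (x_star - 1) * (bm * (1 + a) / rm - r / n + pb * r / (a * bm * n))
    return np.array([
        [0.0, off],
        [n * pb, -pb * r / (a * bm)],
    ])


ORACLE_JACOBIANS = {
    FixedPointFamily.origin: jac_origin,
    FixedPointFamily.coop_depleted: jac_coop_depleted,
    FixedPointFamily.defector_boundary: jac_defector_boundary,
    FixedPointFamily.coop_interior: jac_coop_interior,
    FixedPointFamily.interior: jac_interior,
}


class TestEnumeration:
    def test_slow_regime_has_two_points(self, fig1):
        reports = by_family(enumerate_fixed_points(fig1))
        assert set(reports) == {FixedPointFamily.origin, FixedPointFamily.coop_depleted}

    def test_moderate_strong_fine_has_three_points(self, figure_params):
        reports = by_family(enumerate_fixed_points(figure_params["fig2A"]))
        assert set(reports) == {
            FixedPointFamily.origin,
            FixedPointFamily.coop_depleted,
            FixedPointFamily.coop_interior,
        }
        coop = reports[FixedPointFamily.coop_interior].location
        assert coop.y == pytest.approx(1000 - 500 / 0.6)

    def test_moderate_weak_fine_has_four_points(self, figure_params):
        reports = by_family(enumerate_fixed_points(figure_params["fig2C"]))
        assert len(reports) == 4
        interior = reports[FixedPointFamily.interior].location
        assert interior.x == pytest.approx(0.84)
        assert interior.y == pytest.approx(100.0)

    def test_rapid_intermediate_fine_has_five_points(self, figure_params):
        reports = by_family(enumerate_fixed_points(figure_params["fig3C"]))
        assert len(reports) == 5
        interior = reports[FixedPointFamily.interior].location
        assert interior.x == pytest.approx(0.6)
        assert interior.y == pytest.approx(400.0)

    def test_rapid_weak_fine_has_four_points(self, figure_params):
        reports = enumerate_fixed_points(figure_params["fig3E"])
        assert len(reports) == 4
        families = {rep.family for rep in reports}
        assert FixedPointFamily.interior not in families

    def test_residual_oracle_on_printed_sets(self, figure_params):
        """Every admissible closed-form equilibrium zeroes the vector field."""
        for params in figure_params.values():
            for rep in enumerate_fixed_points(params):
                residual = np.abs(vector_field(params, rep.location))
                assert np.max(residual) < 1e-9 * max(1.0, params.R_m)

    def test_count_bound_and_residual_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            params = random_params(rng)
            reports = enumerate_fixed_points(params)
            assert 2 <= len(reports) <= 5
            for rep in reports:
                residual = np.abs(vector_field(params, rep.location))
                assert np.max(residual) < 1e-9 * max(1.0, params.R_m)

    def test_coincident_candidates_merged_keeping_boundary_family(self, fig1):
        # at r = e_c the full-cooperation sustainable point collides with (1, 0)
        params = fig1.with_(r=0.5)
        reports = enumerate_fixed_points(params)
        locs = [tuple(rep.location) for rep in reports]
        assert len(locs) == len(set(locs))
        families = {rep.family for rep in reports}
        assert FixedPointFamily.coop_depleted in families
        assert FixedPointFamily.coop_interior not in families


class TestJacobian:
    def test_printed_matrix_at_origin(self, fig1):
        np.testing.assert_allclose(
            jacobian(fig1, SystemState(0.0, 0.0)), [[0.25, 0.0], [0.0, -0.45]]
        )

    def test_printed_matrix_at_coop_depleted(self, fig1):
        np.testing.assert_allclose(
            jacobian(fig1, SystemState(1.0, 0.0)), [[-0.25, 0.0], [0.0, -0.2]]
        )

    def test_general_jacobian_matches_specialized_forms(self):
        """The general Jacobian evaluated at each equilibrium must reproduce
        the closed-form specialized matrix for that equilibrium family."""
        rng = np.random.default_rng(4321)
        checked = set()
        for _ in range(400):
            params = random_params(rng)
            for rep in enumerate_fixed_points(params):
                expected = ORACLE_JACOBIANS[rep.family](params)
                np.testing.assert_allclose(
                    rep.jacobian, expected, rtol=1e-10, atol=1e-10
                )
                checked.add(rep.family)
            if checked == set(FixedPointFamily):
                break
        assert checked == set(FixedPointFamily)

    def test_boundary_jacobians_triangular(self):
        """Eigenvalues of boundary equilibria equal the diagonal entries."""
        rng = np.random.default_rng(999)
        for _ in range(40):
            params = random_params(rng)
            for rep in enumerate_fixed_points(params):
                if rep.family is FixedPointFamily.interior:
                    continue
                diag = np.sort(np.diag(rep.jacobian))
                eig = np.sort(rep.eigenvalues.real)
                assert np.max(np.abs(rep.eigenvalues.imag)) < 1e-12
                np.testing.assert_allclose(eig, diag, rtol=1e-12, atol=1e-12)

    def test_interior_trace_negative(self):
        rng = np.random.default_rng(2718)
        found = 0
        for _ in range(500):
            if found >= 20:
                break
            params = random_params(rng)
            for rep in enumerate_fixed_points(params):
                if rep.family is FixedPointFamily.interior:
                    assert np.trace(rep.jacobian) < 0
                    found += 1


class TestStability:
    def test_slow_regime_labels(self, fig1):
        reports = by_family(enumerate_fixed_points(fig1))
        assert reports[FixedPointFamily.coop_depleted].stability is Stability.stable
        origin = reports[FixedPointFamily.origin].stability
        assert origin is Stability.saddle
        assert origin.is_unstable

    def test_non_hyperbolic_at_growth_threshold(self, fig1):
        # r = e_c zeroes one eigenvalue of the Jacobian at (1, 0)
        reports = by_family(enumerate_fixed_points(fig1.with_(r=0.5)))
        assert reports[FixedPointFamily.coop_depleted].stability is Stability.non_hyperbolic

    def test_classifier_sign_patterns(self):
        assert classify_stability(np.array([-1.0, -2.0])) is Stability.stable
        assert classify_stability(np.array([1.0, 2.0])) is Stability.unstable
        assert classify_stability(np.array([-1.0, 2.0])) is Stability.saddle
        assert classify_stability(np.array([0.0, -2.0])) is Stability.non_hyperbolic
        # complex pair decided by real part
        assert classify_stability(np.array([-0.1 + 1j, -0.1 - 1j])) is Stability.stable

    def test_exactly_one_stable_point_matches_regime_prediction(self):
        rng = np.random.default_rng(31415)
        for _ in range(200):
            params = random_params(rng)
            stable = [
                rep for rep in enumerate_fixed_points(params)
                if rep.stability is Stability.stable
            ]
            assert len(stable) == 1
            predicted = classify_regime(params).predicted_attractor
            assert stable[0].location.x == pytest.approx(predicted.x, abs=1e-9)
            assert stable[0].location.y == pytest.approx(predicted.y, abs=1e-9 * params.R_m)


class TestRegime:
    def test_printed_set_outcomes(self, figure_params):
        expected = {
            "fig1": Outcome.full_cooperation_depleted,
            "fig2A": Outcome.full_cooperation_sustainable,
            "fig2C": Outcome.coexistence,
            "fig2E": Outcome.coexistence,
            "fig3A": Outcome.full_cooperation_sustainable,
            "fig3C": Outcome.coexistence,
            "fig3E": Outcome.full_defection_sustainable,
        }
        for name, outcome in expected.items():
            label = classify_regime(figure_params[name])
            assert label.outcome is outcome, name

    def test_growth_classes(self, figure_params):
        assert classify_regime(figure_params["fig1"]).growth_class is GrowthClass.slow
        assert classify_regime(figure_params["fig2A"]).growth_class is GrowthClass.moderate
        assert classify_regime(figure_params["fig3A"]).growth_class is GrowthClass.rapid

    def test_attractors(self, figure_params):
        att = classify_regime(figure_params["fig1"]).predicted_attractor
        assert (att.x, att.y) == (1.0, 0.0)
        att = classify_regime(figure_params["fig3E"]).predicted_attractor
        assert att.x == 0.0
        assert att.y == pytest.approx(25.0)

    def test_boundary_case_flagged(self, fig1):
        label = classify_regime(fig1.with_(r=0.5))
        assert label.outcome is Outcome.boundary_case
        assert label.predicted_attractor is None

    def test_zero_fine_rejected(self, fig1):
        with pytest.raises(ValueError):
            classify_regime(fig1.with_(beta=0.0, permissive=True))

    def test_interior_resource_linear_in_p_beta(self, fig1):
        """y* grows linearly in p*beta with slope R_m/(b_m*alpha)."""
        # interior point admissible for tau_d=0.0625 < p*beta < tau_c=0.125
        params = fig1.with_(r=1.0)
        slope = params.R_m / (params.b_m * params.alpha)
        betas = [0.35, 0.4, 0.45, 0.5]
        ys = []
        for beta in betas:
            p = params.with_(p=0.2, beta=beta)
            interior = by_family(enumerate_fixed_points(p))[FixedPointFamily.interior]
            ys.append(interior.location.y)
        diffs = np.diff(ys) / np.diff([0.2 * b for b in betas])
        np.testing.assert_allclose(diffs, slope, rtol=1e-12)


def test_json_serialization_round_trips_structure(fig1):
    import json

    reports = enumerate_fixed_points(fig1)
    doc = json.loads(reports_to_json(fig1, reports, classify_regime(fig1)))
    assert doc["n_fixed_points"] == 2
    assert doc["params"]["r"] == fig1.r
    assert {fp["stability"] for fp in doc["fixed_points"]} == {"stable", "saddle"}
    assert doc["regime"]["outcome"] == "full_cooperation_depleted"
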