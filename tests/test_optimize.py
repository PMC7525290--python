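"""Angle optimization: scaling shortcut, analytic minima, tie-breaking."""

import numpy as np
import pytest

from pjaplan import (
    LoadCase,
    OptimizationProblem,
    RiskModel,
    SubregionStressSummary,
    TrainConfig,
    assemble_and_solve,
    features_at_alpha,
    optimal_pja,
    risk_of_alpha,
    summarize_stress,
    train,
)

UNIT16 = SubregionStressSummary(np.full(8, 0.002), np.full(8, 0.001), "toy")


def _single_feature_model(w_hidden, b_hidden, w_out, b_out=0.0, feature=10, n=18):
    """A network reading one raw feature; no standardization."""
    H = len(w_hidden)
    W1 = np.zeros((H, n))
    W1[:, feature] = w_hidden
    return RiskModel(W1=W1, b1=np.asarray(b_hidden, float),
                     w2=np.asarray(w_out, float), b2=b_out)


def _problem(model, pre=10.0, tol=1e-3):
    return OptimizationProblem(model=model, unit_summary=UNIT16, G=240.0,
                               pre_pja_deg=pre, age=16.0, gender="F",
                               risk_tolerance=tol)


class TestScalingPath:
    def test_matches_full_fem_resolve(self, default_mesh, disc_materials, unit_summary, rng):
        """Feature vectors from the unit-load scaling shortcut must equal the
        full FEM re-solve at five random angles to 1e-6 relative."""
        G, pre = 240.345, 8.0
        pre_sol = summarize_stress(
            assemble_and_solve(default_mesh, disc_materials, LoadCase(G, pre)),
            default_mesh)
        model = RiskModel(W1=np.zeros((2, 18)), b1=np.zeros(2), w2=np.zeros(2), b2=0.0)
        problem = OptimizationProblem(model=model, unit_summary=unit_summary,
                                      G=G, pre_pja_deg=pre, age=16.0, gender="M")
        for alpha in rng.uniform(0.0, 45.0, size=5):
            post_sol = summarize_stress(
                assemble_and_solve(default_mesh, disc_materials, LoadCase(G, float(alpha))),
                default_mesh)
            full = post_sol.as_vector() - pre_sol.as_vector()
            scaled = features_at_alpha(problem, float(alpha))[:16]
            assert np.allclose(scaled, full, rtol=1e-6, atol=1e-12 * np.abs(full).max())

    def test_pre_op_angle_gives_zero_deltas(self):
        model = _single_feature_model([1.0], [0.0], [1.0])
        problem = _problem(model)
        x = features_at_alpha(problem, problem.pre_pja_deg)
        assert np.allclose(x[:16], 0.0)
        assert risk_of_alpha(problem, problem.pre_pja_deg) == pytest.approx(0.5)

    def test_out_of_bounds_rejected(self):
        problem = _problem(_single_feature_model([1.0], [0.0], [1.0]))
        with pytest.raises(ValueError):
            risk_of_alpha(problem, 60.0)


class TestOptimalPja:
    def test_recovers_constructed_analytic_minimum(self):
        """Risk built to have its unique minimum where the mechanism feature
        equals c, i.e. at alpha* = 7.3 deg; the optimizer must land within
        0.1 deg."""
        alpha_star, pre, k = 7.3, 10.0, 2000.0
        # x_10(alpha) = 0.002 * 240 * (cos a - cos pre) = 0.48 (cos a - cos pre)
        c = 0.48 * (np.cos(np.deg2rad(alpha_star)) - np.cos(np.deg2rad(pre)))
        model = _single_feature_model([k, -k], [-k * c + 1.0, k * c + 1.0], [-2.0, -2.0])
        result = optimal_pja(_problem(model, pre=pre, tol=1e-6))
        assert abs(result.alpha_hat_deg - alpha_star) < 0.1
        assert result.risk <= result.risk_curve[:, 1].min() + 1e-12

    def test_monotone_risk_pushes_to_lower_bound(self):
        # risk decreasing in the feature, feature decreasing in alpha ->
        # risk increasing in alpha -> minimum at the lower bound
        model = _single_feature_model([1.0], [0.0], [-5.0])
        result = optimal_pja(_problem(model, tol=1e-12))
        assert result.alpha_hat_deg < 0.2

    def test_constant_model_returns_pre_op_angle(self):
        model = RiskModel(W1=np.zeros((2, 18)), b1=np.zeros(2), w2=np.zeros(2), b2=0.3)
        result = optimal_pja(_problem(model, pre=9.4))
        assert result.alpha_hat_deg == pytest.approx(9.4)
        assert result.diagnostics["flat"]

    def test_never_worse_than_pure_grid(self, rng):
        X = rng.normal(size=(30, 18))
        y = rng.integers(0, 2, 30).astype(float)
        model, _ = train(X, y, TrainConfig(seed=5, epochs=300))
        problem = _problem(model)
        result = optimal_pja(problem)
        assert result.risk <= result.risk_curve[:, 1].min() + problem.risk_tolerance

    def test_deterministic(self):
        model = _single_feature_model([3.0, -1.0], [0.2, 0.1], [1.5, -0.7])
        r1 = optimal_pja(_problem(model))
        r2 = optimal_pja(_problem(model))
        assert r1.alpha_hat_deg == r2.alpha_hat_deg
        assert r1.risk == r2.risk

    def test_risk_curve_is_continuous(self):
        """No jumps beyond a grid-estimated Lipschitz bound."""
        model = _single_feature_model([3.0], [0.0], [2.0])
        result = optimal_pja(_problem(model))
        risks = result.risk_curve[:, 1]
        steps = np.abs(np.diff(risks))
        assert steps.max() < 10 * np.median(steps) + 1e-6

    def test_invalid_bounds_rejected(self):
        model = _single_feature_model([1.0], [0.0], [1.0])
        with pytest.raises(ValueError):
            OptimizationProblem(model=model, unit_summary=UNIT16, G=240.0,
                                pre_pja_deg=10.0, age=16.0, gender="F",
                                alpha_bounds=(30.0, 10.0))
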