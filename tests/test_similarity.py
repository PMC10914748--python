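"""Reduced momentum/energy residuals, boundary closures and the
first-order system used by the solvers."""

import numpy as np
import pytest

from stenoflow import (
    OdeState,
    SimilarityParams,
    as_first_order_system,
    boundary_residuals,
    energy_residual,
    momentum_residual,
)


def crane_state(eta: float) -> OdeState:
    e = np.exp(-eta)
    return OdeState(eta=eta, F=1.0 - e, Fp=e, Fpp=-e, theta=e, thetap=-e,
                    Fppp=e, thetapp=e)


class TestMomentumResidual:
    def test_trivial_state(self):
        state = OdeState(0.3, 0, 0, 0, 0, 0, Fppp=0.0)
        assert momentum_residual(state, gamma=0.7, C1=0.8, C2=1.3) == 0.0

    @pytest.mark.parametrize("eta", [0.0, 0.5, 2.0, 7.0])
    def test_flat_limit_exponential_profile(self, eta):
        """F = 1 - e^-eta solves the flat-limit equation identically."""
        assert momentum_residual(crane_state(eta), gamma=0.0, C1=1.0, C2=1.0) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_pure_shear_free_state(self):
        state = OdeState(1.0, F=1.0, Fp=1.0, Fpp=0.0, theta=0, thetap=0, Fppp=0.0)
        assert momentum_residual(state, gamma=0.0, C1=1.0, C2=1.0) == -1.0

    def test_requires_third_derivative(self):
        with pytest.raises(ValueError, match="F'''"):
            momentum_residual(OdeState(0, 0, 0, 0, 0, 0), 0.0, 1.0, 1.0)


class TestEnergyResidual:
    def test_constant_temperature_no_flow(self):
        state = OdeState(0.4, 0, 0, 0, theta=0.8, thetap=0.0, thetapp=0.0)
        assert energy_residual(state, gamma=2.0, pr=5.0, C3=1.2) == 0.0

    @pytest.mark.parametrize("eta", [0.0, 1.0, 3.0])
    def test_analogy_reduces_to_momentum(self, eta):
        """With theta = F' and Pr C3 = C1 C2 = 1 the energy equation is the
        momentum equation, hence the exponential profile zeroes it too."""
        assert energy_residual(crane_state(eta), gamma=0.0, pr=1.0, C3=1.0) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_curvature_term_only(self):
        state = OdeState(0.7, F=0, Fp=0, Fpp=0, theta=0.7, thetap=1.0, thetapp=0.0)
        # theta appears only through F' theta = 0 here; (1/2)(2*1*1) = 1
        assert energy_residual(state, gamma=1.0, pr=2.0, C3=1.0) == pytest.approx(1.0)

    def test_requires_second_derivative(self):
        with pytest.raises(ValueError, match="theta''"):
            energy_residual(OdeState(0, 0, 0, 0, 1, 0), 0.0, 1.0, 1.0)


class TestBoundaryResiduals:
    def left(self, **kw):
        base = dict(eta=0.0, F=0.0, Fp=0.0, Fpp=0.0, theta=1.0, thetap=0.0)
        base.update(kw)
        return OdeState(**base)

    def right(self, **kw):
        base = dict(eta=1.0, F=0.0, Fp=0.0, Fpp=0.0, theta=0.0, thetap=0.0)
        base.update(kw)
        return OdeState(**base)

    def test_literal_closure_admits_trivial_solution(self):
        params = SimilarityParams(closure="literal")
        res = boundary_residuals(self.left(), self.right(theta=1.0), params)
        assert np.all(res == 0.0)

    def test_stretching_wall_slip_slot(self):
        params = SimilarityParams(closure="stretching-wall")
        res = boundary_residuals(self.left(theta=0.0), self.right(), params)
        assert res[1] == -1.0  # F'(0) - 1
        assert res[2] == -1.0  # theta(0) - 1

    def test_quiescent_edge_uses_values_not_derivatives(self):
        params = SimilarityParams(closure="quiescent-edge")
        res = boundary_residuals(
            self.left(Fp=1.0), self.right(Fp=0.2, theta=0.1, Fpp=9.0, thetap=9.0), params
        )
        assert res[3] == pytest.approx(0.2)
        assert res[4] == pytest.approx(0.1)

    def test_crane_limit_satisfies_quiescent_closure(self):
        params = SimilarityParams(gamma=0.0, phi1=0.0, phi2=0.0,
                                  eta_edge=40.0, closure="quiescent-edge")
        e = np.exp(-40.0)
        left = OdeState(0.0, F=0.0, Fp=1.0, Fpp=-1.0, theta=1.0, thetap=-1.0)
        right = OdeState(40.0, F=1.0 - e, Fp=e, Fpp=-e, theta=e, thetap=-e)
        assert np.max(np.abs(boundary_residuals(left, right, params))) < 1e-15

    def test_unknown_closure_rejected(self):
        with pytest.raises(ValueError, match="closure"):
            SimilarityParams(closure="free-slip")


class TestFirstOrderSystem:
    def test_roundtrip_residuals_vanish(self):
        """Solving for F''' and theta'' then substituting back into the
        residual forms must give zero to round-off at random states."""
        rng = np.random.default_rng(42)
        params = SimilarityParams(gamma=0.8, pr=4.2, phi1=0.03, phi2=0.07, eta_edge=2.0)
        rhs = as_first_order_system(params)
        C1, C2, C3 = params.mixture.C1, params.mixture.C2, params.mixture.C3
        worst = 0.0
        for _ in range(100):
            eta = float(rng.uniform(0, 2))
            y = rng.normal(size=5)
            dy = rhs(np.array([eta]), y.reshape(5, 1)).ravel()
            state = OdeState(eta, *y, Fppp=dy[2], thetapp=dy[4])
            worst = max(
                worst,
                abs(momentum_residual(state, params.gamma, C1, C2)),
                abs(energy_residual(state, params.gamma, params.pr, C3)),
            )
        assert worst < 1e-12

    def test_flat_limit_momentum_slot(self):
        params = SimilarityParams(gamma=0.0, pr=1.0, phi1=0.0, phi2=0.0)
        rhs = as_first_order_system(params)
        y = np.array([0.4, 1.1, -0.3, 0.0, 0.0])
        dy = rhs(np.array([0.5]), y.reshape(5, 1)).ravel()
        assert dy[2] == pytest.approx(y[1] ** 2 - y[0] * y[2], rel=1e-14)

    def test_flat_limit_energy_slot(self):
        params = SimilarityParams(gamma=0.0, pr=1.0, phi1=0.0, phi2=0.0)
        rhs = as_first_order_system(params)
        y = np.array([0.4, 1.1, -0.3, 0.9, -0.2])
        dy = rhs(np.array([0.5]), y.reshape(5, 1)).ravel()
        assert dy[4] == pytest.approx(y[1] * y[3] - y[0] * y[4], rel=1e-14)

    def test_vectorised_evaluation(self):
        params = SimilarityParams()
        rhs = as_first_order_system(params)
        eta = np.linspace(0, 1, 7)
        y = np.ones((5, 7))
        assert rhs(eta, y).shape == (5, 7)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(gamma=-0.1), dict(pr=0.0), dict(eta_edge=0.0), dict(phi1=1.0)],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimilarityParams(**kwargs)
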