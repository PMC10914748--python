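"""Wall post-processing: scaled friction/Nusselt groups, dimensional
fluxes and physical-field reconstruction."""

import dataclasses

import numpy as np
import pytest

from stenoflow import (
    FlowScales,
    SimilarityParams,
    dimensional_wall_fluxes,
    hybrid_mixture,
    nusselt,
    physical_fields,
    skin_friction,
    solve_profile,
    wall_quantities,
)


@pytest.fixture(scope="module")
def trivial_profile():
    return solve_profile(SimilarityParams(closure="literal"))


class TestScaledGroups:
    @pytest.mark.parametrize(
        "gamma, pr, phi", [(0.1, 3.0, 0.05), (1.0, 5.0, 0.0), (0.5, 2.0, 0.1)]
    )
    def test_exact_algebraic_relations(self, gamma, pr, phi):
        """cf * C1 = F''(0) and nu = -(k_hnf/k_f) theta'(0) to round-off."""
        params = SimilarityParams(gamma=gamma, pr=pr, phi1=phi, phi2=phi)
        prof = solve_profile(params)
        mix = params.mixture
        assert skin_friction(prof, mix) * mix.C1 == pytest.approx(prof.Fpp0, rel=1e-14)
        assert nusselt(prof, mix) == pytest.approx(-mix.k_ratio * prof.thetap0, rel=1e-14)

    def test_trivial_solution_zero_groups(self, trivial_profile):
        mix = trivial_profile.params.mixture
        assert skin_friction(trivial_profile, mix) == pytest.approx(0.0, abs=1e-10)
        assert nusselt(trivial_profile, mix) == pytest.approx(0.0, abs=1e-10)

    def test_crane_skin_friction(self, crane_profile):
        mix = hybrid_mixture(0.0, 0.0)
        assert skin_friction(crane_profile, mix) == pytest.approx(-1.0, abs=1e-4)

    def test_analogy_links_nusselt_to_shear(self):
        mix = hybrid_mixture(0.05, 0.05)
        params = SimilarityParams(gamma=0.2, pr=mix.C1 * mix.C2 / mix.C3,
                                  phi1=0.05, phi2=0.05)
        prof = solve_profile(params)
        assert nusselt(prof, mix) == pytest.approx(-mix.k_ratio * prof.Fpp0, abs=1e-6)

    def test_unconverged_profile_refused(self, default_profile):
        bad_diag = dataclasses.replace(default_profile.diagnostics, converged=False)
        bad = dataclasses.replace(default_profile, diagnostics=bad_diag)
        with pytest.raises(ValueError, match="unconverged"):
            skin_friction(bad, default_profile.params.mixture)


class TestMonotoneTrends:
    """Orderings the similarity equations actually produce at the
    reproduction defaults."""

    def _cf(self, gamma=0.1, pr=3.0, phi=0.05):
        params = SimilarityParams(gamma=gamma, pr=pr, phi1=phi, phi2=phi)
        return skin_friction(solve_profile(params), params.mixture)

    def _nu(self, gamma=0.1, pr=3.0, phi=0.05):
        params = SimilarityParams(gamma=gamma, pr=pr, phi1=phi, phi2=phi)
        return nusselt(solve_profile(params), params.mixture)

    def test_nusselt_increases_with_prandtl(self):
        nus = [abs(self._nu(pr=pr)) for pr in (3.0, 3.5, 4.0)]
        assert nus[0] < nus[1] < nus[2]

    def test_friction_magnitude_increases_with_loading(self):
        cfs = [abs(self._cf(phi=phi)) for phi in (0.01, 0.15, 0.2)]
        assert cfs[0] < cfs[1] < cfs[2]

    def test_curvature_strengthens_wall_gradients(self):
        """Transverse curvature steepens both wall gradients (the classical
        stretching-cylinder behaviour)."""
        cfs = [abs(self._cf(gamma=g)) for g in (0.1, 0.5, 1.0)]
        nus = [abs(self._nu(gamma=g)) for g in (0.1, 0.5, 1.0)]
        assert cfs[0] < cfs[1] < cfs[2]
        assert nus[0] < nus[1] < nus[2]


class TestDimensionalFluxes:
    scales = FlowScales(u0=1.0, nu_f=1.0, T0=300.0, T1=310.0, L0=1.0, R=1.0)

    def test_trivial_solution_zero_fluxes(self, trivial_profile):
        mix = trivial_profile.params.mixture
        tau, q = dimensional_wall_fluxes(trivial_profile, mix, self.scales, x=0.5)
        assert tau == pytest.approx(0.0, abs=1e-8)
        assert q == pytest.approx(0.0, abs=1e-7)

    def test_heat_flux_linear_in_temperature_difference(self, default_profile):
        mix = default_profile.params.mixture
        doubled = FlowScales(u0=1.0, nu_f=1.0, T0=300.0, T1=320.0, L0=1.0, R=1.0)
        tau1, q1 = dimensional_wall_fluxes(default_profile, mix, self.scales, x=0.5)
        tau2, q2 = dimensional_wall_fluxes(default_profile, mix, doubled, x=0.5)
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)
        assert tau2 == pytest.approx(tau1, rel=1e-12)

    def test_crane_wall_shear_with_unit_scales(self, crane_profile):
        """With u0 = nu_f = L0 = 1 the wall shear is mu_f * F''(0) * x."""
        mix = hybrid_mixture(0.0, 0.0)
        unit = FlowScales(u0=1.0, nu_f=1.0, T0=0.0, T1=1.0, L0=1.0, R=1.0)
        mu_f = mix.base.rho * unit.nu_f
        x = 0.7
        tau, _ = dimensional_wall_fluxes(crane_profile, mix, unit, x=x)
        assert tau == pytest.approx(mu_f * crane_profile.Fpp0 * x, rel=1e-12)
        assert tau == pytest.approx(-mu_f * x, rel=1e-3)


class TestPhysicalFields:
    scales = FlowScales(u0=2.0, nu_f=3.0e-6, T0=300.0, T1=310.0, L0=0.04, R=0.002)

    def test_wall_values(self, default_profile):
        x = 0.01
        fields = physical_fields(default_profile, self.scales, x)
        assert fields["r"][0] == pytest.approx(self.scales.R, rel=1e-14)
        # stretching-wall closure: u_wall = u0 x / L0 (F'(0) = 1)
        assert fields["u"][0] == pytest.approx(self.scales.u0 * x / self.scales.L0, rel=1e-8)
        assert fields["v"][0] == pytest.approx(0.0, abs=1e-10)
        assert fields["T"][0] == pytest.approx(self.scales.T1, rel=1e-12)

    def test_radius_grows_outward(self, default_profile):
        fields = physical_fields(default_profile, self.scales, 0.01)
        assert np.all(np.diff(fields["r"]) > 0)

    def test_bundled_wall_quantities(self, default_profile):
        wq = wall_quantities(default_profile, default_profile.params.mixture,
                             scales=self.scales, x=0.01)
        assert wq.cf_scaled * default_profile.params.mixture.C1 == pytest.approx(
            wq.Fpp0, rel=1e-14
        )
        assert wq.tau_w is not None and wq.q_w is not None

    def test_missing_axial_position_refused(self, default_profile):
        with pytest.raises(ValueError, match="axial"):
            wall_quantities(default_profile, default_profile.params.mixture,
                            scales=self.scales)
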