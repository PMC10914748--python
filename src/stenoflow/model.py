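"""Model/Results front end for the stenotic-artery similarity problem.

:class:`StenoticFlowModel` bundles the dimensionless parameters (and,
optionally, dimensional scales and the stenosis geometry) of one
boundary-layer solve; :meth:`StenoticFlowModel.fit` runs the BVP solver
and returns a :class:`StenoticFlowResults` carrying the profile, the
wall quantities, solver diagnostics and a ``summary()`` table.

Typical use::

    from stenoflow import StenoticFlowModel

    model = StenoticFlowModel.from_params(gamma=0.1, pr=3.0, phi1=0.05, phi2=0.05)
    res = model.fit()
    print(res.summary())
    res.profile.write_csv("profile.csv")
"""

from __future__ import annotations

from dataclasses import replace

from .geometry import StenosisGeometry, dimensionless_profile
from .materials import HybridMixture
from .similarity import FlowScales, SimilarityParams
from .solver import SolutionProfile, SolverOptions, solve_profile
from .walls import WallQuantities, dimensional_wall_fluxes, physical_fields, wall_quantities

__all__ = ["StenoticFlowModel", "StenoticFlowResults"]


class StenoticFlowModel:
    """One similarity boundary-layer problem in a narrowed vessel.

    Parameters
    ----------
    params : SimilarityParams
        Dimensionless inputs (gamma, Pr, volume fractions, domain edge,
        boundary-condition closure).
    scales : FlowScales, optional
        Dimensional reference scales; required only for dimensional
        post-processing (wall stress/heat flux, physical fields).
    geometry : StenosisGeometry, optional
        Vessel shape; used by :meth:`at_station` to set the domain edge
        to the local dimensionless radius.
    """

    def __init__(
        self,
        params: SimilarityParams,
        scales: FlowScales | None = None,
        geometry: StenosisGeometry | None = None,
    ):
        self.params = params
        self.scales = scales
        self.geometry = geometry

    @classmethod
    def from_params(
        cls,
        gamma: float = 0.1,
        pr: float = 3.0,
        phi1: float = 0.05,
        phi2: float = 0.05,
        eta_edge: float = 1.0,
        closure: str = "stretching-wall",
        scales: FlowScales | None = None,
        geometry: StenosisGeometry | None = None,
    ) -> "StenoticFlowModel":
        """Build the model directly from scalar parameters."""
        params = SimilarityParams(
            gamma=gamma, pr=pr, phi1=phi1, phi2=phi2, eta_edge=eta_edge, closure=closure
        )
        return cls(params, scales=scales, geometry=geometry)

    @classmethod
    def at_station(
        cls,
        xt: float,
        geometry: StenosisGeometry,
        gamma: float = 0.1,
        pr: float = 3.0,
        phi1: float = 0.05,
        phi2: float = 0.05,
        closure: str = "stretching-wall",
        scales: FlowScales | None = None,
    ) -> "StenoticFlowModel":
        """Model at axial station ``xt`` with the domain edge set to f(xt).

        The axial coupling is quasi-similar: each station is an
        independent similarity solve whose only geometric input is the
        local dimensionless radius.
        """
        eta_edge = float(dimensionless_profile(xt, geometry.eps))
        return cls.from_params(
            gamma=gamma, pr=pr, phi1=phi1, phi2=phi2,
            eta_edge=eta_edge, closure=closure,
            scales=scales, geometry=geometry,
        )

    @property
    def mixture(self) -> HybridMixture:
        return self.params.mixture

    def fit(self, options: SolverOptions | None = None, **kwargs) -> "StenoticFlowResults":
        """Solve the boundary-value problem.

        ``kwargs`` (``tol``, ``method``, ``initial_mesh_size``,
        ``max_nodes``) override fields of ``options``.
        """
        opts = options or SolverOptions()
        if kwargs:
            opts = replace(opts, **kwargs)
        profile = solve_profile(self.params, opts)
        return StenoticFlowResults(self, profile)

    def __repr__(self) -> str:
        p = self.params
        return (
            f"StenoticFlowModel(gamma={p.gamma}, pr={p.pr}, phi1={p.phi1}, "
            f"phi2={p.phi2}, eta_edge={p.eta_edge}, closure={p.closure!r})"
        )


class StenoticFlowResults:
    """Fitted similarity solution with wall quantities and diagnostics."""

    def __init__(self, model: StenoticFlowModel, profile: SolutionProfile):
        self.model = model
        self.profile = profile
        self.wall: WallQuantities = wall_quantities(profile, model.mixture)

    # convenience accessors
    @property
    def Fpp0(self) -> float:
        return self.wall.Fpp0

    @property
    def thetap0(self) -> float:
        return self.wall.thetap0

    @property
    def cf_scaled(self) -> float:
        """Scaled skin friction Re_x^{1/2} C_f."""
        return self.wall.cf_scaled

    @property
    def nu_scaled(self) -> float:
        """Scaled Nusselt group Re_x^{-1/2} Nu_x."""
        return self.wall.nu_scaled

    @property
    def diagnostics(self):
        return self.profile.diagnostics

    def to_frame(self):
        return self.profile.to_frame()

    def wall_fluxes(self, x: float, scales: FlowScales | None = None):
        """Dimensional (tau_w, q_w) at axial station x; needs scales."""
        scales = scales or self.model.scales
        if scales is None:
            raise ValueError("dimensional wall fluxes need FlowScales")
        return dimensional_wall_fluxes(self.profile, self.model.mixture, scales, x)

    def physical_fields(self, x: float, scales: FlowScales | None = None):
        """Dimensional (r, u, v, T) arrays at axial station x; needs scales."""
        scales = scales or self.model.scales
        if scales is None:
            raise ValueError("physical fields need FlowScales")
        return physical_fields(self.profile, scales, x)

    def summary(self) -> str:
        """Plain-text summary of inputs, mixture coefficients and wall outputs."""
        p = self.model.params
        mix = self.model.mixture
        d = self.diagnostics
        lines = [
            "Stenotic-artery hybrid-nanofluid boundary layer",
            "=" * 48,
            f"closure:        {p.closure}",
            f"gamma:          {p.gamma:g}",
            f"Pr:             {p.pr:g}",
            f"phi1 (Al2O3):   {p.phi1:g}",
            f"phi2 (Cu):      {p.phi2:g}",
            f"eta_edge:       {p.eta_edge:g}",
            "-" * 48,
            f"C1, C2, C3:     {mix.C1:.6f}, {mix.C2:.6f}, {mix.C3:.6f}",
            f"mu_hnf/mu_f:    {mix.mu_ratio:.6f}",
            f"k_hnf/k_f:      {mix.k_ratio:.6f}",
            "-" * 48,
            f"F''(0):         {self.Fpp0: .6f}",
            f"theta'(0):      {self.thetap0: .6f}",
            f"Re^1/2 Cf:      {self.cf_scaled: .6f}",
            f"Re^-1/2 Nu:     {self.nu_scaled: .6f}",
            "-" * 48,
            f"solver:         {d.method}, {d.n_nodes} nodes, "
            f"max residual {d.max_residual:.2e}, converged={d.converged}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<StenoticFlowResults Fpp0={self.Fpp0:.4f} thetap0={self.thetap0:.4f} "
            f"cf={self.cf_scaled:.4f} nu={self.nu_scaled:.4f}>"
        )
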