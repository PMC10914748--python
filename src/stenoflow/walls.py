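"""Wall quantities and physical-field reconstruction.

From a converged similarity profile the engineering outputs are the
scaled skin-friction group ``Re_x^{1/2} C_f = F''(0)/C1`` and the scaled
heat-transfer (Nusselt) group ``Re_x^{-1/2} Nu_x = -(k_hnf/k_f) theta'(0)``.
Signs are reported exactly as computed; no convention flipping.

With dimensional reference scales the wall shear stress and heat flux
follow by the chain rule through the similarity transform, and the full
velocity/temperature fields can be mapped back onto the radial
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import HybridMixture
from .similarity import FlowScales
from .solver import SolutionProfile

__all__ = [
    "WallQuantities",
    "skin_friction",
    "nusselt",
    "wall_quantities",
    "dimensional_wall_fluxes",
    "physical_fields",
]


@dataclass(frozen=True)
class WallQuantities:
    """Wall derivatives and the scaled friction/heat-transfer groups."""

    Fpp0: float
    thetap0: float
    cf_scaled: float   # Re_x^{1/2} C_f = F''(0)/C1
    nu_scaled: float   # Re_x^{-1/2} Nu_x = -(k_hnf/k_f) theta'(0)
    tau_w: float | None = None  # Pa, needs FlowScales
    q_w: float | None = None    # W/m^2, needs FlowScales


def _require_converged(profile: SolutionProfile) -> None:
    if not profile.diagnostics.converged:
        raise ValueError("refusing to post-process an unconverged profile")


def skin_friction(profile: SolutionProfile, mix: HybridMixture) -> float:
    """Scaled skin friction Re_x^{1/2} C_f = F''(0) / C1 (signed)."""
    _require_converged(profile)
    return profile.Fpp0 / mix.C1


def nusselt(profile: SolutionProfile, mix: HybridMixture) -> float:
    """Scaled Nusselt group Re_x^{-1/2} Nu_x = -(k_hnf/k_f) theta'(0) (signed)."""
    _require_converged(profile)
    return -mix.k_ratio * profile.thetap0


def _deta_dr_wall(scales: FlowScales) -> float:
    # eta = (r^2 - R^2)/(2R) * sqrt(u0/(nu_f L0)) => d eta/dr |_{r=R} = sqrt(u0/(nu_f L0))
    return np.sqrt(scales.u0 / (scales.nu_f * scales.L0))


def dimensional_wall_fluxes(
    profile: SolutionProfile,
    mix: HybridMixture,
    scales: FlowScales,
    x: float,
) -> tuple[float, float]:
    """Wall shear stress tau_w (Pa) and heat flux q_w (W/m^2) at axial station x.

    ``tau_w = mu_hnf du/dr|_wall`` and ``q_w = -k_hnf dT/dr|_wall`` with the
    radial derivatives obtained from the similarity profile by the chain
    rule. The base-fluid dynamic viscosity is ``rho_f * nu_f``.
    """
    _require_converged(profile)
    deta_dr = _deta_dr_wall(scales)
    mu_f = mix.base.rho * scales.nu_f
    mu_hnf = mu_f * mix.mu_ratio
    k_hnf = mix.base.k * mix.k_ratio
    du_dr = (scales.u0 * x / scales.L0) * profile.Fpp0 * deta_dr
    dT_dr = (scales.T1 - scales.T0) * profile.thetap0 * deta_dr
    return mu_hnf * du_dr, -k_hnf * dT_dr


def wall_quantities(
    profile: SolutionProfile,
    mix: HybridMixture,
    scales: FlowScales | None = None,
    x: float | None = None,
) -> WallQuantities:
    """Bundle the scaled wall groups (and dimensional fluxes if scales given)."""
    _require_converged(profile)
    tau_w = q_w = None
    if scales is not None:
        if x is None:
            raise ValueError("axial position x is required with dimensional scales")
        tau_w, q_w = dimensional_wall_fluxes(profile, mix, scales, x)
    return WallQuantities(
        Fpp0=profile.Fpp0,
        thetap0=profile.thetap0,
        cf_scaled=skin_friction(profile, mix),
        nu_scaled=nusselt(profile, mix),
        tau_w=tau_w,
        q_w=q_w,
    )


def physical_fields(profile: SolutionProfile, scales: FlowScales, x: float):
    """Map the similarity profile to physical (r, u, v, T) arrays.

    The similarity coordinate is treated as the nonnegative wall-normal
    coordinate, so ``r = sqrt(R^2 + 2 R eta sqrt(nu_f L0/u0))`` grows
    outward from the wall. Returns a dict of arrays keyed
    ``r, u, v, T`` on the solution's eta grid.
    """
    _require_converged(profile)
    eta = profile.eta
    r = np.sqrt(scales.R**2 + 2.0 * scales.R * eta * np.sqrt(scales.nu_f * scales.L0 / scales.u0))
    u = (scales.u0 * x / scales.L0) * profile.Fp
    v = -(scales.R / r) * np.sqrt(scales.u0 * scales.nu_f / scales.L0) * profile.F
    T = scales.T0 + (scales.T1 - scales.T0) * profile.theta
    return {"r": r, "u": u, "v": v, "T": T}
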