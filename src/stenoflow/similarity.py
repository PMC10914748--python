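"""Similarity-reduced momentum and energy equations and their closures.

The boundary-layer equations for axial velocity and temperature in the
narrowed vessel collapse, under the similarity transformation
``u = (u0 x / L0) F'(eta)``, ``theta = (T - T0)/(T1 - T0)`` with the
wall-normal similarity coordinate ``eta``, into two coupled ODEs:

    (1/(C1 C2)) [(1 + 2 gamma eta) F''' + 2 gamma F''] + F F'' - F'^2 = 0
    (1/(Pr C3)) [(1 + 2 gamma eta) theta'' + 2 gamma theta'] + F theta' - F' theta = 0

where ``gamma = sqrt(nu_f L0 / (u0 R^2))`` multiplies the transverse-
curvature terms and ``C1, C2, C3`` carry the nanoparticle loading
(see :mod:`stenoflow.materials`).

Three boundary-condition closures are supported on ``[0, eta_edge]``:

``literal``
    ``F(0)=0, F'(0)=0, theta(0)=1`` with ``F''=0, theta'=0`` at the edge.
    This set admits only the trivial solution ``F=0, theta=1``; it is kept
    so that the degeneracy can be demonstrated rather than hidden.
``stretching-wall`` (default)
    ``F'(0)=1`` replaces ``F'(0)=0``, consistent with the wall velocity
    scale ``u0 x / L0`` built into the similarity transform; edge
    conditions unchanged (zero shear, zero heat flux).
``quiescent-edge``
    ``F'(0)=1`` at the wall with a quiescent far field
    ``F'(edge)=0, theta(edge)=0``; this is the classical stretching-surface
    configuration whose flat limit has the closed form ``F = 1 - e^-eta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import HybridMixture, hybrid_mixture

__all__ = [
    "CLOSURES",
    "SimilarityParams",
    "FlowScales",
    "OdeState",
    "momentum_residual",
    "energy_residual",
    "boundary_residuals",
    "as_first_order_system",
]

CLOSURES = ("literal", "stretching-wall", "quiescent-edge")


@dataclass(frozen=True)
class SimilarityParams:
    """Dimensionless inputs of one similarity solve.

    Parameters
    ----------
    gamma : float
        Flow/curvature parameter ``sqrt(nu_f L0/(u0 R^2))``; multiplies
        the transverse-curvature terms ``(1 + 2 gamma eta)``.
    pr : float
        Prandtl number of the base fluid (momentum/thermal diffusivity).
    phi1, phi2 : float
        Nanoparticle volume fractions (Al2O3, Cu by default).
    eta_edge : float
        Outer edge of the similarity domain; defaults to 1.0, the
        dimensionless vessel radius f outside the constriction.
    closure : str
        Boundary-condition closure, one of :data:`CLOSURES`.
    """

    gamma: float = 0.1
    pr: float = 3.0
    phi1: float = 0.05
    phi2: float = 0.05
    eta_edge: float = 1.0
    closure: str = "stretching-wall"
    mixture: HybridMixture = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma!r}")
        if not self.pr > 0:
            raise ValueError(f"Prandtl number must be positive, got {self.pr!r}")
        if not self.eta_edge > 0:
            raise ValueError(f"eta_edge must be positive, got {self.eta_edge!r}")
        if self.closure not in CLOSURES:
            raise ValueError(f"unknown closure {self.closure!r}; expected one of {CLOSURES}")
        object.__setattr__(self, "mixture", hybrid_mixture(self.phi1, self.phi2))


@dataclass(frozen=True)
class FlowScales:
    """Dimensional reference scales for mapping back to physical fields.

    ``u0`` is the reference axial velocity (m/s), ``nu_f`` the base-fluid
    kinematic viscosity (m^2/s), ``T0``/``T1`` the far-field and wall
    temperatures (K), ``L0`` the axial reference length and ``R`` the
    local vessel radius (m).
    """

    u0: float = 1.0
    nu_f: float = 1.0
    T0: float = 0.0
    T1: float = 1.0
    L0: float = 1.0
    R: float = 1.0

    def __post_init__(self) -> None:
        for name in ("u0", "nu_f", "L0", "R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.T1 == self.T0:
            raise ValueError("wall and reference temperatures must differ")


@dataclass
class OdeState:
    """Pointwise state (eta, F, F', F'', theta, theta'), optionally with F''' and theta''."""

    eta: float
    F: float
    Fp: float
    Fpp: float
    theta: float
    thetap: float
    Fppp: float | None = None
    thetapp: float | None = None


def momentum_residual(state: OdeState, gamma: float, C1: float, C2: float) -> float:
    """LHS of the reduced momentum equation at one state (requires F''')."""
    if state.Fppp is None:
        raise ValueError("momentum residual needs the third derivative F'''")
    curv = (1.0 + 2.0 * gamma * state.eta) * state.Fppp + 2.0 * gamma * state.Fpp
    return curv / (C1 * C2) + state.F * state.Fpp - state.Fp**2


def energy_residual(state: OdeState, gamma: float, pr: float, C3: float) -> float:
    """LHS of the reduced energy equation at one state (requires theta'')."""
    if state.thetapp is None:
        raise ValueError("energy residual needs the second derivative theta''")
    curv = (1.0 + 2.0 * gamma * state.eta) * state.thetapp + 2.0 * gamma * state.thetap
    return curv / (pr * C3) + state.F * state.thetap - state.Fp * state.theta


def boundary_residuals(left: OdeState, right: OdeState, params: SimilarityParams) -> np.ndarray:
    """Five boundary residuals for the selected closure.

    ``left`` is the wall state at eta = 0, ``right`` the edge state at
    eta = eta_edge.  A converged solution drives all five entries to zero.
    """
    if params.closure == "literal":
        return np.array(
            [left.F, left.Fp, left.theta - 1.0, right.Fpp, right.thetap]
        )
    if params.closure == "stretching-wall":
        return np.array(
            [left.F, left.Fp - 1.0, left.theta - 1.0, right.Fpp, right.thetap]
        )
    if params.closure == "quiescent-edge":
        return np.array(
            [left.F, left.Fp - 1.0, left.theta - 1.0, right.Fp, right.theta]
        )
    raise ValueError(f"unknown closure {params.closure!r}; expected one of {CLOSURES}")


def as_first_order_system(params: SimilarityParams):
    """Return rhs(eta, y) for the first-order system y = [F, F', F'', theta, theta'].

    The third derivative and theta'' are solved for algebraically:

        F'''    = (C1 C2 (F'^2 - F F'') - 2 gamma F'') / (1 + 2 gamma eta)
        theta'' = (Pr C3 (F' theta - F theta') - 2 gamma theta') / (1 + 2 gamma eta)

    The returned callable is vectorised (accepts ``eta`` of shape (m,) and
    ``y`` of shape (5, m)), as expected by collocation solvers.
    """
    C1, C2, C3 = params.mixture.C1, params.mixture.C2, params.mixture.C3
    gamma, pr = params.gamma, params.pr

    def rhs(eta, y):
        eta = np.asarray(eta, dtype=float)
        F, Fp, Fpp, theta, thetap = y
        curv = 1.0 + 2.0 * gamma * eta
        Fppp = (C1 * C2 * (Fp**2 - F * Fpp) - 2.0 * gamma * Fpp) / curv
        thetapp = (pr * C3 * (Fp * theta - F * thetap) - 2.0 * gamma * thetap) / curv
        return np.vstack([Fp, Fpp, Fppp, thetap, thetapp])

    return rhs
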