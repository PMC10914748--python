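"""Thermophysical properties of the base fluid, mono- and hybrid nanofluids.

The working fluid is blood seeded with two nanoparticle species
(aluminium oxide at volume fraction ``phi1``, copper at ``phi2``).
Effective mixture properties follow the standard two-stage mixing rules:
linear volume-weighted density and heat capacity, the Brinkman viscosity
correlation ``mu_f (1-phi)^-2.5`` applied multiplicatively for the two
species, and the Maxwell two-phase conductivity formula chained twice
(the second stage treats the first-stage nanofluid as the continuous
phase).

The module also provides the three dimensionless coefficients ``C1``,
``C2``, ``C3`` that carry the mixture into the similarity-reduced
momentum and energy equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

__all__ = [
    "MaterialProperties",
    "HybridMixture",
    "MATERIALS",
    "get_material",
    "register_material",
    "density_mixture",
    "rhocp_mixture",
    "viscosity_ratio",
    "maxwell_conductivity_ratio",
    "hybrid_mixture",
    "model_coefficients",
]


@dataclass(frozen=True)
class MaterialProperties:
    """One material: density, specific heat and thermal conductivity.

    Parameters
    ----------
    name : str
        Label used in registries and output tables.
    rho : float
        Density, kg/m^3.
    cp : float
        Specific heat, J kg^-1 K^-1.
    k : float
        Thermal conductivity, W m^-1 K^-1.
    """

    name: str
    rho: float
    cp: float
    k: float

    def __post_init__(self) -> None:
        for field in ("rho", "cp", "k"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(f"{self.name}: {field} must be positive, got {value!r}")

    @property
    def rhocp(self) -> float:
        """Volumetric heat capacity rho*cp, J m^-3 K^-1."""
        return self.rho * self.cp


#: Built-in material constants (base fluid and the two particle species).
_BUILTIN = {
    "blood": MaterialProperties("blood", rho=1050.0, cp=3617.0, k=0.52),
    "Al2O3": MaterialProperties("Al2O3", rho=3970.0, cp=765.0, k=40.0),
    "Cu": MaterialProperties("Cu", rho=8933.0, cp=385.0, k=400.0),
}

MATERIALS = MappingProxyType(_BUILTIN)

_user_materials: dict[str, MaterialProperties] = {}


def get_material(name: str) -> MaterialProperties:
    """Look up a material by name (built-ins first, then user-registered)."""
    if name in _BUILTIN:
        return _BUILTIN[name]
    if name in _user_materials:
        return _user_materials[name]
    known = sorted(set(_BUILTIN) | set(_user_materials))
    raise KeyError(f"unknown material {name!r}; known: {known}")


def register_material(mat: MaterialProperties) -> None:
    """Register a user material. Built-in names cannot be shadowed."""
    if mat.name in _BUILTIN:
        raise ValueError(f"cannot override built-in material {mat.name!r}")
    _user_materials[mat.name] = mat


def _check_fraction(phi: float, name: str = "phi", open_top: bool = False) -> None:
    if not 0.0 <= phi <= 1.0 or (open_top and phi == 1.0):
        top = ")" if open_top else "]"
        raise ValueError(f"{name} must lie in [0, 1{top}, got {phi!r}")


def density_mixture(base: MaterialProperties, particle: MaterialProperties, phi: float) -> float:
    """Effective density of a single nanofluid: (1-phi) rho_f + phi rho_s."""
    _check_fraction(phi)
    return (1.0 - phi) * base.rho + phi * particle.rho


def rhocp_mixture(base: MaterialProperties, particle: MaterialProperties, phi: float) -> float:
    """Effective volumetric heat capacity (rho cp) of a single nanofluid."""
    _check_fraction(phi)
    return (1.0 - phi) * base.rhocp + phi * particle.rhocp


def viscosity_ratio(phi1: float, phi2: float = 0.0) -> float:
    """Brinkman viscosity ratio mu_hnf/mu_f = (1-phi1)^-2.5 (1-phi2)^-2.5.

    Symmetric in its arguments; singular (and rejected) at phi = 1.
    """
    _check_fraction(phi1, "phi1", open_top=True)
    _check_fraction(phi2, "phi2", open_top=True)
    return (1.0 - phi1) ** -2.5 * (1.0 - phi2) ** -2.5


def maxwell_conductivity_ratio(k_cont: float, k_part: float, phi: float) -> float:
    """Maxwell two-phase ratio k_eff/k_cont for spherical inclusions.

    ``k_cont`` is the continuous-phase conductivity, ``k_part`` the
    dispersed particle conductivity, ``phi`` the particle volume fraction.
    """
    if not k_cont > 0 or not k_part > 0:
        raise ValueError(f"conductivities must be positive, got {k_cont!r}, {k_part!r}")
    _check_fraction(phi)
    num = k_part + 2.0 * k_cont - 2.0 * phi * (k_cont - k_part)
    den = k_part + 2.0 * k_cont + phi * (k_cont - k_part)
    return num / den


@dataclass(frozen=True)
class HybridMixture:
    """A hybrid nanofluid with all effective properties and ODE coefficients.

    ``C1 = (1-phi1)^2.5 (1-phi2)^2.5`` (reciprocal of the viscosity ratio),
    ``C2 = rho_hnf/rho_f`` and ``C3 = (k_hnf/k_f) * (rho cp)_hnf/(rho cp)_f``
    are the groups entering the reduced momentum and energy equations.

    ``k_nf_ratio`` is the single-nanofluid (particle 1 in base) Maxwell
    ratio, exposed separately because output tables sometimes normalise the
    heat-transfer group by the mono-nanofluid conductivity instead of the
    hybrid one.
    """

    base: MaterialProperties
    particle1: MaterialProperties
    particle2: MaterialProperties
    phi1: float
    phi2: float
    rho_hnf: float
    mu_ratio: float
    rhocp_hnf: float
    k_nf_ratio: float
    k_ratio: float
    C1: float
    C2: float
    C3: float


def hybrid_mixture(
    phi1: float,
    phi2: float,
    base: MaterialProperties | None = None,
    particle1: MaterialProperties | None = None,
    particle2: MaterialProperties | None = None,
) -> HybridMixture:
    """Build the full hybrid mixture from the two volume fractions.

    Defaults to blood / Al2O3 / Cu. Density and heat capacity use the
    two-stage volume weighting; conductivity chains two Maxwell factors,
    the second taking the particle-1 nanofluid as its continuous phase;
    viscosity is the two-factor Brinkman product.
    """
    base = base or _BUILTIN["blood"]
    particle1 = particle1 or _BUILTIN["Al2O3"]
    particle2 = particle2 or _BUILTIN["Cu"]
    _check_fraction(phi1, "phi1", open_top=True)
    _check_fraction(phi2, "phi2", open_top=True)

    rho_hnf = (1.0 - phi2) * density_mixture(base, particle1, phi1) + phi2 * particle2.rho
    rhocp_hnf = (1.0 - phi2) * rhocp_mixture(base, particle1, phi1) + phi2 * particle2.rhocp
    mu_ratio = viscosity_ratio(phi1, phi2)

    k_nf_ratio = maxwell_conductivity_ratio(base.k, particle1.k, phi1)
    k_nf = base.k * k_nf_ratio
    k_ratio = k_nf_ratio * maxwell_conductivity_ratio(k_nf, particle2.k, phi2)

    C1 = 1.0 / mu_ratio
    C2 = rho_hnf / base.rho
    C3 = k_ratio * (rhocp_hnf / base.rhocp)

    return HybridMixture(
        base=base,
        particle1=particle1,
        particle2=particle2,
        phi1=phi1,
        phi2=phi2,
        rho_hnf=rho_hnf,
        mu_ratio=mu_ratio,
        rhocp_hnf=rhocp_hnf,
        k_nf_ratio=k_nf_ratio,
        k_ratio=k_ratio,
        C1=C1,
        C2=C2,
        C3=C3,
    )


def model_coefficients(mix: HybridMixture) -> tuple[float, float, float]:
    """Return (C1, C2, C3) for the similarity-reduced ODE system."""
    return mix.C1, mix.C2, mix.C3
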