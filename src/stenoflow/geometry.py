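"""Cosine-shaped stenosis geometry.

The constriction occupies the axial window ``(-L0/4, L0/4)`` (length
``L0/2``) of an otherwise straight axisymmetric vessel of radius ``R0``;
its depth at the throat is ``lam``.  The dimensionless severity is
``eps = lam/R0`` and the dimensionless radius ``f = R/R0`` drops smoothly
from 1 at the shoulders to ``1 - eps`` at the throat with C1 continuity
at the junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StenosisGeometry", "radius_profile", "dimensionless_profile"]


@dataclass(frozen=True)
class StenosisGeometry:
    """Cosine stenosis: unobstructed radius R0, span L0/2, depth lam."""

    R0: float = 1.0
    L0: float = 1.0
    lam: float = 0.5
    eps: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.R0 > 0 or not self.L0 > 0:
            raise ValueError("R0 and L0 must be positive")
        if not 0.0 <= self.lam < self.R0:
            raise ValueError(
                f"occlusion height lam must satisfy 0 <= lam < R0, got lam={self.lam!r}"
            )
        object.__setattr__(self, "eps", self.lam / self.R0)

    @classmethod
    def from_severity(cls, eps: float, R0: float = 1.0, L0: float = 1.0) -> "StenosisGeometry":
        """Construct from the dimensionless severity eps = lam/R0."""
        return cls(R0=R0, L0=L0, lam=eps * R0)


def radius_profile(x, geom: StenosisGeometry):
    """Dimensional radius R(x): cosine constriction inside (-L0/4, L0/4), R0 outside.

    Vectorised over ``x``. The junction points are assigned to the
    unobstructed branch; both branches agree there so the profile is
    continuous (and C1, since the derivative vanishes at the junctions).
    """
    x = np.asarray(x, dtype=float)
    inside = (x > -geom.L0 / 4.0) & (x < geom.L0 / 4.0)
    narrowed = geom.R0 - 0.5 * geom.lam * (1.0 + np.cos(4.0 * np.pi * x / geom.L0))
    out = np.where(inside, narrowed, geom.R0)
    return out if out.ndim else float(out)


def dimensionless_profile(xt, eps: float):
    """Dimensionless radius f(x~) = R/R0 for severity eps.

    ``f = 1 - (eps/2)(1 + cos(4 pi x~))`` for ``-1/4 < x~ < 1/4`` and 1
    otherwise, so ``f`` ranges over ``[1 - eps, 1]``.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"severity eps must lie in [0, 1), got {eps!r}")
    xt = np.asarray(xt, dtype=float)
    inside = (xt > -0.25) & (xt < 0.25)
    narrowed = 1.0 - 0.5 * eps * (1.0 + np.cos(4.0 * np.pi * xt))
    out = np.where(inside, narrowed, 1.0)
    return out if out.ndim else float(out)
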