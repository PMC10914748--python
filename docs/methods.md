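# Methods

## Model and assumptions

`stenoflow` treats blood as a steady, two-dimensional, incompressible,
Newtonian fluid in an axisymmetric vessel with a cosine-shaped
constriction of severity `ε = λ/R₀` over the axial window
`(−L₀/4, L₀/4)`. Nanoparticle loading (Al₂O₃ at φ₁, Cu at φ₂) enters
only through effective mixture properties: the suspension is assumed
homogeneous, in local thermal equilibrium with the carrier, with
spherical particles and temperature-independent properties — no
Brownian/thermophoretic slip, no non-Newtonian rheology, no
pulsatility. The boundary-layer equations are collapsed by a similarity
transformation into two coupled ODEs in the wall-normal coordinate η
(see README for the equations). Axial dependence is quasi-similar: each
station x̃ is an independent similarity solve whose only geometric
input is the local dimensionless radius `f(x̃)`, used as the domain
edge `η_edge`.

Although the transformation gives η ≤ 0 for r ≤ R, the coordinate is
treated throughout as the nonnegative wall-normal distance; the factor
`(1 + 2γη)` is then strictly positive and the mapping back to the
radial coordinate is monotone.

## Material constants

Shipped as an immutable registry (density kg/m³, specific heat
J kg⁻¹K⁻¹, conductivity W m⁻¹K⁻¹):

| material | ρ | Cp | k |
|---|---|---|---|
| blood | 1050 | 3617 | 0.52 |
| Al₂O₃ | 3970 | 765 | 40 |
| Cu | 8933 | 385 | 400 |

User materials can be registered at run time; the built-ins cannot be
shadowed. Particle 1 is Al₂O₃ and particle 2 is Cu by default (the
order of the subscripts in the mixing rules); the ordering is
configurable through `hybrid_mixture`'s arguments. The chained Maxwell
conductivity is evaluated with the particle-1 nanofluid as the
continuous phase of the second factor — the only reading under which
the two-factor product is well defined. The mono-nanofluid ratio
`k_nf/k_f` is exposed alongside `k_hnf/k_f` because published
wall-quantity tables are sometimes normalised by the former.

## Boundary-condition closures

The no-slip boundary set `F(0)=0, F′(0)=0, θ(0)=1` with zero-shear,
zero-flux edge conditions admits **only** the trivial solution
`F ≡ 0, θ ≡ 1`: with `F′(0)=0` the momentum equation has no forcing,
and the energy equation then reduces to a homogeneous first-order
equation for θ′ whose zero-flux edge condition forces θ′ ≡ 0. This is
proved degenerate in the test suite rather than silently replaced. The
package therefore defaults to a **stretching-wall** closure,
`F′(0) = 1`, which is the value built into the similarity velocity
scale `u₀x/L₀` and yields the nonzero wall gradients any tabulated
results require. A third, **quiescent-edge** closure
(`F′ = 0, θ = 0` at the edge) exists because its flat limit
(γ = 0, clean fluid, large domain) has the classical closed form
`F = 1 − e^{−η}`, `F″(0) = −1`, used as the solver's analytic oracle.

A second identity used for verification: when `Pr = C₁C₂/C₃` the energy
equation becomes the η-derivative of the momentum equation, so
`θ = F′` exactly under the default closure; the solver must reproduce
this to 10⁻⁶ for arbitrary γ and loading.

The Prandtl number is the conventional momentum-to-thermal diffusivity
ratio of the base fluid. For blood at body temperature the conventional
value is O(20); the defaults below use the smaller tabulated values that
published parameter studies of this model class sweep over.

## Numerics

* **Collocation route** (default): 4th-order collocation with adaptive
  mesh refinement (`scipy.integrate.solve_bvp`, the `bvp4c` method
  class). Default residual tolerance 10⁻⁸, initial uniform mesh of 50
  nodes, cap of 20 000 nodes. Non-convergence raises with diagnostics;
  a partial answer is never returned.
* **Shooting route** (cross-check): RK45 at tolerance 10⁻⁹ with a
  Powell-hybrid root solve on the two unknown wall slopes
  `(F″(0), θ′(0))`. Collocation and shooting agree on the wall
  derivatives to better than 10⁻⁶ across the tested parameter grid.
* **Initial guess**: a fixed cubic for F satisfying the active boundary
  conditions (`F′ = (1−η/η_edge)²`) and a matching quadratic/linear θ;
  no randomness anywhere, so repeated runs are byte-identical.
* **Degenerate inputs**: `γ = 0` removes the curvature terms (the
  factor `1+2γη` never vanishes for γ, η ≥ 0); φ = 0 reduces every
  mixture law to the base fluid exactly; the `literal` closure
  converges immediately to the trivial solution.
* The convergence study re-solves at a ladder of tolerances and reports
  successive differences of the wall derivatives; non-monotone
  behaviour is flagged as a warning, not an error.

## Defaults for table reproduction

Published tables of this model's wall quantities state (γ, Pr) or
(γ, φ) per row but leave the remaining inputs unstated. Reproduction
runs default to φ₁ = φ₂ = 0.05, Pr = 3.0 and η_edge = 1.0 (the
unobstructed dimensionless radius); a single `phi` override sets both
fractions, matching the single-φ column of the skin-friction table. The
`identify` utility replaces guessing: it exhaustively searches a
candidate grid over the unstated inputs for the assignment minimising
the maximum absolute deviation from the printed rows, reports the full
misfit table, and breaks exact ties deterministically (first in grid
order, ties reported).

What the comparison shows, computed honestly and left as-is: the
best-fitting assignments still miss the printed skin-friction entries
by ≈0.9 and the heat-transfer entries by ≈3.9 (minimax); the computed
Nusselt group is positive — the wall is the hot boundary, so
`θ′(0) < 0` — where the printed entries are negative; and both wall
gradient magnitudes *increase* with the curvature parameter γ for every
admissible closure and every edge location scanned (η_edge from 0.3 to
15), the classical transverse-curvature behaviour, whereas the printed
rows decrease. The orderings the model does reproduce are |Nu|
increasing in Pr and |Cf| increasing in φ. Signed quantities are always
reported exactly as the formulas produce them.

## What the defaults emulate — and what they do not

The defaults describe a mid-range stenosis (ε = 0.5 where a shape is
needed), dilute-to-moderate loadings (φ ≤ 0.2), and weak transverse
curvature (γ ≈ 0.1). Passing tests show that the similarity system,
its mixture laws and its post-processing are solved correctly and
consistently — not that the model captures real arterial
haemodynamics: real blood is shear-thinning and pulsatile, stenotic
flow separates and is fully two-dimensional near the throat, and the
similarity reduction only holds in the attached boundary layer.

## Problem sizes

The test suite solves ~60 small BVPs (each a 5-ODE system on a ≤200
node adaptive mesh, milliseconds each); the identification sweeps
evaluate 30 + 24 candidate assignments against 5 unique printed rows
apiece with memoised solves. The full suite and the acceptance script
each complete in well under a minute on one CPU.
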