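# stenoflow

Boundary-layer similarity model of hybrid-nanofluid blood flow through a
cosine-shaped stenotic artery.

## The problem

Arterial stenosis narrows a vessel and changes the wall shear stress and
heat transfer that the endothelium experiences — quantities that matter
both for disease progression and for nanoparticle-mediated therapies, in
which blood is deliberately loaded with metal or oxide nanoparticles.
`stenoflow` models steady, laminar, incompressible, Newtonian flow of
blood carrying two nanoparticle species (Al₂O₃ at volume fraction φ₁ and
Cu at φ₂) through an axisymmetric cosine-shaped constriction, and
computes the velocity and temperature boundary layers and the wall
groups they imply. It is aimed at researchers in biofluid mechanics and
nanofluid heat transfer who want a tested, reproducible reference
implementation of this model class.

## The model

The constriction occupies `−L₀/4 < x < L₀/4` with radius

    R(x) = R₀ − (λ/2)(1 + cos(4πx/L₀)),   and R₀ elsewhere,

so the dimensionless radius is `f(x̃) = 1 − (ε/2)(1 + cos 4πx̃)` with
severity `ε = λ/R₀`. Effective mixture properties use volume-weighted
density and heat capacity, the Brinkman viscosity law
`μ_hnf = μ_f (1−φ₁)^−2.5 (1−φ₂)^−2.5`, and the Maxwell conductivity
formula chained over the two species. A similarity transformation
`u = (u₀x/L₀) F′(η)`, `θ = (T−T₀)/(T₁−T₀)` reduces the boundary-layer
equations to the coupled ODE system

    (1/(C₁C₂)) [(1+2γη) F‴ + 2γF″] + F F″ − F′² = 0
    (1/(Pr C₃)) [(1+2γη) θ″ + 2γθ′] + F θ′ − F′ θ = 0

on `0 ≤ η ≤ η_edge`, where `γ = √(ν_f L₀/(u₀R²))` is the transverse-
curvature (flow) parameter, Pr the base-fluid Prandtl number, and the
mixture enters through `C₁ = (1−φ₁)^2.5(1−φ₂)^2.5`, `C₂ = ρ_hnf/ρ_f`,
`C₃ = (k_hnf/k_f)·(ρCp)_hnf/(ρCp)_f`. The default boundary-condition
closure is a stretching wall, `F(0)=0, F′(0)=1, θ(0)=1` with zero shear
and zero heat flux at the edge (`F″=θ′=0` at `η = η_edge`); see
`docs/methods.md` for why the no-slip variant is degenerate and is kept
only as the `literal` option. The system is solved as a two-point
boundary-value problem by fourth-order collocation, cross-checked by an
independent shooting route, and post-processed into

    Re_x^{1/2} C_f  = F″(0)/C₁           (scaled skin friction)
    Re_x^{−1/2} Nu_x = −(k_hnf/k_f) θ′(0) (scaled Nusselt group)

## Worked example

```python
from stenoflow import StenoticFlowModel

model = StenoticFlowModel.from_params(gamma=0.1, pr=3.0, phi1=0.05, phi2=0.05)
res = model.fit()
print(res.summary())
```

```
Stenotic-artery hybrid-nanofluid boundary layer
================================================
closure:        stretching-wall
gamma:          0.1
Pr:             3
phi1 (Al2O3):   0.05
phi2 (Cu):      0.05
eta_edge:       1
------------------------------------------------
C1, C2, C3:     0.773781, 1.507476, 1.313591
mu_hnf/mu_f:    1.292355
k_hnf/k_f:      1.332563
------------------------------------------------
F''(0):         -0.801995
theta'(0):      -2.143658
Re^1/2 Cf:      -1.036463
Re^-1/2 Nu:      2.856559
------------------------------------------------
solver:         collocation, 197 nodes, max residual 4.30e-09, converged=True
```

The 10% hybrid loading raises the effective viscosity by 29% and the
conductivity by 33%. The negative `F''(0)` is the decelerating shear of
the wall-driven layer; `Re^1/2 Cf` scales it by the viscosity factor
1/C₁. `theta'(0) < 0` says heat flows from the hot wall into the blood,
so the scaled Nusselt group is positive. Profiles are available as
`res.to_frame()`; dimensional wall stress and heat flux via
`res.wall_fluxes(x, scales=...)`.

The same solve from the shell:

```bash
stenoflow solve --gamma 0.1 --pr 3.0 --phi1 0.05 --phi2 0.05 \
    --profile-out profile.csv --summary-out summary.csv
stenoflow geometry --epsilon 0.5 --out shape.csv
stenoflow tables --which 2,3 --out tables/
stenoflow identify --table 3
```

`tables` writes side-by-side computed/printed wall-quantity tables;
`identify` searches a candidate grid for the inputs the published
tables leave unstated. See `docs/methods.md` for what that comparison
shows.

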