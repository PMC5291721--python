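# fasim — coupled cell–substrate–focal-adhesion simulator

`fasim` is a 2D plane-stress finite-element simulator of a single adherent
cell interacting mechanically with a deformable substrate through discrete
focal-adhesion (FA) springs. It is aimed at cell-mechanics and
mechanobiology researchers who want a transparent forward model of the
system that traction force microscopy observes: an actively spreading or
contracting cell, the tractions it exerts, and the substrate displacements
those tractions produce — with adhesion growth fed back from intracellular
stress.

## The model

Three coupled components, all on linear-triangle meshes in a
μm / kPa / min / nN unit system:

**Hypoelastic cell.** The cell is a 2D continuum on a moving Lagrangian
mesh with a frame-invariant rate constitutive law (Oldroyd/upper-convected
stress rate) and a prescribed isotropic active rate of deformation
`D^A = α I` (α > 0: spreading, α < 0: actomyosin contraction):

    ∇·σ_c − k_a (u_c − u_a − u_s) δ(x − x_c) = 0
    dσ_c/dt − ∇v σ_c − σ_c ∇ᵀv = C_c : (D − D^A),   D = sym ∇v

The cell boundary is traction free; deformation that tracks `D^A` exactly
is stress free, so an unattached cell spreads self-similarly with radius
growing as `e^{αt}`.

**Linear-elastic substrate.** A clamped plane-stress body loaded only by
the FA spring point forces `k_a (u_c − u_a − u_s)` at the attachment
points; it is never remeshed (small strains).

**Stress-gated adhesions.** The FA complex is a nodal volume fraction φ
that grows where the average bulk (hydrostatic) stress
`σ̄ = (σ_xx + σ_yy)/2` is compressive:

    ∂φ/∂t = k_σ tanh(−k₂ σ̄) H(−σ̄),   k_σ = 360 min⁻¹, k₂ = 1 kPa⁻¹

Wherever φ ≥ 0.5 the cell is attached by linear springs (k_a = 0.5 nN/μm
per μm² of membrane, born stretch-free). Springs rupture at a critical
stretch (0.4 μm, "weak" FAs) or never ("strong" FAs), and a
microtubule-mimicking rule removes springs from the cell center outward
whenever the FA area exceeds a critical fraction of the cell area,
resetting the local φ to 0.2.

Each time step solves the spring-coupled cell/substrate equilibrium
monolithically, advances φ by forward Euler, applies rupture, re-populates
springs, prunes to the area cap, and periodically rebuilds the deformed
cell mesh with field transfer.

## Worked example

```python
import fasim as fs

cfg = fs.smc_island_preset(duration=30.0)   # spreading SMC on a 50-μm island
result = fs.run_scenario(cfg)
print(result.metrics.iloc[-1])
```

or, equivalently, `python examples/spreading_cell_on_island.py`, which prints

```
after 30 min of spreading:
  cell area                  366.4 μm²  (started at 314.2)
  FA / cell area ratio        0.30      (capped at 0.30)
  max |u_s|                  0.438 μm
  max FA traction             71.4 Pa
```

The cell has grown from 314 to 366 μm² (adhesions confine it below the
free-spreading area of 487 μm²), its FA area rides at the 30 % cap, and the
1-kPa island is dragged 0.44 μm inward at the adhesion footprint, where the
tractions peak. Over the full 120-min validation run the displacement and
traction maxima grow to the micrometer / several-hundred-Pa scale measured
for spreading smooth muscle cells.

The other scripts in `examples/` each exercise one capability: the
cardiomyocyte contraction scenario with rupture-limited tractions, the
substrate-stiffness × FA-size sweep, radial φ/σ̄ profiles with the radial
compressive force, and a custom scenario with VTK snapshot output for
ParaView. A thin CLI wraps the same entry points:
`fasim run <config.yaml>`, `fasim sweep <config.yaml> --axis E_s=2.5,100`,
`fasim validate smc|cardiomyocyte`.

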