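# Methods

This note records the model equations as implemented, the numerical
scheme, the parameter defaults with their rationale, and the places where
the design was genuinely open and a choice had to be made.

## Model

### Cell

The cell occupies a moving 2D domain in plane stress. Its Cauchy stress
σ_c obeys a hypoelastic law written with the Oldroyd (upper-convected)
rate so the response is frame-invariant:

    dσ_c/dt − ∇v σ_c − σ_c ∇ᵀv = C_c : (D − D^A),   D = sym ∇v.

`C_c` is the isotropic plane-stress Hooke matrix
`E/(1−ν²)·[[1, ν, 0], [ν, 1, 0], [0, 0, (1−ν)/2]]` acting on
(ε_xx, ε_yy, γ_xy) with engineering shear. The active rate of deformation
`D^A = α I` is spatially uniform and constant: α = 0.00725 min⁻¹ for
spreading (a circular cell's diameter roughly doubles in two hours),
α = −0.001 min⁻¹ for contraction. Deformation that follows `D^A` exactly
produces no stress; only the passive remainder `D − D^A` does. Quasi-static
equilibrium includes the FA spring point forces `−k(u_c − u_a − u_s)` at
the cell-side anchors; the cell boundary is otherwise traction free. The
material spreading into the plane is treated as supplied from out-of-plane
regions: area is not conserved and no thickness/density field is tracked.

### Substrate

A linear-elastic plane-stress body on a fixed mesh, clamped
(u_s = 0) on its outer boundary, loaded only by the spring forces
`+k(u_c − u_a − u_s)` at the substrate-side anchors x_s. Because the load
depends linearly on u_s, the spring stiffness is assembled into the system
matrix and the solve is exact. Substrate strains stay small; the mesh is
never rebuilt.

### Adhesions

The FA complex is a nodal volume fraction φ ∈ [0, 1] on the cell mesh,
evolving by

    ∂φ/∂t = k_σ tanh(−k₂ σ̄) H(−σ̄),  σ̄ = (σ_xx + σ_yy)/2,

with k_σ = 360 min⁻¹ and k₂ = 1 kPa⁻¹: compression grows adhesions,
tension does nothing, and there is no decay term — φ only falls when a
spring is removed by the pruning rule. The clamp to [0, 1] is the minimal
consistent completion of the unbounded growth law (φ is a volume
fraction). With k_σ = 360 and the working time step, any appreciable
compression saturates φ within a single step; the FA geometry is therefore
governed by where compression exists and by the pruning cap, not by the
growth rate itself.

Wherever φ ≥ 0.5 the cell is attached to the substrate by linear springs.
Spring sites are cell-mesh nodes; each spring's stiffness is
`k_a × (nodal tributary area) × ρ_ref`, with k_a = 0.5 nN/μm
(5×10⁻⁵ dyn/μm) and reference density ρ_ref = 1 spring/μm², so the
attachment stiffness per unit membrane area (0.5 kPa per μm of stretch) is
mesh-independent and results converge under refinement. A site is
considered occupied if an active anchor lies within 0.55 of the target
mesh edge length, which prevents double-binding after remeshing.

Spring bookkeeping per step, in fixed order:

1. **φ advance** — forward Euler, nodal σ̄ taken as the area-weighted mean
   of adjacent element values.
2. **Rupture** (weak mode) — springs with stretch
   `|u_c − u_a − u_s| > 0.4 μm` detach.
3. **Population update** — new springs at unoccupied φ ≥ 0.5 nodes;
   springs at sites whose φ fell below 0.5 are removed. In weak (rupturing)
   mode a binding spring snapshots `u_a = u_c − u_s(x_s)` so its birth
   stretch is exactly zero — ruptured adhesions reattach stretch-free. In
   strong mode binding snapshots `u_a = u_c` only, neglecting the substrate
   displacement at the moment of attachment; on stiff substrates the two
   conventions coincide, on soft ones the strong-mode convention leaves a
   re-binding spring with a finite pre-extension −u_s. Both conventions
   are defensible readings of the model's published description; the
   weak/strong split adopted here follows the explicit statement that
   ruptured adhesions reattach with zero stretch.
4. **Microtubule pruning** — while the φ ≥ 0.5 area exceeds
   `critical_area_ratio × cell area`, the active spring nearest the cell
   centroid is removed (ties broken by lowest id) and φ is lowered to 0.2
   over the nodes within the site-occupancy radius of its anchor,
   representing disassembly of that local complex. Resetting only the
   anchor's patch (rather than a whole element) is what node-anchored
   springs admit; it guarantees the loop terminates at the cap.

## Numerics

* **Elements.** 3-node linear triangles, one-point quadrature, constant
  stress per element, for both bodies. Spring point forces are lumped onto
  the containing triangle's nodes by barycentric weights.
* **Time stepping.** Displacement increments are implicit: per step one
  linear solve finds Δu_c and u_s simultaneously from a monolithic
  operator containing the cell elastic tangent, the substrate operator,
  and the spring stiffness with its cell–substrate coupling blocks
  (`−k N_c N_sᵀ`). A staggered cell/substrate alternation was tried first
  and is only marginally stable once hundreds of springs couple two
  compliant bodies; the monolithic solve is exact, unconditionally stable
  for the linear part, and no more expensive than two staggered
  factorizations. φ uses forward Euler.
* **Convective terms.** `∇v σ + σ ∇ᵀv` is evaluated once per step with the
  previous step's converged velocity. Its per-step magnitude is
  O(dt·|∇v|·|σ|), far below the elastic increment at the slow active rates
  modeled here. Treating it implicitly instead (it is linear in Δu) makes
  the tangent indefinite once compressive stresses reach ~E/2 — a real
  loss of ellipticity of the rate law, not a discretization artifact — so
  the lagged explicit form is used, with the per-element lagged gradient
  capped at 0.05 min⁻¹ (≈ 7× the largest active rate) so a transient local
  rearrangement cannot feed a spurious convective increment.
* **Incremental application.** A sudden spring removal releases stored
  elastic energy; in a soft cell the quasi-static rebound can exceed the
  element size. Each solved increment is scaled back (factor 0.7 per
  retry) until no element inverts or loses more than 80 % of its area; the
  remaining imbalance stays in the stress state and is recovered by the
  next step's solve.
* **Rigid-body modes.** A spring-free cell gets three Lagrange constraints
  (zero mean translation and rotation); a single-anchor cell gets the
  rotation constraint only; two distinct anchors pin all rigid modes.
* **Remeshing.** The deformed cell boundary polygon is resampled at the
  target edge length, the interior refilled with a triangular lattice and
  re-triangulated, every 20 steps at fixed cadence (so compared runs are
  remeshed equally often) plus a quality trigger: minimum
  altitude-to-area ratio below 25 % of the nominal 2/h, or the
  dimensionless shape measure `2A/L_max²` below 0.15, which catches
  collapsing elements the altitude/area ratio (≡ 2/longest edge) cannot.
  Nodal fields transfer by piecewise-linear interpolation (exact for
  linear fields), element stresses by centroid sampling, and spring
  anchors are re-localized at unchanged physical points. Boundary
  self-intersections from local folds are repaired before meshing.
* **Meshes.** Disc meshes are structured concentric rings with point
  counts in multiples of 8, bridged by a deterministic zig-zag, giving
  exactly 8-fold-symmetric connectivity (a Delaunay triangulation of
  cocircular rings breaks rotational symmetry through degenerate
  tie-breaking). Squares use an alternating-diagonal (union-jack) split,
  4-fold symmetric. The equilateral triangle uses a barycentric lattice.

## Parameters and defaults

| parameter | default | unit | why |
|---|---|---|---|
| E_c | 0.5 (SMC), 20 (cardiomyocyte), 1.0 (sweeps) | kPa | measured ranges for the two cell types; the sweep value is fixed by the reported stress levels — with full adhesion the mean compressive stress after time t is bounded by α t E_c/(1−ν) ≈ 0.93 E_c at 90 min, and the reported ≈0.88 kPa maximum requires E_c ≈ 1 |
| E_s | 1 / 15 / 2.5–100 | kPa | scenario-defined |
| ν | 0.3 | – | both bodies |
| k_a | 0.5 | nN/μm | 5×10⁻⁵ dyn/μm, converted once |
| ρ_ref | 1.0 | μm⁻² | reference spring density; checked once against the spreading-cell maximum traction and frozen |
| k_σ, k₂ | 360, 1.0 | min⁻¹, kPa⁻¹ | adhesion growth law (k₂ multiplies a stress, so its unit is kPa⁻¹) |
| rupture stretch | ∞ or 0.4 | μm | strong / weak FA modes |
| critical area ratio | 0.3 (validations), 0.1–0.6 (sweeps) | – | the validation scenarios leave it unstated; 0.3 is the mid-range of the sweep axis |
| FA layout | 8 patches of 3.14 μm² at R = 4 or 7 μm, φ = 0.6 seeded | | initial seed level is above the 0.5 threshold, below saturation; cardiomyocyte uses 3 patches toward the triangle corners at 0.7× circumradius |
| dt | 0.25 | min | forward-Euler φ updates stable near the clamp; halving dt changes 20-min end-state metrics by < 1 % |
| cell mesh edge | 1.0 (disc), 1.5 (triangle) | μm | desk-scale resolution; the validation runs then take tens of seconds each |
| substrate mesh edge | 1.6 (island), 1.5 (cardiomyocyte), 3.0 (sweeps) | μm | fine enough that peak tractions are not diluted by nodal lumping |
| substrate extent | 50-μm island / 90–120-μm squares | μm | squares ≥ 6× the initial cell diameter so far-field clamping has little influence on tractions |
| remesh cadence | 20 steps | | fixed cadence, quality-triggered fallback |
| coupling tolerance | 1e-4 μm | | retained in the configuration; the monolithic solve is exact so the per-step fixed point is trivial |

## What the scenarios emulate, and what they do not

The built-in scenarios reproduce the *conditions* of two published
experimental systems — a smooth muscle cell spreading on a 50-μm
collagen-coated polyacrylamide island, and a rat cardiomyocyte contracting
on patterned silicone — as idealized 2D continua: perfect discs/triangles,
uniform isotropic activity, deterministic adhesion rules. They do not
capture stochastic integrin kinetics, stress fibers or branched-actin
structure, cyclic beating (the contraction runs once to a plateau), cell
migration, 3D substrate effects, or the experimentally observed *increase*
of spread area with substrate stiffness (the model predicts a decrease, a
known property of this model family: stiffer substrates stretch the
springs more, and the larger restoring forces confine spreading). Passing
scenario checks therefore show that the implementation reproduces this
model's behavior, not that the model captures every feature of real cells.

A consequence of the model's own rules worth knowing: with isotropic
active spreading, the material ring just outside any anchored band is
genuinely hoop-compressed (its circumferential expansion is blocked), so
φ grows one node ring beyond the band and the FA front creeps outward
until the area cap binds. Centrally seeded layouts therefore migrate into
peripheral rings here, and their FA area reaches the cap rather than
self-limiting below it.

## Known limitations

* Stress–modulus ratios above ~1 (soft cells under sustained constrained
  activity) approach the hypoelastic law's loss of ellipticity; the
  lagged-convective scheme with incremental application marches through,
  but local element collapse then triggers frequent quality remeshes, and
  end-state maxima (max |u_s|, max traction) carry a few-percent
  discretization sensitivity from spring-population churn.
* Maximum-type read-outs depend on the substrate mesh through the nodal
  tributary areas used for traction lumping; the documented edges are
  chosen so the FA footprint spans several substrate nodes.
* The σ̄ = 0 Heaviside gate makes FA-front motion sensitive to near-zero
  stress signs; behavior at the front should be interpreted at mesh
  resolution, not pointwise.
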