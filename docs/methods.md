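# Methods

## Physical model and assumptions

FG-Nups are modelled as *ideal* continuous Gaussian chains: the elastic
backbone energy (3k_BT/2b²)∫|dR/ds|²ds is the only intra-chain term,
and chain–chain excluded volume and cohesion are deliberately absent,
so the computed barrier isolates the conformational-entropy
contribution. This is the regime in which FG-Nups have been reported to
behave like near-ideal polymers; where cohesion dominates, a meshwork
(selective-phase) picture is more appropriate and this model
underestimates the barrier stiffness.

The channel is a cylinder (diameter D_pore, height h_pore, axis = z,
z ∈ [0, h_pore]); the cargo a sphere of diameter d_cargo, by default at
the pore center (0, 0, h_pore/2). Hard surfaces (wall, cargo) absorb
the propagator (Dirichlet 0); the open ends reflect it (Neumann). The
adsorption field is a square well: V(r) = −γ where the distance to the
nearest binding spot is strictly less than r_cutoff, else 0. All
energies are in k_BT (β = 1) and lengths in nm; the only unit
conversion in the package is 1 k_BT/nm = 4.114 pN, i.e. T = 298 K,
applied when insertion forces are reported (the temperature choice
affects only the pN scale, never the k_BT-unit results).

## Parameters

| symbol | default | unit | meaning |
|---|---|---|---|
| n | 80 | – | number of FG-Nups |
| b | 0.86 | nm | Kuhn length (chain flexibility) |
| l | 180 | nm | FG-Nup contour length; N = l/b ≈ 209.3 |
| D_pore, h_pore | 40, 40 | nm | channel diameter and height |
| γ | 0.9–1.2 | k_BT | adsorption well depth per contact |
| r_cutoff | 0.86 | nm | adsorption range (= b) |
| Δs | 0.4 | – | contour step |
| v_cell | 0.1 | nm³ | nominal cell volume → 0.95 nm node spacing |
| σ_v | 1 | nm⁻² | cargo-surface vertex density |
| S* | π·20² | nm² | reference binding area (20-nm cargo surface) |
| r_cluster | 8.6 | nm | clustering-degree neighbourhood (10b) |

γ outside 0.9–1.2 k_BT is allowed with a warning; those bounds bracket
the plausible per-contact strength of FG-motif/NTR interactions.

## Discretization

Two vertex-centred finite-volume grids share one solver:

* **Cartesian 3-D grid** for arbitrary cargo positions and adsorption
  fields. Node spacing defaults to the edge of a regular tetrahedron of
  volume 0.1 nm³ (0.947 nm ≈ b), the coarsest spacing consistent with
  the continuous-chain approximation; coarser requests warn (or raise
  in strict mode).
* **Axisymmetric (r, z) grid** for centered (on-axis) inert cargoes,
  where the solution is exactly rotationally symmetric. It runs at half
  the 3-D spacing (0.47 nm by default) since the 2-D problem is cheap,
  and agrees with the 3-D path to within a few percent in ΔF (tested).

Curved Dirichlet surfaces are embedded by a Shortley–Weller correction:
a fluid node whose grid neighbour lies inside a solid couples to the
zero boundary value at the true surface-intersection fraction θ of the
link (θ clamped at 0.05 to keep the operator well conditioned). The
wall at r = R is node-aligned in the axisymmetric grid and therefore
exact there. Cell volumes carry the 2πr measure in the axisymmetric
grid; the outermost fluid ring extends to the wall so volume integrals
are exact to O(h²).

The contour direction uses backward Euler with a uniform effective step
Δs_eff = N/⌈N/Δs⌉ ≤ Δs. This lands on s = N exactly and makes the
contour grid symmetric about N/2, so the density integrand
q_c(·, s_k)q̃(·, N − s_k) only needs stored steps. Each step solves one
sparse symmetric system (M + Δs(b²/6)K + ΔsMV)q⁺ = Mq via a single LU
factorization reused across all ~524 steps; the per-step relative
residual is checked against 10⁻¹⁰ because free-energy differences of
0.1 k_BT require it.

Key discrete identities (all tested):

* the operator is self-adjoint in the volume-weight inner product, so
  Green-function reciprocity holds to solver precision and, with
  tether sources weighted 1/(w_j q̃_j(N)), the density integral
  ∫ρ = n·N is exact to machine precision;
* the scheme is an M-matrix, so 0 ≤ q̃ ≤ 1 when V = 0 (discrete
  maximum principle);
* against the absorbing-half-space closed form erf(z√(3/(2b²s))) the
  relative error at nodes ≥ b from the wall is ≈ 0.14% at reference
  resolution (reliability floor |ΔF| ≥ 0.1 k_BT), grows when Δs is
  doubled, and shrinks under refinement.

ΔF is always a difference of two solves at matched resolution, which
cancels the discretization bias of the absolute free energies; the
d → 0 limit is exactly 0 by construction.

## Synthetic tether layout

The tether map of a reconstructed NPC is not distributed with this
package; the default stand-in preserves its two load-bearing features —
anchors on the wall, relocated 1 nm inward to keep them clear of the
discrete Dirichlet surface — and distributes n = 80 anchors over two
rings of 40 at z = h/3 and 2h/3 with equal angular spacing (rings
staggered by half a spacing; fully deterministic). A CSV override
(`x_nm,y_nm,z_nm`, projected radially onto the anchor radius) accepts
measured coordinates. Critical diameters shift by well under a
nanometre between 2-, 4- and 8-ring layouts, so conclusions are not
layout-sensitive; nevertheless the synthetic layout emulates only the
wall-tethered geometry of real NPCs, not their axial anchor
distribution, and passing tests bound layout sensitivity only among
ring-like arrangements.

## Binding spots and orientation averaging

The cargo surface is discretized into N_all = round(σ_v π d²) vertices
on a deterministic Fibonacci lattice (σ_v = 1/nm², one vertex per Kuhn
length squared — the model's resolution scale). Uniform layouts fill
the spherical cap around the body-frame −z pole whose area fraction
matches the requested coverage (cap fraction = (1 − cos θ_c)/2); Kent
layouts sample N_bind vertices without replacement with weight
proportional to the Kent density (β = 0 throughout this work), under an
explicit recorded seed. When a fixed absolute binding area S is
requested for a cargo too small to carry it, coverage clamps at 1 with
a warning — the geometric impossibility has no other resolution.

Decorated cargoes are rotated through the fixed 220-orientation grid
θ = pπ/5, φ = mπ/10 and ΔF̄ is the arithmetic mean of the
per-orientation free energies (the package follows the "averaged free
energy" reading; a Boltzmann average over partition functions is
available as an option). Because the vertex lattice rotates with the
cargo, even a fully covered cargo is only statistically isotropic: the
per-orientation spread is a finite-N_all effect (≈ 6% at N_all = 50,
≈ 1% at N_all = 400 on a 4-nm cargo) and vanishes with σ_v.

## Monte-Carlo oracle

The independent check samples discrete chains directly: per-coordinate
Gaussian steps of variance b²Δs/3 (the exact discrete analogue of the
b²/6 diffusivity), Boltzmann weight exp(−Δs ΣV) along the path, death
on obstacle contact with a Brownian-bridge correction
1 − exp(−2φ_kφ_{k+1}/σ²) for undetected crossings between samples
(locally planar surfaces), and exact reflection folding at the open
ends. The bridge correction is biased O(√Δs · curvature) on curved
surfaces, so oracle comparisons run at Δs = 0.0125; at that step the
sampler and the PDE solver agree within statistical error on the small
pore instance used in the tests. The oracle exists to validate, not to
produce production-scale results.

## Problem sizes used in tests and the acceptance script

The reference diameter scans (t-style targets) run on the axisymmetric
grid: 19 diameters plus one empty solve take a few seconds each; the
insertion-force sweep (≈ 210 solves) a couple of minutes. Full 3-D
orientation averages at reference scale are expensive (hours for a full
scan), so the property tests exercise the 3-D and binding-spot code on
a D = h = 10 nm pore with 8 chains of N = 25–50 — large enough to
contain every code path, small enough for seconds-per-solve. These
sizes are the package's own testing choices and are not tuned to any
particular result.

## Known limitations and numerical caveats

* **No chain–chain interactions.** Excluded volume and cohesiveness are
  out of scope by construction; measured insertion forces (≲ 80 pN at
  reference parameters) should therefore undershoot experimental
  stiffness.
* **Small-cargo regime vs free volume.** ΔF(d) grows like d^1.5 for
  d ≲ 8 nm (depletion-like insertion) and faster than d³ beyond; any
  growth slower than d³ is mildly *concave* against the free volume
  v = πD²h/4 − πd³/6. The convexity of ΔF(v) — the thermodynamic
  stability statement — holds on the entropic-exclusion branch
  (d ≥ 8 nm); the small-d deviation is ≈ 0.1 k_BT, at the solver's
  reliability floor.
* **Square-well potential on a grid.** With r_cutoff = b and node
  spacing ≈ b, each binding spot touches only a handful of nodes; the
  adsorption energy is resolution-limited in the same way as in any
  grid/mesh realization of Eq.-level square wells. Use finer spacing
  when absolute (not comparative) attractive free energies matter.
* **Critical-diameter extraction** assumes a single upward ΔF = 1 k_BT
  crossing; multi-crossing scans (strongly attractive cargoes) return
  the final upward crossing with a warning.
* The insertion-force path is the on-axis mouth→center sweep with
  central differences; off-axis insertion paths are not modelled.
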