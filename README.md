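# npcfield

Field-theoretic free-energy calculations for cargo transport through the
nuclear pore complex (NPC).

The NPC passes small molecules freely but blocks inert cargoes larger
than roughly the passive-diffusion limit, while cargoes coated with
nuclear transport receptors (NTRs) slip through up to nearly the pore
diameter. `npcfield` implements a minimal physical model of this
selectivity: the intrinsically disordered FG-Nups that fill the channel
are ideal continuous Gaussian chains tethered to the pore wall, and the
only ingredients are their conformational entropy and a short-range
adsorption energy at NTR binding spots. The package is aimed at
biophysicists who want quantitative entropic-barrier estimates, and at
anyone designing nucleus-targeted cargoes who needs to know how binding
spot number and placement shift the transportable size limit.

## Model

Each of the *n* FG-Nups is a continuous Gaussian chain **R**(s),
s ∈ [0, N], N = l/b, with Kuhn length *b* and contour length *l*,
tethered at **r**⊥,ᵢ on the channel wall. Chain statistics follow the
propagator q(**r**, s) obeying the modified diffusion equation

    [∂/∂s − (b²/6)∇² + βV(r)] q(r, s) = 0,

with absorbing (Dirichlet) conditions on the cylindrical pore wall and
on the spherical cargo surface, reflecting (Neumann) conditions on the
two open pore ends, and V the square-well adsorption field of depth γ
within r_cutoff = b of any binding spot. The partition function is
Z = Πᵢ q̃(**r**⊥,ᵢ, N), where q̃ starts from q̃(·, 0) = 1; the free
energy is F = −k_BT ln Z, and the observable of interest is the
insertion cost ΔF = F_cargo − F_empty. The mean segment density is
ρ(**r**) = ∫₀ᴺ q_c(**r**, s) q̃(**r**, N − s) ds with q_c propagated
from normalized tether sources, and integrates exactly to n·N.

Reference parameters (yeast NPC): n = 80, b = 0.86 nm, l = 180 nm,
D_pore = h_pore = 40 nm. A cargo whose ΔF (orientation-averaged ΔF̄ for
decorated cargoes) equals 1 k_BT defines the critical transportable
diameter d\*. Binding spots are selected on a density-conserving
Fibonacci surface lattice either as a uniform spherical cap or by
sampling a Kent (von Mises–Fisher for β = 0) directional distribution
with concentration κ, so the effect of clustering the same binding area
can be isolated.

The contour variable is stepped implicitly (backward Euler, Δs = 0.4)
over a finite-volume discretization of the pore: a full 3-D Cartesian
grid with embedded-boundary (Shortley–Weller) treatment of the curved
wall and cargo, plus an exact axisymmetric (r, z) reduction for
centered inert cargoes that makes the diameter scans run in seconds.
A brute-force Monte-Carlo chain sampler and the absorbing-wall closed
form erf(z√(3/(2b²s))) validate the solver independently.

## Worked example

```python
import npcfield as nf
from npcfield.config import RunConfig, run_inert_scan

scan, report = run_inert_scan(RunConfig())   # reference pore, inert cargoes
print(scan.table.head(5).to_string(index=False))
print("critical diameter:", report["critical_diameter_nm"], "nm")
```

prints

```
 d_cargo_nm   dF_kBT  dF_is_averaged
        2.0 0.203987           False
        4.0 0.599232           False
        6.0 1.294276           False
        8.0 2.443592           False
       10.0 4.254644           False
critical diameter: 5.153215686097147 nm
```

ΔF rises monotonically with cargo size — pure conformational entropy
creates the barrier — and crosses the thermal energy at d\* ≈ 5.2 nm,
in the experimentally observed 5–9 nm passive-diffusion range. Dilating
the pore to D_pore = 60 nm (`RunConfig(pore_diameter_nm=60)`) moves d\*
to ≈ 20 nm. The same drivers are available from the shell:

```sh
npcfield inert-scan --out results/
npcfield attractive-scan --config my.yaml --gamma 1.1 --kappa 2.0
npcfield validate
```

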