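# Methods

## Scope and model

`memswell` simulates water-driven volume change of a closed membrane shaped
as an axisymmetric spheroid, with the membrane's stretching stress coupled
into the water flux, and separately analyzes prescribed shapes with Helfrich
curvature elasticity. It deliberately excludes solute transport across the
membrane, membrane potential, metabolism, cytoskeletal elasticity and pore
kinetics: the only transported species is water, so solute content is
conserved and internal concentrations follow C_i(t) = C_i(0) V(0)/V(t)
exactly. That closed form is used instead of integrating the concentration
ODE, which removes stiffness and makes conservation exact by construction.

## Geometry

Shapes are spheroids of revolution (a, a, c), parameterized by the polar
angle θ: r = a sin θ, z = c cos θ. Everything is closed-form:

* volume (4/3)πa²c; oblate area 2πa²[1 + ((1−e²)/e) artanh e] with
  e² = 1 − c²/a², switching to a series within |1 − c/a| < 1e-8 of the
  sphere (avoids 0/0) and to the prolate arcsin form for c > a. The prolate
  branch exists because work-minimizing swelling in the disrupted regime
  drives the polar axis past the equatorial one.
* principal curvatures κ_m = ac/Δ³, κ_φ = c/(aΔ), Δ² = a²cos²θ + c²sin²θ;
  H = (κ_m+κ_φ)/2, K = κ_m κ_φ. Sign convention: outward normal, H > 0 and
  K > 0 for convex shapes. The surface Laplacian of H is evaluated
  analytically by the chain rule through u = Δ² (the axisymmetric
  Laplace–Beltrami operator (1/(rΔ)) d/dθ[(r/Δ) dH/dθ]); a finite-difference
  oracle in the test suite verifies it to 1e-4.
* surface integrals use Gauss–Legendre nodes in θ (default 200), giving
  spectral accuracy: Gauss–Bonnet holds to ~1e-13 and quadrature area matches
  the closed form to ~1e-14 in practice (tests enforce 1e-6 / 1e-8).

## Mechanics and units

The stretch response is a diagonal rigidity tensor with zero-strain values
g00 (equatorial, doubly degenerate) and gzz0 (polar) and a disruption law
g = g_0/(1 + β|d|^{n1}) acting on the absolute axis deformation in µm. For
odd n1 the magnitude is used so rigidity stays positive and strain-sign
symmetric. The stretching pressure is (2 g0 Δr + gzz Δz)/S, directed inward.

Membrane-mechanics literature mixes CGS, SI and practical units, and the
parameter presets shipped here carry magnitudes that are not mutually
consistent across those systems. The package therefore computes **everything
in one audited convention** — rigidities in N/m (1 dyn/nm = 1e4 N/m),
lengths/areas in µm/µm², pressures in Pa, concentrations in mM (numerically
mol/m³), bending moduli in erg — and forces every configuration input to be
a "value unit" string converted explicitly on load (`memswell.units`).
A dedicated test evaluates the pressure formulas independently in CGS with
explicit conversion factors and requires 1e-12 agreement with the SI path.
No attempt is made to silently rescale preset values to make historically
quoted pressure magnitudes come out; the computed numbers are reported as
the convention gives them.

Shipped rigidity preset (`imm_rigidity`, from a murine-heart
inner-mitochondrial-membrane fit): n1 = 4, g00 = 0.0101 dyn/nm,
gzz0 = 0.008 dyn/nm, β0 = 1.8e4 µm⁻⁴, βz = 1.6e4 µm⁻⁴. Default temperature
310 K (body temperature; the configs accept any T > 0).

### Water permeability

The preset permeability is printed in the fixture verbatim as
3.1e2 µl·min⁻¹Pa⁻¹µm⁻², which converts to 5.2e3 m s⁻¹ Pa⁻¹ — an unphysical
magnitude (typical osmotic permeabilities are ~1e-12 m s⁻¹ Pa⁻¹) that would
put the entire swelling transient below microseconds. Simulation scenarios
therefore default to p_w = 3.1e-14 m s⁻¹ Pa⁻¹ (same mantissa, SI magnitude),
chosen once so that the linear-regime risetime 1/(α S̄ p̄_w) of the resting
8 × 2 µm cell is of order 100 s — a minutes-scale transient typical of
osmotic equilibration experiments. p_w is a constant per run; time-dependent
permeability is out of scope.

## Volume partition

One volume ODE must determine two axis strains. The default rule
("energy-min") minimizes the stored elastic work
W = ∫₀^Δr 2 g0(r) r dr + ∫₀^Δz gzz(z) z dz subject to
(a0+Δr)²(c0+Δz) = 3V/4π, reduced to a 1-D search in Δz (the constraint
fixes Δr), with a coarse scan guarding the nonconvexity the disruption
plateaus introduce. The integrals have an arctan closed form for n1 = 4 and
fall back to quadrature otherwise. Small-strain limit: Δr/Δz → c·gzz0/(a·g00)
(≈ 0.198 for the preset), i.e. most deformation goes to the soft polar axis;
past disruption virtually all of it does. Because observed swollen
erythrocyte-like shapes deform mostly equatorially (Δr/Δz ≈ 3), the partition
rule is a config setting, never hard-coded: "self-similar" (ζ = ξ) and
"fixed-ratio:x" are provided. The returned deformation satisfies the volume
constraint exactly by construction.

A caveat of per-volume work minimization: in the disrupted regime the
equatorial strain is not strictly monotone in time (it relaxes by ~1e-8 µm as
the polar axis softens); the polar strain and the volume are monotone.

## Time integration and saturation

V is the only ODE state; LSODA integrates dV/dt = S(V) p_w (ΔP_os − ΔP_IMM)
with rtol = atol = 1e-8 by default (halving the tolerances moves the
saturation volume by ~1e-7 relative; tests enforce < 1e-3). A terminal event
stops the run once the relative rate |dV/dt|/V falls below 1e-9 s⁻¹ — the
threshold is set an order below the 1e-4 cross-validation tolerance between
the ODE route and the root-found equilibrium, since the terminal error scales
as threshold divided by the local relaxation rate (~5e-5 s⁻¹ in the slowest
disrupted runs). Output is a fixed deterministic grid, logarithmic in time
(t = 0 plus a geometric ladder over six decades), because the transient and
the saturation tail of disrupted runs are separated by ~10⁵ in time scale and
the linear-response fit needs resolved early dynamics.

The equilibrium solver (`saturation_state`) brackets ΔP_os(V) = ΔP_IMM(V)
between V0 and the classical osmotic-only volume V0·ΣC_in/ΣC_out, scanning
log-densely near V0 (reversible roots sit at small strain) with the last
node hugging the classical volume (disrupted-regime roots sit within ~1e-10
of it), then polishes with Brent's method. The balance is classified
"reversible" if it lies on the rising branch of ΔP_IMM(V) and "irreversible"
past the disruption peak. Under the shipped preset, every 10–50 mM run is
irreversible: the osmotic drive (≥4.4e4 Pa) exceeds the maximum stretching
pressure the work-minimizing path can mobilize (~1.3e4 Pa).

`fit_alpha` extracts the linear-response coupling α as the through-origin
least-squares slope of ΔP_IMM against ΔV over the |ΔV|/V0 < 5% window
(through the origin because ΔP_IMM(0) = 0 identically), and a risetime rate
either by an exponential fit of ΔV(t) (meaningful when the whole run is
linear) or as the product α S̄ p_w with S̄ averaged over the fit window
(robust for runs that leave the linear regime).

## Bending analysis

The energy density is (k_c/2)(2H + c0)² + k_d K — the total-curvature
convention consistent with the shape equation implemented in `el_residual`;
c0 defaults to 0 (symmetric planar bilayer). For a prescribed shape the
equation is linear in (Δp, λ); `solve_inverse_bending` solves the
area-weighted least-squares problem (uniform-in-θ weighting is an option)
and always reports the residual RMS and the condition number. On a sphere
the two columns are collinear (only Δp − 2λ/R identifiable — the Laplace
law); the solution is flagged degenerate, and a λ-fixed mode provides the
well-posed alternative.

`fit_bending_constants` recovers (k_c, k_d) from per-shape observations with
deterministic Nelder–Mead (objective tolerance 1e-10). Two structural facts
shape the objective: the fitted (Δp, λ) are exactly proportional to k_c
(positive homogeneity), and k_d never enters the shape equation for fixed
topology because ∮K dA = 4π is shape-independent (Gauss–Bonnet). Hence k_c
is identified by matching observed bending pressures, while k_d requires
observed total energies (which carry the 4πk_d term); without energies k_d
is honestly reported as unidentifiable and left at its starting value. The
homogeneous-plate relation k_c = g h²/(12(1−ν²)) is provided to seed the fit
from the stretch rigidity.

Note on magnitudes: with bending moduli of order 1e-5 erg (1e-12 J, some
seven orders above typical lipid-bilayer values) the fitted bending pressure
of the 8 × 2 µm cell is of order 1e6 Pa; with typical bilayer moduli
(~1e-12 erg) it is of order 0.1 Pa. The package treats the moduli as free
inputs and draws no conclusion about which magnitude is physical; the robust
qualitative result, independent of the modulus scale, is that the bending
pressure magnitude decreases monotonically as the equilibrium volume grows.

## What the fixtures emulate — and what they do not

The sweep scenarios (10–50 mM NaCl inside, 1 mM outside, 310 K, resting
8 × 2 µm shape) represent a cell in strongly hypotonic surroundings with a
dilute interior — the regime where ignoring membrane stress distorts the
classical prediction most. They are *not* a physiological erythrocyte
(≈145 mM plasma osmolarity, cytoskeleton-dominated elasticity, active
transport), so passing tests demonstrate the mechanics–osmosis coupling and
its numerics, not quantitative erythrocyte behavior. The preset rigidity is
a mitochondrial-membrane fit reused as a plausible stiff-membrane example.

## Numerical choices, determinism, limitations

* No randomness anywhere: identical configs produce byte-identical CSVs
  (12 significant digits, LF endings, fixed column order with species
  alphabetical). A seed field exists in the config schema but is reserved.
* Degenerate inputs: isotonic media are an exact fixed point of the ODE and
  return V_sat = V0; hypotonic interiors are rejected by the equilibrium
  solver; non-positive axes, areas and volumes raise immediately; prolate
  shapes warn (oblate intent) but are fully supported.
* Partition search tolerance 1e-13 of the bracket; flux-balance root xtol
  1e-13·V0; bounded 1-D minimization with a 65-point guard scan.
* Known limitations: constant p_w; diagonal rigidity tensor with no
  viscoelasticity or strain-rate dependence; no forward Helfrich shape
  solver (shapes are inputs, not outputs); spontaneous curvature fixed at 0
  in all shipped analyses; bending and stretching are analyzed as separate
  modules, not jointly minimized.
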