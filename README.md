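# memswell

Osmotic swelling dynamics of a closed-membrane cell — an erythrocyte-like
oblate spheroid — with the membrane's mechanical resistance built into the
water balance, plus a Helfrich curvature-elasticity analyzer for prescribed
equilibrium shapes.

## Who this is for

Membrane biophysicists and modellers who want to ask: when a cell (or an
organelle such as a mitochondrion) sits in a hypotonic environment, how far
does it swell before the stretched membrane pushes back hard enough to stop
the water influx — and when does it *not* stop, because large strain has
disrupted the membrane (the pathological, irreversible regime)?

## The model

The cell is an axisymmetric spheroid with equatorial semi-axis *a* and polar
semi-axis *c* (resting shape *a* = 8 µm, *c* = 2 µm). Water flux follows the
pressure imbalance across the membrane:

    dV/dt = S(t) · p_w · (ΔP_os − ΔP_IMM)

* **Osmotic drive** (van 't Hoff): ΔP_os = k_B N_A T Σ_i (C_i^in − C_i^out).
  Solutes do not cross the membrane, so C_i^in(t) · V(t) is conserved — the
  concentration ODE dC_i/dt = −(C_i/V) dV/dt is solved exactly in closed form.
* **Stretching pressure**: ΔP_IMM = (2 g₀ Δr + g_zz Δz) / S, with axis
  deformations Δr = a − a₀, Δz = c − c₀ and a diagonal rigidity tensor that
  *disrupts* at large strain:

      g₀ = g₀₀ / (1 + β₀ Δr^n₁),   g_zz = g_zz,0 / (1 + β_z Δz^n₁)

  When the osmotic drive exceeds the largest stretching pressure the intact
  membrane can generate, rigidity collapses and swelling proceeds nearly to
  the osmotic-only limit — the irreversible regime.
* **Shape partition**: a single volume ODE must be mapped to two axis strains;
  the default rule minimizes the stored elastic work under the volume
  constraint (alternatives: self-similar scaling, fixed strain ratio).
* **Linearized oracle**: for small strain ΔP_IMM ≈ α ΔV gives
  ΔV(t) = (ΔP_os/α)(1 − e^(−α S̄ p̄_w t)) — an exponential whose risetime is
  independent of the osmotic drive while the amplitude scales with it.
* **Helfrich bending** (separate analysis of prescribed shapes): energy
  density (k_c/2)(2H + c₀)² + k_d K; the shape equation
  Δp − 2λH + k_c(2H + c₀)(2H² − c₀H − 2K) + 2k_c ∇²H = 0 is linear in
  (Δp, λ), so for a given shape those are fitted by area-weighted least
  squares, with the condition number reported (a sphere is degenerate:
  only Δp − 2λ/R is identifiable — the Laplace law).

All spheroid geometry (area, volume, principal curvatures, the surface
Laplacian of H, Gauss–Legendre surface quadrature) is closed-form.

## Worked example

```
$ memswell make-fixtures fx
$ memswell equilibrium --config fx/swell_10mM.yaml
{
  "a_um": 8.0,
  "c_um": 19.999998012648966,
  "V_sat_um3": 5361.650929352401,
  "dP_os_Pa": 0.0005122364829042197,
  "dP_imm_Pa": 0.0005122364831484666,
  "regime": "irreversible"
}
```

Reading: starting from 10 mM NaCl inside vs 1 mM outside, the osmotic drive
(≈4.6 × 10⁴ Pa initially) exceeds anything the shipped rigidity preset can
oppose (≲1.3 × 10⁴ Pa along the work-minimizing deformation path), so the
membrane disrupts: the cell swells to V_sat ≈ 5362 µm³ ≈ 10 × V₀, i.e. almost
to the osmotic-only equilibrium where the interior has diluted to the outside
concentration, and the flux balance closes at a residual pressure of only
~5 × 10⁻⁴ Pa. The work-minimizing partition puts the growth into the soft
polar axis (*c* grows from 2 to 20 µm while *a* stays at 8 µm). A weak drive
(e.g. 2.5 mM inside) instead stops on the rising elastic branch
("reversible": V_sat ≈ 544.7 µm³, ΔP_os = ΔP_IMM ≈ 7.5 × 10³ Pa).

A concentration sweep reports the linear-response risetime and saturation:

```
$ memswell sweep --concentrations 10,30,50 --out sw
$ cat sw/summary.csv
C_in_mM,V_sat_um3,S_sat_um2,regime,alpha_Pa_per_um3,risetime_rate_per_s
10.0,5361.650929352401,1673.717378531813,irreversible,697.8178757191388,0.009880589933058792
30.0,16084.954369634808,4775.255596416645,irreversible,684.15819454567,0.009692675403965898
50.0,26808.257307144348,7919.347073807311,irreversible,708.359691956115,0.01003823547724951
```

The risetime rate (α S̄ p̄_w ≈ 0.01 s⁻¹, i.e. ≈100 s) is nearly the same for
every drive while the saturation volume grows fivefold — the signature of the
linearized model. `memswell simulate --config FILE --out DIR` writes the full
trajectory CSV plus a run manifest, and `memswell bending --shape a=8,c=2
--kc "1.38e-5 erg" --kd "0.71e-5 erg"` prints the fitted (Δp, λ) for a shape.

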