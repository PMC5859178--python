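# guvpore

Analysis of giant-unilamellar-vesicle (GUV) electroporation movies:
contour tracking → area / perimeter / form-factor time series → per-pulse
response statistics → biophysical inference (transmembrane voltage,
electrical tension, tether-vs-viscous force balance, pore efflux and
pore-radius estimation) — plus a synthetic bright-field movie generator
with exact ground truth, so every stage is testable without experimental
recordings.

## Who this is for

Membrane-biophysics labs that pulse single GUVs between electrodes, record
them in bright field (sucrose interior / glucose bath, 10–25 fps), and want
a reproducible, scriptable replacement for ad-hoc contour-tracking scripts:
one pipeline from TIFF stacks to response curves and pore-size estimates.

## The model

Per frame, the vesicle cross-section is measured by its area *A*, perimeter
*P* and the form factor

FF = 4πA / P² (1 for a circle, < 1 for any deformed shape),

and per pulse by the normalised area A_norm = A_f / A_i (final over initial
area; < 1 means shrinkage). Cohort responses are binned against the applied
field E (30 V/mm bins) and fitted with a 4-parameter logistic.

The biophysics layer implements the standard spherical-vesicle pulse
response:

- charging time τ = R·C_m·(1/λ_i + 1/(2λ_e)) (spherical-shell form;
  the simplified τ = R·C_m·(1/λ_e + 1/λ_i) is available as variant `simplified`),
- transmembrane voltage Ψ_m = 1.5·R·E·(1 − e^(−t/τ)),
- electrical tension σ_el ≈ 0.5·C_m·Ψ_m²,
- electric tether force F_el = 2π√(2·k_c·σ_el) versus the viscous drag
  F_v = 2π·η_eff·V_t on a growing tubule — with gel-phase membranes ~10⁶×
  more surface-viscous than fluid ones, this balance explains why fluid
  membranes shed lipid (tubules/vesicles) while gel membranes buckle,
- single-pore efflux Q = 2σr³/(3η₀R) and its exact inversion
  r = (3η₀RQ/2σ)^(1/3),
- efflux from the projected-area loss Q = −√(4A/π)·dA/dt,
- an adiabatic Joule-heating bound ΔT = λE²Δt/(ρc_p).

## Worked example

```python
import guvpore as gp

# Charging times at the reference constants
# (lambda_e = 4.5 uS/cm, lambda_i = 6 uS/cm, R = 20 um)
tau_gel = gp.charging_time(20e-6, gp.biophysics.gel_membrane(), gp.MediumParams())
tau_fluid = gp.charging_time(
    20e-6,
    gp.biophysics.fluid_membrane(c_m=gp.biophysics.uF_per_cm2_to_F_per_m2(0.55)),
    gp.MediumParams(),
)
print(f"tau gel   {tau_gel*1e6:.0f} us")     # tau gel   250 us
print(f"tau fluid {tau_fluid*1e6:.0f} us")   # tau fluid 306 us

# A micron-scale pore drains a 20-um vesicle fast ...
q = gp.pore_efflux(1e-6, 1e-3, 1e-3, 20e-6)
print(f"Q(r=1 um) = {q*1e18:.0f} um^3/s")    # Q(r=1 um) = 33333 um^3/s
# ... and an observed efflux inverts to a pore radius
r = gp.pore_radius_from_efflux(1000e-18, 1e-3, 1e-3, 20e-6)
print(f"r(Q=1000 um^3/s) = {r*1e6:.2f} um")  # r(Q=1000 um^3/s) = 0.31 um
```

End-to-end on synthetic data (shell):

```bash
guvpore demo demo_out --seed 1
```

generates a 6-vesicle cohort whose true per-pulse A_norm(E) follows a
logistic with midpoint 200 V/mm and lower plateau 0.7, tracks every movie,
and prints the run manifest. The fitted curve lands at
`e50 ≈ 194 V/mm`, `upper ≈ 1.00`, `lower ≈ 0.71` (seed 1), i.e. within one
30 V/mm bin of the generating truth, and `demo_out/results/pore_estimates.csv`
recovers the generating pore radii (0.2–0.5 µm) to better than 10%.

Individual stages are available as `guvpore simulate / track / respond /
biophys / pipeline`; all accept CSV/TIFF in and write deterministic
CSV/JSON out.

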