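# Methods

## Scope and model

`guvpore` analyses time-lapse bright-field movies of single giant
unilamellar vesicles (GUVs) exposed to trains of short DC pulses of
increasing amplitude. The measurement chain is:

1. **Contour tracking** — per frame, recover the vesicle boundary and
   measure area *A* (µm²), perimeter *P* (µm), the form factor
   FF = 4πA/P², and an interior/exterior contrast index
   C = (⟨I_out⟩ − ⟨I_in⟩)/(⟨I_out⟩ + ⟨I_in⟩).
2. **Per-pulse responses** — A_norm = A_f/A_i with A_i the mean area over
   the pre-pulse window and A_f the mean over the last quartile of the
   post-pulse window; FF_final likewise; a per-vesicle contrast-loss class
   (`none` / `gradual` / `complete`).
3. **Cohort statistics** — responses binned against the applied field in
   30 V/mm bins (mean ± sample sd) and fitted by a 4-parameter logistic
   y(E) = u − (u−l)/(1 + e^(−(E−E50)/w)). The response axis is the applied
   field, not the induced transmembrane voltage, because repeatedly pulsed
   vesicles are no longer spherical and Ψ_m is then ill-defined.
4. **Biophysics** — charging time, transmembrane voltage, electrical
   tension, the tether-vs-viscous force balance, and the efflux → pore
   radius inversion (below).

### Charging time and transmembrane voltage

For a spherical vesicle of radius R in media of conductivities λ_e
(outside) and λ_i (inside), with membrane capacitance C_m, the default
charging time is the spherical-shell result

    tau = R C_m (1/lambda_i + 1/(2 lambda_e)).

With the reference constants (λ_e = 4.5 µS/cm, λ_i = 6 µS/cm,
C_m = 0.45 µF/cm² gel / 0.5–0.6 µF/cm² fluid, R = 20 µm) this gives 250 µs
(gel) and 278–333 µs (fluid), i.e. "about 300 µs". The simplified form
τ = R·C_m·(1/λ_e + 1/λ_i), which yields 350 µs for the same gel inputs, is
kept available as variant `"simplified"`; the default was chosen because it
alone reproduces the reference values (250 µs gel, ≈300 µs fluid) from the
stated constants. The
pole transmembrane voltage is Ψ_m = 1.5·R·E·(1 − e^(−t/τ)) and the
electrical membrane tension σ_el ≈ 0.5·C_m·Ψ_m².

### Fluid-vs-gel force balance

An electric tether-pulling force F_el = 2π√(2·k_c·σ_el) drives lipid out
of the vesicle body into tubules or daughter vesicles; viscous dissipation
F_v = 2π·η_eff·V_t opposes tubule elongation at speed V_t. The maximum
steady elongation speed is V_t* = F_el/(2π·η_eff). Since the effective
surface viscosity of a gel-phase membrane is ~10⁶× the fluid-phase value,
V_t* drops by the same factor: fluid membranes shed lipid and shrink while
staying spherical (FF ≈ 1), gel membranes conserve lipid and buckle
(A_norm ≈ 1, FF < 1) as they lose volume. That dichotomy is the signature
the segmentation/response chain is validated against.

### Efflux and pore size

Post-pulse shrinkage is interpreted as volume efflux through a single
dominant pore of radius r under membrane tension σ:

    Q = 2 sigma r^3 / (3 eta0 R),        r = (3 eta0 R Q / (2 sigma))^(1/3)

(η₀ = liquid viscosity). The measured efflux comes from the projected
disc area A = πR² of a spherical vesicle: Q = −dV/dt = −√(4A/π)·dA/dt,
where dA/dt is the analytic derivative of a least-squares exponential fit
A(t) = A_∞ + ΔA·e^(−t/τ_d) of the post-pulse area series (a smoothing
spline with numeric derivative is provided as a sensitivity alternative).
Because r ∝ Q^(1/3), modest misfit of the decay shape attenuates: a 15%
efflux error is <5% in radius. The single-pore assumption is carried
explicitly in every pore estimate.

### Joule heating

The per-pulse temperature bound uses the adiabatic estimate
ΔT = λE²Δt/(ρc_p) (all dissipated power heats the bath in place, no
transport during the sub-millisecond pulse). At the strongest reference
pulse (λ = 6 µS/cm, E = 890 V/mm, Δt = 500 µs, ρc_p = 4.18 MJ m⁻³ K⁻¹)
it gives ΔT ≈ 0.057 K — heating is negligible.

## Contour tracking

Detection is a two-pass subpixel level-set extraction on the Gaussian-
smoothed frame (σ = 2 px default):

1. largest closed marching-squares iso-contour at the Otsu level, with an
   equivalent-radius floor (`min_radius_px`, default 8 px);
2. re-extraction at the midpoint of the interior and exterior plateau
   *medians* estimated from the first-pass mask (robust to the rim halo);
3. an edge-consistency check: the gradient magnitude sampled along the
   contour must not collapse anywhere (5th percentile ≥ 0.25× median), so
   a contour that leaked through a broken rim — an open macropore — is
   rejected and the frame recorded as a gap rather than fabricated
   geometry. Gap frames are reported, never interpolated.

A naive binary pixel count was deliberately not used for the perimeter:
counting pixel edges overestimates P of a circle by up to 4/π and would
bias FF(circle) to ≈ 0.62, failing the basic calibration FF(circle) = 1.
The level-set estimator reproduces FF(circle) = 1 to < 10⁻³ on noiseless
renders and the enclosed area to < 0.5% for radii ≥ 30 px.

With several objects in frame the largest closed contour is kept (the
experiments image one vesicle per movie; the rule exists for robustness).
The contrast index samples the interior ≥ 5 px inside the contour and an
exterior annulus 5–15 px outside (configurable), clear of the rim.

Contrast-loss classification: `complete` if the contrast inside any single
post-pulse window falls below 10% of the pre-experiment baseline;
`gradual` if, without such a collapse, the cumulative decline exceeds 25%
of baseline; `none` otherwise. The thresholds are package conventions
(reported in output metadata): the gradual/complete distinction is described
only qualitatively in the literature, with no quantitative cutoff.

## Synthetic movie generator

The generator emulates the appearance of a sucrose-filled GUV in a glucose
bath: uniform interior and exterior intensity plateaus joined by a smooth
step, with a refractive-index halo rendered as an *odd*
(derivative-of-Gaussian) rim — a dark band just inside and a bright ring
just outside the membrane. The odd profile is a deliberate choice: it
keeps the mid-plateau iso-level of the noiseless image exactly on the true
boundary, whereas a purely additive bright ring shifts any level-set
contour inward by about one rim width and would corrupt the
rendering-vs-truth calibration. Macropores are rendered by erasing both
rim and step over an angular arc with a smooth taper, which is what makes
pore frames fail the edge-consistency check (a gap), matching the
one-frame pore visibility of real recordings. Sensor noise is additive
Gaussian (the recordings' noise statistics are not characterised; Poisson
detail adds nothing at this abstraction). Frames are quantised to 16-bit
before writing, so TIFF round-trips are lossless, and all randomness flows
from the scenario seed — identical scenarios are bit-identical.

Shapes are radial Fourier perturbations of an (optionally elliptical)
disc, r(θ) = r_ellipse(θ) + Σ aₖcos(kθ+φₖ); ground-truth area/perimeter/FF
come from a 4096-gon polygonisation (FF error ~4·10⁻⁷). Buckling
timelines rescale the whole shape so the cross-section area is *exactly*
conserved while modes grow — the gel-phase signature. Shrinkage timelines
either relax exponentially to a target area or follow the single-pore
ODE dV/dt = −Q(r, R) (explicit RK4, fixed dt ≤ 1 ms; the ODE is smooth and
non-stiff at these scales), whose generating pore radius is recorded as
truth for closed-loop validation. The accumulated efflux is integrated
inside the same RK4 loop, so volume bookkeeping holds to integrator
accuracy (~10⁻¹⁴ relative).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: optical physics (no point-spread function,
defocus or refraction; the halo is stylised), three-dimensional shape
(only the equatorial cross-section is rendered; a real buckled vesicle's
projected area depends on viewing direction), debris and neighbouring
vesicles, illumination drift, and motion blur. Results on real recordings
therefore need the usual visual spot-checks of the tracked contours.

## Synthetic study conditions

The bundled demo cohort fixes the conditions the validation runs under:
per-pulse A_norm(E) follows the logistic u = 1, l = 0.7, E50 = 200 V/mm,
w = 40 V/mm, with multiplicative per-pulse noise (sd 0.02); eight 500 µs
pulses at 50–400 V/mm per vesicle; radii drawn from 15–22 µm; pulses with
a resolvable drop (≥ 2%) decay along the single-pore law with the pore
open for 60% of the post window (generating radii ≈ 0.2–0.5 µm);
vesicles alternate between a gradual contrast fate (40% cumulative loss
over the movie) and a complete collapse (τ = 1 s, small residual contrast)
at the first pulse ≥ 250 V/mm. Movie scale is kept desk-sized — 128 px
frames at 0.5 µm/px, 4 fps, 5 pre / 40 post frames per pulse, 6 vesicles —
which keeps a full cohort run at about a minute while leaving every
recovery criterion (E50 within one bin, pore radii within 10%, contrast
classes exact) comfortably testable.

## Numerical choices

- **Sigmoid fit**: 4-parameter logistic (no particular functional form is
  standard for these response curves; the logistic is the minimal monotone sigmoid
  with plateau semantics). Multi-start least squares (midpoint at the
  field quartiles × three width scales), best residual kept; a negative
  fitted width is folded back to the equivalent w > 0 parameterisation.
  Constant data short-circuits to u = l = mean.
- **Area-decay fit**: single exponential with bounds ΔA ≥ 0,
  τ_d ∈ [~0, 50×span]; a time constant pinned at the bound flags a decay
  indistinguishable from linear (the initial slope ΔA/τ_d remains well
  determined, which is all the efflux estimate needs). The pipeline
  truncates each post-pulse series where the decay has levelled off
  (first frame within 10% of the window minimum) so resealed plateaus do
  not dilute the fit.
- **A_f window**: last quartile of the post-pulse window, averaging out
  frame noise while honouring the "final state minutes after the pulse"
  definition. Single-frame definitions were rejected as needlessly noisy.
- **Binning**: bins [k·w, (k+1)·w), empty bins omitted, sample sd
  (ddof = 1), sd = 0 for singleton bins.
- **Degenerate inputs**: blank frames, sub-minimum contours, broken rims
  → typed exceptions (`NoContourError` et al.); whole-movie failure is a
  per-vesicle skip at pipeline level, never a cohort abort; ODE collapse
  (R → pore radius) raises with the failure time.

## Known limitations

- Experimental cohort statistics for this system (the ~30% shrinkage at ~400 V/mm, the
  measured efflux bounds, the contrast-class frequencies) derive from
  recordings that are not deposited; this package validates the *methods*
  on synthetic ground truth instead of reproducing those numbers.
- The membrane tension σ entering the pore inversion is not measurable
  from bright field; pore radii scale as σ^(−1/3) and the default
  σ = 10⁻³ N/m is an order-of-magnitude placeholder that users should set
  explicitly for quantitative claims. Likewise k_c and η_eff defaults are
  literature-scale placeholders.
- The equivalence of the contour estimator with any particular historical
  tracking script cannot be verified; the estimator is instead calibrated
  against the FF(circle) = 1 identity and synthetic truth.
- Single-pore efflux is an upper-bound interpretation: several smaller
  pores carrying the same Q would each be smaller than the reported r.
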