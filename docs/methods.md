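# Methods

## Overview

`iplsim` couples two stages over one shared 2-D Cartesian tissue grid
(5 µm cells, y lateral × z depth): a Monte Carlo simulation of broadband
photon transport that produces the absorbed-energy-density matrix per
unit fluence, and an alternating-direction-implicit (ADI) integration of
the heat equation that uses that matrix, modulated by a pulse train, as
its volumetric source.  Because transport is linear and effectively
instantaneous on millisecond scales, it is run once per comparison; only
the thermal stage depends on the pulse structure.

## Geometry and tissue properties

The default block is 4.8 mm wide × 4.0 mm deep: an 80 µm epidermis (5%
melanosomes), dermis below, and a centered follicle rod 200 µm wide from
200 to 2200 µm depth (30% melanosomes).  The rod is the plane section of
a cylinder; no bulb widening is modeled.  Cells are half-open squares
[iΔ, (i+1)Δ); z = 0 is the air–tissue boundary.  Probes: epidermal at
20 µm depth on the beam axis (z-index 4), follicular at 2000 µm depth,
two cells (10 µm) inboard of the rod's lateral edge.  The lateral domain
size is a free parameter; 4.8 mm puts the mirror-image follicles (see
boundary conditions) far enough apart that they do not appreciably
deplete each other's light supply, and the deep boundary sits 1.8 mm
below the follicle.

Thermal constants (k, ρ, c) and refractive indices are the tabulated
per-tissue values; the anisotropy factor is g = 0.789 for every tissue
and wavelength.  Diffusivity α is always derived as k/(ρc).

### Optical coefficients

µₐ per tissue combines three chromophores, each an explicit config
parameter:

- **Melanin**: µₐ = f · S · λ[nm]^−3.48 (1/cm), linear in the melanosome
  volume fraction f.  The anchor S is the single most influential
  under-determined constant in the model (published melanosome
  absorption spans an order of magnitude).  Default S = 3.55×10¹²,
  toward the strongly pigmented (dark terminal hair) end of the
  literature range; see "Calibration" below.
- **Water** and **oxygenated whole blood**: compact tables interpolated
  log-linearly, scaled by per-tissue volume fractions (defaults: water
  0.2/0.3/0.05 and blood 0/0.001/0 for epidermis/dermis/hair).
- **Scattering**: µₛ(λ) = a·(λ/500)^−0.7 + c·(λ/500)^−4 (Mie from
  collagen + Rayleigh from small structures), full (not reduced)
  coefficients; defaults a, c = (1.2, 0.4), (1.0, 0.3), (1.0, 0.3) ×10⁴
  m⁻¹ for epidermis/dermis/hair, i.e. reduced scattering of roughly
  15–25 cm⁻¹ across the band.

## Spectrum

The source is 600 × 1 nm bins over 500–1100 nm.  The synthetic default
is a 5500 K blackbody envelope with a hard long-pass cut at 695 nm — a
standard hair-removal filter edge — normalized to unit weight and
carrying 10 J/cm².  Any measured spectrum on the same grid can be
substituted from two-column text; other grids are rejected rather than
resampled.  Launch wavelengths are inverse-CDF draws, so each packet
carries total_fluence/n_photons and the ensemble carries the configured
radiant exposure exactly.

## Photon transport

Packets launch at the surface, normally incident, uniformly over the
aperture (default: the full domain width).  Specular reflection
((n−1)/(n+1))², n = 1.34, is tallied per photon and the packet enters
with the remaining weight.  The walk alternates:

1. optical depth τ = −ln R, consumed cell by cell along the ray (DDA
   traversal), so heterogeneous optics need no step splitting;
2. deposition ΔW = W·µₐ/µₜ at the interaction site;
3. Henyey–Greenstein redirection: cos θ from the closed-form inverse
   CDF (isotropic 2R−1 at g = 0), φ = 2πR, applied to a full 3-D
   direction vector.

Only the (y, z) projection of the direction advances the position; the
true 3-D path length is used for attenuation (optical depth per unit
in-plane distance is µₜ/√(u_y²+u_z²)).  This keeps the angular
statistics of a broad-field 2-D model unbiased — as many photons
scatter into the simulation plane as out of it.

Boundaries: the top surface applies unpolarized Fresnel reflection with
total internal reflection for upward packets; internal index mismatches
(dermis/hair) are treated as matched.  Lateral boundaries are mirrors by
default, emulating an infinite uniform broad field (an open mode tallies
lateral escape into `transmitted` instead).  Packets crossing the deep
boundary are transmitted.

Termination follows the 1/100-weight rule.  The default deposits the
residual weight in the terminal cell so that specular + diffuse +
transmitted + absorbed + residual ≡ 1 to 1e−9 and the thermal source is
well-posed; a config switch restores the literal discard, with the lost
fraction reported in the tally.

The RNG is a single seeded stream; a (seed, n_photons) pair reproduces
the absorption matrix bit-exactly, and the seed is recorded in every
output.

## Pulse structures

Each category is a train of identical trapezoidal sub-pulses with the
tabulated rise/hold/fall/off times; the train total of 30 energy units
is split evenly (so the 7-pulse close stack carries 30/7 = 4.29 per
pulse and the 5-pulse spaced stack 6.00).  The "off" interval of the
single-pulse systems is post-pulse observation padding, not emission.
The normalized instantaneous power fraction integrates to exactly 1
analytically; the solver uses its exact step-average, so the
time-integrated source equals the absorbed energy map regardless of dt.
The free-discharge trapezoid (1.5/2/3 ms) is the quantitative
parameterization used; a spiky capacitor-discharge shape would sharpen
its peak power further.

## Thermal solver

Peaceman–Rachford ADI: each step is an implicit-y then implicit-z
half-step, each solving independent tridiagonal systems by Thomas
elimination; heterogeneous conductivity enters through harmonic-mean
interface conductances (flux continuity at epidermis/dermis/hair
boundaries).  Perfusion is not modeled.  dt defaults to 50 µs (half the
shortest 100 µs rise time); the suite checks that halving dt moves the
probe peaks by < 0.1 °C, that a free Gaussian matches the analytic 2-D
kernel to < 1% L2, and that adiabatic runs conserve energy to < 0.5%.

Boundary conditions (all switchable): deep and lateral boundaries fixed
at baseline; the surface exchanges heat convectively with
h = 4500 W m⁻² K⁻¹ against an ambient equal to the baseline — a
gel-coupled contact window pre-equilibrated to skin temperature, the
usual clinical coupling of IPL handpieces.  Tying the ambient to the
baseline means surface exchange acts only on the pulse-induced rise;
a colder window would superimpose a pre-pulse cooling transient that
differs between the 40 ms and 115 ms simulations and would contaminate
the comparison.  Baseline temperature is 37 °C (deep-tissue
physiological; the follicle probe sits at 2 mm).  Comparisons are
computed on temperature rises as well as absolute values, and both are
reported.

## Calibration of under-determined parameters

The emission spectrum, chromophore concentrations, scattering
coefficients, baseline and boundary conditions are not fixed by the
problem statement, yet the headline outputs — the free-discharge vs
square-pulse epidermal excess (~22%) and the 70 °C follicular threshold
structure — depend on them.  They were set once, by a parameter study,
to jointly plausible values and then frozen:

- the **surface exchange coefficient** controls how fast the heated
  epidermal slab relaxes and thus the free-discharge advantage; bare-skin
  convection (h ≈ 10) yields ≈ 11% excess, the gel-coupled default
  (h = 4500) ≈ 22–24%;
- the **melanin anchor**, **695 nm cutoff**, **low dermal absorption**
  and **moderate scattering** set how much light reaches the follicle at
  2 mm; the defaults place the close-stack peak just above and the
  spaced-stack peak just below 70 °C.

In a 2-D model the follicle is an infinite slab, so its heat loss is
markedly slower than a 3-D cylinder's; the close-stack vs spaced-stack
peak difference at the follicle is therefore intrinsically small (≈ 1 °C
at these settings), and the 70 °C threshold separates them only
narrowly.  Monte Carlo seed scatter at 10⁶ photons is ≈ 0.3 °C at the
follicle probe, so that particular split is reproducible but not far
from the noise floor — an honest limitation of a 2-D treatment, in which
retained heat is a known artifact.

## What the synthetic data does and does not show

The synthetic spectrum is a smooth filtered-blackbody stand-in for a
measured flashlamp spectrum (which has line structure and possibly
time-varying content); the tissue is a single idealized follicle in
homogeneous layers.  Passing tests demonstrate the internal consistency
of the transport and heat physics and the *relative* behavior of the
four pulse structures under matched delivery; they do not validate
absolute temperatures in real skin, which depend on the device spectrum,
skin type, follicle geometry and 3-D conduction.

## Numerical choices and degenerate inputs

- Optical-property lookups are precomputed per (tissue, 1 nm bin).
- DDA traversal snaps positions exactly onto crossed cell faces to
  avoid floating-point stalls at boundaries.
- cos θ from the inverse CDF is clamped to [−1, 1] against rounding.
- A zero-diameter follicle is a valid control geometry (probe location
  then raises a clear error); AIR cells below the surface are rejected.
- Non-finite photon bookkeeping or probe temperatures raise immediately
  (simulation bug, not a data condition).
- Problem sizes: the default comparison uses 10⁶ packets on a 960×800
  grid with 50 µs steps — the scale at which the probe statistics are
  converged to a few tenths of a degree; CI fixtures use 100×100 cells
  and 2×10⁴ packets.

## Known limitations

2-D conduction retains heat relative to reality (no radial escape out of
the plane); internal Fresnel events are ignored; optical properties are
temperature-independent; no perfusion, no active cooling devices, no
multi-follicle fields, no Arrhenius damage kinetics — peak temperature
against a 70 °C point standard is the only damage surrogate.
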