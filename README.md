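# iplsim

Coupled Monte Carlo light-transport and heat-diffusion simulation of
intense pulsed light (IPL) photoepilation.

Commercial IPL hair-removal systems deliver the same nominal radiant
exposure with very different temporal pulse structures: a single
capacitor-shaped **free discharge**, a constant-power **square pulse**, a
tightly packed burst of sub-pulses (**close pulse stacking**), or widely
spaced sub-pulses (**spaced pulse stacking**).  `iplsim` models how this
temporal shaping alone changes the peak temperatures reached in the
melanin-rich epidermis (safety) and in a buried hair follicle
(efficacy), at matched fluence, for clinicians and light-based-device
designers who want to compare system categories rather than marketing
sheets.

## Model

The skin is a 2-D Cartesian block at 5 µm resolution: an 80 µm epidermis
with 5% melanosome volume fraction, a melanin-free dermis, and a hair
follicle — a 200 µm diameter rod with 30% melanin, buried 200 µm below
the surface and extending 2000 µm in length.

1. **Light transport.**  The broadband source is 600 wavelengths of 1 nm
   bandwidth (500–1100 nm), normalized so the launched ensemble carries
   the configured radiant exposure (default 10 J/cm²).  Weighted photon
   packets perform a Monte Carlo random walk: exponential optical-depth
   steps s = −ln R/µₜ, Henyey–Greenstein redirection

   P(θ) = (1 − g²) / (1 + g² − 2g cos θ)^{3/2},  g = 0.789,

   sampled by the closed-form inverse CDF, azimuth φ = 2πR, and a weight
   deposition ΔW = W·µₐ/(µₐ+µₛ) at each interaction site.  Packets
   terminate when 1/100 of the launch weight remains; the residual is
   deposited in place so the run conserves energy exactly.  The result
   is the absorbed-energy-density matrix per unit fluence.

2. **Heat flow.**  That matrix, scaled by the fluence and modulated by
   the pulse train's instantaneous power fraction, drives the 2-D heat
   equation ∂²T/∂y² + ∂²T/∂z² + H/k = (1/α)·∂T/∂t, advanced with the
   alternating-direction-implicit (ADI) scheme and finite-volume
   interface conductances between tissues.  Temperature is recorded at
   two probes: 20 µm below the surface on the beam axis, and 10 µm
   inside the follicle edge at 2000 µm depth (where the regrowth-
   supporting stem cells reside; damage is postulated above 70 °C).

Each of the four pulse categories is a train of trapezoidal sub-pulses
(rise/hold/fall/off) with the tabulated device timings; every train
delivers the same total fluence, so differences in the probe traces are
due to temporal structure alone.

## Worked example

```python
from iplsim import RunConfig
from iplsim.pipeline import run_comparison

report = run_comparison(RunConfig(), quiet=True)   # ~6 min, one CPU
print({k: round(v, 1) for k, v in report.peak_epidermal.items()})
print({k: round(v, 1) for k, v in report.peak_follicle.items()})
print({k: round(v, 1) for k, v in report.excess_percent.items()})
```

prints (default configuration: 10 J/cm², 10⁶ photons, seed 12345)

```
{'free_discharge': 91.1, 'square_pulse': 80.7, 'close_pulse_stack': 74.2, 'spaced_pulse_stack': 69.5}
{'free_discharge': 83.1, 'square_pulse': 73.8, 'close_pulse_stack': 70.1, 'spaced_pulse_stack': 69.1}
{'square_pulse': 23.7, 'close_pulse_stack': 45.5, 'spaced_pulse_stack': 66.3}
```

First line: peak epidermal temperature (°C) per category — free
discharge is hottest (its short, peaky envelope gives epidermal heat no
time to conduct away), exceeding the square-pulse *rise* by ≈ 22–24%.
Second line: peak follicle-probe temperature — free discharge, square
pulse and close stacking reach the 70 °C follicular-damage point while
spaced stacking falls short at matched fluence, because heat leaks away
during its long 15 ms inter-pulse gaps.  Third line: percent excess of
the free-discharge epidermal rise over each other category.

The same run is available from the shell:

```
iplsim run --seed 12345 --out results/
iplsim fixture --kind default --out config.yaml   # dump & edit defaults
```

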