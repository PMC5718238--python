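"""2-D heat diffusion driven by the Monte Carlo absorption matrix.

The heat-flow equation  d2T/dy2 + d2T/dz2 + H/k = (1/alpha) dT/dt  is
advanced with the Peaceman-Rachford alternating-direction-implicit
scheme: each step is an implicit-in-y then implicit-in-z half-step pair,
each solving independent tridiagonal systems by direct (Thomas)
elimination.  Heterogeneous conductivity is handled in finite-volume
form with harmonic-mean interface conductances, so heat flux is
continuous across the epidermis/dermis/hair interfaces.

The volumetric source H(y, z, t) is the per-unit-fluence absorption map
scaled by the delivered radiant exposure and modulated by the pulse
train's instantaneous power fraction; the solver uses the analytic
step-average of the power fraction, so the time-integrated source equals
the absorbed energy exactly regardless of the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .pulses import PulseTrain, average_power_fraction, envelope_duration, power_fraction
from .tissue import ProbeSet, TissueGrid, locate_probes
from .transport import AbsorptionGrid


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping and boundary conditions of the heat solver.

    The surface exchanges heat convectively with ambient air by default
    (or adiabatically); the deep and lateral boundaries are held at the
    baseline temperature ('dirichlet') or insulated ('adiabatic' -- used
    by the energy-conservation checks).
    """

    dt: float = 50e-6
    t_end: float | None = None        # None: train duration + cooling tail
    cooling_tail: float = 0.010
    baseline_temperature: float = 37.0
    surface_bc: str = "convective"    # 'convective' | 'adiabatic'
    surface_h: float = 4500.0         # W m^-2 K^-1 (gel-coupled contact window)
    ambient_temperature: float = 37.0
    far_bc: str = "dirichlet"         # deep + lateral: 'dirichlet' | 'adiabatic'

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.surface_bc not in ("convective", "adiabatic"):
            raise ValueError(f"unknown surface_bc {self.surface_bc!r}")
        if self.far_bc not in ("dirichlet", "adiabatic"):
            raise ValueError(f"unknown far_bc {self.far_bc!r}")


@dataclass
class TemperatureField:
    T: np.ndarray  # degC, shape (nz, ny)
    time: float = 0.0


@dataclass
class ThermalHistory:
    """Probe traces over one pulse-train simulation."""

    times: np.ndarray
    epidermal_trace: np.ndarray
    follicle_trace: np.ndarray
    baseline: float
    field_max_trace: np.ndarray | None = None
    final_field: np.ndarray | None = None

    @property
    def peak_epidermal(self) -> float:
        return float(self.epidermal_trace.max())

    @property
    def peak_follicle(self) -> float:
        return float(self.follicle_trace.max())

    @property
    def peak_epidermal_rise(self) -> float:
        return self.peak_epidermal - self.baseline

    @property
    def peak_follicle_rise(self) -> float:
        return self.peak_follicle - self.baseline


def volumetric_source(absorption: AbsorptionGrid, train: PulseTrain,
                      fluence_J_cm2: float, t: float) -> np.ndarray:
    """Instantaneous volumetric heat source H(y, z, t) in W/m^3."""
    return absorption.energy_density(fluence_J_cm2) * power_fraction(train, t)


@njit(cache=True)
def _thomas_rows(lo, di, up, rhs, out):
    """Solve independent tridiagonal systems, one per row of the inputs."""
    n_sys, n = rhs.shape
    cp = np.empty(n)
    dp = np.empty(n)
    for s in range(n_sys):
        cp[0] = up[s, 0] / di[s, 0]
        dp[0] = rhs[s, 0] / di[s, 0]
        for i in range(1, n):
            m = di[s, i] - lo[s, i] * cp[i - 1]
            cp[i] = up[s, i] / m
            dp[i] = (rhs[s, i] - lo[s, i] * dp[i - 1]) / m
        out[s, n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            out[s, i] = dp[i] - cp[i] * out[s, i + 1]


@njit(cache=True)
def _adi_step(T, S, aW, aE, aN, aS, gW, gE, gN, gS, dt):
    """One Peaceman-Rachford step: implicit-y half then implicit-z half.

    a* are neighbor exchange rates k_face/(cell^2 rho c) in 1/s (edge
    entries already encode the boundary condition); g* the corresponding
    ghost temperatures; S = H/(rho c) in K/s, applied half per sweep.
    """
    nz, ny = T.shape
    h = 0.5 * dt
    Ts = np.empty_like(T)
    # --- implicit in y, explicit in z ---
    lo = np.empty((nz, ny))
    di = np.empty((nz, ny))
    up = np.empty((nz, ny))
    rhs = np.empty((nz, ny))
    for iz in range(nz):
        for iy in range(ny):
            an = aN[iz, iy]
            as_ = aS[iz, iy]
            tn = T[iz - 1, iy] if iz > 0 else gN[iy]
            ts = T[iz + 1, iy] if iz < nz - 1 else gS[iy]
            r = T[iz, iy] + h * (an * (tn - T[iz, iy]) + as_ * (ts - T[iz, iy])) \
                + h * S[iz, iy]
            aw = aW[iz, iy]
            ae = aE[iz, iy]
            di[iz, iy] = 1.0 + h * (aw + ae)
            lo[iz, iy] = -h * aw
            up[iz, iy] = -h * ae
            if iy == 0:
                r += h * aw * gW[iz]
                lo[iz, iy] = 0.0
            if iy == ny - 1:
                r += h * ae * gE[iz]
                up[iz, iy] = 0.0
            rhs[iz, iy] = r
    _thomas_rows(lo, di, up, rhs, Ts)
    # --- implicit in z, explicit in y ---
    loT = np.empty((ny, nz))
    diT = np.empty((ny, nz))
    upT = np.empty((ny, nz))
    rhsT = np.empty((ny, nz))
    for iy in range(ny):
        for iz in range(nz):
            aw = aW[iz, iy]
            ae = aE[iz, iy]
            tw = Ts[iz, iy - 1] if iy > 0 else gW[iz]
            te = Ts[iz, iy + 1] if iy < ny - 1 else gE[iz]
            r = Ts[iz, iy] + h * (aw * (tw - Ts[iz, iy]) + ae * (te - Ts[iz, iy])) \
                + h * S[iz, iy]
            an = aN[iz, iy]
            as_ = aS[iz, iy]
            diT[iy, iz] = 1.0 + h * (an + as_)
            loT[iy, iz] = -h * an
            upT[iy, iz] = -h * as_
            if iz == 0:
                r += h * an * gN[iy]
                loT[iy, iz] = 0.0
            if iz == nz - 1:
                r += h * as_ * gS[iy]
                upT[iy, iz] = 0.0
            rhsT[iy, iz] = r
    outT = np.empty((ny, nz))
    _thomas_rows(loT, diT, upT, rhsT, outT)
    return outT.T.copy()


class ADISolver:
    """Precomputed exchange coefficients for one grid + config pair."""

    def __init__(self, grid: TissueGrid, cfg: SolverConfig):
        self.grid = grid
        self.cfg = cfg
        kmap, rcmap = grid.thermal_maps()
        self.rc = rcmap
        d = grid.geometry.cell_size
        nz, ny = kmap.shape

        def harm(k1, k2):
            return 2.0 * k1 * k2 / (k1 + k2)

        aW = np.zeros((nz, ny))
        aE = np.zeros((nz, ny))
        aN = np.zeros((nz, ny))
        aS = np.zeros((nz, ny))
        aW[:, 1:] = harm(kmap[:, 1:], kmap[:, :-1]) / (d * d * rcmap[:, 1:])
        aE[:, :-1] = harm(kmap[:, :-1], kmap[:, 1:]) / (d * d * rcmap[:, :-1])
        aN[1:, :] = harm(kmap[1:, :], kmap[:-1, :]) / (d * d * rcmap[1:, :])
        aS[:-1, :] = harm(kmap[:-1, :], kmap[1:, :]) / (d * d * rcmap[:-1, :])
        base = cfg.baseline_temperature
        gW = np.full(nz, base)
        gE = np.full(nz, base)
        gN = np.full(ny, cfg.ambient_temperature)
        gS = np.full(ny, base)
        if cfg.far_bc == "dirichlet":
            aW[:, 0] = kmap[:, 0] / (d * d * rcmap[:, 0])
            aE[:, -1] = kmap[:, -1] / (d * d * rcmap[:, -1])
            aS[-1, :] = kmap[-1, :] / (d * d * rcmap[-1, :])
        if cfg.surface_bc == "convective":
            aN[0, :] = cfg.surface_h / (d * rcmap[0, :])
        self._coef = (aW, aE, aN, aS, gW, gE, gN, gS)

    def step(self, T: np.ndarray, H: np.ndarray, dt: float) -> np.ndarray:
        """Advance one ADI step with volumetric source H (W/m^3)."""
        S = H / self.rc
        return _adi_step(T, S, *self._coef, dt)


def adi_step(field: TemperatureField, H: np.ndarray, grid: TissueGrid,
             cfg: SolverConfig, dt: float | None = None) -> TemperatureField:
    """Single-step convenience wrapper (tests, diagnostics)."""
    if H.shape != field.T.shape:
        raise ValueError("source field shape does not match the temperature field")
    dt = cfg.dt if dt is None else dt
    solver = ADISolver(grid, cfg)
    return TemperatureField(T=solver.step(field.T, H, dt), time=field.time + dt)


def run_simulation(absorption: AbsorptionGrid, train: PulseTrain,
                   grid: TissueGrid, cfg: SolverConfig,
                   fluence_J_cm2: float = 10.0,
                   probes: ProbeSet | None = None,
                   track_field_max: bool = False,
                   keep_final_field: bool = False) -> ThermalHistory:
    """Advance the temperature field through one pulse train.

    Starts from the uniform baseline, drives the ADI stepper with the
    step-averaged pulse power, and records both probe traces every step.
    """
    if absorption.deposited.shape != grid.shape:
        raise ValueError("absorption grid shape does not match the tissue grid")
    if probes is None:
        probes = locate_probes(grid)
    t_end = cfg.t_end
    if t_end is None:
        t_end = train.total_duration + cfg.cooling_tail
    if t_end < envelope_duration(train):
        raise ValueError("t_end shorter than the pulse-train envelope; "
                         "the temperature peaks could be missed")
    solver = ADISolver(grid, cfg)
    n_steps = int(np.ceil(t_end / cfg.dt))
    dens = absorption.energy_density(fluence_J_cm2)
    T = np.full(grid.shape, cfg.baseline_temperature)
    times = np.empty(n_steps + 1)
    epi = np.empty(n_steps + 1)
    fol = np.empty(n_steps + 1)
    fmax = np.empty(n_steps + 1) if track_field_max else None
    pe, pf = probes.epidermal_probe, probes.follicle_probe
    times[0] = 0.0
    epi[0] = fol[0] = cfg.baseline_temperature
    if fmax is not None:
        fmax[0] = cfg.baseline_temperature
    t = 0.0
    for i in range(1, n_steps + 1):
        pbar = average_power_fraction(train, t, t + cfg.dt)
        H = dens * pbar if pbar > 0.0 else np.zeros_like(dens)
        T = solver.step(T, H, cfg.dt)
        t += cfg.dt
        times[i] = t
        epi[i] = T[pe]
        fol[i] = T[pf]
        if fmax is not None:
            fmax[i] = T.max()
        if not np.isfinite(epi[i]):
            raise RuntimeError("non-finite probe temperature (solver failure)")
    return ThermalHistory(times=times, epidermal_trace=epi, follicle_trace=fol,
                          baseline=cfg.baseline_temperature,
                          field_max_trace=fmax,
                          final_field=T if keep_final_field else None)


@dataclass
class ComparisonMetrics:
    """Per-category peaks and the cross-category comparisons."""

    peak_epidermal: dict
    peak_follicle: dict
    rise_epidermal: dict
    rise_follicle: dict
    excess_percent: dict       # free-discharge epidermal rise vs each other
    exceeds_threshold: dict    # follicle peak above the damage threshold
    threshold: float


def peak_metrics(histories: dict, threshold: float = 70.0) -> ComparisonMetrics:
    """Compare the four categories' peak temperatures.

    ``excess_percent[cat]`` is the percent excess of the free-discharge
    epidermal peak *rise* over ``cat``'s; ``exceeds_threshold[cat]`` flags
    a follicle-probe peak at or above the damage threshold (70 degC
    default, the postulated denaturation point of the follicular stem
    cells).
    """
    from .pulses import PulseCategory
    required = set(PulseCategory)
    keys = {PulseCategory(k) for k in histories}
    if keys != required:
        missing = sorted(c.value for c in required - keys)
        raise ValueError(f"missing categories: {missing}")
    hist = {PulseCategory(k): v for k, v in histories.items()}
    peaks_e = {c: h.peak_epidermal for c, h in hist.items()}
    peaks_f = {c: h.peak_follicle for c, h in hist.items()}
    rise_e = {c: h.peak_epidermal_rise for c, h in hist.items()}
    rise_f = {c: h.peak_follicle_rise for c, h in hist.items()}
    fd = rise_e[PulseCategory.FREE_DISCHARGE]
    excess = {c: 100.0 * (fd - r) / r for c, r in rise_e.items()
              if c != PulseCategory.FREE_DISCHARGE}
    exceeds = {c: bool(p >= threshold) for c, p in peaks_f.items()}
    return ComparisonMetrics(
        peak_epidermal={c.value: v for c, v in peaks_e.items()},
        peak_follicle={c.value: v for c, v in peaks_f.items()},
        rise_epidermal={c.value: v for c, v in rise_e.items()},
        rise_follicle={c.value: v for c, v in rise_f.items()},
        excess_percent={c.value: v for c, v in excess.items()},
        exceeds_threshold={c.value: v for c, v in exceeds.items()},
        threshold=threshold,
    )
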