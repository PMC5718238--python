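"""Monte Carlo photon transport through the 2-D tissue grid.

Weighted photon packets are launched at the surface with a wavelength
drawn from the emission spectrum, walk through the grid with
exponentially sampled optical depth, deposit a fraction mu_a/mu_t of
their weight at every interaction site, and are redirected by the
Henyey-Greenstein phase function.  Packets terminate when one hundredth
of the launch weight remains (the residual is deposited in the terminal
cell by default so the tally conserves energy exactly).

Photons scatter in 3-D but only the in-plane (y, z) projection of the
step advances the position; the out-of-plane direction component is
tracked so the angular statistics stay unbiased.  Optical depth is
consumed cell by cell (DDA traversal), so heterogeneous optics are
handled without step splitting bias.  Only the air-epidermis boundary
reflects (specular at launch, Fresnel with total internal reflection on
the way out); internal index mismatches are treated as matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .spectrum import EmissionSpectrum
from .tissue import TissueGrid

_EPS_PLANE = 1e-12

# ---------------------------------------------------------------------------
# Elementary sampling operations (pure, array-friendly reference forms).
# The compiled kernel below inlines the same formulas.
# ---------------------------------------------------------------------------


def hg_phase(theta, g: float):
    """Henyey-Greenstein phase function P(theta) = (1-g^2)/(1+g^2-2g cos)^(3/2).

    Normalized over cos(theta) in [-1, 1] with weight 1/2 (so g = 0 gives
    the constant 1); even in theta and strictly positive for |g| < 1.
    """
    if not abs(g) < 1.0:
        raise ValueError("|g| must be < 1")
    c = np.cos(theta)
    return (1.0 - g * g) / (1.0 + g * g - 2.0 * g * c) ** 1.5


def sample_deflection(g: float, R):
    """Inverse-CDF draw of cos(theta) from the HG phase function.

    cos = (1/2g) * [1 + g^2 - ((1-g^2)/(1-g+2gR))^2] for g != 0, the
    isotropic 2R-1 otherwise.  R uniform in [0, 1]; R=0 gives the full
    backward, R=1 the full forward limit.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R > 1):
        raise ValueError("R must lie in [0, 1]")
    if g == 0.0:
        out = 2.0 * R - 1.0
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * R)
        out = (1.0 + g * g - s * s) / (2.0 * g)
    return np.clip(out, -1.0, 1.0)[()] if np.ndim(out) else float(np.clip(out, -1, 1))


def sample_azimuth(R):
    """Azimuthal scattering angle phi = 2*pi*R, uniform on [0, 2*pi)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 1):
        raise ValueError("R must lie in [0, 1)")
    out = 2.0 * np.pi * R
    return out if out.ndim else float(out)


def sample_path_length(mu_t: float, R):
    """Exponential step length s = -ln(R)/mu_t (mean free path 1/mu_t)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R > 1):
        raise ValueError("R must lie in (0, 1]")
    out = -np.log(R) / mu_t
    return out if out.ndim else float(out)


def surface_fresnel(n_tissue: float, incidence: float = 0.0) -> float:
    """Unpolarized Fresnel reflectance of the air-tissue boundary for a
    photon arriving from air at the given incidence angle (rad).

    At normal incidence this is ((n-1)/(n+1))^2; it tends to 1 at grazing.
    """
    if n_tissue < 1.0:
        raise ValueError("refractive index must be >= 1")
    ci = np.cos(incidence)
    st = np.sin(incidence) / n_tissue
    if st >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st * st)
    rs = ((ci - n_tissue * ct) / (ci + n_tissue * ct)) ** 2
    rp = ((ct - n_tissue * ci) / (ct + n_tissue * ci)) ** 2
    return float(0.5 * (rs + rp))


@dataclass
class Photon:
    """One weighted packet: continuous (y, z) position, a 3-D unit
    direction (x out of plane), a weight in (0, 1], and a wavelength."""

    position: tuple[float, float]  # (y, z), m
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (ux, uy, uz)
    weight: float = 1.0
    wavelength_nm: float = 700.0

    def __post_init__(self):
        ux, uy, uz = self.direction
        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")


def deposit_weight(photon: Photon, mu_a: float, mu_s: float) -> float:
    """One interaction's weight deposition dW = W * mu_a/(mu_a + mu_s).

    Decrements the photon's weight and returns the deposited fraction.
    """
    mu_t = mu_a + mu_s
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    dw = photon.weight * mu_a / mu_t
    photon.weight -= dw
    return dw


# ---------------------------------------------------------------------------
# Compiled kernel
# ---------------------------------------------------------------------------

STATUS_TERMINATED = 0
STATUS_DIFFUSE_REFLECTED = 1
STATUS_TRANSMITTED = 2
STATUS_LATERAL_ESCAPE = 3


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _internal_fresnel(n1, ci):
    """Reflectance leaving tissue (index n1) into air at cos(incidence) ci."""
    si = np.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 * si
    if st >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st * st)
    rs = (n1 * ci - ct) / (n1 * ci + ct)
    rp = (n1 * ct - ci) / (n1 * ct + ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _trace(y, z, ux, uy, uz, w, li, cls, mua_t, mus_t, g, n_surf, delta,
           mirror, w_min, deposit_residual, A):
    """Walk one packet to termination.  Deposits into A (weight units).

    Returns (status, escaped_weight, absorbed_weight, residual_weight).
    """
    nz, ny = cls.shape
    iy = int(y / delta)
    iz = int(z / delta)
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1
    absorbed = 0.0
    while True:
        tau = -np.log(np.random.random() + 1e-300)
        p = np.sqrt(uy * uy + uz * uz)
        if p > _EPS_PLANE:
            vy = uy / p
            vz = uz / p
            # consume optical depth cell by cell along the in-plane ray;
            # 3-D path per unit in-plane distance is 1/p
            while True:
                tcls = cls[iz, iy]
                mut = mua_t[tcls, li] + mus_t[tcls, li]
                if vy > 0.0:
                    dy = ((iy + 1) * delta - y) / vy
                elif vy < 0.0:
                    dy = (iy * delta - y) / vy
                else:
                    dy = 1e30
                if vz > 0.0:
                    dz = ((iz + 1) * delta - z) / vz
                elif vz < 0.0:
                    dz = (iz * delta - z) / vz
                else:
                    dz = 1e30
                d = dy if dy < dz else dz
                if d < 0.0:
                    d = 0.0
                tau_cell = mut * d / p
                if tau_cell >= tau and mut > 0.0:
                    dmove = tau * p / mut
                    y += vy * dmove
                    z += vz * dmove
                    break  # interact in (iz, iy)
                tau -= tau_cell
                if dy < dz:
                    # snap exactly onto the crossed y face
                    if vy > 0.0:
                        iy += 1
                        y = iy * delta
                    else:
                        y = iy * delta
                        iy -= 1
                    z += vz * d
                    if iy < 0 or iy >= ny:
                        if mirror:
                            uy = -uy
                            vy = -vy
                            iy = 0 if iy < 0 else ny - 1
                        else:
                            return STATUS_LATERAL_ESCAPE, w, absorbed, 0.0
                else:
                    if vz > 0.0:
                        iz += 1
                        z = iz * delta
                    else:
                        z = iz * delta
                        iz -= 1
                    y += vy * d
                    if iz < 0:
                        # air-epidermis boundary from below: Fresnel / TIR
                        ci = -uz
                        if np.random.random() < _internal_fresnel(n_surf, ci):
                            uz = -uz
                            vz = -vz
                            iz = 0
                        else:
                            return STATUS_DIFFUSE_REFLECTED, w, absorbed, 0.0
                    elif iz >= nz:
                        return STATUS_TRANSMITTED, w, absorbed, 0.0
        # interaction in cell (iz, iy)
        tcls = cls[iz, iy]
        mua = mua_t[tcls, li]
        mus = mus_t[tcls, li]
        mut = mua + mus
        if mut <= 0.0:
            continue
        dw = w * mua / mut
        A[iz, iy] += dw
        absorbed += dw
        w -= dw
        if w < w_min:
            if deposit_residual:
                A[iz, iy] += w
            return STATUS_TERMINATED, 0.0, absorbed, w
        # Henyey-Greenstein redirection in 3-D
        if g != 0.0:
            s = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
            cost = (1.0 + g * g - s * s) / (2.0 * g)
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
        else:
            cost = 2.0 * np.random.random() - 1.0
        sint = np.sqrt(1.0 - cost * cost)
        phi = 2.0 * np.pi * np.random.random()
        cosp = np.cos(phi)
        sinp = np.sin(phi)
        if abs(uz) > 0.99999:
            ux = sint * cosp
            uy = sint * sinp
            uz = cost if uz > 0.0 else -cost
        else:
            den = np.sqrt(1.0 - uz * uz)
            ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
            uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
            uz_n = -sint * cosp * den + uz * cost
            norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
            ux = ux_n / norm
            uy = uy_n / norm
            uz = uz_n / norm


@njit(cache=True)
def _run_kernel(n_photons, seed, cls, mua_t, mus_t, g, n_surf, delta, cdf,
                beam_lo, beam_hi, mirror, w_min, deposit_residual, A):
    np.random.seed(seed)
    r_sp = ((n_surf - 1.0) / (n_surf + 1.0)) ** 2
    specular = 0.0
    diffuse = 0.0
    transmitted = 0.0
    lateral = 0.0
    absorbed = 0.0
    residual = 0.0
    n_bins = cdf.shape[0]
    for _ in range(n_photons):
        u = np.random.random()
        li = np.searchsorted(cdf, u, side="right")
        if li >= n_bins:
            li = n_bins - 1
        y0 = beam_lo + np.random.random() * (beam_hi - beam_lo)
        specular += r_sp
        status, escaped, aw, rw = _trace(
            y0, 0.0, 0.0, 0.0, 1.0, 1.0 - r_sp, li, cls, mua_t, mus_t, g,
            n_surf, delta, mirror, w_min, deposit_residual, A)
        absorbed += aw
        residual += rw
        if status == STATUS_DIFFUSE_REFLECTED:
            diffuse += escaped
        elif status == STATUS_TRANSMITTED:
            transmitted += escaped
        elif status == STATUS_LATERAL_ESCAPE:
            lateral += escaped
    return specular, diffuse, transmitted, lateral, absorbed, residual


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransportTally:
    """Where the launched unit of optical energy went (fractions sum to 1).

    Lateral escape (open-boundary runs only) is folded into ``transmitted``.
    """

    specular_reflected: float
    diffuse_reflected: float
    transmitted: float
    absorbed: float
    terminated_residual: float

    @property
    def total(self) -> float:
        return (self.specular_reflected + self.diffuse_reflected
                + self.transmitted + self.absorbed + self.terminated_residual)


@dataclass
class AbsorptionGrid:
    """Absorbed energy density per unit delivered fluence.

    ``deposited`` has units 1/m: multiplying by the radiant exposure in
    J/m^2 gives the volumetric energy density in J/m^3 for each 5 um cell.
    Bit-exactly reproducible for a fixed seed and photon count.
    """

    deposited: np.ndarray
    n_photons: int
    rng_seed: int
    cell_size: float
    spectrum_hash: str = ""
    meta: dict = field(default_factory=dict)

    def energy_density(self, fluence_J_cm2: float) -> np.ndarray:
        """J/m^3 deposited for the given radiant exposure (J/cm^2)."""
        return self.deposited * (fluence_J_cm2 * 1e4)


@dataclass(frozen=True)
class PropagationResult:
    status: str
    escaped_weight: float
    absorbed_weight: float
    residual_weight: float


_STATUS_NAMES = {
    STATUS_TERMINATED: "terminated",
    STATUS_DIFFUSE_REFLECTED: "diffuse_reflected",
    STATUS_TRANSMITTED: "transmitted",
    STATUS_LATERAL_ESCAPE: "lateral_escape",
}

#: Packets terminate when one hundredth of the launch weight remains.
WEIGHT_THRESHOLD = 0.01


def _tables_for(grid: TissueGrid, wavelengths_nm: np.ndarray):
    mua, mus = grid.optical_tables(wavelengths_nm)
    return np.ascontiguousarray(mua), np.ascontiguousarray(mus)


def propagate_photon(photon: Photon, grid: TissueGrid, seed: int,
                     absorption: np.ndarray | None = None,
                     mirror_lateral: bool = True,
                     deposit_residual: bool = True) -> PropagationResult:
    """Walk a single launched packet through the grid (for diagnostics and
    tests; bulk runs use :func:`run_transport`)."""
    wl = np.array([photon.wavelength_nm])
    mua, mus = _tables_for(grid, wl)
    if absorption is None:
        absorption = np.zeros(grid.shape)
    if absorption.shape != grid.shape:
        raise ValueError("absorption array shape does not match the grid")
    y, z = photon.position
    ux, uy, uz = photon.direction
    _seed_rng(seed)
    status, escaped, absorbed, residual = _trace(
        y, z, ux, uy, uz, photon.weight, 0, grid.class_map, mua, mus,
        grid.optics.anisotropy, grid.surface_refractive_index,
        grid.geometry.cell_size, mirror_lateral, WEIGHT_THRESHOLD,
        deposit_residual, absorption)
    if not (np.isfinite(absorbed) and np.isfinite(escaped)):
        raise RuntimeError("non-finite photon bookkeeping (simulation bug)")
    return PropagationResult(_STATUS_NAMES[status], escaped, absorbed, residual)


def run_transport(grid: TissueGrid, spectrum: EmissionSpectrum, n_photons: int,
                  seed: int, beam: tuple[float, float] | None = None,
                  mirror_lateral: bool = True,
                  deposit_residual: bool = True) -> tuple[AbsorptionGrid, TransportTally]:
    """Launch ``n_photons`` packets and accumulate the absorption matrix.

    The beam is a uniform-irradiance aperture at normal incidence
    (defaults to the full domain width); each packet's wavelength is an
    inverse-CDF draw from the spectrum.  The returned absorption grid is
    normalized per unit fluence so it can drive any pulse train and
    radiant exposure.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    width = grid.geometry.domain_width
    if beam is None:
        beam = (0.0, width)
    lo, hi = beam
    if not 0.0 <= lo < hi <= width:
        raise ValueError("beam aperture must lie within the domain width")
    mua, mus = _tables_for(grid, spectrum.wavelengths)
    A = np.zeros(grid.shape)
    out = _run_kernel(
        n_photons, seed, grid.class_map, mua, mus, grid.optics.anisotropy,
        grid.surface_refractive_index, grid.geometry.cell_size,
        spectrum.cdf, lo, hi, mirror_lateral, WEIGHT_THRESHOLD,
        deposit_residual, A)
    specular, diffuse, transmitted, lateral, absorbed, residual = out
    tally = TransportTally(
        specular_reflected=specular / n_photons,
        diffuse_reflected=diffuse / n_photons,
        transmitted=(transmitted + lateral) / n_photons,
        absorbed=absorbed / n_photons,
        terminated_residual=residual / n_photons,
    )
    beam_width = hi - lo
    cell = grid.geometry.cell_size
    # per-unit-fluence energy density: fluence * beam_width / n_photons per
    # deposited unit weight, spread over the cell area (out-of-plane depth 1 m)
    scale = beam_width / (n_photons * cell * cell)
    absorption = AbsorptionGrid(
        deposited=A * scale, n_photons=n_photons, rng_seed=seed,
        cell_size=cell, spectrum_hash=spectrum.content_hash(),
        meta={"beam": (lo, hi), "mirror_lateral": mirror_lateral,
              "deposit_residual": deposit_residual},
    )
    return absorption, tally


def save_absorption(path, absorption: AbsorptionGrid) -> None:
    """Self-describing array dump (.npz with metadata)."""
    np.savez_compressed(
        path, deposited=absorption.deposited,
        n_photons=absorption.n_photons, rng_seed=absorption.rng_seed,
        cell_size=absorption.cell_size,
        spectrum_hash=np.bytes_(absorption.spectrum_hash.encode()))


def load_absorption(path) -> AbsorptionGrid:
    with np.load(path) as f:
        return AbsorptionGrid(
            deposited=f["deposited"], n_photons=int(f["n_photons"]),
            rng_seed=int(f["rng_seed"]), cell_size=float(f["cell_size"]),
            spectrum_hash=bytes(f["spectrum_hash"]).decode())
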