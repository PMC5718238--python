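"""Tissue classes, optical/thermal properties and the 2-D simulation grid.

The model skin is a Cartesian map at 5 um resolution: a melanin-rich
epidermis (80 um, 5% melanosomes by default) over a melanin-free dermis,
with a buried hair follicle -- a vertical rod 200 um in diameter starting
200 um below the surface and extending 2000 um in length, at 30% melanin.
Depth z increases downward from the air-tissue boundary at z = 0; each
cell covers the half-open square [i*d, (i+1)*d).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from . import chromophores
from .chromophores import blood_mu_a, melanin_mu_a, water_mu_a


class TissueClass(IntEnum):
    AIR = 0
    EPIDERMIS = 1
    DERMIS = 2
    HAIR = 3


#: Single anisotropy factor used for every tissue and wavelength.
ANISOTROPY = 0.789


@dataclass(frozen=True)
class OpticalProperties:
    """Interaction coefficients of one tissue at one wavelength (SI)."""

    mu_a: float  # absorption coefficient, 1/m
    mu_s: float  # scattering coefficient, 1/m
    g: float     # anisotropy factor (mean cosine of deflection)
    n: float     # refractive index

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy factor must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class ThermalProperties:
    """Constant thermal properties of one tissue class (SI)."""

    k: float    # thermal conductivity, W m^-1 K^-1
    rho: float  # density, kg m^-3
    c: float    # specific heat, J kg^-1 K^-1

    def __post_init__(self):
        if min(self.k, self.rho, self.c) <= 0:
            raise ValueError("thermal properties must be strictly positive")

    @property
    def alpha(self) -> float:
        """Thermal diffusivity k/(rho*c), m^2 s^-1 (always derived)."""
        return self.k / (self.rho * self.c)


#: Physical constants of the tissue layers.
THERMAL_PROPERTIES: dict[TissueClass, ThermalProperties] = {
    TissueClass.EPIDERMIS: ThermalProperties(k=0.5, rho=1200.0, c=3600.0),
    TissueClass.DERMIS: ThermalProperties(k=0.53, rho=1200.0, c=3800.0),
    TissueClass.HAIR: ThermalProperties(k=0.24, rho=1210.0, c=3500.0),
}

REFRACTIVE_INDEX: dict[TissueClass, float] = {
    TissueClass.EPIDERMIS: 1.34,
    TissueClass.DERMIS: 1.37,
    TissueClass.HAIR: 1.7,
}


@dataclass(frozen=True)
class ScatteringLaw:
    """mu_s(lambda) = mie_500*(lambda/500)^-mie_power + rayleigh_500*(lambda/500)^-4.

    Mie scattering from collagen fibres plus Rayleigh scattering from
    small tissue structures; coefficients are the full (not reduced)
    scattering coefficients at the 500 nm reference, in 1/m.
    """

    mie_500: float
    mie_power: float
    rayleigh_500: float

    def mu_s(self, wavelength_nm):
        r = np.asarray(wavelength_nm, dtype=float) / 500.0
        return self.mie_500 * r ** (-self.mie_power) + self.rayleigh_500 * r ** (-4.0)


@dataclass(frozen=True)
class OpticsConfig:
    """Per-tissue chromophore fractions and scattering laws.

    The melanin anchor (concentration -> mu_a conversion) is surfaced here
    rather than hidden: ``melanin_scale_cm``/``melanin_exponent`` define the
    pure-melanosome power law that the per-tissue volume fractions scale.
    """

    melanin_scale_cm: float = 3.55e12
    melanin_exponent: float = chromophores.MELANOSOME_EXPONENT
    water_fraction: dict = field(default_factory=lambda: {
        TissueClass.EPIDERMIS: 0.2,
        TissueClass.DERMIS: 0.3,
        TissueClass.HAIR: 0.05,
    })
    blood_fraction: dict = field(default_factory=lambda: {
        TissueClass.EPIDERMIS: 0.0,
        TissueClass.DERMIS: 0.001,
        TissueClass.HAIR: 0.0,
    })
    scattering: dict = field(default_factory=lambda: {
        TissueClass.EPIDERMIS: ScatteringLaw(1.2e4, 0.7, 4.0e3),
        TissueClass.DERMIS: ScatteringLaw(1.0e4, 0.7, 3.0e3),
        TissueClass.HAIR: ScatteringLaw(1.0e4, 0.7, 3.0e3),
    })
    anisotropy: float = ANISOTROPY


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the simulated tissue block (SI lengths)."""

    cell_size: float = 5e-6
    epidermis_thickness: float = 80e-6
    melanin_fraction_epidermis: float = 0.05
    melanin_fraction_hair: float = 0.30
    follicle_top_depth: float = 200e-6
    follicle_diameter: float = 200e-6
    follicle_length: float = 2000e-6
    domain_width: float = 4800e-6
    domain_depth: float = 4000e-6
    probe_epidermis_depth: float = 20e-6
    probe_follicle_depth: float = 2000e-6

    def __post_init__(self):
        d = self.cell_size
        if d <= 0:
            raise ValueError("cell_size must be positive")
        for name in ("epidermis_thickness", "follicle_top_depth",
                     "follicle_diameter", "follicle_length",
                     "domain_width", "domain_depth"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
            if abs(v / d - round(v / d)) > 1e-9:
                raise ValueError(f"{name}={v} is not a multiple of cell_size={d}")
        if self.follicle_top_depth + self.follicle_length > self.domain_depth:
            raise ValueError("follicle extends beyond domain_depth")
        if self.follicle_diameter > self.domain_width:
            raise ValueError("follicle wider than domain")

    @property
    def n_cells_y(self) -> int:
        return int(round(self.domain_width / self.cell_size))

    @property
    def n_cells_z(self) -> int:
        return int(round(self.domain_depth / self.cell_size))


def melanin_fraction_for(geometry: GeometryConfig, tissue: TissueClass) -> float:
    if tissue == TissueClass.EPIDERMIS:
        return geometry.melanin_fraction_epidermis
    if tissue == TissueClass.HAIR:
        return geometry.melanin_fraction_hair
    return 0.0


def tissue_optics(tissue: TissueClass, wavelength_nm: float,
                  geometry: GeometryConfig | None = None,
                  optics: OpticsConfig | None = None) -> OpticalProperties:
    """Optical properties of a tissue class at one wavelength.

    Deterministic and pure: mu_a combines the melanin power law (scaled by
    the tissue's melanosome fraction) with the water/blood background;
    mu_s follows the Mie + Rayleigh law; g and n are the tabulated
    constants.  AIR has no interaction coefficients and is rejected.
    """
    if tissue == TissueClass.AIR:
        raise ValueError("AIR has no optical interaction coefficients")
    geometry = geometry if geometry is not None else GeometryConfig()
    optics = optics if optics is not None else OpticsConfig()
    f_mel = melanin_fraction_for(geometry, tissue)
    mu_a = (melanin_mu_a(wavelength_nm, f_mel,
                         scale_cm=optics.melanin_scale_cm,
                         exponent=optics.melanin_exponent)
            + water_mu_a(wavelength_nm, optics.water_fraction[tissue])
            + blood_mu_a(wavelength_nm, optics.blood_fraction[tissue]))
    mu_s = optics.scattering[tissue].mu_s(wavelength_nm)
    return OpticalProperties(mu_a=float(mu_a), mu_s=float(mu_s),
                             g=optics.anisotropy, n=REFRACTIVE_INDEX[tissue])


@dataclass(frozen=True)
class ProbeSet:
    """Cell indices (iz, iy) of the two temperature probes."""

    epidermal_probe: tuple[int, int]
    follicle_probe: tuple[int, int]


@dataclass
class TissueGrid:
    """2-D map of tissue classes plus the property lookups."""

    class_map: np.ndarray  # int8, shape (nz, ny)
    geometry: GeometryConfig
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    thermal: dict = field(default_factory=lambda: dict(THERMAL_PROPERTIES))

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_map.shape

    def optics_at(self, tissue: TissueClass, wavelength_nm: float) -> OpticalProperties:
        return tissue_optics(tissue, wavelength_nm, self.geometry, self.optics)

    def optical_tables(self, wavelengths_nm: np.ndarray):
        """(mu_a, mu_s) lookup tables, shape (4 classes, n_wavelengths), 1/m.

        Row 0 (AIR) is zero; the transport kernel never scatters there.
        """
        n = len(wavelengths_nm)
        mua = np.zeros((4, n))
        mus = np.zeros((4, n))
        for t in (TissueClass.EPIDERMIS, TissueClass.DERMIS, TissueClass.HAIR):
            f_mel = melanin_fraction_for(self.geometry, t)
            mua[t] = (melanin_mu_a(wavelengths_nm, f_mel,
                                   scale_cm=self.optics.melanin_scale_cm,
                                   exponent=self.optics.melanin_exponent)
                      + water_mu_a(wavelengths_nm, self.optics.water_fraction[t])
                      + blood_mu_a(wavelengths_nm, self.optics.blood_fraction[t]))
            mus[t] = self.optics.scattering[t].mu_s(wavelengths_nm)
        return mua, mus

    def thermal_maps(self):
        """(k, rho*c) per-cell arrays for the heat solver."""
        kmap = np.empty(self.class_map.shape)
        rcmap = np.empty(self.class_map.shape)
        for t, props in self.thermal.items():
            sel = self.class_map == int(t)
            kmap[sel] = props.k
            rcmap[sel] = props.rho * props.c
        if np.any(self.class_map == int(TissueClass.AIR)):
            raise ValueError("AIR cells below the surface are not supported")
        return kmap, rcmap

    @property
    def surface_refractive_index(self) -> float:
        return REFRACTIVE_INDEX[TissueClass.EPIDERMIS]


def build_grid(config: GeometryConfig | None = None,
               optics: OpticsConfig | None = None) -> TissueGrid:
    """Build the class map: epidermis on top, the follicle rod centered
    laterally, dermis everywhere else below the surface."""
    config = config if config is not None else GeometryConfig()
    optics = optics if optics is not None else OpticsConfig()
    ny, nz = config.n_cells_y, config.n_cells_z
    d = config.cell_size
    cmap = np.full((nz, ny), int(TissueClass.DERMIS), dtype=np.int8)
    n_epi = int(round(config.epidermis_thickness / d))
    cmap[:n_epi, :] = int(TissueClass.EPIDERMIS)
    w = int(round(config.follicle_diameter / d))
    if w > 0:
        z0 = int(round(config.follicle_top_depth / d))
        z1 = int(round((config.follicle_top_depth + config.follicle_length) / d))
        y0 = ny // 2 - w // 2
        cmap[z0:z1, y0:y0 + w] = int(TissueClass.HAIR)
    return TissueGrid(class_map=cmap, geometry=config, optics=optics)


def locate_probes(grid: TissueGrid) -> ProbeSet:
    """Place the epidermal probe on the beam axis at the configured depth
    (20 um default) and the follicle probe 10 um (2 cells) inboard of the
    follicle's lateral edge at the configured depth (2000 um default)."""
    g = grid.geometry
    d = g.cell_size
    ny = g.n_cells_y
    iz_epi = int(round(g.probe_epidermis_depth / d))
    iy_axis = ny // 2
    iz_fol = int(round(g.probe_follicle_depth / d))
    if iz_fol >= grid.class_map.shape[0]:
        raise ValueError("follicle probe depth outside the domain")
    row = grid.class_map[iz_fol]
    hair_cols = np.flatnonzero(row == int(TissueClass.HAIR))
    if hair_cols.size == 0:
        raise ValueError(
            f"no HAIR cells at the follicle probe depth "
            f"{g.probe_follicle_depth * 1e6:.0f} um"
        )
    iy_fol = int(hair_cols[-1]) - 2  # 10 um inboard of the right edge
    probe = ProbeSet(epidermal_probe=(iz_epi, iy_axis),
                     follicle_probe=(iz_fol, iy_fol))
    if grid.class_map[probe.follicle_probe] != int(TissueClass.HAIR):
        raise ValueError("follicle probe does not fall inside HAIR cells")
    return probe
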