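"""Run configuration: one human-editable YAML file drives the whole
comparison (geometry, optics, spectrum, fluence, photon budget, solver,
categories, output)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
import hashlib
import warnings

import yaml

from .pulses import PulseCategory
from .spectrum import EmissionSpectrum, make_synthetic_spectrum, read_spectrum
from .thermal import SolverConfig
from .tissue import GeometryConfig, OpticsConfig, ScatteringLaw, TissueClass

#: Photon counts below this are fine for CI fixtures but noisy for
#: production comparisons.
PRODUCTION_PHOTONS = 10_000


@dataclass(frozen=True)
class SpectrumConfig:
    shape: str = "planck"
    cutoff_nm: float = 695.0
    temperature_K: float = 5500.0
    measured_path: str | None = None

    def build(self, total_fluence: float) -> EmissionSpectrum:
        if self.measured_path:
            return read_spectrum(self.measured_path, total_fluence=total_fluence)
        return make_synthetic_spectrum(cutoff_nm=self.cutoff_nm,
                                       temperature_K=self.temperature_K,
                                       total_fluence=total_fluence,
                                       shape=self.shape)


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    fluence: float = 10.0          # J/cm^2
    n_photons: int = 1_000_000
    seed: int = 12345
    damage_threshold: float = 70.0  # degC, follicular denaturation
    categories: tuple[str, ...] = tuple(c.value for c in PulseCategory)
    output_dir: str | None = None

    def __post_init__(self):
        if self.fluence <= 0:
            raise ValueError("fluence must be positive")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        for c in self.categories:
            PulseCategory(c)
        if self.n_photons < PRODUCTION_PHOTONS:
            warnings.warn(
                f"n_photons={self.n_photons} is below the recommended "
                f"{PRODUCTION_PHOTONS} for production runs", stacklevel=2)


def _to_plain(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    for sect in ("water_fraction", "blood_fraction"):
        d["optics"][sect] = {TissueClass(k).name.lower(): v
                             for k, v in d["optics"][sect].items()}
    d["optics"]["scattering"] = {
        TissueClass(k).name.lower(): asdict(v) if not isinstance(v, dict) else v
        for k, v in cfg.optics.scattering.items()}
    d["categories"] = list(cfg.categories)
    return d


def _from_plain(d: dict) -> RunConfig:
    d = dict(d)
    geo = GeometryConfig(**d.pop("geometry", {}))
    opt = d.pop("optics", {})
    if opt:
        kwargs = dict(opt)
        for sect in ("water_fraction", "blood_fraction"):
            if sect in kwargs:
                kwargs[sect] = {TissueClass[k.upper()]: float(v)
                                for k, v in kwargs[sect].items()}
        if "scattering" in kwargs:
            kwargs["scattering"] = {TissueClass[k.upper()]: ScatteringLaw(**v)
                                    for k, v in kwargs["scattering"].items()}
        optics = OpticsConfig(**kwargs)
    else:
        optics = OpticsConfig()
    spec = SpectrumConfig(**d.pop("spectrum", {}))
    sol = SolverConfig(**d.pop("solver", {}))
    if "categories" in d:
        d["categories"] = tuple(d["categories"])
    return RunConfig(geometry=geo, optics=optics, spectrum=spec, solver=sol, **d)


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(_to_plain(cfg), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return _from_plain(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]
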