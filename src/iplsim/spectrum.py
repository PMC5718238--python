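"""Broadband IPL emission spectrum on 1-nm bins.

The source is modeled as 600 wavelengths of 1 nm bandwidth spanning
500-1100 nm, normalized so the launched photon ensemble carries the
configured total radiant exposure (10 J/cm^2 by default).  The default
synthetic shape is a long-pass-filtered blackbody envelope mimicking a
filtered xenon-flashlamp output; a measured spectrum can be substituted
from two-column text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np

N_BINS = 600
WAVELENGTHS_NM = np.arange(500.0, 1100.0)  # bin lower edges / labels, 1 nm pitch


@dataclass(frozen=True)
class EmissionSpectrum:
    weights: np.ndarray            # relative intensity per bin, sums to 1
    total_fluence: float = 10.0    # radiant exposure, J/cm^2
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if wl.shape != (N_BINS,) or not np.allclose(np.diff(wl), 1.0):
            raise ValueError("spectrum must have exactly 600 bins at 1 nm pitch")
        if wl[0] != 500.0:
            raise ValueError("spectral support must start at 500 nm")
        if w.shape != (N_BINS,):
            raise ValueError("weights must have 600 entries")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive total")
        if self.total_fluence <= 0:
            raise ValueError("total_fluence must be positive")
        w = w / w.sum()
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "wavelengths", wl)

    @property
    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.weights)
        c[-1] = 1.0
        return c

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(np.float64(self.total_fluence).tobytes())
        return h.hexdigest()[:16]


def make_synthetic_spectrum(cutoff_nm: float = 530.0, temperature_K: float = 5500.0,
                            total_fluence: float = 10.0,
                            shape: str = "planck") -> EmissionSpectrum:
    """Synthetic filtered-flashlamp spectrum.

    ``planck`` uses a blackbody envelope at the given plasma temperature
    with a hard long-pass cut at ``cutoff_nm``; ``flat`` is uniform above
    the cutoff.  Weights below the cutoff are exactly zero.
    """
    if not 500.0 <= cutoff_nm <= 1100.0:
        raise ValueError("cutoff must lie within the 500-1100 nm support")
    wl = WAVELENGTHS_NM
    if shape == "planck":
        lam = wl * 1e-9
        h, c, kb = 6.62607e-34, 2.99792e8, 1.380649e-23
        weights = lam ** -5.0 / np.expm1(h * c / (lam * kb * temperature_K))
        weights = weights / weights.max()
    elif shape == "flat":
        weights = np.ones(N_BINS)
    else:
        raise ValueError(f"unknown spectrum shape {shape!r}")
    weights = np.where(wl < cutoff_nm, 0.0, weights)
    if not np.any(weights > 0):
        raise ValueError("spectrum is identically zero after filtering")
    return EmissionSpectrum(weights=weights, total_fluence=total_fluence)


def sample_wavelength(spectrum: EmissionSpectrum, u) -> np.ndarray | float:
    """Inverse-CDF draw of a launch wavelength from the spectrum.

    ``u`` is uniform in [0, 1); the empirical bin frequencies converge to
    the spectral weights.
    """
    idx = np.searchsorted(spectrum.cdf, u, side="right")
    idx = np.clip(idx, 0, N_BINS - 1)
    out = spectrum.wavelengths[idx]
    return float(out) if np.isscalar(u) else out


def photon_energy(spectrum: EmissionSpectrum, n_photons: int) -> float:
    """Radiant exposure carried per launched packet (J/cm^2) so that the
    ensemble carries exactly ``total_fluence``."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    return spectrum.total_fluence / n_photons


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    """Two-column text: wavelength_nm, relative_intensity."""
    np.savetxt(path, np.column_stack([spectrum.wavelengths, spectrum.weights]),
               fmt="%.1f %.8e", header="wavelength_nm relative_intensity")


def read_spectrum(path, total_fluence: float = 10.0) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, relative_intensity) text spectrum.

    The grid must already be the 600 x 1 nm support; anything else is
    rejected rather than silently resampled.
    """
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected two-column (wavelength, intensity) text")
    return EmissionSpectrum(weights=data[:, 1], wavelengths=data[:, 0],
                            total_fluence=total_fluence)
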