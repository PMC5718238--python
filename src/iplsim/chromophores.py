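"""Wavelength-dependent absorption of the skin chromophores.

Melanin dominates both the epidermal and the follicular response in
photoepilation; water and oxyhemoglobin provide the small broadband
background of the dermis.  Melanin follows the widely used melanosome
power law; water and whole-blood curves are compact tables interpolated
log-linearly.  All coefficients are returned in SI units (1/m).
"""

from __future__ import annotations

import numpy as np

#: Spectral support of the source model, nm (inclusive lower, exclusive upper
#: bin edge convention is handled by :mod:`iplsim.spectrum`).
WAVELENGTH_MIN_NM = 500.0
WAVELENGTH_MAX_NM = 1100.0

#: Interior melanosome absorption anchor: mu_a = MELANOSOME_SCALE * lambda^-3.48
#: with lambda in nm gives mu_a in 1/cm.  This is the standard literature
#: power law for the monotone decline of melanin absorption through the
#: visible and near infrared.  Exposed so the concentration-to-mu_a
#: conversion is a visible, configurable anchor rather than a buried magic
#: number.
MELANOSOME_SCALE_CM = 1.70e12
MELANOSOME_EXPONENT = 3.48


def _check_wavelength(wavelength_nm):
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl < WAVELENGTH_MIN_NM) or np.any(wl > WAVELENGTH_MAX_NM):
        raise ValueError(
            f"wavelength {wavelength_nm!r} nm outside spectral support "
            f"[{WAVELENGTH_MIN_NM:g}, {WAVELENGTH_MAX_NM:g}] nm"
        )
    return wl


def melanin_mu_a(wavelength_nm, melanin_fraction, *, scale_cm=MELANOSOME_SCALE_CM,
                 exponent=MELANOSOME_EXPONENT):
    """Absorption coefficient (1/m) of a melanin-containing tissue.

    Linear in the melanosome volume fraction; strictly decreasing in
    wavelength.

    Parameters
    ----------
    wavelength_nm : float or array
        Wavelength in nm, within the 500-1100 nm spectral support.
    melanin_fraction : float
        Melanosome volume fraction in [0, 1] (0.05 for the epidermis,
        0.30 for the hair shaft at the defaults).
    """
    wl = _check_wavelength(wavelength_nm)
    f = float(melanin_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"melanin_fraction must be in [0, 1], got {f}")
    mua_cm = scale_cm * wl ** (-exponent)
    return f * mua_cm * 100.0  # 1/cm -> 1/m


# Pure-water absorption, (nm, 1/cm).  Approximate literature values; the
# contribution is small everywhere below 900 nm.
_WATER_NM = np.array([
    500.0, 550.0, 600.0, 650.0, 700.0, 750.0, 800.0, 850.0,
    900.0, 930.0, 950.0, 970.0, 1000.0, 1050.0, 1100.0,
])
_WATER_MUA_CM = np.array([
    2.5e-4, 4.5e-4, 2.2e-3, 3.2e-3, 6.0e-3, 2.8e-2, 2.0e-2, 4.3e-2,
    6.8e-2, 1.3e-1, 2.7e-1, 4.5e-1, 3.6e-1, 1.4e-1, 1.9e-1,
])

# Whole oxygenated blood (150 g Hb/L), (nm, 1/cm); approximate.
_HBO2_NM = np.array([
    500.0, 520.0, 540.0, 560.0, 577.0, 590.0, 600.0, 620.0, 650.0,
    700.0, 750.0, 800.0, 850.0, 900.0, 950.0, 1000.0, 1100.0,
])
_HBO2_MUA_CM = np.array([
    112.0, 150.0, 345.0, 177.0, 338.0, 70.0, 17.0, 3.5, 2.0,
    1.55, 2.8, 4.4, 5.7, 6.4, 6.5, 6.1, 5.6,
])


def _log_interp(wl, table_nm, table_mua_cm):
    return 100.0 * 10.0 ** np.interp(wl, table_nm, np.log10(table_mua_cm))


def water_mu_a(wavelength_nm, water_fraction=1.0):
    """Absorption coefficient (1/m) of the water content of a tissue."""
    wl = _check_wavelength(wavelength_nm)
    return float(water_fraction) * _log_interp(wl, _WATER_NM, _WATER_MUA_CM)


def blood_mu_a(wavelength_nm, blood_fraction=1.0):
    """Absorption coefficient (1/m) of oxygenated whole blood at the given
    volume fraction (dermal microvasculature)."""
    wl = _check_wavelength(wavelength_nm)
    return float(blood_fraction) * _log_interp(wl, _HBO2_NM, _HBO2_MUA_CM)
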