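"""Differential Raman cross sections, band combination and tip spectra.

The differential cross section of Stokes Raman scattering by mode k is

    dσ/dΩ = (π²/ε₀²) (ν̃_in − ν̃_k)⁴ · h / (8π²c ν̃_k)
            · |α′_k|² / (1 − exp(−h c ν̃_k / k_B T)),

with the wavenumbers ν̃ in m⁻¹, the near-field polarizability α′_k converted
from Å³ (the unit natural to Å-gridded densities) to SI (C·m²·V⁻¹) via
4πε₀·10⁻³⁰, and CODATA constants throughout; the result is in m²·sr⁻¹.  The
Boltzmann denominator accounts for thermal population of the vibrational
ground state; the default temperature is 298 K.

Near-degenerate modes that a spectrometer cannot separate are combined
incoherently: distinct normal modes scatter at distinct vibrational
frequencies, so their images add as intensities, pixel by pixel, within a
band window (default width 20 cm⁻¹).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import constants as _const

from .imaging import TERSImage
from .raman import NormalMode

__all__ = [
    "RamanRecord",
    "BandSpec",
    "Spectrum",
    "cross_section",
    "combine_band",
    "tip_spectrum",
    "ALPHA_A3_TO_SI",
]

#: Polarizability volume (Å³) → SI polarizability (C·m²·V⁻¹).
ALPHA_A3_TO_SI = 4.0 * np.pi * _const.epsilon_0 * 1e-30

_CM_TO_M = 100.0  # cm⁻¹ → m⁻¹


@dataclasses.dataclass
class RamanRecord:
    """Per-mode near-field Raman response at one tip position."""

    mode: NormalMode
    alpha_prime: complex  # zz near-field polarizability, Å³
    cross_section: float  # dσ/dΩ, m²·sr⁻¹
    nu_in: float          # incident wavenumber, cm⁻¹
    temperature: float    # K

    def __post_init__(self) -> None:
        if self.cross_section < 0 or not np.isfinite(self.cross_section):
            raise ValueError("cross section must be finite and non-negative")


@dataclasses.dataclass
class BandSpec:
    """A spectral band: symmetric window center ± width/2, cm⁻¹."""

    center: float
    width: float = 20.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")

    def contains(self, frequency: float) -> bool:
        return abs(frequency - self.center) <= self.width / 2.0


def cross_section(
    alpha_prime: complex, nu_in: float, nu_k: float, temperature: float = 298.0
) -> float:
    """Differential Raman cross section dσ/dΩ in m²·sr⁻¹.

    Parameters
    ----------
    alpha_prime : complex
        Near-field Raman polarizability α′_k, Å³.
    nu_in, nu_k : float
        Incident and mode wavenumbers, cm⁻¹; requires ``nu_in > nu_k > 0``
        (Stokes scattering).
    temperature : float
        K; must be positive.
    """
    if nu_k <= 0:
        raise ValueError(f"mode wavenumber must be positive, got {nu_k}")
    if nu_k >= nu_in:
        raise ValueError(
            f"Stokes scattering requires nu_in > nu_k, got {nu_in} <= {nu_k}"
        )
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    h, c, kb, eps0 = _const.h, _const.c, _const.k, _const.epsilon_0
    nu_in_m = nu_in * _CM_TO_M
    nu_k_m = nu_k * _CM_TO_M
    alpha_si = abs(alpha_prime) * ALPHA_A3_TO_SI
    boltzmann = 1.0 - np.exp(-h * c * nu_k_m / (kb * temperature))
    return float(
        (np.pi**2 / eps0**2)
        * (nu_in_m - nu_k_m) ** 4
        * h / (8.0 * np.pi**2 * c * nu_k_m)
        * alpha_si**2
        / boltzmann
    )


def combine_band(
    images: list[tuple[TERSImage, float]], band: BandSpec
) -> TERSImage:
    """Pixelwise sum of the images whose frequencies fall inside the band.

    ``images`` is a list of (image, frequency cm⁻¹) pairs sharing one scan
    geometry.  The combination is incoherent (intensities add); modes outside
    ``center ± width/2`` are ignored.  An empty in-band set yields a zero
    image with a warning.
    """
    if not images:
        raise ValueError("combine_band needs at least one image to define geometry")
    first = images[0][0]
    for img, _ in images[1:]:
        if (
            img.intensities.shape != first.intensities.shape
            or not np.allclose(img.x, first.x)
            or not np.allclose(img.y, first.y)
        ):
            raise ValueError("images in a band must share scan geometry")
    in_band = [(img, f) for img, f in images if band.contains(f)]
    if not in_band:
        warnings.warn(
            f"no modes inside band {band.center} ± {band.width / 2} cm⁻¹;"
            " returning a zero image",
            stacklevel=2,
        )
        total = np.zeros_like(first.intensities)
    else:
        total = np.sum([img.intensities for img, _ in in_band], axis=0)
    meta = {
        "band_center_cm1": band.center,
        "band_width_cm1": band.width,
        "combined_frequencies_cm1": [f for _, f in in_band],
        "profile": first.meta.get("profile"),
        "fwhm": first.meta.get("fwhm"),
        "height": first.meta.get("height"),
    }
    return TERSImage(total, first.x, first.y, meta)


@dataclasses.dataclass
class Spectrum:
    """A sampled (or stick) spectrum at one tip position."""

    wavenumbers: np.ndarray  # cm⁻¹
    values: np.ndarray       # dσ/dΩ density (m²·sr⁻¹·cm) or sticks (m²·sr⁻¹)
    stick: bool
    meta: dict = dataclasses.field(default_factory=dict)

    def save_text(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        header = (
            "wavenumber_cm-1  dsigma_dOmega"
            + ("_m2_sr-1" if self.stick else "_m2_sr-1_per_cm-1")
        )
        np.savetxt(
            path, np.column_stack([self.wavenumbers, self.values]),
            fmt="%.10e", header=header,
        )
        if sidecar:
            with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
                json.dump({"stick": self.stick, **self.meta}, fh, indent=2, sort_keys=True)


def tip_spectrum(
    records: list[RamanRecord],
    broadening_fwhm: float = 10.0,
    wavenumbers: np.ndarray | None = None,
    padding: float = 100.0,
    step: float = 0.5,
) -> Spectrum:
    """Spectrum at a fixed tip: area-normalized Lorentzian line per mode.

    Each mode contributes a Lorentzian centered at ν̃_k whose integrated area
    equals its cross section, so the numeric integral of the spectrum equals
    the sum of the cross sections.  ``broadening_fwhm = 0`` returns a stick
    spectrum (one row per mode).  The Lorentzian line shape and its default
    10 cm⁻¹ width are display parameters, not physics.
    """
    if not records:
        raise ValueError("tip_spectrum needs at least one record")
    if broadening_fwhm < 0:
        raise ValueError("broadening FWHM must be >= 0")
    freqs = np.array([r.mode.frequency for r in records])
    sigmas = np.array([r.cross_section for r in records])
    meta = {
        "nu_in_cm1": records[0].nu_in,
        "temperature_K": records[0].temperature,
        "broadening_fwhm_cm1": broadening_fwhm,
        "mode_indices": [r.mode.index for r in records],
    }
    if broadening_fwhm == 0:
        order = np.argsort(freqs)
        return Spectrum(freqs[order], sigmas[order], stick=True, meta=meta)
    if wavenumbers is None:
        lo = max(freqs.min() - padding, step)
        hi = freqs.max() + padding
        wavenumbers = np.arange(lo, hi + step / 2, step)
    gamma = broadening_fwhm / 2.0
    nu = np.asarray(wavenumbers, dtype=float)
    lines = (gamma / np.pi) / ((nu[None, :] - freqs[:, None]) ** 2 + gamma**2)
    return Spectrum(nu, (sigmas[:, None] * lines).sum(axis=0), stick=False, meta=meta)
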