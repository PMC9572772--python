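"""Absorption spectra and excited-state lists.

This module carries the UV-Vis side of a charge-transfer (CT) complex study:
locating band maxima, converting wavelengths to band-gap energies, and
broadening a discrete excited-state list (wavelength, oscillator strength)
into a simulated absorption curve.  A CT complex shows a new visible band
absent from both the electron donor and acceptor spectra; its position and
height drive all downstream equilibrium analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .constants import HC_EV_NM

__all__ = [
    "Spectrum",
    "ExcitedState",
    "find_lambda_max",
    "wavelength_to_ev",
    "ev_to_wavelength",
    "simulate_uv_spectrum",
    "read_spectrum_csv",
    "read_excited_states_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """A sampled absorbance spectrum.

    Parameters
    ----------
    wavelength_nm : array-like
        Strictly increasing wavelengths in nm.
    absorbance : array-like
        Absorbance (AU), same length as ``wavelength_nm``.
    label, solvent : str
        Free-text metadata.
    pathlength_cm : float
        Optical pathlength, must be positive (default 1.0 cm).
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    solvent: str = ""
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelength and absorbance must be equal-length 1-D")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", ab)

    def smoothed(self, window: int = 7, polyorder: int = 2) -> "Spectrum":
        """Return a Savitzky-Golay smoothed copy (explicit, never implicit)."""
        return Spectrum(
            self.wavelength_nm,
            savgol_filter(self.absorbance, window, polyorder),
            label=self.label,
            solvent=self.solvent,
            pathlength_cm=self.pathlength_cm,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "absorbance": self.absorbance}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ExcitedState:
    """One electronic excitation: wavelength, energy and oscillator strength.

    ``energy_ev`` may be omitted, in which case it is derived from the
    wavelength.  When both are given they must agree with E = hc/lambda to
    0.5% (guards against transposed table columns).
    """

    lambda_nm: float
    oscillator_strength: float
    energy_ev: float | None = None
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.lambda_nm <= 0:
            raise ValueError("lambda_nm must be positive")
        if self.oscillator_strength < 0:
            raise ValueError("oscillator strength must be nonnegative")
        if self.energy_ev is None:
            object.__setattr__(self, "energy_ev", HC_EV_NM / self.lambda_nm)
        else:
            if abs(self.energy_ev * self.lambda_nm / HC_EV_NM - 1.0) > 5e-3:
                raise ValueError(
                    "energy_ev and lambda_nm disagree with E = hc/lambda by >0.5%"
                )


def wavelength_to_ev(lambda_nm: float) -> float:
    """Convert a wavelength (nm) to photon energy (eV), E = hc/lambda."""
    if np.any(np.asarray(lambda_nm) <= 0):
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / lambda_nm


def ev_to_wavelength(energy_ev: float) -> float:
    """Inverse of :func:`wavelength_to_ev`."""
    if np.any(np.asarray(energy_ev) <= 0):
        raise ValueError("energy must be positive")
    return HC_EV_NM / energy_ev


def find_lambda_max(
    spectrum: Spectrum, window_nm: tuple[float, float]
) -> tuple[float, float]:
    """Locate the absorbance maximum inside a wavelength window.

    Returns ``(lambda_max_nm, a_max)``.  Ties are broken toward the longer
    wavelength: the CT band is the red-most feature of interest, so on a
    plateau the red edge is reported.

    Raises
    ------
    ValueError
        If the window misses the sampled range or covers fewer than 3 points.
    """
    lo, hi = window_nm
    if hi <= lo:
        raise ValueError("window must satisfy low < high")
    mask = (spectrum.wavelength_nm >= lo) & (spectrum.wavelength_nm <= hi)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 sampled points")
    wl = spectrum.wavelength_nm[mask]
    ab = spectrum.absorbance[mask]
    # argmax over reversed arrays -> last (longest-wavelength) maximum
    idx = len(ab) - 1 - int(np.argmax(ab[::-1]))
    return float(wl[idx]), float(ab[idx])


def simulate_uv_spectrum(
    states: Sequence[ExcitedState],
    fwhm_ev: float = 0.333,
    grid_nm: Sequence[float] | None = None,
    label: str = "simulated",
) -> Spectrum:
    """Convolve excited states into a simulated UV-Vis spectrum.

    Each state contributes a Gaussian in *energy* space centred at its
    excitation energy with peak height equal to its oscillator strength
    (arbitrary units); the sum is then sampled on ``grid_nm``.  The 0.333 eV
    default FWHM matches the common convolution convention of TD-DFT
    spectrum builders.
    """
    if len(states) == 0:
        raise ValueError("need at least one excited state")
    if fwhm_ev <= 0:
        raise ValueError("fwhm_ev must be positive")
    if grid_nm is None:
        grid_nm = np.arange(200.0, 800.0 + 0.5, 0.5)
    grid_nm = np.asarray(grid_nm, dtype=float)
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    e_grid = HC_EV_NM / grid_nm
    total = np.zeros_like(grid_nm)
    for s in states:
        total += s.oscillator_strength * np.exp(
            -0.5 * ((e_grid - s.energy_ev) / sigma) ** 2
        )
    return Spectrum(grid_nm, total, label=label)


def read_spectrum_csv(path: str | Path, **meta) -> Spectrum:
    """Read a two-column ``wavelength_nm,absorbance`` CSV (header required)."""
    df = pd.read_csv(path, comment="#")
    if not {"wavelength_nm", "absorbance"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns wavelength_nm,absorbance")
    df = df.sort_values("wavelength_nm")
    return Spectrum(df["wavelength_nm"].values, df["absorbance"].values, **meta)


def read_excited_states_csv(path: str | Path) -> list[ExcitedState]:
    """Read ``lambda_nm,osc_strength[,assignment]`` rows."""
    df = pd.read_csv(path, comment="#")
    if not {"lambda_nm", "osc_strength"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns lambda_nm,osc_strength")
    return [
        ExcitedState(
            lambda_nm=float(r["lambda_nm"]),
            oscillator_strength=float(r["osc_strength"]),
            assignment=str(r.get("assignment", "")),
        )
        for _, r in df.iterrows()
    ]
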