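"""Light calibration: optical power to isomerization rate (R*/s).

Conversion proceeds in three steps: (1) the calibrated total power becomes a
power density over the illuminated spot; (2) the LED emission spectrum is
rescaled so its integral equals that density; (3) the spectrum is converted
to photon-flux density per wavelength (dividing by the photon energy
h*c/lambda), weighted by the photoreceptor's per-photon spectral
sensitivity, integrated, and scaled by the receptor's collecting area.

The sensitivity weighting is applied to photon flux, not energy, because
spectral sensitivities are isomerization probabilities per photon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralCurve", "collecting_area", "power_to_isomerizations",
           "DEFAULT_SPOT_DIAMETER_UM"]

_H = 6.62607015e-34  # J s
_C = 2.99792458e8    # m/s

# effective collecting areas, um^2
_COLLECTING_AREAS = {
    ("primate", "rod"): 1.0,
    ("primate", "cone"): 0.37,
    ("mouse", "rod"): 0.5,
    ("mouse", "cone"): 0.2,
}

# the stimulation spot uniformly illuminates a 600-um diameter disk
DEFAULT_SPOT_DIAMETER_UM = 600.0


def collecting_area(cell_type: str) -> float:
    """Collecting area (um^2) for a ``<species>_<class>`` tag such as
    ``mouse_rod``."""
    species, _, klass = cell_type.partition("_")
    try:
        return _COLLECTING_AREAS[(species, klass)]
    except KeyError:
        raise ValueError(f"unknown cell type {cell_type!r}") from None


@dataclass
class SpectralCurve:
    """Two-column spectral table: wavelengths (nm, strictly increasing) and
    nonnegative per-wavelength values (relative emitted power, or
    isomerization probability per photon)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be nonnegative")


def power_to_isomerizations(total_power: float, emission: SpectralCurve,
                            sensitivity: SpectralCurve, cell_type: str,
                            spot_diameter: float = DEFAULT_SPOT_DIAMETER_UM) -> float:
    """Convert a calibrated power reading (W) into R*/s for one receptor.

    ``spot_diameter`` is in um.  The emission and sensitivity curves are
    linearly interpolated onto their overlapping wavelength support and
    integrated by the trapezoid rule; only the emission spectrum's shape
    matters (its normalization is absorbed by the rescaling step).
    """
    if total_power <= 0 or spot_diameter <= 0:
        raise ValueError("power and spot diameter must be positive")
    area_spot = np.pi * (spot_diameter / 2.0) ** 2  # um^2
    power_density = total_power / area_spot          # W / um^2

    lo = max(emission.wavelengths[0], sensitivity.wavelengths[0])
    hi = min(emission.wavelengths[-1], sensitivity.wavelengths[-1])
    if hi <= lo:
        raise ValueError("emission and sensitivity spectra do not overlap")
    wl = np.union1d(emission.wavelengths, sensitivity.wavelengths)
    wl = wl[(wl >= lo) & (wl <= hi)]
    if len(wl) < 2:
        wl = np.array([lo, hi])
    em = np.interp(wl, emission.wavelengths, emission.values)
    sens = np.interp(wl, sensitivity.wavelengths, sensitivity.values)

    integral = np.trapezoid(em, wl)
    if integral <= 0:
        raise ValueError("emission spectrum integrates to zero on the overlap")
    em_cal = em * (power_density / integral)  # W / um^2 / nm

    # photon energy at each wavelength (J); wavelengths in nm -> m
    e_photon = _H * _C / (wl * 1e-9)
    photon_flux = em_cal / e_photon           # photons / s / um^2 / nm
    rate_density = np.trapezoid(photon_flux * sens, wl)  # R* / s / um^2
    return float(collecting_area(cell_type) * rate_density)
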