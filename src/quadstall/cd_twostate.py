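"""Circular-dichroism diagnostics of two-state quadruplex melting.

A parallel-topology RNA G-quadruplex shows a positive CD band near
265 nm and a negative band near 240 nm. If melting is two-state, every
spectrum in a temperature series is a mixture of exactly two basis
spectra, S(lambda, T) = f(T) B_folded + (1-f(T)) B_unfolded, which
implies (i) an isosbestic point wherever the bases cross and (ii) a
perfectly linear relation between the intensities at any two
wavelengths across the series. Both diagnostics are implemented here;
the CD-monitored melting curve itself is fitted with
:mod:`quadstall.melt_thermo`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .melt_thermo import MeltingCurve

__all__ = [
    "SpectrumSeries", "TopologyCall", "IsosbesticResult", "LinearityResult",
    "topology_signature", "isosbestic_point", "two_state_linearity",
    "melting_curve_at", "read_spectrum_csv", "write_spectrum_csv",
]


@dataclass(frozen=True)
class SpectrumSeries:
    """CD intensities (mdeg) on a wavelength x temperature grid.

    ``intensity[i, j]`` is the signal at ``temperatures[i]`` (Celsius)
    and ``wavelengths[j]`` (nm); both grids strictly increasing.
    """

    wavelengths: np.ndarray
    temperatures: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.temperatures, dtype=float)
        m = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "intensity", m)
        if np.any(np.diff(wl) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("grids must be strictly increasing")
        if m.shape != (t.size, wl.size):
            raise ValueError(
                f"intensity shape {m.shape} != "
                f"(n_temperatures={t.size}, n_wavelengths={wl.size})"
            )

    def spectrum_at(self, temperature: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.temperatures - temperature)))
        return self.intensity[i]

    def wavelength_index(self, wavelength: float, tol: float = 1.0) -> int:
        j = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[j] - wavelength) > tol:
            raise ValueError(
                f"{wavelength} nm not on grid (nearest "
                f"{self.wavelengths[j]} nm, tolerance {tol} nm)"
            )
        return j


@dataclass(frozen=True)
class TopologyCall:
    """Classification of a single spectrum."""

    classification: str            # "parallel-like" or "other"
    peak_wavelength: float | None  # positive maximum in 260-270 nm
    peak_intensity: float | None
    trough_wavelength: float | None  # negative minimum in 235-245 nm
    trough_intensity: float | None


@dataclass(frozen=True)
class IsosbesticResult:
    wavelength: float
    spread: float              # cross-temperature variance at that lambda
    variance_profile: np.ndarray


@dataclass(frozen=True)
class LinearityResult:
    r: float
    slope: float
    intercept: float
    lambda1: float
    lambda2: float


def topology_signature(
    wavelengths: np.ndarray,
    intensity: np.ndarray,
    amplitude_threshold: float = 2.0,
) -> TopologyCall:
    """Call a spectrum parallel-like from its 265/240 nm signature.

    Parallel-like iff there is a positive maximum in 260-270 nm and a
    negative minimum in 235-245 nm, both exceeding ``amplitude_threshold``
    (mdeg) in magnitude. The threshold separates genuine quadruplex
    signatures from the residual structure of a non-folding variant.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if wavelengths[0] > 230.0 or wavelengths[-1] < 300.0:
        raise ValueError("wavelength range must cover 230-300 nm")
    peak_band = (wavelengths >= 260.0) & (wavelengths <= 270.0)
    trough_band = (wavelengths >= 235.0) & (wavelengths <= 245.0)
    i_peak = int(np.flatnonzero(peak_band)[np.argmax(intensity[peak_band])])
    i_trough = int(
        np.flatnonzero(trough_band)[np.argmin(intensity[trough_band])]
    )
    peak_val = float(intensity[i_peak])
    trough_val = float(intensity[i_trough])
    is_parallel = (peak_val > amplitude_threshold
                   and trough_val < -amplitude_threshold)
    return TopologyCall(
        classification="parallel-like" if is_parallel else "other",
        peak_wavelength=float(wavelengths[i_peak]),
        peak_intensity=peak_val,
        trough_wavelength=float(wavelengths[i_trough]),
        trough_intensity=trough_val,
    )


def isosbestic_point(series: SpectrumSeries) -> IsosbesticResult:
    """Locate the isosbestic point of a melting series.

    Returns the wavelength minimizing the variance of the raw intensity
    across temperatures, with that minimum variance as the spread. Ties
    resolve to the lowest wavelength (argmin convention); a genuinely
    two-state series has near-zero spread at the bases' crossing.
    """
    if series.temperatures.size < 3:
        raise ValueError("isosbestic analysis needs >= 3 temperatures")
    variance = np.var(series.intensity, axis=0)
    # ties (within float rounding of the profile's scale) resolve to the
    # lowest wavelength
    tol = np.min(variance) + 1e-12 * max(float(np.max(variance)), 1.0)
    j = int(np.flatnonzero(variance <= tol)[0])
    return IsosbesticResult(
        wavelength=float(series.wavelengths[j]),
        spread=float(variance[j]),
        variance_profile=variance,
    )


def two_state_linearity(
    series: SpectrumSeries,
    lambda1: float = 265.0,
    lambda2: float = 242.0,
) -> LinearityResult:
    """Pearson correlation of intensities at two wavelengths over T.

    For a two-state series the points (S(lambda2, T), S(lambda1, T)) lie
    on a straight line, so |r| = 1 up to noise. Constant signal at either
    wavelength leaves r undefined and raises.
    """
    j1 = series.wavelength_index(lambda1)
    j2 = series.wavelength_index(lambda2)
    y = series.intensity[:, j1]
    x = series.intensity[:, j2]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "constant signal at one wavelength: correlation undefined"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    return LinearityResult(r=r, slope=float(slope),
                           intercept=float(intercept),
                           lambda1=float(series.wavelengths[j1]),
                           lambda2=float(series.wavelengths[j2]))


def melting_curve_at(series: SpectrumSeries,
                     wavelength: float = 265.0,
                     replicate_id: str = "cd") -> MeltingCurve:
    """Extract the CD melting curve at one wavelength for van't Hoff fitting."""
    j = series.wavelength_index(wavelength)
    return MeltingCurve(
        temperatures=series.temperatures,
        signal=series.intensity[:, j],
        wavelength=float(series.wavelengths[j]),
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# CSV I/O (long format: temperature_C, wavelength_nm, intensity_mdeg)


def write_spectrum_csv(series: SpectrumSeries, path: str | Path) -> None:
    t_grid, wl_grid = np.meshgrid(series.temperatures, series.wavelengths,
                                  indexing="ij")
    pd.DataFrame({
        "temperature_C": t_grid.ravel(),
        "wavelength_nm": wl_grid.ravel(),
        "intensity_mdeg": series.intensity.ravel(),
    }).to_csv(path, index=False, float_format="%.10g")


def read_spectrum_csv(path: str | Path) -> SpectrumSeries:
    df = pd.read_csv(path)
    required = {"temperature_C", "wavelength_nm", "intensity_mdeg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pivot = df.pivot_table(index="temperature_C", columns="wavelength_nm",
                           values="intensity_mdeg")
    return SpectrumSeries(
        wavelengths=pivot.columns.to_numpy(dtype=float),
        temperatures=pivot.index.to_numpy(dtype=float),
        intensity=pivot.to_numpy(dtype=float),
    )
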