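"""Spectrophotometric transmission analysis.

Converts cuvette transmission measurements (%T versus wavelength, usually
in triplicate) into absorption-coefficient spectra via the Beer-Lambert
law, propagates replicate scatter into an error band, and calibrates the
per-unit-concentration absorption of candidate phantom absorbers by
through-origin linear regression.

The conversion attributes all attenuation to absorption; samples are
expected to be measured scattering-free (scatterer replaced by water).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TransmissionSpectrum",
    "AbsorptionSpectrum",
    "AbsorberCalibration",
    "transmission_to_absorption",
    "fit_calibration",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


@dataclass
class TransmissionSpectrum:
    """Replicate %T(lambda) measurements through a cuvette.

    Attributes
    ----------
    wavelengths : array, nm
        Strictly increasing wavelength grid.
    replicates : array, shape (n_wavelengths, n_replicates)
        Percent transmission values, each in (0, 100].
    path_length : float, cm
        Cuvette optical path length d.
    label : str
        Absorber name and concentration, free text.
    """

    wavelengths: np.ndarray
    replicates: np.ndarray
    path_length: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        if self.replicates.shape[0] != self.wavelengths.shape[0]:
            if self.replicates.shape[1] == self.wavelengths.shape[0]:
                self.replicates = self.replicates.T
            else:
                raise ValueError("replicates and wavelengths have incompatible shapes")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 1:
            raise ValueError("wavelengths must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.replicates <= 0) or np.any(self.replicates > 100):
            raise ValueError("%T values must lie in (0, 100]")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0 cm")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    def mean(self) -> np.ndarray:
        """Per-wavelength mean %T across replicates."""
        return self.replicates.mean(axis=1)

    def std(self, ddof: int = 1) -> np.ndarray:
        """Per-wavelength replicate standard deviation (sample, n-1, by default)."""
        if self.n_replicates < 2:
            return np.zeros_like(self.wavelengths)
        return self.replicates.std(axis=1, ddof=ddof)


@dataclass
class AbsorptionSpectrum:
    """Absorption coefficient spectrum with a one-sigma error band (cm^-1)."""

    wavelengths: np.ndarray
    mu_a: np.ndarray
    delta_mu_a: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.delta_mu_a = np.asarray(self.delta_mu_a, dtype=float)
        if np.any(self.delta_mu_a < 0):
            raise ValueError("delta_mu_a must be >= 0")

    def at(self, wavelength_nm: float) -> tuple[float, float]:
        """(mu_a, delta_mu_a) linearly interpolated at one wavelength."""
        mu = float(np.interp(wavelength_nm, self.wavelengths, self.mu_a))
        d = float(np.interp(wavelength_nm, self.wavelengths, self.delta_mu_a))
        return mu, d


@dataclass(frozen=True)
class AbsorberCalibration:
    """Through-origin linear calibration mu_a = slope * concentration at one wavelength."""

    name: str
    wavelength: float
    slope: float
    slope_units: str = "cm^-1 per g/L"
    fit_r2: float = float("nan")

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "wavelength_nm": self.wavelength,
            "slope": self.slope,
            "slope_units": self.slope_units,
            "r2": self.fit_r2,
        }


def transmission_to_absorption(
    spectrum: TransmissionSpectrum,
    *,
    ddof: int = 1,
    sigma: np.ndarray | float | None = None,
) -> AbsorptionSpectrum:
    """Beer-Lambert conversion of %T to mu_a with first-order error propagation.

    Per wavelength, with %T_bar the replicate mean and sigma the replicate
    standard deviation (both on the percent scale):

        mu_a       = -(1/d) * ln(%T_bar / 100)
        delta mu_a = |d mu_a / d %T| * sigma = sigma / (d * %T_bar)

    Parameters
    ----------
    spectrum : TransmissionSpectrum
    ddof : int
        Delta degrees of freedom for the replicate standard deviation
        (1 = sample standard deviation, the default).
    sigma : array or float, optional
        Known per-wavelength measurement noise (percent-transmission units)
        to use in place of the replicate estimate — e.g. an instrument
        characterisation, or when only a single replicate is available.

    Notes
    -----
    All attenuation is attributed to absorption (scattering-free sample);
    this assumption is logged on every call.
    """
    logger.info(
        "transmission_to_absorption: attributing all attenuation to absorption "
        "(scattering-free sample assumed) for %r",
        spectrum.label or "<unlabelled spectrum>",
    )
    t_bar = spectrum.mean()
    if np.any(t_bar <= 0):
        raise ValueError("mean %T must be > 0 at every wavelength")
    if sigma is None:
        if spectrum.n_replicates < 2:
            logger.warning(
                "single replicate and no known sigma supplied: delta_mu_a set to 0"
            )
            sig = np.zeros_like(t_bar)
        else:
            sig = spectrum.std(ddof=ddof)
    else:
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), t_bar.shape)
    d = spectrum.path_length
    mu_a = -np.log(t_bar / 100.0) / d
    delta = sig / (d * t_bar)
    return AbsorptionSpectrum(
        wavelengths=spectrum.wavelengths.copy(),
        mu_a=mu_a,
        delta_mu_a=delta,
        label=spectrum.label,
    )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    *,
    name: str = "",
    wavelength: float = float("nan"),
    slope_units: str = "cm^-1 per g/L",
) -> AbsorberCalibration:
    """Through-origin least-squares calibration of mu_a versus concentration.

    The slope is sum(c*mu) / sum(c^2); R^2 is computed relative to the
    origin-constrained model (uncentered total sum of squares), so a
    single point always yields R^2 = 1.

    Raises
    ------
    ValueError
        If no points are given, any concentration is negative, or all
        concentrations are zero.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one (concentration, mu_a) point")
    c, mu = pts[:, 0], pts[:, 1]
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    denom = float(np.sum(c**2))
    if denom == 0:
        raise ValueError("all concentrations are zero: slope is undefined")
    slope = float(np.sum(c * mu) / denom)
    ss_res = float(np.sum((mu - slope * c) ** 2))
    ss_tot = float(np.sum(mu**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AbsorberCalibration(
        name=name, wavelength=wavelength, slope=slope, slope_units=slope_units, fit_r2=r2
    )


def read_spectrum_csv(
    path: str | Path, path_length: float = 1.0, *, label: str = ""
) -> TransmissionSpectrum:
    """Read a transmission spectrum CSV with columns ``wavelength_nm, T1_pct, ...``.

    Non-monotone wavelength grids are sorted with a warning.  Out-of-range
    %T values or non-numeric cells raise a ``ValueError`` naming the first
    offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "wavelength_nm" not in cols:
        raise ValueError(f"{path}: missing 'wavelength_nm' column (found {cols})")
    rep_cols = [c for c in cols if c != "wavelength_nm"]
    if not rep_cols:
        raise ValueError(f"{path}: no replicate %T columns found")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: non-numeric cell in data row {row}")
    t = numeric[rep_cols].to_numpy()
    out_of_range = (t <= 0) | (t > 100)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.any(axis=1))[0]) + 1
        raise ValueError(f"{path}: %T outside (0, 100] in data row {row}")
    w = numeric["wavelength_nm"].to_numpy()
    if np.any(np.diff(w) <= 0):
        logger.warning("%s: wavelength grid not strictly increasing; sorting", path)
        order = np.argsort(w, kind="stable")
        w, t = w[order], t[order]
        if np.any(np.diff(w) <= 0):
            raise ValueError(f"{path}: duplicate wavelengths in grid")
    return TransmissionSpectrum(
        wavelengths=w, replicates=t, path_length=path_length, label=label or str(path)
    )


def write_spectrum_csv(spectrum: TransmissionSpectrum, path: str | Path) -> None:
    """Write a spectrum in the CSV dialect understood by :func:`read_spectrum_csv`."""
    data = {"wavelength_nm": spectrum.wavelengths}
    for i in range(spectrum.n_replicates):
        data[f"T{i + 1}_pct"] = spectrum.replicates[:, i]
    pd.DataFrame(data).to_csv(path, index=False)
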