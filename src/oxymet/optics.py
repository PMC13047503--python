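"""Forward optics for broadband near-infrared spectroscopy.

This module holds the pieces shared by the spectral fitter and the
simulator: wavelength-indexed specific absorption (extinction) tables,
the modified Beer--Lambert forward attenuation model, and the smoothed
second-derivative operator used to remove the (assumed constant)
scattering baseline from measured spectra.

Units
-----
* wavelengths: nm, on a strictly increasing regular grid
* extinction coefficients: OD · µM⁻¹ · cm⁻¹ for hemoglobin and
  cytochrome-c-oxidase species; OD · M⁻¹ · cm⁻¹ for water (the water
  *concentration* is carried explicitly as volume fraction × molarity
  of pure water, so the table entry stays per-molar)
* attenuation: OD; second derivatives: OD/nm²
* pathlength: cm
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "PURE_WATER_MOLARITY_M",
    "REQUIRED_CHROMOPHORES",
    "DEFAULT_GRID_NM",
    "ExtinctionTable",
    "TissueState",
    "AttenuationSpectrum",
    "ExtinctionSchemaError",
    "GridError",
    "load_extinction_table",
    "attenuation_forward",
    "second_derivative",
    "second_derivative_operator",
]

#: molar concentration of pure water (mol/L); tissue water enters the
#: Beer–Lambert sum as volume_fraction × this value.
PURE_WATER_MOLARITY_M = 55.5

REQUIRED_CHROMOPHORES = ("HbO2", "dHb", "oxCCO", "reCCO", "water")

#: default working grid: 1 nm spacing over the acquisition range.
DEFAULT_GRID_NM = np.arange(705.0, 961.0, 1.0)

_BUILTIN_TABLES = {"synthetic": "extinction_synthetic.csv"}


class ExtinctionSchemaError(ValueError):
    """Extinction table is missing required chromophores or has extras."""


class GridError(ValueError):
    """Wavelength grid is not strictly increasing / regular."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ExtinctionTable:
    """Specific absorption coefficients on a common wavelength grid."""

    wavelengths: np.ndarray
    epsilon: Mapping[str, np.ndarray]
    metadata: str = ""

    def __post_init__(self):
        wl = _as_1d_float(self.wavelengths, "wavelengths")
        object.__setattr__(self, "wavelengths", wl)
        if wl.size < 3:
            raise GridError("wavelength grid needs at least 3 points")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        eps = {}
        for name, vec in dict(self.epsilon).items():
            v = _as_1d_float(vec, f"epsilon[{name}]")
            if v.size != wl.size:
                raise ExtinctionSchemaError(
                    f"coefficient vector for {name!r} has length {v.size}, "
                    f"grid has {wl.size}"
                )
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ExtinctionSchemaError(
                    f"coefficients for {name!r} must be finite and >= 0"
                )
            eps[name] = v
        missing = set(REQUIRED_CHROMOPHORES) - set(eps)
        if missing:
            raise ExtinctionSchemaError(f"missing required chromophores: {sorted(missing)}")
        object.__setattr__(self, "epsilon", eps)

    @property
    def spacing(self) -> float:
        d = np.diff(self.wavelengths)
        if not np.allclose(d, d[0]):
            raise GridError("grid is not regularly spaced")
        return float(d[0])

    def value(self, name: str, wavelength_nm) -> np.ndarray | float:
        """Coefficient at arbitrary wavelengths by linear interpolation."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise GridError(f"wavelength outside table range [{lo}, {hi}] nm")
        out = np.interp(lam, self.wavelengths, self.epsilon[name])
        return float(out) if np.ndim(wavelength_nm) == 0 else out

    def resample(self, grid) -> "ExtinctionTable":
        """Linear resampling onto a new grid (identity on the same grid)."""
        grid = _as_1d_float(grid, "grid")
        if grid.size == self.wavelengths.size and np.array_equal(grid, self.wavelengths):
            return self
        eps = {name: self.value(name, grid) for name in self.epsilon}
        return ExtinctionTable(grid, eps, metadata=self.metadata)

    def matrix(self, names) -> np.ndarray:
        """Column-stack coefficient vectors, shape (n_wavelengths, len(names))."""
        return np.column_stack([self.epsilon[n] for n in names])

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        idx = np.nonzero((self.wavelengths >= lo_nm) & (self.wavelengths <= hi_nm))[0]
        if idx.size == 0:
            raise GridError(f"window [{lo_nm}, {hi_nm}] nm is outside the grid")
        return idx

    def to_csv(self, path) -> None:
        cols = {"wavelength_nm": self.wavelengths}
        cols.update({n: self.epsilon[n] for n in REQUIRED_CHROMOPHORES})
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class TissueState:
    """Ground-truth optical state of a tissue volume.

    ``concentrations`` maps chromophore name to µM, except ``water``
    which is a dimensionless volume fraction in [0, 1].  ``baseline``
    is the scattering offset/slope (a, b) of S(λ) = a + b·λ in OD and
    OD/nm.
    """

    concentrations: Mapping[str, float]
    pathlength_L: float
    baseline: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        conc = dict(self.concentrations)
        for name, c in conc.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"concentration of {name!r} must be finite and >= 0")
        w = conc.get("water", 0.0)
        if not 0.0 <= w <= 1.0:
            raise ValueError("water fraction must lie in [0, 1]")
        if not (np.isfinite(self.pathlength_L) and self.pathlength_L > 0):
            raise ValueError("pathlength_L must be positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "baseline", (float(self.baseline[0]), float(self.baseline[1])))


@dataclass(frozen=True)
class AttenuationSpectrum:
    """A single attenuation spectrum A(λ) in OD (or OD/nm² after differentiation)."""

    wavelengths: np.ndarray
    attenuation: np.ndarray
    timestamp: float | None = None

    def __post_init__(self):
        wl = _as_1d_float(self.wavelengths, "wavelengths")
        at = _as_1d_float(self.attenuation, "attenuation")
        if wl.size != at.size:
            raise ValueError("wavelengths and attenuation must have the same length")
        if not np.all(np.isfinite(at)):
            raise ValueError("attenuation values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "attenuation", at)


def load_extinction_table(source="synthetic", grid=None) -> ExtinctionTable:
    """Load a chromophore extinction table and resample it to a working grid.

    Parameters
    ----------
    source:
        Either the name of a bundled table (``"synthetic"``) or a path to
        a CSV file with header ``wavelength_nm,HbO2,dHb,oxCCO,reCCO,water``.
    grid:
        Target wavelength grid in nm; defaults to 1 nm over 705–960 nm.

    The bundled table is a synthetic surrogate with literature-shaped
    curves (deoxyhemoglobin band near 760 nm, the 800–850 nm water
    feature with the 970 nm shoulder, broad oxidized/reduced CCO bands);
    see its ``metadata`` field for provenance.
    """
    if grid is None:
        grid = DEFAULT_GRID_NM
    if isinstance(source, str) and source in _BUILTIN_TABLES:
        ref = resources.files("oxymet.data") / _BUILTIN_TABLES[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
        meta = (
            "synthetic surrogate extinction curves (not the UCL reference "
            "compilation); shapes chosen to mimic published NIR features"
        )
    else:
        df = pd.read_csv(source)
        meta = f"user table: {source}"
    if "wavelength_nm" not in df.columns:
        raise ExtinctionSchemaError("CSV must contain a 'wavelength_nm' column")
    extras = set(df.columns) - {"wavelength_nm", *REQUIRED_CHROMOPHORES}
    if extras:
        raise ExtinctionSchemaError(f"unknown chromophore columns: {sorted(extras)}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise GridError("wavelength_nm column must be strictly increasing")
    eps = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "wavelength_nm"}
    table = ExtinctionTable(wl, eps, metadata=meta)
    return table.resample(grid)


def attenuation_forward(state: TissueState, table: ExtinctionTable) -> AttenuationSpectrum:
    """Modified Beer–Lambert forward model.

    A(λ) = L · Σᵢ εᵢ(λ)·cᵢ + a + b·λ, where the water term uses
    fraction × molarity of pure water so that the per-molar table entry
    and the dimensionless fraction combine into an absorption in OD.
    """
    lam = table.wavelengths
    total = np.zeros_like(lam)
    for name, conc in state.concentrations.items():
        if name not in table.epsilon:
            raise KeyError(f"chromophore {name!r} not present in extinction table")
        c_eff = conc * PURE_WATER_MOLARITY_M if name == "water" else conc
        total += table.epsilon[name] * c_eff
    a, b = state.baseline
    atten = state.pathlength_L * total + a + b * lam
    return AttenuationSpectrum(lam, atten)


def second_derivative_operator(values, spacing: float, window_length: int = 11, polyorder: int = 3):
    """Savitzky–Golay smoothed second derivative along the last axis.

    Works on 1-D spectra or (n_frames, n_wavelengths) arrays.  Edge
    policy: local polynomial extrapolation (``mode='interp'``), which
    reproduces polynomial inputs exactly across the full output length.
    """
    values = np.asarray(values, dtype=float)
    if window_length % 2 == 0 or window_length <= polyorder:
        raise ValueError("window_length must be odd and greater than polyorder")
    if values.shape[-1] < window_length:
        raise ValueError("spectrum shorter than the smoothing window")
    return savgol_filter(
        values, window_length, polyorder, deriv=2, delta=spacing, axis=-1, mode="interp"
    )


def second_derivative(
    spectrum: AttenuationSpectrum, window_length: int = 11, polyorder: int = 3
) -> AttenuationSpectrum:
    """Smoothed d²A/dλ² of a spectrum (units OD/nm²), same grid and length."""
    wl = spectrum.wavelengths
    d = np.diff(wl)
    if not np.allclose(d, d[0]):
        raise GridError("second derivative requires a regular wavelength grid")
    d2 = second_derivative_operator(
        spectrum.attenuation, float(d[0]), window_length, polyorder
    )
    return AttenuationSpectrum(wl, d2, timestamp=spectrum.timestamp)
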