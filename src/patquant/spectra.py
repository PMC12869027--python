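"""Chromophore extinction tables and absorption-spectrum assembly.

The photoacoustic forward model ties the initial pressure to optical absorption,
``p0 = Gamma * phi * mu_a``, and absorption to chromophore concentrations,
``mu_a(lambda) = sum_k c_k eps_k(lambda)``.  This module holds the sampled-spectrum
containers and the bundled extinction tables for the four chromophores used
throughout: oxy-/deoxy-hemoglobin (HbO2, Hb) and their phantom surrogates
nickel and copper sulfate (NiSO4, CuSO4).

Tables are shipped as CSV (``wavelength_nm,value``; unit in a leading ``#``
comment), tabulated 650-950 nm at 2-nm spacing.  Values between knots are
linearly interpolated; requests outside the tabulated range raise instead of
extrapolating.  The bundled hemoglobin curves cross near 804 nm and are
near-isosbestic (within 5%) at both 800 and 808 nm; the package normalizes
compensating fluence spectra at 800 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

from .errors import ChromophoreLookupError, WavelengthRangeError

#: wavelength (nm) where the bundled HbO2/Hb tables cross
ISOSBESTIC_NM = 804.0

#: default normalization wavelength for compensating fluence spectra
REFERENCE_NM = 800.0

_BUNDLED = {"HbO2": "extinction_hbo2.csv", "Hb": "extinction_hb.csv",
            "NiSO4": "extinction_niso4.csv", "CuSO4": "extinction_cuso4.csv"}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing optical wavelengths in nm, within [650, 950]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a wavelength grid needs at least 2 wavelengths")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if v[0] < 650.0 or v[-1] > 950.0:
            raise WavelengthRangeError("wavelengths must lie within [650, 950] nm")

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and \
            self.values.shape == other.values.shape and \
            bool(np.all(self.values == other.values))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid wavelength; raises if absent."""
        idx = np.nonzero(np.isclose(self.values, wavelength_nm))[0]
        if idx.size == 0:
            raise ValueError(f"{wavelength_nm} nm is not on the grid")
        return int(idx[0])

    def nearest(self, wavelength_nm: float) -> float:
        """Grid wavelength closest to the request (ties go to the shorter one)."""
        return float(self.values[np.argmin(np.abs(self.values - wavelength_nm))])


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength on a shared grid.

    The amplitude unit depends on role: extinction in cm^-1 M^-1 (or cm^-1 per
    g/L for the sulfates), fluence dimensionless after normalization, pressure
    in arbitrary units.
    """

    grid: WavelengthGrid
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        if a.shape != (len(self.grid),):
            raise ValueError("amplitudes length must equal grid length")
        if not np.all(np.isfinite(a)):
            raise ValueError("spectrum amplitudes must be finite")

    def at(self, wavelength_nm: float) -> float:
        return float(self.amplitudes[self.grid.index_of(wavelength_nm)])

    def normalized_at(self, wavelength_nm: float) -> "Spectrum":
        ref = self.at(wavelength_nm)
        if ref <= 0:
            raise ValueError("cannot normalize at a non-positive amplitude")
        return Spectrum(self.grid, self.amplitudes / ref)

    def interpolated_to(self, grid: WavelengthGrid) -> "Spectrum":
        """Linear interpolation onto another grid (no extrapolation)."""
        lo, hi = self.grid.values[0], self.grid.values[-1]
        if grid.values[0] < lo or grid.values[-1] > hi:
            raise WavelengthRangeError(
                f"target grid exceeds the tabulated range [{lo}, {hi}] nm")
        return Spectrum(grid, np.interp(grid.values, self.grid.values, self.amplitudes))


@dataclass
class ExtinctionTable:
    """Mapping chromophore name -> tabulated extinction spectrum."""

    entries: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, name: str, wavelengths_nm: Iterable[float],
            values: Iterable[float], note: str = "") -> None:
        wl = np.asarray(list(wavelengths_nm), float)
        v = np.asarray(list(values), float)
        if np.any(v < 0):
            raise ValueError("extinction values must be non-negative")
        self.entries[name] = (wl, v)
        self.metadata[name] = note

    def _lookup(self, name: str):
        for key in self.entries:
            if key.lower() == name.lower():
                return self.entries[key]
        raise ChromophoreLookupError(name)

    def names(self):
        return list(self.entries)


def get_extinction(name: str, grid: WavelengthGrid,
                   table: ExtinctionTable | None = None) -> Spectrum:
    """Extinction spectrum of a chromophore interpolated onto ``grid``.

    Linear interpolation between tabulated knots; requests outside the
    tabulated range raise :class:`WavelengthRangeError`.
    """
    table = table if table is not None else load_default_table()
    wl, v = table._lookup(name)
    if grid.values[0] < wl[0] or grid.values[-1] > wl[-1]:
        raise WavelengthRangeError(
            f"grid outside tabulated range [{wl[0]}, {wl[-1]}] nm for {name}")
    return Spectrum(grid, np.interp(grid.values, wl, v))


def build_absorption(concentrations: Mapping[str, float], table: ExtinctionTable,
                     grid: WavelengthGrid) -> Spectrum:
    """Absorption spectrum ``mu_a(lambda) = sum_k c_k eps_k(lambda)`` on ``grid``.

    Concentration units follow each table entry's header (molar for the Hb
    species, g/L for the sulfates).  Linear in every concentration.
    """
    out = np.zeros(len(grid))
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
        out += c * get_extinction(name, grid, table).amplitudes
    return Spectrum(grid, out)


_default_table: ExtinctionTable | None = None


def load_default_table() -> ExtinctionTable:
    """The bundled HbO2/Hb/NiSO4/CuSO4 table (cached)."""
    global _default_table
    if _default_table is None:
        t = ExtinctionTable()
        for name, fname in _BUNDLED.items():
            text = resources.files("patquant.data").joinpath(fname).read_text()
            note_lines, wl, vals = [], [], []
            for line in text.splitlines():
                if line.startswith("#"):
                    note_lines.append(line.lstrip("# "))
                elif line and not line.startswith("wavelength"):
                    w, v = line.split(",")
                    wl.append(float(w))
                    vals.append(float(v))
            t.add(name, wl, vals, note=" ".join(note_lines))
        _default_table = t
    return _default_table
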