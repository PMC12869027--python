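"""Spectral estimators: linear unmixing (LU), compensated linear unmixing
(CLU), and the convex-cone (CC) angular-distance method.

All three map a measured photoacoustic amplitude spectrum p0(lambda) at one
location (or cluster) to non-negative chromophore concentrations and derived
quantities:

    %sO2 = 100 * c_ox / (c_ox + c_de)        THb = c_ox + c_de

LU assumes a wavelength-flat fluence (p0 proportional to mu_a) and solves a
non-negative least-squares fit against the two extinction spectra.  CLU first
divides p0 by a single representative fluence spectrum phi_ave.  CC represents
the unknown fluence as a non-negative combination of simulated eigenspectra
and picks the candidate saturation whose cone lies at the smallest angle from
the measured spectrum.

Because the Grueneisen coefficient and laser energy are unknown positive
per-location scales, concentrations and THb are relative; %sO2 is
scale-invariant for all three methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import CompensationDomainError
from .photon_sim import EigenspectraSet
from .spectra import ExtinctionTable, Spectrum, WavelengthGrid, get_extinction

__all__ = ["PressureSpectrum", "UnmixResult", "lu_unmix", "clu_unmix",
           "cc_estimate", "so2_from_conc", "thb_from_conc",
           "DEFAULT_SO2_GRID_STEP"]

DEFAULT_SO2_GRID_STEP = 0.5

HB_PAIR = ("HbO2", "Hb")
SULFATE_PAIR = ("NiSO4", "CuSO4")


@dataclass(frozen=True)
class PressureSpectrum:
    """Beamformed pressure amplitudes (arbitrary units) at one location."""

    grid: WavelengthGrid
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, float)
        object.__setattr__(self, "amplitudes", a)
        if a.shape != (len(self.grid),):
            raise ValueError("amplitudes length must equal grid length")
        if not np.all(np.isfinite(a)):
            raise ValueError("pressure amplitudes must be finite")
        if len(self.grid) < 3:
            raise ValueError("unmixing needs at least 3 wavelengths")


@dataclass(frozen=True)
class UnmixResult:
    c_ox: float
    c_de: float
    so2_pct: float  # NaN when undefined (zero total concentration)
    thb_rel: float
    method: str
    residual: float

    @property
    def so2_defined(self) -> bool:
        return not math.isnan(self.so2_pct)


def so2_from_conc(c_ox: float, c_de: float) -> float:
    """Saturation percentage; NaN when both concentrations are zero."""
    if c_ox < 0 or c_de < 0:
        raise ValueError("concentrations must be non-negative")
    tot = c_ox + c_de
    if tot <= 0:
        return float("nan")
    # ratio first, then scale: keeps the result in [0, 100] to the last ulp
    return min(100.0, max(0.0, 100.0 * (c_ox / tot)))


def thb_from_conc(c_ox: float, c_de: float) -> float:
    if c_ox < 0 or c_de < 0:
        raise ValueError("concentrations must be non-negative")
    return c_ox + c_de


def _design_matrix(grid: WavelengthGrid, table: ExtinctionTable,
                   species_pair: tuple) -> np.ndarray:
    ox, de = species_pair
    return np.column_stack([get_extinction(ox, grid, table).amplitudes,
                            get_extinction(de, grid, table).amplitudes])


def lu_unmix(p: PressureSpectrum, table: ExtinctionTable,
             species_pair: tuple = HB_PAIR) -> UnmixResult:
    """Non-negative least-squares fit of p0 against the two extinction
    spectra, treating p0 as the absorption proxy (flat-fluence assumption)."""
    if not np.any(p.amplitudes):
        return UnmixResult(0.0, 0.0, float("nan"), 0.0, "LU", 0.0)
    e = _design_matrix(p.grid, table, species_pair)
    c, rnorm = nnls(e, p.amplitudes)
    c_ox, c_de = float(c[0]), float(c[1])
    return UnmixResult(c_ox, c_de, so2_from_conc(c_ox, c_de),
                       thb_from_conc(c_ox, c_de), "LU", float(rnorm))


def clu_unmix(p: PressureSpectrum, phi_ave: Spectrum, table: ExtinctionTable,
              species_pair: tuple = HB_PAIR) -> UnmixResult:
    """LU applied to the spectrally compensated spectrum p0 / phi_ave.

    phi_ave may be tabulated on a superset grid (e.g. simulated at 11
    wavelengths, applied at a 4-wavelength clinical subset); it is
    interpolated onto p's grid and must be strictly positive there.
    """
    phi = phi_ave.amplitudes if phi_ave.grid == p.grid \
        else phi_ave.interpolated_to(p.grid).amplitudes
    if np.any(phi <= 0):
        raise CompensationDomainError("phi_ave must be strictly positive on the grid")
    res = lu_unmix(PressureSpectrum(p.grid, p.amplitudes / phi), table, species_pair)
    return UnmixResult(res.c_ox, res.c_de, res.so2_pct, res.thb_rel, "CLU",
                       res.residual)


def _mixture_extinction(e: np.ndarray, s_pct: float) -> np.ndarray:
    """mu_a(lambda; s) at unit total concentration."""
    f = s_pct / 100.0
    return f * e[:, 0] + (1.0 - f) * e[:, 1]


def cc_estimate(p: PressureSpectrum, eig: EigenspectraSet,
                table: ExtinctionTable, species_pair: tuple = HB_PAIR,
                so2_grid: np.ndarray | None = None) -> UnmixResult:
    """Convex-cone saturation estimate by angular-distance minimization.

    For every candidate saturation s, the generators g_i = phi_i * mu_a(.; s)
    span the cone of spectra realizable under any non-negative fluence
    combination; the measured spectrum's angle to the cone is the angle to its
    non-negative least-squares projection.  The winning s (smallest angle;
    ties to the smallest s) is returned with residual = angle in radians, and
    (c_ox, c_de) split the projection magnitude (L2 norm, relative units)
    according to s.
    """
    if so2_grid is None:
        so2_grid = np.arange(0.0, 100.0 + 1e-9, DEFAULT_SO2_GRID_STEP)
    so2_grid = np.asarray(so2_grid, float)
    if so2_grid.size == 0 or so2_grid.min() < 0 or so2_grid.max() > 100:
        raise ValueError("so2_grid must be non-empty with values in [0, 100]")

    pnorm = float(np.linalg.norm(p.amplitudes))
    if pnorm <= 0:
        return UnmixResult(0.0, 0.0, float("nan"), 0.0, "CC", float("nan"))

    phis = np.column_stack([s.interpolated_to(p.grid).amplitudes
                            if s.grid != p.grid else s.amplitudes
                            for s in eig.spectra])  # (n_wl, n_eig)
    e = _design_matrix(p.grid, table, species_pair)

    best_angle = np.inf
    best_s = float(so2_grid[0])
    best_proj = np.zeros_like(p.amplitudes)
    for s in so2_grid:
        gens = phis * _mixture_extinction(e, s)[:, None]
        coef, _ = nnls(gens, p.amplitudes)
        proj = gens @ coef
        nproj = np.linalg.norm(proj)
        if nproj <= 0:
            angle = np.pi / 2
        else:
            # chord form of the angle between unit vectors: exact near zero,
            # where arccos of a dot product loses all precision
            chord = np.linalg.norm(p.amplitudes / pnorm - proj / nproj)
            angle = float(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
        if angle < best_angle - 1e-15:
            best_angle, best_s, best_proj = angle, float(s), proj

    thb = float(np.linalg.norm(best_proj))
    c_ox = thb * best_s / 100.0
    c_de = thb * (1.0 - best_s / 100.0)
    so2 = best_s if thb > 0 else float("nan")
    return UnmixResult(c_ox, c_de, so2, thb, "CC", best_angle)
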