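"""Depth-wise fluence/acoustic compensation and whole-image quantification.

Measured photoacoustic amplitude decays with depth both optically (fluence
attenuation on the way in, coefficient mu_f) and acoustically (attenuation of
the generated pressure wave on the way out, coefficient mu_b).  Both are
modeled as single exponentials and undone jointly:

    p_compensated(z, lambda) = p(z, lambda) * exp[(mu_f + mu_b) * z]

with z the depth from the transducer face in cm.  The factor is the same at
every wavelength, so it rescales THb but cancels in %sO2.

The integrated spectral and depth compensation (ISDC) pipeline combines this
with CLU spectral compensation: %sO2 from CLU (depth factor irrelevant), THb
from CLU on the depth-compensated map.

mu_f comes from a Monte-Carlo fit (``fit_depth_attenuation``); mu_b must be
supplied by the user (in the clinical workflow it comes from co-registered
ultrasound, which is outside this package's scope).  The bundled default of
0.5 cm^-1 is a placeholder for synthetic studies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .photon_sim import DepthModel
from .spectra import ExtinctionTable, Spectrum, WavelengthGrid
from .unmix import HB_PAIR, PressureSpectrum, clu_unmix, lu_unmix

__all__ = ["PressureMap", "QuantMaps", "compensate_depth", "lu_maps",
           "clu_maps", "isdc_maps", "DEFAULT_MU_B", "AMPLITUDE_FLOOR_FRAC"]

#: placeholder acoustic attenuation for synthetic studies (cm^-1)
DEFAULT_MU_B = 0.5

#: pixels dimmer than this fraction of the 99th-percentile amplitude are
#: flagged undefined (maps are only meaningful on vascular/ROI signal)
AMPLITUDE_FLOOR_FRAC = 0.05


@dataclass
class PressureMap:
    """Per-wavelength beamformed pressure images (n_wavelengths, nz, nx)."""

    grid: WavelengthGrid
    images: np.ndarray
    pixel_size_mm: float
    z0_cm: float = 0.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, float)
        if self.images.ndim != 3 or self.images.shape[0] != len(self.grid):
            raise ValueError("images must be (n_wavelengths, nz, nx)")
        if self.pixel_size_mm <= 0 or self.z0_cm < 0:
            raise ValueError("pixel_size must be positive and z0 non-negative")
        if self.mask is not None and self.mask.shape != self.images.shape[1:]:
            raise ValueError("mask shape must match the image shape")

    @property
    def nz(self) -> int:
        return self.images.shape[1]

    @property
    def nx(self) -> int:
        return self.images.shape[2]

    def depths_cm(self) -> np.ndarray:
        """Depth of each row (row 0 shallowest): z0 + i * pixel_size."""
        return self.z0_cm + np.arange(self.nz) * self.pixel_size_mm / 10.0


@dataclass
class QuantMaps:
    """%sO2 (NaN where undefined) and relative THb images."""

    so2_map: np.ndarray
    thb_map: np.ndarray
    method: str
    depth_model: Optional[DepthModel] = None
    grid: Optional[WavelengthGrid] = None
    pixel_size_mm: float = 0.0
    z0_cm: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        defined = ~np.isnan(self.so2_map)
        if np.any((self.so2_map[defined] < 0) | (self.so2_map[defined] > 100)):
            raise ValueError("defined so2 values must lie in [0, 100]")
        if np.any(self.thb_map < 0):
            raise ValueError("thb must be non-negative")


def compensate_depth(m: PressureMap, model: DepthModel) -> PressureMap:
    """Multiply every pixel at depth z by exp[(mu_f + mu_b) z], identically at
    all wavelengths."""
    factor = np.exp((model.mu_f + model.mu_b) * m.depths_cm())
    return PressureMap(m.grid, m.images * factor[None, :, None],
                       m.pixel_size_mm, m.z0_cm, m.mask)


def _pixel_selection(m: PressureMap) -> np.ndarray:
    amp = np.abs(m.images).max(axis=0)
    floor = AMPLITUDE_FLOOR_FRAC * np.percentile(amp, 99)
    sel = amp >= floor
    if m.mask is not None:
        sel &= m.mask
    return sel


def _unmix_map(m: PressureMap, method: str, phi_ave: Optional[Spectrum],
               table: ExtinctionTable, species_pair: tuple,
               depth_model: Optional[DepthModel]) -> QuantMaps:
    sel = _pixel_selection(m)
    so2 = np.full(m.images.shape[1:], np.nan)
    thb = np.zeros(m.images.shape[1:])
    for iz, ix in zip(*np.nonzero(sel)):
        p = PressureSpectrum(m.grid, m.images[:, iz, ix])
        if method == "LU":
            r = lu_unmix(p, table, species_pair)
        else:
            r = clu_unmix(p, phi_ave, table, species_pair)
        so2[iz, ix] = r.so2_pct
        thb[iz, ix] = r.thb_rel
    return QuantMaps(so2, thb, method, depth_model, m.grid, m.pixel_size_mm,
                     m.z0_cm)


def lu_maps(m: PressureMap, table: ExtinctionTable,
            species_pair: tuple = HB_PAIR) -> QuantMaps:
    """Per-pixel LU over the mask; sub-floor pixels are flagged undefined
    (NaN %sO2, zero THb)."""
    return _unmix_map(m, "LU", None, table, species_pair, None)


def clu_maps(m: PressureMap, phi_ave: Spectrum, table: ExtinctionTable,
             species_pair: tuple = HB_PAIR) -> QuantMaps:
    """Per-pixel CLU (spectral compensation only, no depth correction)."""
    q = _unmix_map(m, "CLU", phi_ave, table, species_pair, None)
    return q


def isdc_maps(m: PressureMap, phi_ave: Spectrum, model: DepthModel,
              table: ExtinctionTable, species_pair: tuple = HB_PAIR) -> QuantMaps:
    """Integrated spectral and depth compensation.

    The depth factor is wavelength-independent, so CLU on the depth-compensated
    map yields the CLU %sO2 unchanged while THb absorbs the exp[(mu_f+mu_b) z]
    restoration.  A single CLU pass over the compensated map therefore produces
    both maps.
    """
    comp = compensate_depth(m, model)
    q = _unmix_map(comp, "CLU", phi_ave, table, species_pair, model)
    return QuantMaps(q.so2_map, q.thb_map, "ISDC", model, m.grid,
                     m.pixel_size_mm, m.z0_cm)
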